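# Pinned default hyperparameters for the regressor zoo.
#
# Values are the library defaults at the versions this package was developed
# against, recorded explicitly so that results survive library upgrades.
# Deviations from library defaults (all iteration caps, raised to avoid
# spurious non-convergence on small feature matrices) are marked "# pinned".
linear: {}
lasso:
  alpha: 1.0
  max_iter: 10000        # pinned (library default 1000)
decision_tree: {}
random_forest:
  n_estimators: 100
svr:
  kernel: rbf
  C: 1.0
  epsilon: 0.1
  gamma: scale
mlp:
  hidden_layer_sizes: [100]
  activation: relu
  solver: adam
  max_iter: 2000         # pinned (library default 200)
enr:
  alpha: 1.0
  l1_ratio: 0.5
  max_iter: 10000        # pinned (library default 1000)
xgb:
  n_estimators: 100
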