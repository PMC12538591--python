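# Methods

This note records the model, the data-processing conventions, the synthetic
benchmark design, and the numerical and design choices behind `enztherm`,
at the level of detail a maintainer or reviewer needs to reason about the
results the tests and `scripts/acceptance.py` compute.

## The decomposition

A sequence's activity–temperature behaviour is factored into three
quantities, each with its own training table derived from the raw activity
records:

- **T_opt** — per sequence, the temperature at which its highest kcat/Km
  was recorded. For a sequence measured at a single temperature, that
  temperature is taken as T_opt (and its value as the maximum). Ties at the
  maximum are broken toward the lowest temperature by default
  (configurable); the conservative choice, since reported optima err low
  when profiles plateau.
- **log10 kcat/Km,max** — log10 of the maximum. The log transform makes the
  heavy-tailed efficiency distribution approximately normal, which is the
  scale on which the regressors and metrics operate throughout.
- **relative profile** — every record becomes a point
  (ΔT = T − T_opt, rel = kcat/Km ÷ max). By construction each sequence has
  exactly one (0, 1.0) anchor; replicate measurements equal to the maximum
  at T_opt are collapsed to a single anchor, other replicates are kept as
  distinct points.

Composition at prediction time is multiplicative in linear space, i.e.
additive in log10:

    log10 kcat/Km(T) = log10_max_hat + log10(max(rel_hat(T − t_opt_hat), ε)).

The floor ε (default 1e-3) exists because nothing constrains a regressor's
relative-activity output to be positive; without it a single zero output
sends the log-composition to −∞. The default corresponds to "activity three
decades below the maximum", comfortably below anything that survives the
outlier filter (see below). Module 3 is trained on the *relative*
temperature ΔT (true T_opt during training, Module 1's prediction at
inference), because the profile dataset is indexed by temperature offsets;
an absolute-temperature mode is available behind the `temperature_mode`
flag for comparison.

A consequence of the decomposition worth keeping in mind: errors propagate.
A biased T_opt prediction shifts the whole reconstructed profile sideways;
the evaluation on (sequence, T) points charges that error at every
temperature.

## Data processing order and filtering

Processing order is: curve-based estimation → outlier filtering → dataset
building. Records estimated from an activity–temperature curve (a reported
reference kcat/Km plus relative activities at other temperatures) are
flagged `is_estimated` and re-derive the reference point exactly. The
default outlier filter keeps kcat/Km in the fixed linear-scale range
[1e-2, 1e5] mM⁻¹ s⁻¹ — the typical range for enzymes — with an IQR
alternative (Tukey fences, 1.5×IQR, computed on log10 values). When a
sequence's maximal record is filtered out, its T_opt is recomputed from the
surviving records rather than dropped. Every exclusion is logged with a
reason into the derived datasets' `filter_log`.

## Sequence representations

All encoders are scikit-learn transformers fitted on training sequences
only — inside every cross-validation fold, so the n-gram vocabulary,
one-hot padding length and alignment frame never see validation sequences.

- **n-gram (n = 1–4)**: overlapping substring counts; the vocabulary is the
  lexicographically sorted set of n-grams observed in training (not the
  full 20ⁿ space, which keeps n = 3, 4 tractable); unseen query n-grams are
  dropped. n = 1 is bag-of-words residue composition.
- **one-hot**: 20 columns per position, zero-padded to a fixed maximum
  length; sequences longer than the fitted length are an error, not a
  truncation.
- **BLOSUM45/62**: each aligned position contributes the 20
  substitution-score values of the residue observed there (standard
  published matrices via Biopython); gaps contribute zeros. The alignment
  frame is either a user-supplied MSA (aligned FASTA from any standard
  tool, the recommended path) or a naive star-alignment fallback that
  projects every sequence onto the longest training sequence via pairwise
  global alignment. The fallback drops residues inserted relative to the
  reference (with a warning); it is exact for substitution-only variant
  sets such as the synthetic families, and approximate otherwise.
- **embedding table**: a lookup of externally precomputed fixed-length
  vectors (e.g. protein language-model embeddings) keyed by sequence id.
  Embeddings are never computed in-process and no model weights are
  bundled.

**Pairwise identity** uses a global alignment maximizing the match count
(match 1, mismatch 0, gap 0), with identity = matches / alignment length.
Among the typically many optimal alignments the implementation prefers the
most compact one (an infinitesimal gap penalty of 1e-6 per gap position),
which makes the denominator well defined; the test suite checks this
against a brute-force (max matches, then min gaps) dynamic-programming
oracle. Alignment length as denominator is one of several defensible
conventions (shorter-sequence length being the main alternative); it is the
one used consistently here, including for the max-identity-to-training-set
stratification (threshold 0.80 by default).

## Regressors and evaluation

The zoo: linear regression, LASSO, decision tree, random forest, SVR, MLP,
elastic net, XGBoost. Hyperparameters are pinned in
`src/enztherm/regressor_defaults.yaml` so results survive library
upgrades; the only deviations from library defaults are raised iteration
caps for LASSO/elastic-net/MLP (to avoid spurious non-convergence on small
design matrices), marked as such in the file. Stochastic learners are
seeded from the `RegressorSpec`.

Splitting is always by protein sequence: distinct sequence ids are
shuffled by a seeded RNG and dealt into k near-equal folds; every data row
follows its sequence's fold. Disjointness of train and validation ids is
asserted at plan construction and again per fold (a violation raises, it
is never papered over). Repeated-round evaluation draws a fresh grouped
plan per seed (seeds 0–9 by convention) and holds out the first fold —
one 80/20 split per round; this reading of "repeated random splitting"
versus "all five folds per round" is configurable by simply iterating the
plan's folds.

Metrics: R² = 1 − SS_res/SS_tot, MAE, RMSE, Pearson correlation; R² and
PCC are reported as NaN (flagged undefined) for n < 2 or zero variance
rather than raising. Paired model comparison uses the two-sided Wilcoxon
signed-rank test: zero differences dropped before ranking, exact
enumeration p for n ≤ 25 without ties, normal approximation otherwise; the
reported statistic is min(W+, W−).

## The combination sweep

Candidate (encoder, regressor) models for each module are combined in a
full cross product and every triple is scored on held-out log10 kcat/Km.
Models are trained once per round and their module-level validation
predictions cached, so a 20×20×20 sweep costs 60 trainings per round plus
8000 cheap compositions, not 8000 trainings. Triples whose training fails
are recorded with a `failed` status rather than aborting the sweep.
Ranking is by mean validation R² (descending), ties broken by lower MAE;
the sort is stable.

## The synthetic benchmark

The generator emulates the statistical structure of curated
activity–temperature datasets without requiring any download:

- **Families**: 25 wild-type base sequences (uniform over the 20 canonical
  residues, length 300) each with 7 mutants by independent per-site
  substitution at rate 0.02 — 200 sequences with high within-family and low
  between-family identity, mirroring the wild-type/mutant structure of
  curated enzyme datasets.
- **Planted kinetics**: T_opt and log10 max are clipped affine maps of two
  fixed random linear functionals of residue composition (midpoint ±
  quarter-range per standard unit, ranges 20–80 °C and −1 to 4
  log10(mM⁻¹ s⁻¹)). Composition-linear truths make n-gram encoders (even
  n = 1) sufficient learners, so recovery tests probe pipeline correctness
  rather than model capacity.
- **Profile**: an asymmetric Gaussian, exp(−ΔT²/2σ²) with σ_left = 18 °C
  below and σ_right = 8 °C above the optimum (±15% family-level jitter,
  right ≤ left enforced) — activity falls faster above T_opt, mimicking
  denaturation. The asymmetric-Gaussian form was chosen over
  thermodynamic rate models for closed-form testability.
- **Measurements**: a 10–90 °C grid in 10 °C steps with N(0, 0.15) noise in
  log10. The profile is centered on the grid point nearest the continuous
  planted optimum (the *anchor*), and the anchor record is drawn
  noiseless. This centering makes the noiseless data exactly
  self-consistent: the observed argmax is the grid point nearest the
  truth, the observed maximum equals the planted maximum, and the derived
  relative activities equal the planted profile — properties the recovery
  tests assert to 1e-9. The noiseless anchor can be disabled.

What the benchmark does *not* emulate: real substitution processes and
conserved motifs, insertion/deletion variation, composition-nonlinear
sequence–function relationships, heteroscedastic or systematic assay
error, and the sparse, irregular temperature coverage of literature data.
Passing recovery tests therefore demonstrates that the pipeline is
correct and that the decomposition recomposes faithfully — not that any
particular accuracy will be achieved on real enzyme data.

## Benchmark problem sizes and observed behaviour

The standard recovery benchmark is 200 sequences × 9 grid temperatures
(1800 records, ~1470 surviving the default filter), with n-gram(2) +
random-forest models and a grouped 5-fold plan; module-level noiseless
recovery is scored against the planted continuous parameters. Scoring
Module 1 against its grid-quantized training labels instead would cap R²
near 0.96 for a perfect learner (quantization variance ≈ 8.3 °C² against
a ≈ 230 °C² label variance), which is why recovery against the planted
truth is the reported quantity. The stability comparison uses a smaller
benchmark (10 families × 5 sequences, length 120) over split seeds 0–9 so
ten rounds of four model fits stay fast.

On this synthetic benchmark the single-module control is roughly as
accurate as the composed framework (sometimes better), and the
split-to-split spread of the two architectures is comparable; both
quantities are computed and reported per run rather than asserted,
because the benchmark's composition-linear, dense-grid structure is
friendly to the direct model in ways sparse real data is not. The
framework's advantages on real data — lower split-dependence and less
overfitting — are claims about data regimes the generator deliberately
does not reproduce.

## Known limitations

- The star-alignment fallback is not a real MSA; supply an aligned FASTA
  for anything beyond substitution-only variant sets.
- The geometric-averaging baseline's exact weighting (identity-weighted
  log-mean, with an unweighted top-k alternative, k = 5) is this package's
  reconstruction of the similarity-averaging idea; both modes are
  documented and tested against explicit-loop oracles.
- `predict_profile` under `temperature_mode="absolute"` reports
  ΔT = T − t_opt_hat for reference, but Module 3 then consumes absolute
  temperatures; the two modes are not interchangeable after training.
- Substrate identity, pH and other assay covariates are out of scope; the
  activity table carries them only as free-text provenance.
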