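import itertools
import math

import numpy as np
import pandas as pd
import pytest

from enztherm import (
    NGramEncoder,
    RegressorSpec,
    SequenceSet,
    compute_metrics,
    cross_validate,
    evaluate_subsets,
    grouped_split,
    make_regressor,
    regressor_defaults,
    wilcoxon_signed_rank,
)
from enztherm.exceptions import (
    ConfigError,
    UndefinedResultError,
    ValidationError,
)
from enztherm.modeling import REGRESSOR_NAMES
from enztherm.records import CANONICAL_RESIDUES


# ---------------------------------------------------------------------------
# regressor zoo


@pytest.mark.parametrize("name", REGRESSOR_NAMES)
def test_zoo_members_fit_and_predict(name):
    rng = np.random.default_rng(0)
    X = rng.random((40, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.01 * rng.standard_normal(40)
    model = make_regressor(RegressorSpec(name, random_seed=7))
    model.fit(X, y)
    assert model.predict(X).shape == (40,)


def test_unknown_regressor_name():
    with pytest.raises(ConfigError):
        make_regressor(RegressorSpec("gradient_unicorn"))


def test_seeded_learners_are_deterministic():
    rng = np.random.default_rng(1)
    X, y = rng.random((60, 8)), rng.random(60)
    preds = []
    for _ in range(2):
        model = make_regressor(RegressorSpec("random_forest", random_seed=7))
        model.fit(X, y)
        preds.append(model.predict(X))
    assert np.array_equal(preds[0], preds[1])


def test_defaults_file_covers_the_zoo():
    defaults = regressor_defaults()
    assert set(REGRESSOR_NAMES) <= set(defaults)


# ---------------------------------------------------------------------------
# splitting


def test_grouped_split_near_equal_folds():
    plan = grouped_split([f"s{i}" for i in range(10)], k=5, seed=0)
    assert len(plan.folds) == 5
    assert all(len(valid) == 2 for _, valid in plan.folds)
    validated = [sid for _, valid in plan.folds for sid in valid]
    assert sorted(validated) == sorted(f"s{i}" for i in range(10))


def test_grouped_split_too_few_ids():
    with pytest.raises(ConfigError):
        grouped_split(["a", "b", "c"], k=5, seed=0)


def test_grouped_split_reproducible_and_seed_sensitive():
    ids = [f"s{i}" for i in range(30)]
    assert grouped_split(ids, 5, seed=3).folds == grouped_split(ids, 5, seed=3).folds
    assert grouped_split(ids, 5, seed=3).folds != grouped_split(ids, 5, seed=4).folds


def test_grouped_split_ignores_duplicate_rows():
    plan = grouped_split(["a", "b", "a", "c", "b", "d", "e"], k=5, seed=0)
    assert sorted(plan.units) == ["a", "b", "c", "d", "e"]


# ---------------------------------------------------------------------------
# metrics


@pytest.mark.parametrize(
    "y,yhat,r2,mae",
    [
        ([1, 2, 3], [1, 2, 3], 1.0, 0.0),
        ([1, 2, 3], [2, 2, 2], 0.0, 2 / 3),
        ([1, 2, 3], [2, 3, 4], -0.5, 1.0),
    ],
)
def test_metrics_hand_arithmetic(y, yhat, r2, mae):
    m = compute_metrics(y, yhat)
    assert m.r2 == pytest.approx(r2, abs=1e-12)
    assert m.mae == pytest.approx(mae, abs=1e-12)


def test_metrics_perfect_prediction():
    m = compute_metrics([1, 2, 3], [1, 2, 3])
    assert (m.rmse, m.n) == (0.0, 3)
    assert m.pcc == pytest.approx(1.0, abs=1e-12)


def test_metrics_length_mismatch():
    with pytest.raises(ValidationError):
        compute_metrics([1, 2], [1, 2, 3])


def test_metrics_zero_variance_flagged_undefined():
    m = compute_metrics([2, 2, 2], [1, 2, 3])
    assert math.isnan(m.r2) and math.isnan(m.pcc)
    assert not m.defined


# ---------------------------------------------------------------------------
# cross-validation


def _composition_regression_data(n_sequences=300, length=60, seed=1, permute=False):
    """Sequences whose target is a noiseless linear function of n=1 counts."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype=np.uint8)
    weights = rng.normal(0, 3.0, size=20)
    sequences = SequenceSet()
    targets = []
    for i in range(n_sequences):
        codes = rng.integers(0, 20, size=length)
        sequences.add(f"s{i}", alphabet[codes].tobytes().decode())
        counts = np.bincount(codes, minlength=20)
        targets.append(float(counts @ weights))
    if permute:
        targets = [targets[i] for i in rng.permutation(n_sequences)]
    table = pd.DataFrame({"sequence_id": sequences.ids, "target": targets})
    return table, sequences


def test_cross_validate_recovers_planted_composition_signal():
    table, sequences = _composition_regression_data(seed=1)
    plan = grouped_split(sequences.ids, k=5, seed=1)
    report = cross_validate(
        table, sequences, NGramEncoder(n=1), RegressorSpec("lasso"), plan
    )
    assert len(report.per_fold) == 5
    assert report.mean("r2") >= 0.95


def test_cross_validate_destroyed_signal_control():
    table, sequences = _composition_regression_data(seed=1, permute=True)
    plan = grouped_split(sequences.ids, k=5, seed=1)
    report = cross_validate(
        table, sequences, NGramEncoder(n=1), RegressorSpec("lasso"), plan
    )
    assert report.mean("r2") <= 0.1


def test_cross_validate_keeps_predictions_per_fold():
    table, sequences = _composition_regression_data(n_sequences=25, seed=2)
    plan = grouped_split(sequences.ids, k=5, seed=0)
    report = cross_validate(
        table,
        sequences,
        NGramEncoder(n=1),
        RegressorSpec("linear"),
        plan,
        keep_predictions=True,
    )
    assert len(report.predictions) == 25  # every sequence validates exactly once
    assert set(report.predictions["fold"]) == set(range(5))


# ---------------------------------------------------------------------------
# subset evaluation


def test_evaluate_subsets_partitions_rows():
    predictions = pd.DataFrame(
        {
            "sequence_id": ["a", "b", "c", "d"],
            "y_true": [1.0, 2.0, 3.0, 4.0],
            "y_pred": [1.1, 2.1, 2.9, 4.2],
        }
    )
    flags = {"a": True, "b": True, "c": False, "d": False}
    max_si = {"a": 0.9, "b": 0.7, "c": 0.95, "d": 0.5}
    out = evaluate_subsets(predictions, flags, max_si, si_threshold=0.8)
    assert out["wild_type"].n + out["mutant"].n == 4
    assert out["max_si>0.8"].n + out["max_si<=0.8"].n == 4


def test_evaluate_subsets_undefined_for_small_subset():
    predictions = pd.DataFrame(
        {"sequence_id": ["a", "b"], "y_true": [1.0, 2.0], "y_pred": [1.0, 2.0]}
    )
    out = evaluate_subsets(predictions, {"a": True, "b": True})
    assert out["mutant"].n == 0 and not out["mutant"].defined
    assert out["wild_type"].n == 2


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def exact_two_sided_p(diffs):
    """Full enumeration over all sign assignments of the |differences|."""
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    n = len(diffs)
    w_plus = ranks[diffs > 0].sum()
    total = ranks.sum()
    w_min, w_max = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_min or w >= w_max:
            count += 1
    return min(1.0, count / 2**n)


def test_all_positive_differences_n5():
    result = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    assert result.statistic == 0.0
    assert result.p_value == pytest.approx(0.0625, abs=1e-12)
    assert result.n_pairs == 5


def test_identical_scores_undefined():
    with pytest.raises(UndefinedResultError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def test_symmetry_under_swap():
    a, b = [1.0, 2.5, 3.0, 4.8, 2.2], [0.5, 3.0, 2.0, 5.0, 1.0]
    assert wilcoxon_signed_rank(a, b).p_value == wilcoxon_signed_rank(b, a).p_value


def test_zero_differences_dropped():
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [1.0, 0.5, 2.0, 3.5, 4.9, 5.0]  # first pair ties
    assert wilcoxon_signed_rank(a, b).n_pairs == 5


@pytest.mark.parametrize("n", range(3, 9))
def test_exact_p_matches_enumeration(n):
    rng = np.random.default_rng(n)
    magnitudes = rng.permutation(np.arange(1, n + 1)).astype(float)
    for pattern in itertools.product((-1, 1), repeat=n):
        diffs = magnitudes * np.array(pattern)
        result = wilcoxon_signed_rank(diffs, np.zeros(n))
        assert result.p_value == pytest.approx(exact_two_sided_p(diffs), abs=1e-9)
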