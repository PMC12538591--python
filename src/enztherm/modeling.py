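"""Regressor zoo, sequence-grouped splitting, metrics, and paired statistics.

Data are always split by protein sequence: every measurement of a sequence
follows that sequence's fold assignment, so no sequence appears in both the
training and the validation side of any split. This is the generalization
test that matters here — with random row-level splitting, predicting a known
sequence at a new temperature is nearly trivial and scores are inflated.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import clone

from .exceptions import ConfigError, LeakageError, UndefinedResultError, ValidationError
from .records import SequenceSet

REGRESSOR_NAMES = (
    "linear",
    "lasso",
    "decision_tree",
    "random_forest",
    "svr",
    "mlp",
    "enr",
    "xgb",
)
_SEEDED = {"decision_tree", "random_forest", "mlp", "xgb"}

_defaults_cache: dict[str, dict] | None = None


def regressor_defaults() -> dict[str, dict]:
    """The pinned default hyperparameters for every learner in the zoo."""
    global _defaults_cache
    if _defaults_cache is None:
        text = (
            importlib.resources.files("enztherm")
            .joinpath("regressor_defaults.yaml")
            .read_text()
        )
        _defaults_cache = yaml.safe_load(text)
    return {name: dict(params or {}) for name, params in _defaults_cache.items()}


@dataclass(frozen=True)
class RegressorSpec:
    """A named learner plus hyperparameter overrides and a fixed seed."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    random_seed: int = 0

    def label(self) -> str:
        return self.name


def make_regressor(spec: RegressorSpec):
    """Instantiate a fit/predict regressor from a spec.

    Stochastic learners (trees, forests, MLP, gradient boosting) are seeded
    from ``spec.random_seed`` so repeated builds are bit-reproducible.
    """
    if spec.name not in REGRESSOR_NAMES:
        raise ConfigError(
            f"unknown regressor {spec.name!r}; expected one of {REGRESSOR_NAMES}"
        )
    params = regressor_defaults().get(spec.name, {})
    params.update(spec.hyperparameters)
    if spec.name in _SEEDED:
        params.setdefault("random_state", spec.random_seed)

    if spec.name == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression(**params)
    if spec.name == "lasso":
        from sklearn.linear_model import Lasso

        return Lasso(**params)
    if spec.name == "enr":
        from sklearn.linear_model import ElasticNet

        return ElasticNet(**params)
    if spec.name == "decision_tree":
        from sklearn.tree import DecisionTreeRegressor

        return DecisionTreeRegressor(**params)
    if spec.name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(**params)
    if spec.name == "svr":
        from sklearn.svm import SVR

        return SVR(**params)
    if spec.name == "mlp":
        from sklearn.neural_network import MLPRegressor

        return MLPRegressor(**params)
    from xgboost import XGBRegressor

    return XGBRegressor(**params)


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    """k folds over distinct sequence ids: (train_ids, valid_ids) pairs."""

    units: list[str]
    folds: list[tuple[list[str], list[str]]]
    round_seed: int

    def __post_init__(self) -> None:
        all_units = set(self.units)
        for train, valid in self.folds:
            t, v = set(train), set(valid)
            if t & v:
                raise LeakageError(
                    f"fold shares sequence ids between train and valid: {t & v}"
                )
            if t | v != all_units:
                raise ValidationError("fold does not cover all units")


def grouped_split(sequence_ids: Sequence[str], k: int = 5, seed: int = 0) -> SplitPlan:
    """Shuffle distinct sequence ids and deal them into k near-equal folds.

    All data rows of a sequence follow its fold assignment, guaranteeing
    no sequence overlap between training and validation sets.
    """
    units = list(dict.fromkeys(sequence_ids))  # distinct, first-seen order
    if len(units) < k:
        raise ConfigError(
            f"need at least k={k} distinct sequence ids, got {len(units)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = [units[i] for i in rng.permutation(len(units))]
    fold_arrays = np.array_split(np.arange(len(shuffled)), k)
    folds = []
    for idx in fold_arrays:
        valid = [shuffled[i] for i in idx]
        valid_set = set(valid)
        train = [u for u in shuffled if u not in valid_set]
        folds.append((train, valid))
    return SplitPlan(units=units, folds=folds, round_seed=seed)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class EvalMetrics:
    """R^2, MAE, RMSE and Pearson correlation for one prediction set.

    ``r2`` and ``pcc`` are NaN (flagged undefined) when y_true has fewer than
    two values or zero variance.
    """

    r2: float
    mae: float
    rmse: float
    pcc: float
    n: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.r2) or math.isnan(self.pcc))


_UNDEFINED = EvalMetrics(math.nan, math.nan, math.nan, math.nan, 0)


def compute_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> EvalMetrics:
    """R^2 = 1 - SS_res/SS_tot, MAE, RMSE and Pearson correlation."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValidationError(
            f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted"
        )
    n = yt.shape[0]
    if n == 0:
        return _UNDEFINED
    err = yp - yt
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if n < 2 or ss_tot == 0 or np.std(yp) == 0:
        r2 = math.nan if (n < 2 or ss_tot == 0) else 1.0 - float(np.sum(err**2)) / ss_tot
        return EvalMetrics(r2=r2, mae=mae, rmse=rmse, pcc=math.nan, n=n)
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    pcc = float(stats.pearsonr(yt, yp).statistic)
    return EvalMetrics(r2=r2, mae=mae, rmse=rmse, pcc=pcc, n=n)


@dataclass
class EvalReport:
    """Per-fold metrics with their mean and standard deviation."""

    model: str
    per_fold: list[EvalMetrics]
    predictions: pd.DataFrame | None = None
    subsets: dict[str, EvalMetrics] = field(default_factory=dict)

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.per_fold], dtype=float)

    def mean(self, metric: str = "r2") -> float:
        return float(np.nanmean(self._values(metric)))

    def sd(self, metric: str = "r2") -> float:
        # ddof=0 over exactly the per-fold list
        return float(np.nanstd(self._values(metric)))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "r2": m.r2, "mae": m.mae, "rmse": m.rmse, "pcc": m.pcc, "n": m.n}
            for i, m in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    table: pd.DataFrame,
    sequences: SequenceSet,
    encoder,
    spec: RegressorSpec,
    plan: SplitPlan,
    extra_columns: Sequence[str] = (),
    target_column: str = "target",
    keep_predictions: bool = False,
) -> EvalReport:
    """Sequence-grouped cross-validation of one encoder+regressor model.

    ``table`` holds one row per training example with columns ``sequence_id``,
    ``target_column`` and any ``extra_columns`` (numeric features appended
    after the sequence encoding, e.g. the temperature offset). The encoder is
    cloned and fitted on the training sequences of each fold only — the
    n-gram vocabulary, one-hot padding and alignment frame never see
    validation sequences. Leakage is asserted, not assumed.
    """
    missing = set(table["sequence_id"]) - set(plan.units)
    if missing:
        raise ValidationError(f"rows reference sequence ids outside the plan: {missing}")
    keyed_by = getattr(encoder, "keyed_by", "sequence")

    per_fold: list[EvalMetrics] = []
    prediction_frames: list[pd.DataFrame] = []
    for fold_index, (train_ids, valid_ids) in enumerate(plan.folds):
        overlap = set(train_ids) & set(valid_ids)
        if overlap:
            raise LeakageError(f"fold {fold_index}: leaked sequence ids {overlap}")
        enc = clone(encoder)
        train_keys = train_ids if keyed_by == "id" else [sequences[s] for s in train_ids]
        enc.fit(train_keys)

        def design(rows: pd.DataFrame) -> np.ndarray:
            keys = (
                rows["sequence_id"].tolist()
                if keyed_by == "id"
                else [sequences[s] for s in rows["sequence_id"]]
            )
            X = enc.transform(keys)
            if extra_columns:
                X = np.hstack([X, rows[list(extra_columns)].to_numpy(dtype=float)])
            return X

        train_rows = table[table["sequence_id"].isin(train_ids)]
        valid_rows = table[table["sequence_id"].isin(valid_ids)]
        model = make_regressor(spec)
        model.fit(design(train_rows), train_rows[target_column].to_numpy(dtype=float))
        y_pred = np.asarray(model.predict(design(valid_rows)), dtype=float)
        y_true = valid_rows[target_column].to_numpy(dtype=float)
        per_fold.append(compute_metrics(y_true, y_pred))
        if keep_predictions:
            frame = valid_rows[["sequence_id"]].copy()
            frame["fold"] = fold_index
            frame["y_true"] = y_true
            frame["y_pred"] = y_pred
            prediction_frames.append(frame)

    label = f"{type(encoder).__name__}+{spec.name}"
    predictions = (
        pd.concat(prediction_frames, ignore_index=True) if keep_predictions else None
    )
    return EvalReport(model=label, per_fold=per_fold, predictions=predictions)


def evaluate_subsets(
    predictions: pd.DataFrame,
    wild_type_flags: Mapping[str, bool],
    max_identity: Mapping[str, float] | None = None,
    si_threshold: float = 0.80,
) -> dict[str, EvalMetrics]:
    """Metrics on wild-type/mutant and high/low max-sequence-identity subsets.

    ``predictions`` needs columns sequence_id, y_true, y_pred. Subsets with
    fewer than two rows are reported as undefined metrics, not errors.
    """
    def metrics_for(mask: pd.Series) -> EvalMetrics:
        part = predictions[mask]
        if len(part) < 2:
            return EvalMetrics(math.nan, math.nan, math.nan, math.nan, len(part))
        return compute_metrics(part["y_true"], part["y_pred"])

    unknown = set(predictions["sequence_id"]) - set(wild_type_flags)
    if unknown:
        raise ValidationError(f"sequences without wild-type annotation: {unknown}")
    is_wt = predictions["sequence_id"].map(dict(wild_type_flags)).astype(bool)
    out = {"wild_type": metrics_for(is_wt), "mutant": metrics_for(~is_wt)}
    if max_identity is not None:
        unknown = set(predictions["sequence_id"]) - set(max_identity)
        if unknown:
            raise ValidationError(f"sequences without max-identity values: {unknown}")
        si = predictions["sequence_id"].map(dict(max_identity)).astype(float)
        out[f"max_si>{si_threshold:g}"] = metrics_for(si > si_threshold)
        out[f"max_si<={si_threshold:g}"] = metrics_for(si <= si_threshold)
    return out


# ---------------------------------------------------------------------------
# paired comparison


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired scores."""

    statistic: float  # min(W+, W-)
    p_value: float
    n_pairs: int
    sided: str = "two-sided"


def wilcoxon_signed_rank(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped before ranking. The p-value is exact
    (full enumeration) for n <= 25 without ties in |differences|, and a
    normal approximation otherwise. The reported statistic is min(W+, W-).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired score lists must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    n = diffs.shape[0]
    if n == 0:
        raise UndefinedResultError(
            "all paired differences are zero; the test is undefined"
        )
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    has_ties = len(np.unique(np.abs(diffs))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stats.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method=method
        )
    return ComparisonResult(
        statistic=min(w_plus, w_minus),
        p_value=float(min(result.pvalue, 1.0)),
        n_pairs=n,
    )
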