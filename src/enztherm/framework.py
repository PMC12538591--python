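"""The three-module kcat/Km(T) predictor, its single-module control, and the
sequence-similarity geometric-averaging baseline.

The prediction task — catalytic efficiency as a nonlinear function of protein
sequence and temperature — is decomposed into three regressions:

* **Module 1** predicts the optimum temperature T_opt from the sequence.
* **Module 2** predicts log10 of the maximum efficiency kcat/Km,max.
* **Module 3** predicts relative activity (kcat/Km divided by the maximum)
  from the sequence plus the temperature offset dT = T - T_opt.

At prediction time the modules compose: dT is formed against Module 1's
predicted optimum, Module 3's relative activity is applied multiplicatively
in linear space (additively in log10), and the relative value is clipped
below at ``rel_floor`` so a zero or negative regressor output cannot send the
log-prediction to -infinity:

    log10 kcat/Km(T) = log10_max_hat + log10(max(rel_hat(dT), rel_floor)).

The single-module control maps (sequence encoding + absolute temperature)
directly to log10 kcat/Km without the decomposition. Both are scikit-learn
style estimators with sequence-grouped training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .datasets import build_derived_datasets
from .exceptions import ConfigError, ValidationError
from .features import pairwise_identity
from .modeling import (
    EvalMetrics,
    RegressorSpec,
    compute_metrics,
    grouped_split,
    make_regressor,
)
from .records import ActivityRecord, SequenceSet, sequences_from_records

logger = logging.getLogger(__name__)

#: Default clip for Module 3's relative activity before the log10 composition.
DEFAULT_REL_FLOOR = 1e-3


@dataclass
class ProfilePrediction:
    """A predicted activity-temperature profile for one sequence."""

    sequence_id: str
    t_opt_hat: float
    log10_max_hat: float
    points: pd.DataFrame  # temperature_C, delta_t_C, rel_hat, log10_kcat_km_hat

    def to_frame(self) -> pd.DataFrame:
        frame = self.points.copy()
        frame.insert(0, "sequence_id", self.sequence_id)
        frame["kcat_km_hat"] = 10.0 ** frame["log10_kcat_km_hat"]
        return frame


def compose_log10(
    log10_max_hat: float | np.ndarray,
    rel_hat: float | np.ndarray,
    rel_floor: float = DEFAULT_REL_FLOOR,
) -> np.ndarray:
    """log10 kcat/Km from the module outputs, with the rel-floor clip."""
    if rel_floor <= 0:
        raise ConfigError("rel_floor must be positive")
    rel = np.maximum(np.asarray(rel_hat, dtype=float), rel_floor)
    return np.asarray(log10_max_hat, dtype=float) + np.log10(rel)


def predict_profile(
    model,
    sequence: str,
    temperatures: Sequence[float],
    sequence_id: str = "query",
) -> ProfilePrediction:
    """Compose any object exposing the three module predictions into a profile.

    ``model`` must provide ``predict_topt(sequence)``,
    ``predict_log10_max(sequence)``, ``predict_rel(sequence, delta_ts)`` and a
    ``rel_floor`` attribute. Used both by :class:`ThreeModuleRegressor` and by
    oracle stubs in tests.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0:
        raise ValidationError("temperatures must be non-empty")
    t_opt_hat = float(model.predict_topt(sequence))
    log10_max_hat = float(model.predict_log10_max(sequence))
    delta_t = temps - t_opt_hat
    rel_hat = np.asarray(model.predict_rel(sequence, delta_t), dtype=float)
    log10_hat = compose_log10(log10_max_hat, rel_hat, model.rel_floor)
    points = pd.DataFrame(
        {
            "temperature_C": temps,
            "delta_t_C": delta_t,
            "rel_hat": rel_hat,
            "log10_kcat_km_hat": log10_hat,
        }
    )
    return ProfilePrediction(sequence_id, t_opt_hat, log10_max_hat, points)


def _restrict(records: Sequence[ActivityRecord], ids: set[str]) -> list[ActivityRecord]:
    return [r for r in records if r.sequence_id in ids]


class ThreeModuleRegressor(RegressorMixin, BaseEstimator):
    """Temperature-dependent kcat/Km predictor composed of three regressions.

    Parameters
    ----------
    m1_encoder, m2_encoder, m3_encoder : sequence-feature transformers
        (cloned and fitted on the training sequences at ``fit`` time).
    m1_spec, m2_spec, m3_spec : :class:`RegressorSpec` for each module.
    rel_floor : lower clip for Module 3's relative activity in the log10
        composition.
    temperature_mode : ``"relative"`` trains Module 3 on dT = T - T_opt
        (true T_opt during training, predicted at inference);
        ``"absolute"`` trains it on the absolute assay temperature.
    tie_break : passed to the dataset builder for equal maxima.

    Fitted attributes carry a trailing underscore (``m1_model_``,
    ``training_ids_``, ...). ``predict`` takes ``(sequence, temperature_C)``
    pairs and returns log10 kcat/Km in log10(mM^-1 s^-1).
    """

    def __init__(
        self,
        m1_encoder=None,
        m1_spec: RegressorSpec = RegressorSpec("random_forest"),
        m2_encoder=None,
        m2_spec: RegressorSpec = RegressorSpec("random_forest"),
        m3_encoder=None,
        m3_spec: RegressorSpec = RegressorSpec("random_forest"),
        rel_floor: float = DEFAULT_REL_FLOOR,
        temperature_mode: str = "relative",
        tie_break: str = "lowest_T",
    ):
        self.m1_encoder = m1_encoder
        self.m1_spec = m1_spec
        self.m2_encoder = m2_encoder
        self.m2_spec = m2_spec
        self.m3_encoder = m3_encoder
        self.m3_spec = m3_spec
        self.rel_floor = rel_floor
        self.temperature_mode = temperature_mode
        self.tie_break = tie_break

    def _default_encoder(self):
        from .features import NGramEncoder

        return NGramEncoder(n=2)

    def fit(
        self,
        records: Sequence[ActivityRecord],
        y: object = None,
        training_ids: Iterable[str] | None = None,
    ) -> "ThreeModuleRegressor":
        if self.temperature_mode not in ("relative", "absolute"):
            raise ConfigError(f"unknown temperature_mode {self.temperature_mode!r}")
        if self.rel_floor <= 0:
            raise ConfigError("rel_floor must be positive")
        all_sequences = sequences_from_records(records)
        ids = set(training_ids) if training_ids is not None else set(all_sequences.ids)
        train_records = _restrict(records, ids)
        if not train_records:
            raise ValidationError("training_ids select no records")
        self.sequences_ = sequences_from_records(train_records)
        self.training_ids_ = sorted(ids & set(self.sequences_.ids))
        derived = build_derived_datasets(train_records, tie_break=self.tie_break)
        self.derived_ = derived
        if not derived.topt:
            raise ValidationError("module 1 (T_opt) training set is empty")
        if not derived.maxima:
            raise ValidationError("module 2 (log10 max) training set is empty")
        if not derived.profile:
            raise ValidationError("module 3 (profile) training set is empty")

        seq_of = dict(self.sequences_.items())
        topt_by_id = {e.sequence_id: e.t_opt_C for e in derived.topt}

        # Module 1: sequence -> T_opt
        self.m1_encoder_ = clone(self.m1_encoder or self._default_encoder())
        m1_seqs = [seq_of[e.sequence_id] for e in derived.topt]
        X1 = self.m1_encoder_.fit(m1_seqs).transform(m1_seqs)
        self.m1_model_ = make_regressor(self.m1_spec)
        self.m1_model_.fit(X1, np.array([e.t_opt_C for e in derived.topt]))

        # Module 2: sequence -> log10 kcat/Km,max
        self.m2_encoder_ = clone(self.m2_encoder or self._default_encoder())
        m2_seqs = [seq_of[e.sequence_id] for e in derived.maxima]
        X2 = self.m2_encoder_.fit(m2_seqs).transform(m2_seqs)
        self.m2_model_ = make_regressor(self.m2_spec)
        self.m2_model_.fit(X2, np.array([e.log10_max for e in derived.maxima]))

        # Module 3: sequence + temperature offset -> relative activity
        self.m3_encoder_ = clone(self.m3_encoder or self._default_encoder())
        unique_seqs = self.sequences_.sequences()
        self.m3_encoder_.fit(unique_seqs)
        m3_seqs = [seq_of[e.sequence_id] for e in derived.profile]
        X3_seq = self.m3_encoder_.transform(m3_seqs)
        if self.temperature_mode == "relative":
            temp_feature = np.array([e.delta_t_C for e in derived.profile])
        else:
            temp_feature = np.array(
                [e.delta_t_C + topt_by_id[e.sequence_id] for e in derived.profile]
            )
        X3 = np.hstack([X3_seq, temp_feature.reshape(-1, 1)])
        self.m3_model_ = make_regressor(self.m3_spec)
        self.m3_model_.fit(X3, np.array([e.rel_activity for e in derived.profile]))
        return self

    # -- module-level predictions ------------------------------------------

    def predict_topt(self, sequence: str) -> float:
        return float(self.m1_model_.predict(self.m1_encoder_.transform([sequence]))[0])

    def predict_log10_max(self, sequence: str) -> float:
        return float(self.m2_model_.predict(self.m2_encoder_.transform([sequence]))[0])

    def predict_rel(self, sequence: str, delta_ts: Sequence[float]) -> np.ndarray:
        delta_ts = np.asarray(delta_ts, dtype=float)
        seq_features = self.m3_encoder_.transform([sequence])
        X = np.hstack(
            [
                np.repeat(seq_features, delta_ts.shape[0], axis=0),
                delta_ts.reshape(-1, 1),
            ]
        )
        return np.asarray(self.m3_model_.predict(X), dtype=float)

    # -- composed predictions ----------------------------------------------

    def predict_profile(
        self,
        sequence: str,
        temperatures: Sequence[float],
        sequence_id: str = "query",
    ) -> ProfilePrediction:
        if self.temperature_mode == "absolute":
            # Module 3 saw absolute temperatures; dT is still reported.
            temps = np.asarray(temperatures, dtype=float)
            t_opt_hat = float(self.predict_topt(sequence))
            log10_max_hat = float(self.predict_log10_max(sequence))
            seq_features = self.m3_encoder_.transform([sequence])
            X = np.hstack(
                [np.repeat(seq_features, temps.shape[0], axis=0), temps.reshape(-1, 1)]
            )
            rel_hat = np.asarray(self.m3_model_.predict(X), dtype=float)
            log10_hat = compose_log10(log10_max_hat, rel_hat, self.rel_floor)
            points = pd.DataFrame(
                {
                    "temperature_C": temps,
                    "delta_t_C": temps - t_opt_hat,
                    "rel_hat": rel_hat,
                    "log10_kcat_km_hat": log10_hat,
                }
            )
            return ProfilePrediction(sequence_id, t_opt_hat, log10_max_hat, points)
        return predict_profile(self, sequence, temperatures, sequence_id)

    def predict(self, X: Sequence[tuple[str, float]]) -> np.ndarray:
        """log10 kcat/Km for ``(sequence, temperature_C)`` pairs."""
        by_sequence: dict[str, list[int]] = {}
        temps = np.empty(len(X))
        for i, (seq, temp) in enumerate(X):
            by_sequence.setdefault(seq, []).append(i)
            temps[i] = temp
        out = np.empty(len(X))
        for seq, idx in by_sequence.items():
            profile = self.predict_profile(seq, temps[idx])
            out[idx] = profile.points["log10_kcat_km_hat"].to_numpy()
        return out


class SingleModuleRegressor(RegressorMixin, BaseEstimator):
    """Direct (sequence + absolute temperature) -> log10 kcat/Km control.

    The non-decomposed control: one regressor trained on every activity
    record, with the assay temperature as a trailing feature column.
    """

    def __init__(
        self,
        encoder=None,
        spec: RegressorSpec = RegressorSpec("random_forest"),
    ):
        self.encoder = encoder
        self.spec = spec

    def fit(
        self,
        records: Sequence[ActivityRecord],
        y: object = None,
        training_ids: Iterable[str] | None = None,
    ) -> "SingleModuleRegressor":
        all_sequences = sequences_from_records(records)
        ids = set(training_ids) if training_ids is not None else set(all_sequences.ids)
        train_records = _restrict(records, ids)
        if not train_records:
            raise ValidationError("training set is empty")
        self.sequences_ = sequences_from_records(train_records)
        from .features import NGramEncoder

        self.encoder_ = clone(self.encoder) if self.encoder is not None else NGramEncoder(n=2)
        self.encoder_.fit(self.sequences_.sequences())
        seqs = [r.sequence for r in train_records]
        X = np.hstack(
            [
                self.encoder_.transform(seqs),
                np.array([[r.temperature_C] for r in train_records]),
            ]
        )
        y_log = np.log10([r.kcat_km for r in train_records])
        self.model_ = make_regressor(self.spec)
        self.model_.fit(X, y_log)
        return self

    def predict(self, X: Sequence[tuple[str, float]]) -> np.ndarray:
        """log10 kcat/Km for ``(sequence, temperature_C)`` pairs."""
        seqs = [seq for seq, _ in X]
        temps = np.array([[temp] for _, temp in X])
        features = np.hstack([self.encoder_.transform(seqs), temps])
        return np.asarray(self.model_.predict(features), dtype=float)

    def predict_profile(
        self,
        sequence: str,
        temperatures: Sequence[float],
        sequence_id: str = "query",
    ) -> ProfilePrediction:
        """Mirror of the framework's profile output.

        T_opt_hat is the queried temperature with the highest prediction and
        rel_hat the linear-scale ratio to that maximum.
        """
        temps = np.asarray(temperatures, dtype=float)
        if temps.size == 0:
            raise ValidationError("temperatures must be non-empty")
        log10_hat = self.predict([(sequence, t) for t in temps])
        best = int(np.argmax(log10_hat))
        t_opt_hat = float(temps[best])
        log10_max_hat = float(log10_hat[best])
        points = pd.DataFrame(
            {
                "temperature_C": temps,
                "delta_t_C": temps - t_opt_hat,
                "rel_hat": 10.0 ** (log10_hat - log10_max_hat),
                "log10_kcat_km_hat": log10_hat,
            }
        )
        return ProfilePrediction(sequence_id, t_opt_hat, log10_max_hat, points)


# ---------------------------------------------------------------------------
# geometric averaging baseline


def geometric_baseline(
    train_pairs: Sequence[tuple[str, float]],
    query: str,
    weighting: str = "identity_weighted",
    k: int = 5,
) -> float:
    """Sequence-similarity geometric averaging of training targets.

    A non-learning reference predictor. ``identity_weighted`` takes
    10^(sum_i w_i log10 y_i / sum_i w_i) with w_i the global pairwise
    identity between the query and training sequence i. ``top_k`` takes the
    unweighted geometric mean over the k most identical training sequences.
    Targets must be positive (the average happens in log space).
    """
    if not train_pairs:
        raise ValidationError("train_pairs must be non-empty")
    if any(y <= 0 for _, y in train_pairs):
        raise ValidationError("geometric averaging requires positive targets")
    if weighting not in ("identity_weighted", "top_k"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    identities = np.array([pairwise_identity(query, seq) for seq, _ in train_pairs])
    log_targets = np.log10([y for _, y in train_pairs])
    if weighting == "identity_weighted":
        total = identities.sum()
        if total == 0:
            raise ValidationError("all identity weights are zero")
        return float(10.0 ** (identities @ log_targets / total))
    if k > len(train_pairs):
        logger.warning("k=%d exceeds training size %d; truncated", k, len(train_pairs))
        k = len(train_pairs)
    top = np.argsort(-identities, kind="stable")[:k]
    return float(10.0 ** log_targets[top].mean())


class GeometricMeanBaseline(RegressorMixin, BaseEstimator):
    """Estimator wrapper around :func:`geometric_baseline`."""

    def __init__(self, weighting: str = "identity_weighted", k: int = 5):
        self.weighting = weighting
        self.k = k

    def fit(self, X: Sequence[str], y: Sequence[float]) -> "GeometricMeanBaseline":
        if len(X) != len(y):
            raise ValidationError("X and y must have equal length")
        self.train_pairs_ = list(zip(X, (float(v) for v in y)))
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.array(
            [
                geometric_baseline(self.train_pairs_, query, self.weighting, self.k)
                for query in X
            ]
        )


# ---------------------------------------------------------------------------
# combination sweep and stability comparison


@dataclass(frozen=True)
class ModelCandidate:
    """A named (encoder, regressor) pair entering the combination sweep."""

    label: str
    encoder: object
    spec: RegressorSpec


@dataclass
class CombinationRanking:
    """All (m1, m2, m3) combinations ranked by mean validation r2."""

    table: pd.DataFrame  # m1, m2, m3, mean_r2, sd_r2, status

    def __len__(self) -> int:
        return len(self.table)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def enumerate_and_rank_combinations(
    m1_candidates: Sequence[ModelCandidate],
    m2_candidates: Sequence[ModelCandidate],
    m3_candidates: Sequence[ModelCandidate],
    records: Sequence[ActivityRecord],
    split_seeds: Sequence[int] = (0,),
    k: int = 5,
    rel_floor: float = DEFAULT_REL_FLOOR,
) -> CombinationRanking:
    """Evaluate every (m1, m2, m3) candidate triple on held-out sequences.

    Per split seed, sequences are dealt into k grouped folds and the first
    fold serves as the validation set (one 80/20 split per round). Each
    candidate model is trained once per round and its validation predictions
    are cached, so the full cross product costs |m1|x|m2|x|m3| cheap
    compositions rather than retrainings. Triples whose training fails are
    recorded with a ``failed`` status instead of aborting the sweep.

    Ranking is by mean validation r2 on log10 kcat/Km (descending), ties
    broken by lower mean MAE.
    """
    if not (m1_candidates and m2_candidates and m3_candidates):
        raise ConfigError("candidate lists must be non-empty")
    sequences = sequences_from_records(records)
    n_rounds = len(split_seeds)
    triple_scores: dict[tuple[str, str, str], list[EvalMetrics]] = {}
    failed: set[tuple[str, str, str]] = set()

    for seed in split_seeds:
        plan = grouped_split(sequences.ids, k=k, seed=seed)
        train_ids, valid_ids = plan.folds[0]
        train_set = set(train_ids)
        valid_records = [r for r in records if r.sequence_id in set(valid_ids)]
        valid_seq_ids = [r.sequence_id for r in valid_records]
        unique_valid = list(dict.fromkeys(valid_seq_ids))
        temps = np.array([r.temperature_C for r in valid_records])
        y_true = np.log10([r.kcat_km for r in valid_records])

        def fit_module(candidate: ModelCandidate, module: str):
            model = ThreeModuleRegressor(
                m1_encoder=candidate.encoder,
                m1_spec=candidate.spec,
                m2_encoder=candidate.encoder,
                m2_spec=candidate.spec,
                m3_encoder=candidate.encoder,
                m3_spec=candidate.spec,
                rel_floor=rel_floor,
            )
            return model.fit(records, training_ids=train_set)

        # cache per-candidate module predictions on the validation sequences
        topt_hat: dict[str, dict[str, float]] = {}
        m1_models: dict[str, ThreeModuleRegressor] = {}
        for cand in m1_candidates:
            try:
                model = fit_module(cand, "m1")
                m1_models[cand.label] = model
                topt_hat[cand.label] = {
                    sid: model.predict_topt(sequences[sid]) for sid in unique_valid
                }
            except Exception as exc:  # noqa: BLE001 - sweep must be resumable
                logger.warning("module-1 candidate %s failed: %s", cand.label, exc)
        logmax_hat: dict[str, dict[str, float]] = {}
        for cand in m2_candidates:
            try:
                model = fit_module(cand, "m2")
                logmax_hat[cand.label] = {
                    sid: model.predict_log10_max(sequences[sid]) for sid in unique_valid
                }
            except Exception as exc:  # noqa: BLE001
                logger.warning("module-2 candidate %s failed: %s", cand.label, exc)
        m3_models: dict[str, ThreeModuleRegressor] = {}
        for cand in m3_candidates:
            try:
                m3_models[cand.label] = fit_module(cand, "m3")
            except Exception as exc:  # noqa: BLE001
                logger.warning("module-3 candidate %s failed: %s", cand.label, exc)

        # rel predictions depend on the (m1, m3) pair through delta_t
        rel_hat: dict[tuple[str, str], np.ndarray] = {}
        for a_label, topts in topt_hat.items():
            delta = temps - np.array([topts[sid] for sid in valid_seq_ids])
            for c_label, m3_model in m3_models.items():
                rel = np.empty(len(valid_records))
                for sid in unique_valid:
                    idx = [i for i, s in enumerate(valid_seq_ids) if s == sid]
                    rel[idx] = m3_model.predict_rel(sequences[sid], delta[idx])
                rel_hat[(a_label, c_label)] = rel

        for a in m1_candidates:
            for b in m2_candidates:
                for c in m3_candidates:
                    key = (a.label, b.label, c.label)
                    if (
                        a.label not in topt_hat
                        or b.label not in logmax_hat
                        or c.label not in m3_models
                    ):
                        failed.add(key)
                        continue
                    logmax = np.array(
                        [logmax_hat[b.label][sid] for sid in valid_seq_ids]
                    )
                    y_pred = compose_log10(
                        logmax, rel_hat[(a.label, c.label)], rel_floor
                    )
                    triple_scores.setdefault(key, []).append(
                        compute_metrics(y_true, y_pred)
                    )

    rows = []
    for a in m1_candidates:
        for b in m2_candidates:
            for c in m3_candidates:
                key = (a.label, b.label, c.label)
                metrics = triple_scores.get(key, [])
                if key in failed or len(metrics) < n_rounds:
                    rows.append(
                        {
                            "m1": key[0],
                            "m2": key[1],
                            "m3": key[2],
                            "mean_r2": math.nan,
                            "sd_r2": math.nan,
                            "mean_mae": math.nan,
                            "status": "failed",
                        }
                    )
                    continue
                r2s = np.array([m.r2 for m in metrics])
                maes = np.array([m.mae for m in metrics])
                rows.append(
                    {
                        "m1": key[0],
                        "m2": key[1],
                        "m3": key[2],
                        "mean_r2": float(r2s.mean()),
                        "sd_r2": float(r2s.std()),
                        "mean_mae": float(maes.mean()),
                        "status": "ok",
                    }
                )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_r2", "mean_mae"],
        ascending=[False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return CombinationRanking(table)


@dataclass
class StabilityReport:
    """Per-round r2 of the three-module and single-module models."""

    three_module_r2: list[float]
    single_module_r2: list[float]
    seeds: list[int]

    @property
    def three_module_sd(self) -> float:
        return float(np.std(self.three_module_r2))

    @property
    def single_module_sd(self) -> float:
        return float(np.std(self.single_module_r2))

    def summary(self) -> dict[str, float]:
        return {
            "three_module_mean_r2": float(np.mean(self.three_module_r2)),
            "three_module_sd_r2": self.three_module_sd,
            "single_module_mean_r2": float(np.mean(self.single_module_r2)),
            "single_module_sd_r2": self.single_module_sd,
        }


def compare_framework_stability(
    records: Sequence[ActivityRecord],
    encoder,
    spec: RegressorSpec,
    split_seeds: Sequence[int] = tuple(range(10)),
    k: int = 5,
    rel_floor: float = DEFAULT_REL_FLOOR,
) -> StabilityReport:
    """Matched-seed r2 of the composed framework vs the single-module control.

    For each split seed, a grouped k-fold plan is drawn and its first fold
    held out; both models use the same encoder and regressor. The per-round
    r2 lists (and their standard deviations) quantify how strongly each
    architecture's score depends on the data split; the ordering is reported,
    not asserted.
    """
    sequences = sequences_from_records(records)
    three_r2: list[float] = []
    single_r2: list[float] = []
    for seed in split_seeds:
        plan = grouped_split(sequences.ids, k=k, seed=seed)
        train_ids, valid_ids = plan.folds[0]
        valid_records = [r for r in records if r.sequence_id in set(valid_ids)]
        pairs = [(r.sequence, r.temperature_C) for r in valid_records]
        y_true = np.log10([r.kcat_km for r in valid_records])

        three = ThreeModuleRegressor(
            m1_encoder=clone(encoder),
            m1_spec=spec,
            m2_encoder=clone(encoder),
            m2_spec=spec,
            m3_encoder=clone(encoder),
            m3_spec=spec,
            rel_floor=rel_floor,
        ).fit(records, training_ids=set(train_ids))
        three_r2.append(compute_metrics(y_true, three.predict(pairs)).r2)

        single = SingleModuleRegressor(encoder=clone(encoder), spec=spec).fit(
            records, training_ids=set(train_ids)
        )
        single_r2.append(compute_metrics(y_true, single.predict(pairs)).r2)
        logger.info(
            "seed %d: three-module r2=%.3f single-module r2=%.3f",
            seed,
            three_r2[-1],
            single_r2[-1],
        )
    return StabilityReport(three_r2, single_r2, list(split_seeds))
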