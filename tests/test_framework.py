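import numpy as np
import pytest

from enztherm import (
    GeometricMeanBaseline,
    ModelCandidate,
    NGramEncoder,
    RegressorSpec,
    SingleModuleRegressor,
    ThreeModuleRegressor,
    compare_framework_stability,
    compute_metrics,
    enumerate_and_rank_combinations,
    geometric_baseline,
    grouped_split,
    predict_profile,
    sequences_from_records,
)
from enztherm.exceptions import ValidationError

LINEAR = RegressorSpec("linear")


def linear_model(**kwargs):
    return ThreeModuleRegressor(
        m1_encoder=NGramEncoder(1),
        m1_spec=LINEAR,
        m2_encoder=NGramEncoder(1),
        m2_spec=LINEAR,
        m3_encoder=NGramEncoder(1),
        m3_spec=LINEAR,
        **kwargs,
    )


class StubModel:
    """Fixed module outputs for exercising the composition arithmetic."""

    def __init__(self, t_opt=50.0, log10_max=2.0, rel_fn=None, rel_floor=1e-3):
        self.t_opt = t_opt
        self.log10_max = log10_max
        self.rel_fn = rel_fn or (lambda dts: np.ones_like(dts))
        self.rel_floor = rel_floor

    def predict_topt(self, sequence):
        return self.t_opt

    def predict_log10_max(self, sequence):
        return self.log10_max

    def predict_rel(self, sequence, delta_ts):
        return self.rel_fn(np.asarray(delta_ts, dtype=float))


class TestComposition:
    def test_multiplicative_composition(self):
        # t_opt=50, log10_max=2, rel(+10)=0.5 -> 10^2 * 0.5 = 50 at 60 C
        stub = StubModel(rel_fn=lambda dts: np.where(dts == 10.0, 0.5, 1.0))
        profile = predict_profile(stub, "ACD", [60.0])
        frame = profile.to_frame()
        assert frame["kcat_km_hat"].iloc[0] == pytest.approx(50.0, rel=1e-12)
        assert frame["delta_t_C"].iloc[0] == 10.0

    def test_prediction_at_optimum_is_the_maximum(self):
        profile = predict_profile(StubModel(), "ACD", [50.0])
        assert profile.points["log10_kcat_km_hat"].iloc[0] == pytest.approx(2.0)

    def test_rel_floor_prevents_log_blowup(self):
        stub = StubModel(rel_fn=lambda dts: np.zeros_like(dts), rel_floor=1e-3)
        profile = predict_profile(stub, "ACD", [80.0])
        value = profile.points["log10_kcat_km_hat"].iloc[0]
        assert np.isfinite(value)
        assert value == pytest.approx(2.0 + np.log10(1e-3))

    def test_empty_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            predict_profile(StubModel(), "ACD", [])


class TestThreeModule:
    def test_smoke_train_and_heldout_predict(self, small_benchmark):
        records = small_benchmark["records"]
        sequences = small_benchmark["sequences"]
        holdout = sequences.ids[-2:]
        training = set(sequences.ids) - set(holdout)
        model = linear_model().fit(records, training_ids=training)
        for sid in holdout:
            profile = model.predict_profile(sequences[sid], [20.0, 50.0, 80.0], sid)
            assert np.isfinite(profile.points["log10_kcat_km_hat"]).all()
            assert (
                profile.points["delta_t_C"]
                == profile.points["temperature_C"] - profile.t_opt_hat
            ).all()

    def test_disjoint_training_ids_rejected(self, small_benchmark):
        with pytest.raises(ValidationError):
            linear_model().fit(small_benchmark["records"], training_ids={"nope"})

    def test_deterministic_given_seeds(self, small_benchmark):
        records = small_benchmark["records"]
        seq = small_benchmark["sequences"].sequences()[0]
        spec = RegressorSpec("random_forest", random_seed=3)
        preds = []
        for _ in range(2):
            model = ThreeModuleRegressor(
                m1_encoder=NGramEncoder(1),
                m1_spec=spec,
                m2_encoder=NGramEncoder(1),
                m2_spec=spec,
                m3_encoder=NGramEncoder(1),
                m3_spec=spec,
            ).fit(records)
            preds.append(model.predict([(seq, 30.0), (seq, 60.0)]))
        assert np.array_equal(preds[0], preds[1])

    def test_absolute_temperature_mode(self, small_benchmark):
        records = small_benchmark["records"]
        seq = small_benchmark["sequences"].sequences()[0]
        model = linear_model(temperature_mode="absolute").fit(records)
        profile = model.predict_profile(seq, [30.0, 60.0])
        assert np.isfinite(profile.points["log10_kcat_km_hat"]).all()


class TestSingleModule:
    def test_recovers_signal_on_heldout_sequences(self, small_benchmark):
        records = small_benchmark["records"]
        sequences = sequences_from_records(records)
        plan = grouped_split(sequences.ids, k=5, seed=1)
        train_ids, valid_ids = plan.folds[0]
        model = SingleModuleRegressor(
            encoder=NGramEncoder(1), spec=RegressorSpec("random_forest", random_seed=1)
        ).fit(records, training_ids=set(train_ids))
        valid = [r for r in records if r.sequence_id in set(valid_ids)]
        y_pred = model.predict([(r.sequence, r.temperature_C) for r in valid])
        y_true = np.log10([r.kcat_km for r in valid])
        assert compute_metrics(y_true, y_pred).r2 > 0

    def test_temperature_sensitivity(self, small_benchmark):
        records = small_benchmark["records"]
        seq = small_benchmark["sequences"].sequences()[0]
        model = SingleModuleRegressor(encoder=NGramEncoder(1), spec=LINEAR).fit(records)
        low, high = model.predict([(seq, 20.0), (seq, 80.0)])
        assert low != high

    def test_deterministic(self, small_benchmark):
        records = small_benchmark["records"]
        seq = small_benchmark["sequences"].sequences()[0]
        spec = RegressorSpec("random_forest", random_seed=5)
        a = SingleModuleRegressor(NGramEncoder(1), spec).fit(records)
        b = SingleModuleRegressor(NGramEncoder(1), spec).fit(records)
        assert np.array_equal(a.predict([(seq, 37.0)]), b.predict([(seq, 37.0)]))

    def test_profile_mirrors_framework_output(self, small_benchmark):
        records = small_benchmark["records"]
        seq = small_benchmark["sequences"].sequences()[0]
        model = SingleModuleRegressor(NGramEncoder(1), LINEAR).fit(records)
        profile = model.predict_profile(seq, [20.0, 40.0, 60.0, 80.0])
        assert profile.points["rel_hat"].max() == pytest.approx(1.0)
        assert set(profile.points.columns) == {
            "temperature_C",
            "delta_t_C",
            "rel_hat",
            "log10_kcat_km_hat",
        }


class TestGeometricBaseline:
    def test_equidistant_neighbors_geometric_mean(self):
        # both training sequences are at identity 0.5 from the query
        pairs = [("AAAACCCC", 10.0), ("CCCCAAAA", 1000.0)]
        assert geometric_baseline(pairs, "AAAAAAAA") == pytest.approx(100.0)

    def test_single_pair_returns_its_target(self):
        assert geometric_baseline([("ACD", 42.0)], "ACW") == pytest.approx(42.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            geometric_baseline([("ACD", 42.0)], "WYW")

    def test_identity_weighted_log_arithmetic(self):
        # identities 0.9 and 0.1; targets 10 and 1000 -> 10^(0.9*1 + 0.1*3)
        pairs = [("CAAAAAAAAA", 10.0), ("ACCCCCCCCC", 1000.0)]
        value = geometric_baseline(pairs, "AAAAAAAAAA")
        assert value == pytest.approx(10**1.2, rel=1e-9)

    def test_top_k_mode(self):
        pairs = [("AAAAAAAAAA", 10.0), ("AAAAAAAAAC", 1000.0), ("CCCCCCCCCC", 1e6)]
        value = geometric_baseline(pairs, "AAAAAAAAAA", weighting="top_k", k=2)
        assert value == pytest.approx(np.sqrt(10.0 * 1000.0))

    def test_k_truncated_with_warning(self):
        value = geometric_baseline(
            [("ACD", 100.0)], "ACD", weighting="top_k", k=5
        )
        assert value == pytest.approx(100.0)

    def test_nonpositive_targets_rejected(self):
        with pytest.raises(ValidationError):
            geometric_baseline([("ACD", -1.0)], "ACD")

    def test_estimator_wrapper_matches_function(self):
        pairs = [("AAAACCCC", 10.0), ("CCCCAAAA", 1000.0), ("AACCAACC", 31.0)]
        baseline = GeometricMeanBaseline().fit(
            [s for s, _ in pairs], [y for _, y in pairs]
        )
        queries = ["AAAAAAAA", "ACACACAC"]
        expected = [geometric_baseline(pairs, q) for q in queries]
        assert baseline.predict(queries) == pytest.approx(expected)


class TestCombinationSweep:
    def _candidates(self, labels):
        return [ModelCandidate(lab, NGramEncoder(1), LINEAR) for lab in labels]

    def test_single_candidate_each(self, small_benchmark):
        ranking = enumerate_and_rank_combinations(
            self._candidates(["a"]),
            self._candidates(["b"]),
            self._candidates(["c"]),
            small_benchmark["records"],
            split_seeds=[0],
        )
        assert len(ranking) == 1
        assert ranking.table["status"].iloc[0] == "ok"

    def test_cross_product_sorted_by_mean_r2(self, small_benchmark):
        ranking = enumerate_and_rank_combinations(
            self._candidates(["a1", "a2"]),
            self._candidates(["b1", "b2", "b3"]),
            self._candidates(["c1", "c2", "c3", "c4"]),
            small_benchmark["records"],
            split_seeds=[0],
        )
        assert len(ranking) == 24
        r2 = ranking.table["mean_r2"].to_numpy()
        assert all(r2[i] >= r2[i + 1] for i in range(len(r2) - 1))


def test_stability_report_structure(small_benchmark):
    report = compare_framework_stability(
        small_benchmark["records"],
        NGramEncoder(1),
        LINEAR,
        split_seeds=[0, 1, 2],
    )
    assert len(report.three_module_r2) == len(report.single_module_r2) == 3
    summary = report.summary()
    assert set(summary) == {
        "three_module_mean_r2",
        "three_module_sd_r2",
        "single_module_mean_r2",
        "single_module_sd_r2",
    }
    assert report.three_module_sd >= 0 and report.single_module_sd >= 0
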