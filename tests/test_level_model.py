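"""Preprocessing primitives, the level-up pipeline and the fusion harness."""

import numpy as np
import pytest

import rehabdss as r
from rehabdss.exceptions import DegenerateColumnError, UnlearnableError, WrongModelError
from rehabdss.level_model import (
    Algorithm,
    ModelConfig,
    PreprocessSpec,
    Scaler,
    Selector,
    chi_square_select,
    chi_square_statistic,
    default_config,
    evaluate,
    fit_level_model,
    minmax_normalize,
    predict_level_up,
    standardize,
    variance_score,
)
from rehabdss.metrics import FEATURE_NAMES, Mode


class TestScalers:
    def test_minmax_maps_to_unit_interval(self):
        out = minmax_normalize(np.array([[0.0], [5.0], [10.0]]))
        assert out[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_minmax_identity_on_unit_column(self):
        col = np.array([[0.0], [0.3], [1.0]])
        assert minmax_normalize(col) == pytest.approx(col)

    def test_minmax_constant_column_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.array([[3.0], [3.0], [3.0]]))
        assert (out == 0.0).all()

    def test_standardize_hand_value_sample_convention(self):
        # sample sd of [1,2,3] is 1, so output is exactly [-1, 0, 1]
        out = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert out[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_standardize_output_moments(self, rng):
        x = rng.normal(5, 3, size=(200, 4))
        out = standardize(x)
        assert out.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert out.std(axis=0, ddof=1) == pytest.approx(np.ones(4))

    def test_standardize_constant_column_raises(self):
        with pytest.raises(DegenerateColumnError):
            standardize(np.array([[1.0], [1.0]]))


class TestVarianceScore:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.25), (0.0, 0.0), (0.2, 0.16)])
    def test_bernoulli_variance(self, p, expected):
        assert variance_score(p) == pytest.approx(expected)

    def test_from_binary_column(self):
        col = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])  # p = 0.2
        assert variance_score(col) == pytest.approx(0.16)


class TestChiSquare:
    def test_statistic_hand_computed_2x2(self):
        # contingency [10, 20; 20, 10]: margins 30/30, N=60 -> E=15 per cell
        observed = [10, 20, 20, 10]
        expected = [15, 15, 15, 15]
        assert chi_square_statistic(observed, expected) == pytest.approx(20.0 / 3.0)

    def test_feature_matching_expectation_scores_zero_and_ranks_last(self):
        y = np.array([0, 0, 1, 1])
        x = np.column_stack(
            [
                [1.0, 0.0, 0.0, 1.0],  # per-class sums equal -> statistic 0
                [1.0, 1.0, 0.0, 0.0],  # fully label-aligned
            ]
        )
        assert chi_square_select(x, y, k=1) == [1]

    def test_k_equal_to_feature_count_is_identity(self, rng):
        x = rng.uniform(0, 1, size=(40, 6))
        y = rng.integers(0, 2, size=40)
        assert chi_square_select(x, y, k=6) == list(range(6))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            chi_square_select(np.array([[-1.0], [1.0]]), np.array([0, 1]), k=1)

    def test_ties_broken_toward_lower_index(self):
        y = np.array([0, 0, 1, 1])
        col = np.array([1.0, 0.0, 0.0, 1.0])  # statistic 0
        x = np.column_stack([col, col, col])
        assert chi_square_select(x, y, k=2) == [0, 1]


class TestFitPredict:
    def test_default_pipeline_composition(self, feature_library):
        m = fit_level_model(feature_library, "passive")
        assert m.spec.scaler == Scaler.NORMALIZE
        assert m.spec.selector == Selector.CHI_SQUARE
        assert m.spec.k_or_components == 19
        assert len(m.selected_features) == 19
        clf = m.classifier
        assert clf.n_estimators == 54
        assert clf.max_depth == 16
        assert clf.random_state == 70

    def test_separable_library_memorized(self):
        lib = r.generate_feature_library(200, mode="passive", label_noise=0.0, seed=3)
        m = fit_level_model(lib, "passive")
        X, y, _ = lib.feature_matrix("passive")
        rep = evaluate(m, (X, y))
        assert rep.accuracy == 100.0

    def test_same_seed_reproduces_predictions(self, feature_library):
        X, _, _ = feature_library.feature_matrix("passive")
        m1 = fit_level_model(feature_library, "passive", seed=5)
        m2 = fit_level_model(feature_library, "passive", seed=5)
        assert m1.selected_features == m2.selected_features
        assert m1.predict_proba(X) == pytest.approx(m2.predict_proba(X))

    def test_single_class_library_unlearnable(self):
        lib = r.generate_feature_library(
            50, mode="passive", thresholds={"mean_engagement": -1.0,
                                            "mean_velocity": -1.0},
            label_noise=0.0, seed=0,
        )
        with pytest.raises(UnlearnableError):
            fit_level_model(lib, "passive")

    def test_predict_bounds_and_threshold(self, feature_library):
        m = fit_level_model(feature_library, "passive")
        for case in feature_library.partition("passive")[:20]:
            p, decision = predict_level_up(m, case.features)
            assert 0.0 <= p <= 1.0
            assert decision == (p >= 0.5)

    def test_wrong_mode_rejected(self, feature_library):
        m = fit_level_model(feature_library, "passive")
        assisted = r.generate_feature_library(5, mode="assisted", seed=1)
        with pytest.raises(WrongModelError):
            predict_level_up(m, assisted.partition("assisted")[0].features)

    def test_persistence_round_trip(self, tmp_path, feature_library):
        m = fit_level_model(feature_library, "passive", seed=2)
        path = tmp_path / "model.joblib"
        r.save_model(m, path)
        m2 = r.load_model(path)
        X, _, _ = feature_library.feature_matrix("passive")
        assert m2.predict_proba(X) == pytest.approx(m.predict_proba(X))
        assert m2.library_fingerprint == m.library_fingerprint
        assert m2.selected_features == m.selected_features


class _StubModel:
    """Fixed-probability scorer for checking metric arithmetic."""

    def __init__(self, probs):
        self.mode = Mode.PASSIVE
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return self._p


class TestEvaluate:
    def test_all_correct_is_perfect(self):
        y = np.array([1, 1, 0, 0])
        rep = evaluate(_StubModel([0.9, 0.8, 0.1, 0.2]), (np.zeros((4, 1)), y))
        assert (rep.accuracy, rep.recall, rep.f1) == (100.0, 100.0, 100.0)
        assert rep.auc == 1.0

    def test_hand_computed_confusion_table(self):
        # TP=8, FN=2, TN=8, FP=2 -> accuracy 80%, recall 80%, F1 80%
        y = np.array([1] * 10 + [0] * 10)
        probs = np.array([1.0] * 8 + [0.0] * 2 + [0.0] * 8 + [1.0] * 2)
        rep = evaluate(_StubModel(probs), (np.zeros((20, 1)), y))
        assert rep.accuracy == pytest.approx(80.0)
        assert rep.recall == pytest.approx(80.0)
        assert rep.f1 == pytest.approx(80.0)
        # binary scores: AUC = P(p+ > p-) + 0.5 P(tie) = 0.64 + 0.16
        assert rep.auc == pytest.approx(0.8)

    def test_label_independent_scores_have_chance_auc(self, rng):
        n = 4000
        y = rng.integers(0, 2, size=n)
        probs = rng.uniform(0, 1, size=n)
        rep = evaluate(_StubModel(probs), (np.zeros((n, 1)), y))
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(UnlearnableError):
            evaluate(_StubModel([0.5, 0.5]), (np.zeros((2, 1)), np.array([1, 1])))


class TestFusionComparison:
    def test_cross_product_row_count_and_determinism(self, session_library):
        specs = [
            PreprocessSpec(Scaler.NORMALIZE, Selector.CHI_SQUARE, 10),
            PreprocessSpec(Scaler.RAW, Selector.VARIANCE, 10),
        ]
        cfgs = [
            default_config(Algorithm.RANDOM_FOREST),
            ModelConfig(Algorithm.LOGISTIC_REGRESSION,
                        {"penalty": "l2", "solver": "liblinear", "C": 0.1}),
        ]
        t1 = r.run_fusion_comparison(session_library, specs, cfgs, seed=4)
        t2 = r.run_fusion_comparison(session_library, specs, cfgs, seed=4)
        assert len(t1) == 3 * 2 * 2
        assert t1.equals(t2)

    def test_production_cell_beats_majority_baseline(self, session_library):
        t = r.run_fusion_comparison(
            session_library,
            specs=[PreprocessSpec(Scaler.NORMALIZE, Selector.CHI_SQUARE, 19)],
            cfgs=[default_config(Algorithm.RANDOM_FOREST)],
            seed=0,
            modes=[Mode.ASSISTED],
        )
        X, y, _ = session_library.feature_matrix("assisted")
        majority = 100.0 * max(y.mean(), 1 - y.mean())
        assert t["accuracy"].iloc[0] >= majority
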