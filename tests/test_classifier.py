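import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from celldiff.classifier import (
    ConfidenceCalibrator,
    DiffusionClassifier,
    calibrate_confidence,
    confidence_score,
    trial_errors,
)
from celldiff.rng import stream
from helpers import CondBiasStub, EpsPlusBiasStub, NoisyStub, tiny_setup


@pytest.fixture
def setup3():
    return tiny_setup(K=3, D=12)


class TestTrialErrors:
    def test_cond_bias_stub_matches_hand_computation(self, setup3):
        sched, cond, codec = setup3
        rng = stream(0, "te")
        z0 = rng.standard_normal(12).astype(np.float32)
        eps = rng.standard_normal(12).astype(np.float32)
        bias = rng.standard_normal((3, 12)).astype(np.float32)
        stub = CondBiasStub(bias)
        errs = trial_errors(stub, z0, 5, eps, sched, cond)
        for i, c in enumerate(cond.class_names):
            expected = float(np.sum((eps.astype(np.float64) - bias[i]) ** 2))
            assert abs(errs[c] - expected) <= 1e-10

    def test_eps_recovering_stub_gives_zero_and_bias_norm(self, setup3):
        """Class 0 predicts the injected noise exactly; class 1 is off by a
        constant vector, so its error is that vector's squared norm."""
        sched, cond, codec = setup3
        bias = np.zeros((3, 12), dtype=np.float32)
        bias[1, 0] = 1.0
        stub = EpsPlusBiasStub(sched, bias)
        eps = stream(1, "te2").standard_normal(12).astype(np.float32)
        errs = trial_errors(stub, np.zeros(12, dtype=np.float32), 7, eps, sched, cond)
        assert errs["c0"] == pytest.approx(0.0, abs=1e-9)
        assert errs["c1"] == pytest.approx(1.0, abs=1e-5)

    def test_weight_scales_linearly(self, setup3):
        sched, cond, _ = setup3
        stub = CondBiasStub(np.ones((3, 12), dtype=np.float32))
        z0 = np.zeros(12, dtype=np.float32)
        eps = np.full(12, 0.5, dtype=np.float32)
        e1 = trial_errors(stub, z0, 3, eps, sched, cond, w_t=1.0)
        e2 = trial_errors(stub, z0, 3, eps, sched, cond, w_t=2.0)
        for c in e1:
            assert e2[c] == pytest.approx(2 * e1[c], rel=1e-12)

    def test_empty_class_set_rejected(self, setup3):
        sched, cond, _ = setup3
        with pytest.raises(ValueError, match="empty"):
            trial_errors(CondBiasStub(np.zeros((3, 12))), np.zeros(12), 1,
                         np.zeros(12), sched, cond, classes=[])


class TestExhaustive:
    def test_analytic_bias_ordering(self, setup3):
        """Predictions eps + b_c with ||b_0|| < ||b_1|| < ||b_2|| make class 0
        the argmin for any trial count."""
        sched, cond, codec = setup3
        bias = np.zeros((3, 12), dtype=np.float32)
        bias[1, 0], bias[2, 0] = 0.5, 1.0
        clf = DiffusionClassifier(EpsPlusBiasStub(sched, bias), sched, cond, codec)
        img = np.zeros((2, 2, 3))
        for n in (1, 5, 50):
            assert clf.classify_exhaustive(img, n_iters=n, seed=4).predicted == "c0"

    def test_single_class_returns_zero_confidence(self):
        sched, cond, codec = tiny_setup(K=1, D=12)
        clf = DiffusionClassifier(CondBiasStub(np.zeros((1, 12))), sched, cond, codec)
        r = clf.classify_exhaustive(np.zeros((2, 2, 3)), n_iters=5, seed=0)
        assert r.predicted == "c0"
        assert r.confidence_raw == 0.0

    def test_same_seed_identical_result(self, setup3):
        sched, cond, codec = setup3
        clf = DiffusionClassifier(NoisyStub(3), sched, cond, codec)
        clf2 = DiffusionClassifier(NoisyStub(3), sched, cond, codec)
        img = np.zeros((2, 2, 3))
        assert (clf.classify_exhaustive(img, n_iters=20, seed=9).to_dict()
                == clf2.classify_exhaustive(img, n_iters=20, seed=9).to_dict())

    def test_decision_equals_bruteforce_argmin_of_trial_table(self, setup3):
        """Oracle equivalence: with elimination disabled the decision is the
        exact argmin of the stored per-class error table."""
        sched, cond, codec = setup3
        img = np.zeros((2, 2, 3))
        for s in range(10):
            clf = DiffusionClassifier(NoisyStub(s), sched, cond, codec)
            r = clf.classify_exhaustive(img, n_iters=30, seed=s, keep_trials=True)
            table = np.array([[tr.weighted_error_by_class[c]
                               for c in cond.class_names] for tr in r.trials])
            assert r.predicted == cond.class_names[int(np.argmin(table.mean(0)))]
            for c, m in r.mean_error_by_class.items():
                assert m == pytest.approx(
                    table[:, cond.class_names.index(c)].mean(), rel=1e-12)

    def test_shared_trial_pairing(self, setup3):
        """Every trial records one (t, eps_seed) shared by all classes."""
        sched, cond, codec = setup3
        clf = DiffusionClassifier(NoisyStub(1), sched, cond, codec)
        r = clf.classify_exhaustive(np.zeros((2, 2, 3)), n_iters=10, seed=2,
                                    keep_trials=True)
        assert len(r.trials) == 10
        for tr in r.trials:
            assert set(tr.weighted_error_by_class) == set(cond.class_names)


class TestEliminating:
    def test_constant_positive_difference_eliminates_at_min_evals(self, setup3):
        sched, cond, codec = tiny_setup(K=2, D=12)
        bias = np.zeros((2, 12), dtype=np.float32)
        bias[1, 0] = 1.0  # class 1 constantly worse by exactly 1
        clf = DiffusionClassifier(EpsPlusBiasStub(sched, bias), sched, cond, codec)
        r = clf.classify_eliminating(np.zeros((2, 2, 3)), min_evals=20, seed=5)
        assert r.predicted == "c0"
        assert r.total_iterations == 20
        assert len(r.elimination_order) == 1
        name, it, p = r.elimination_order[0]
        assert (name, it) == ("c1", 20)
        assert p < 1e-6

    def test_planted_best_class_survives(self):
        """With a planted effect the correct class is essentially never
        eliminated (safety of the conservative threshold)."""
        sched, cond, codec = tiny_setup(K=3, D=12)
        rng = stream(0, "plant")
        survived = 0
        n_runs = 200
        for s in range(n_runs):
            bias = 0.4 * np.abs(rng.standard_normal((3, 12))).astype(np.float32)
            bias[0] = 0.0  # planted best
            clf = DiffusionClassifier(EpsPlusBiasStub(sched, bias), sched, cond, codec)
            r = clf.classify_eliminating(np.zeros((2, 2, 3)), max_iters=100, seed=s)
            survived += r.predicted == "c0"
        assert survived / n_runs >= 0.99

    def test_result_bookkeeping_invariants(self, setup3):
        sched, cond, codec = setup3
        clf = DiffusionClassifier(NoisyStub(7), sched, cond, codec)
        r = clf.classify_eliminating(np.zeros((2, 2, 3)), max_iters=60, seed=1)
        for name, it, p in r.elimination_order:
            assert r.n_scores_by_class[name] >= 20
            assert p < 2e-3
        assert r.n_scores_by_class[r.predicted] == r.total_iterations

    def test_parameter_validation(self, setup3):
        sched, cond, codec = setup3
        clf = DiffusionClassifier(NoisyStub(0), sched, cond, codec)
        img = np.zeros((2, 2, 3))
        with pytest.raises(ValueError, match="min_evals"):
            clf.classify_eliminating(img, min_evals=1)
        with pytest.raises(ValueError, match="p_threshold"):
            clf.classify_eliminating(img, p_threshold=1.5)


class TestConfidence:
    def test_gap_examples(self):
        assert confidence_score({"a": 0.3, "b": 0.3, "c": 0.9}) == 0.0
        assert confidence_score({"a": 0.1, "b": 0.4}) == pytest.approx(0.3)
        assert confidence_score({"b": 0.4, "a": 0.1}) == pytest.approx(0.3)

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            confidence_score({"a": 0.1})

    def test_minmax_calibration(self):
        cal = calibrate_confidence([0.0, 5.0, 10.0])
        np.testing.assert_allclose(cal.transform(np.array([0.0, 5.0, 10.0])),
                                   [0.0, 0.5, 1.0])
        assert cal.transform(20.0) == 1.0  # clipped
        assert cal.transform(-3.0) == 0.0

    def test_constant_scores_warn_and_map_to_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            cal = calibrate_confidence([2.0, 2.0, 2.0])
        assert cal.transform(5.0) == 0.0

    def test_serialisation(self):
        cal = ConfidenceCalibrator(1.0, 3.0)
        cal2 = ConfidenceCalibrator.from_dict(cal.to_dict())
        assert cal2.transform(2.0) == 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=20),
           st.lists(st.floats(min_value=-200, max_value=200), min_size=2,
                    max_size=20))
    def test_calibrated_mapping_is_monotone(self, fit_scores, query):
        if max(fit_scores) == min(fit_scores):
            return
        cal = ConfidenceCalibrator.fit(fit_scores)
        q = np.sort(np.asarray(query))
        out = cal.transform(q)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 1))
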