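import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from celldiff.psychometrics import (
    BernoulliTrialSet,
    PsychometricModel,
    aggregate_expert_confidence,
    binned_accuracy,
    fit_psychometric,
    logit_gap_confidence,
    psychometric_value,
    simulate_observer,
)
from celldiff.rng import stream


class TestPsychometricValue:
    def test_upper_asymptote(self):
        m = PsychometricModel(threshold=0.5, width=0.3, guess_rate=0.2,
                              lapse_rate=0.07)
        assert psychometric_value(100.0, m) == pytest.approx(1 - 0.07, abs=1e-9)

    def test_lower_asymptote(self):
        m = PsychometricModel(threshold=0.5, width=0.3, guess_rate=0.2)
        assert psychometric_value(-100.0, m) == pytest.approx(0.2, abs=1e-9)

    def test_threshold_convention_value(self):
        # S(m) = 0.8 by construction: psi(m) = 0.1 + 0.9 * 0.8 = 0.82
        m = PsychometricModel(threshold=0.5, width=0.4, guess_rate=0.1,
                              lapse_rate=0.0)
        assert psychometric_value(0.5, m) == pytest.approx(0.82, abs=1e-12)

    def test_width_convention_span(self):
        m = PsychometricModel(threshold=0.0, width=1.0, guess_rate=0.5)
        # locate S = 0.05 / 0.95 via psi and invert the affine wrapping
        from scipy.stats import norm

        z80, z95 = norm.ppf(0.8), norm.ppf(0.95)
        slope = 2 * z95 / 1.0
        x05 = (norm.ppf(0.05) - z80) / slope
        x95 = (z95 - z80) / slope
        assert x95 - x05 == pytest.approx(1.0, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PsychometricModel(0.5, -0.1, 0.2)
        with pytest.raises(ValueError):
            PsychometricModel(0.5, 0.3, 0.6, lapse_rate=0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-1, 2), st.floats(0.01, 3), st.floats(0.01, 0.6),
           st.floats(0, 0.3))
    def test_monotone_in_signal(self, m, w, g, lam):
        if g + lam >= 1:
            return
        model = PsychometricModel(m, w, g, lam)
        xs = np.linspace(-2, 3, 50)
        assert np.all(np.diff(psychometric_value(xs, model)) >= -1e-12)


@pytest.fixture(scope="module")
def fitted():
    truth = PsychometricModel(0.5, 0.4, 0.1, 0.05)
    signals = np.tile(np.linspace(0, 1, 21), 100)
    trials = simulate_observer(truth, signals, seed=5)
    return fit_psychometric(trials, guess_rate=0.1), trials, truth


class TestFit:
    def test_posterior_mass_normalised(self, fitted):
        fit, _, _ = fitted
        assert abs(fit.posterior.sum() - 1.0) <= 1e-9

    def test_credibility_interval_contains_posterior_mean(self, fitted):
        fit, _, _ = fitted
        for p in ("threshold", "width", "lapse"):
            lo, hi = fit.ci95[p]
            assert lo <= fit.posterior_mean[p] <= hi

    def test_recovers_generating_threshold(self, fitted):
        fit, _, truth = fitted
        lo, hi = fit.ci95["threshold"]
        assert abs(fit.posterior_mean["threshold"] - truth.threshold) < truth.width / 4
        assert lo < hi

    def test_grid_likelihood_matches_bruteforce(self, fitted):
        """Independent per-trial Bernoulli log-likelihood at random nodes."""
        fit, trials, _ = fitted
        rng = stream(0, "nodes")
        for _ in range(10):
            im = int(rng.integers(len(fit.grid_m)))
            iw = int(rng.integers(len(fit.grid_w)))
            il = int(rng.integers(len(fit.grid_lam)))
            model = PsychometricModel(fit.grid_m[im], fit.grid_w[iw], 0.1,
                                      fit.grid_lam[il])
            psi = np.clip(psychometric_value(trials.signals, model),
                          1e-12, 1 - 1e-12)
            ll = float(np.sum(np.where(trials.correct, np.log(psi),
                                       np.log1p(-psi))))
            assert abs(ll - fit.log_likelihood[im, iw, il]) <= 1e-9 * max(1, abs(ll))

    def test_ceiling_data_concentrates_lapse_low(self):
        signals = np.tile(np.linspace(0, 1, 11), 40)
        trials = BernoulliTrialSet(signals, np.ones_like(signals, dtype=int))
        fit = fit_psychometric(trials, guess_rate=0.1)
        assert fit.posterior_mean["lapse"] < 0.05
        assert 1.0 - fit.posterior_mean["lapse"] >= 0.95

    def test_requires_two_distinct_signals(self):
        trials = BernoulliTrialSet(np.full(10, 0.5), np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="distinct"):
            fit_psychometric(trials, guess_rate=0.1)

    def test_summary_renders(self, fitted):
        fit, _, _ = fitted
        s = fit.summary()
        assert "threshold" in s and "95% CrI" in s


class TestObserver:
    def test_high_signal_no_lapse_always_correct(self):
        m = PsychometricModel(0.3, 0.2, 0.25, lapse_rate=0.0)
        trials = simulate_observer(m, np.full(200, 5.0), seed=1)
        assert trials.correct.all()

    def test_empirical_accuracy_converges_to_psi(self):
        m = PsychometricModel(0.5, 0.4, 0.1, 0.05)
        x = 0.55
        trials = simulate_observer(m, np.full(10_000, x), seed=2)
        p = float(psychometric_value(x, m))
        assert abs(trials.correct.mean() - p) < 4 * np.sqrt(p * (1 - p) / 10_000)

    def test_seeded_reproducibility(self):
        m = PsychometricModel(0.5, 0.4, 0.1, 0.05)
        x = np.linspace(0, 1, 50)
        np.testing.assert_array_equal(simulate_observer(m, x, seed=9).correct,
                                      simulate_observer(m, x, seed=9).correct)


class TestBinnedAccuracy:
    def test_single_occupied_bin(self):
        trials = BernoulliTrialSet(np.full(10, 0.55), np.array([1] * 7 + [0] * 3))
        pts = binned_accuracy(trials, n_bins=5)
        assert len(pts) == 1
        assert pts[0]["accuracy"] == pytest.approx(0.7)
        assert pts[0]["count"] == 10

    def test_counts_conserved(self):
        rng = stream(3, "bins")
        trials = BernoulliTrialSet(rng.random(123),
                                   rng.integers(0, 2, 123))
        pts = binned_accuracy(trials, n_bins=7)
        assert sum(p["count"] for p in pts) == 123

    def test_hand_computed_three_bins(self):
        x = np.array([0.1, 0.2, 0.5, 0.55, 0.9, 0.95])
        y = np.array([1, 0, 1, 1, 0, 1])
        pts = binned_accuracy(BernoulliTrialSet(x, y), n_bins=3)
        assert [p["count"] for p in pts] == [2, 2, 2]
        assert [p["accuracy"] for p in pts] == [0.5, 1.0, 0.5]
        assert pts[0]["mean_signal"] == pytest.approx(0.15)


class TestExpertAggregation:
    def test_paper_mapping(self):
        assert aggregate_expert_confidence(["high", "moderate", "none"]) == \
            pytest.approx(5 / 9)
        assert aggregate_expert_confidence(["high", "high"]) == 1.0
        assert aggregate_expert_confidence(["low"]) == pytest.approx(1 / 3)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            aggregate_expert_confidence(["very sure"])
        with pytest.raises(ValueError):
            aggregate_expert_confidence([])


class TestLogitGap:
    def test_examples(self):
        assert logit_gap_confidence([2.0, 2.0, -1.0]) == 0.0
        assert logit_gap_confidence([3.0, 1.0]) == 2.0

    def test_shift_invariance(self):
        z = np.array([0.4, -1.2, 3.3, 0.0])
        assert logit_gap_confidence(z) == pytest.approx(logit_gap_confidence(z + 10))

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            logit_gap_confidence([1.0])
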