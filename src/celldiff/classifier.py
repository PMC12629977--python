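"""Classification by class-conditional noise-prediction error.

Under Bayes' rule with a uniform class prior, the predicted class is the
one maximising the class-conditional likelihood; a conditional diffusion
model's denoising loss is a monotone surrogate for the negative
log-likelihood, so the decision rule is

    c_hat = argmin_c  E_{eps, t} [ w_t * || eps - eps_theta(z_t, t, c) ||^2 ].

Each trial draws one (t, eps) pair and scores *every* surviving class with
the same pair, giving paired error samples.  Inference either runs a fixed
number of trials (exhaustive mode) or progressively eliminates classes that
are statistically unlikely to achieve the lowest error — a successive-
elimination best-arm identification scheme driven by a paired Student's
t-test with a conservative threshold (default p < 2e-3, at least 20 scores
per class, at most 2000 trials).

The model's confidence in a decision is the gap between the two smallest
mean errors, min-max rescaled to [0, 1] on a calibration batch that is
frozen before any test data is touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffusion import (
    ClassConditioning,
    DenoiserModel,
    IdentityCodec,
    LatentCodec,
    NoiseSchedule,
    add_noise,
)
from .rng import child_seed, stream

__all__ = [
    "TrialRecord",
    "ClassifierResult",
    "trial_errors",
    "DiffusionClassifier",
    "confidence_score",
    "ConfidenceCalibrator",
    "calibrate_confidence",
]

logger = logging.getLogger(__name__)


@dataclass
class TrialRecord:
    """One inference trial: the shared (t, eps) and each survivor's error."""

    iteration: int
    t: int
    eps_seed: int
    weighted_error_by_class: dict[str, float]


@dataclass
class ClassifierResult:
    """Outcome of one classification run."""

    predicted: str
    mean_error_by_class: dict[str, float]
    n_scores_by_class: dict[str, int]
    elimination_order: list[tuple[str, int, float]]
    total_iterations: int
    confidence_raw: float
    confidence: float | str = "uncalibrated"
    tests_performed: int = 0
    delta_by_class: dict[str, np.ndarray] | None = None
    trials: list[TrialRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "predicted": self.predicted,
            "mean_error_by_class": {k: float(v) for k, v in self.mean_error_by_class.items()},
            "n_scores_by_class": {k: int(v) for k, v in self.n_scores_by_class.items()},
            "elimination_order": [
                [c, int(i), float(p)] for c, i, p in self.elimination_order
            ],
            "total_iterations": int(self.total_iterations),
            "confidence_raw": float(self.confidence_raw),
            "confidence": self.confidence if isinstance(self.confidence, str)
            else float(self.confidence),
            "tests_performed": int(self.tests_performed),
        }


def trial_errors(
    model: DenoiserModel,
    z0: np.ndarray,
    t: int,
    eps: np.ndarray,
    schedule: NoiseSchedule,
    conditioning: ClassConditioning,
    classes: list[str] | None = None,
    w_t: float = 1.0,
) -> dict[str, float]:
    """Weighted per-class error for one shared (t, eps) trial.

    Returns ``{c: w_t * ||eps - eps_theta(z_t, t, embed(c))||^2}`` where the
    same noised latent z_t is scored under every class condition.
    """
    classes = list(conditioning.class_names) if classes is None else list(classes)
    if not classes:
        raise ValueError("empty class set")
    if w_t <= 0:
        raise ValueError(f"w_t must be > 0, got {w_t}")
    z0 = np.asarray(z0, dtype=np.float32)
    eps = np.asarray(eps, dtype=np.float32)
    if eps.shape != z0.shape:
        raise ValueError(f"eps shape {eps.shape} != z0 shape {z0.shape}")
    z_t = add_noise(z0, t, eps, schedule).astype(np.float32)
    X = np.tile(z_t, (len(classes), 1))
    C = np.stack([conditioning.embed(c) for c in classes])
    pred = model.predict(X, np.full(len(classes), t), C)
    err = np.sum((eps[None, :].astype(np.float64) - pred.astype(np.float64)) ** 2, axis=1)
    return {c: float(w_t * e) for c, e in zip(classes, err)}


def confidence_score(mean_error_by_class: dict[str, float]) -> float:
    """Raw confidence: second-smallest minus smallest mean weighted error."""
    if len(mean_error_by_class) < 2:
        raise ValueError("confidence requires at least 2 classes")
    e = np.sort(np.array(list(mean_error_by_class.values()), dtype=float))
    return float(e[1] - e[0])


class ConfidenceCalibrator:
    """Min-max rescaling of raw confidence gaps to [0, 1].

    Fitted once on a calibration batch (by default the validation split) and
    frozen; applied scores are clipped to [0, 1].  A constant calibration
    batch yields the constant-0 mapping with a warning.
    """

    def __init__(self, lo: float, hi: float):
        self.lo = float(lo)
        self.hi = float(hi)

    @classmethod
    def fit(cls, raw_scores) -> "ConfidenceCalibrator":
        scores = np.asarray(list(raw_scores), dtype=float)
        if len(scores) < 2 or not np.all(np.isfinite(scores)):
            raise ValueError("need >= 2 finite scores to calibrate")
        lo, hi = float(scores.min()), float(scores.max())
        if lo == hi:
            warnings.warn("all calibration scores identical; mapping is constant 0")
        return cls(lo, hi)

    def transform(self, raw):
        raw = np.asarray(raw, dtype=float)
        if self.hi == self.lo:
            return np.zeros_like(raw) if raw.ndim else 0.0
        out = np.clip((raw - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        return out if raw.ndim else float(out)

    def __call__(self, raw):
        return self.transform(raw)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceCalibrator":
        return cls(d["lo"], d["hi"])


def calibrate_confidence(raw_scores) -> ConfidenceCalibrator:
    """Fit the min-max confidence mapping on a calibration batch."""
    return ConfidenceCalibrator.fit(raw_scores)


def _p_from_moments(mean: float, sd: float, n: int, alternative: str) -> float:
    """Paired t-test p-value from the difference mean and SD over n trials.

    Degenerate zero-variance differences: p = 0 for a positive mean
    (elimination certain), p = 1 otherwise.
    """
    if sd == 0.0:
        return 0.0 if mean > 0 else 1.0
    tstat = mean / (sd / np.sqrt(n))
    if alternative == "greater":
        return float(stats.t.sf(tstat, n - 1))
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(tstat), n - 1))
    raise ValueError(f"unknown alternative {alternative!r}")


def _paired_p_value(d: np.ndarray, alternative: str = "two-sided") -> float:
    """Paired t-test p-value on raw differences ``d`` (candidate - best)."""
    d = np.asarray(d, dtype=float)
    return _p_from_moments(float(d.mean()), float(d.std(ddof=1)), len(d), alternative)


class DiffusionClassifier:
    """Bundles a denoiser, schedule, codec and conditioning into a classifier.

    ``timestep_weights`` (w_t), if given, is an array of length T+1 indexed
    by timestep; the default is uniform weighting, which is unbiased for
    between-class comparison because every class is scored with the same
    (t, eps) pair in each trial.
    """

    def __init__(
        self,
        model: DenoiserModel,
        schedule: NoiseSchedule,
        conditioning: ClassConditioning,
        codec: LatentCodec | None = None,
        timestep_weights: np.ndarray | None = None,
        calibrator: ConfidenceCalibrator | None = None,
        t_range: tuple[int, int] | None = None,
    ):
        self.model = model
        self.schedule = schedule
        self.conditioning = conditioning
        self.codec = codec if codec is not None else IdentityCodec()
        if t_range is None:
            t_range = (1, schedule.T)
        t_lo, t_hi = int(t_range[0]), int(t_range[1])
        if not 1 <= t_lo <= t_hi <= schedule.T:
            raise ValueError(f"t_range must satisfy 1 <= lo <= hi <= T, got {t_range}")
        #: inclusive band trials sample t from, uniformly.  The full range is
        #: the null choice; a band excluding near-pure-noise timesteps cuts
        #: trial variance when the class signal is concentrated at low noise.
        self.t_range = (t_lo, t_hi)
        if timestep_weights is not None:
            timestep_weights = np.asarray(timestep_weights, dtype=np.float64)
            if len(timestep_weights) != schedule.T + 1:
                raise ValueError("timestep_weights must have length T+1")
            if np.any(timestep_weights <= 0):
                raise ValueError("timestep_weights must be positive")
        self.timestep_weights = timestep_weights
        self.calibrator = calibrator

    # ------------------------------------------------------------------

    def _encode(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.ndim == 1:  # already a latent
            return image.astype(np.float32)
        return self.codec.encode(image).astype(np.float32)

    def _wt(self, t: np.ndarray) -> np.ndarray:
        if self.timestep_weights is None:
            return np.ones(len(t))
        return self.timestep_weights[t]

    def fit_timestep_weights(self, images: np.ndarray, seed: int = 0,
                             n_samples: int = 512, n_bins: int = 10) -> np.ndarray:
        """Optional variance-reducing w_t: inverse across-class mean error per t-bin.

        Estimated on a calibration pass; returns (and installs) an array of
        length T+1 giving 1 / (mean error in the timestep's bin), so that
        trials at noisy timesteps with intrinsically large errors do not
        dominate the running means.
        """
        rng = stream(seed, "wt_calibration")
        T = self.schedule.T
        K = self.conditioning.K
        D = self.codec.latent_shape[0]
        Z = self.codec.encode(np.asarray(images)).astype(np.float32)
        idx = rng.integers(0, len(Z), size=n_samples)
        ts = rng.integers(self.t_range[0], self.t_range[1] + 1, size=n_samples)
        eps = rng.standard_normal((n_samples, D)).astype(np.float32)
        zt = add_noise(Z[idx], ts, eps, self.schedule).astype(np.float32)
        X = np.repeat(zt, K, axis=0)
        t_rep = np.repeat(ts, K)
        C = np.tile(self.conditioning.embed_all(), (n_samples, 1))
        pred = self.model.predict(X, t_rep, C)
        err = np.sum((np.repeat(eps, K, axis=0).astype(np.float64) - pred) ** 2, axis=1)
        err = err.reshape(n_samples, K).mean(axis=1)
        edges = np.linspace(0, T, n_bins + 1)
        bin_of = np.clip(np.digitize(ts, edges[1:-1]), 0, n_bins - 1)
        mean_per_bin = np.array([
            err[bin_of == b].mean() if np.any(bin_of == b) else err.mean()
            for b in range(n_bins)
        ])
        t_axis = np.arange(T + 1)
        bins_t = np.clip(np.digitize(t_axis, edges[1:-1]), 0, n_bins - 1)
        w = 1.0 / mean_per_bin[bins_t]
        self.timestep_weights = w
        return w

    # ------------------------------------------------------------------

    def classify_exhaustive(
        self,
        image: np.ndarray,
        n_iters: int = 200,
        seed: int = 0,
        accumulate_deltas: bool = False,
        keep_trials: bool = False,
        chunk: int | None = None,
    ) -> ClassifierResult:
        """Score every class for ``n_iters`` shared-(t, eps) trials, no elimination.

        The decision is the argmin of mean weighted error; ties break to the
        lowest class index with a logged warning.  With
        ``accumulate_deltas`` the signed residual mean Delta_c (the
        counterfactual accumulator) is returned per class from the same
        trial stream.
        """
        if n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if chunk is None:
            # conv backbones build large im2col buffers; bound the batch
            chunk = 64 if getattr(self.model, "arch", None) == "conv" else 256
        z0 = self._encode(image)
        D = z0.shape[0]
        K = self.conditioning.K
        names = self.conditioning.class_names
        rng = stream(seed, "classify")
        ts = rng.integers(self.t_range[0], self.t_range[1] + 1, size=n_iters)
        wt = self._wt(ts)
        Call = self.conditioning.embed_all()
        err_table = np.empty((n_iters, K))
        delta_sum = np.zeros((K, D)) if accumulate_deltas else None
        trials: list[TrialRecord] = []
        for start in range(0, n_iters, chunk):
            stop = min(start + chunk, n_iters)
            b = stop - start
            eps = rng.standard_normal((b, D)).astype(np.float32)
            zt = add_noise(np.tile(z0, (b, 1)), ts[start:stop], eps, self.schedule)
            X = np.repeat(zt.astype(np.float32), K, axis=0)
            t_rep = np.repeat(ts[start:stop], K)
            C = np.tile(Call, (b, 1))
            pred = self.model.predict(X, t_rep, C)
            res = np.repeat(eps, K, axis=0).astype(np.float64) - pred.astype(np.float64)
            err = np.sum(res * res, axis=1).reshape(b, K)
            err_table[start:stop] = err * wt[start:stop, None]
            if accumulate_deltas:
                delta_sum += res.reshape(b, K, D).sum(axis=0)
            if keep_trials:
                for i in range(b):
                    trials.append(TrialRecord(
                        iteration=start + i, t=int(ts[start + i]), eps_seed=start + i,
                        weighted_error_by_class=dict(zip(names, err_table[start + i])),
                    ))
        means = err_table.mean(axis=0)
        pred_idx = int(np.argmin(means))
        if np.sum(means == means[pred_idx]) > 1:
            logger.warning("tied mean errors; breaking tie to lowest class index")
        raw = confidence_score(dict(zip(names, means))) if K >= 2 else 0.0
        return ClassifierResult(
            predicted=names[pred_idx],
            mean_error_by_class=dict(zip(names, means)),
            n_scores_by_class={c: n_iters for c in names},
            elimination_order=[],
            total_iterations=n_iters,
            confidence_raw=raw,
            confidence=self.calibrator.transform(raw) if self.calibrator else "uncalibrated",
            delta_by_class=(
                {c: delta_sum[i] / n_iters for i, c in enumerate(names)}
                if accumulate_deltas else None
            ),
            trials=trials,
        )

    def classify_eliminating(
        self,
        image: np.ndarray,
        p_threshold: float = 2e-3,
        min_evals: int = 20,
        max_iters: int = 2000,
        seed: int = 0,
        alternative: str = "two-sided",
        keep_trials: bool = False,
        block: int = 16,
    ) -> ClassifierResult:
        """Successive-elimination classification.

        Every trial scores all surviving classes with one shared (t, eps).
        Once each survivor has at least ``min_evals`` scores, each
        non-best survivor is tested against the current best (the survivor
        with the lowest running mean) by a paired Student's t-test on the
        per-trial error differences, and eliminated when its mean error is
        the larger and p < ``p_threshold``.  Stops at one survivor or
        ``max_iters`` trials; the decision is then the argmin of running
        means among the survivors.
        """
        if not 0.0 < p_threshold < 1.0:
            raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
        if min_evals < 2:
            raise ValueError("min_evals must be >= 2 (t-test undefined below)")
        z0 = self._encode(image)
        D = z0.shape[0]
        K = self.conditioning.K
        names = self.conditioning.class_names
        rng = stream(seed, "classify")
        Call = self.conditioning.embed_all()
        alive = list(range(K))
        err_sum = np.zeros(K)
        n_scores = np.zeros(K, dtype=int)
        # incremental paired-difference statistics: S[i, j] and SS[i, j] hold
        # sum and sum-of-squares of (err_i - err_j) over the shared trials
        S = np.zeros((K, K))
        SS = np.zeros((K, K))
        elimination_order: list[tuple[str, int, float]] = []
        tests_performed = 0
        trials: list[TrialRecord] = []
        it = 0
        while it < max_iters and (len(alive) > 1 or (K == 1 and it < min_evals)):
            # trials are scored in blocks for throughput; the t-test cadence
            # is still per iteration, and scores drawn for a class after its
            # elimination iteration are simply discarded
            B = min(block, max_iters - it)
            block_alive = list(alive)
            nb = len(block_alive)
            ts = rng.integers(self.t_range[0], self.t_range[1] + 1, size=B)
            eps_blk = rng.standard_normal((B, D)).astype(np.float32)
            zts = add_noise(np.tile(z0, (B, 1)), ts, eps_blk, self.schedule
                            ).astype(np.float32)
            X = np.repeat(zts, nb, axis=0)
            pred = self.model.predict(X, np.repeat(ts, nb),
                                      np.tile(Call[block_alive], (B, 1)))
            res = (np.repeat(eps_blk, nb, axis=0).astype(np.float64)
                   - pred.astype(np.float64))
            errs_blk = np.sum(res * res, axis=1).reshape(B, nb) * self._wt(ts)[:, None]
            col_of = {ci: j for j, ci in enumerate(block_alive)}
            for b in range(B):
                if len(alive) < 2 and K > 1:
                    break
                it += 1
                cols = [col_of[ci] for ci in alive]
                err = errs_blk[b, cols]
                ix = np.ix_(alive, alive)
                dmat = err[:, None] - err[None, :]
                S[ix] += dmat
                SS[ix] += dmat * dmat
                err_sum[alive] += err
                n_scores[alive] += 1
                if keep_trials:
                    trials.append(TrialRecord(
                        iteration=it, t=int(ts[b]), eps_seed=it,
                        weighted_error_by_class={names[ci]: float(e)
                                                 for ci, e in zip(alive, err)},
                    ))
                if it < min_evals or len(alive) < 2:
                    continue
                means = err_sum[alive] / it
                best = alive[int(np.argmin(means))]
                for ci in list(alive):
                    if ci == best:
                        continue
                    n = it
                    mean_d = S[ci, best] / n
                    var_d = max(0.0, (SS[ci, best] - S[ci, best] ** 2 / n) / (n - 1))
                    tests_performed += 1
                    p = _p_from_moments(mean_d, np.sqrt(var_d), n, alternative)
                    if mean_d > 0 and p < p_threshold:
                        alive.remove(ci)
                        elimination_order.append((names[ci], it, p))
        scored = n_scores > 0
        means_alive = {ci: float(err_sum[ci] / n_scores[ci]) for ci in alive}
        pred_idx = min(alive, key=lambda ci: (means_alive[ci], ci))
        if sum(1 for v in means_alive.values() if v == means_alive[pred_idx]) > 1:
            logger.warning("tied mean errors at stopping; lowest class index wins")
        # final running means of all classes (incl. eliminated) for the gap
        all_means = {names[ci]: float(err_sum[ci] / n_scores[ci])
                     for ci in range(K) if scored[ci]}
        raw = confidence_score(all_means) if K >= 2 else 0.0
        return ClassifierResult(
            predicted=names[pred_idx],
            mean_error_by_class=all_means,
            n_scores_by_class={names[ci]: int(n_scores[ci]) for ci in range(K)},
            elimination_order=elimination_order,
            total_iterations=it,
            confidence_raw=raw,
            confidence=self.calibrator.transform(raw) if self.calibrator else "uncalibrated",
            tests_performed=tests_performed,
            trials=trials,
        )

    # ------------------------------------------------------------------

    def classify_batch(
        self,
        images: np.ndarray,
        mode: str = "eliminate",
        seed: int = 0,
        **kwargs,
    ) -> list[ClassifierResult]:
        """Classify a batch, one child seed per image."""
        results = []
        for i, img in enumerate(images):
            s = child_seed(seed, "batch", i)
            if mode == "eliminate":
                results.append(self.classify_eliminating(img, seed=s, **kwargs))
            elif mode == "exhaustive":
                results.append(self.classify_exhaustive(img, seed=s, **kwargs))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        return results
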