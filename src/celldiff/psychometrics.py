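"""Bayesian psychometric evaluation of confidence.

An ideal observer's accuracy as a function of a discriminability index x
(here: a confidence score in [0, 1], from the model, a baseline, or human
labellers) follows a psychometric function

    psi(x) = gamma + (1 - gamma - lambda) * S(x; m, w),

rising from the chance guess rate gamma (fixed at 1/K for a K-class forced
choice) to 1 - lambda, where lambda is the lapse rate.  The inner sigmoid S
is a cumulative normal re-parameterised by its threshold m — the signal
value where S reaches 0.8, matching the threshold-at-80%-accuracy
convention — and its width w, the signal interval over which S rises from
0.05 to 0.95.

Fitting is fully Bayesian on a dense (m, w, lambda) grid: Bernoulli
likelihood, lambda ~ Beta(1, 10), m uniform over the observed signal range
(padded 10%), w log-uniform; the posterior is exact within grid resolution
and deterministic.  The returned fit carries marginal posterior means,
equal-tailed 95% credibility intervals whose endpoints are grid nodes
bracketing the 2.5%/97.5% cumulative mass, the maximum-likelihood node and
the full grid for joint-density plots, statsmodels-style via ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rng import stream

__all__ = [
    "PsychometricModel",
    "BernoulliTrialSet",
    "PsychometricFit",
    "psychometric_value",
    "fit_psychometric",
    "simulate_observer",
    "binned_accuracy",
    "aggregate_expert_confidence",
    "logit_gap_confidence",
    "CONFIDENCE_VALUE_MAP",
]

_Z80 = float(stats.norm.ppf(0.8))
_Z95 = float(stats.norm.ppf(0.95))
_Z05 = float(stats.norm.ppf(0.05))

#: numerical values of the labeller confidence vocabulary
CONFIDENCE_VALUE_MAP = {"high": 1.0, "moderate": 2.0 / 3.0, "low": 1.0 / 3.0,
                        "none": 0.0}


@dataclass(frozen=True)
class PsychometricModel:
    """Psychometric function parameters.

    ``threshold``: signal where the inner sigmoid reaches 0.8 (the 80%%-
    accuracy point unscaled by guess and lapse rates).  ``width``: signal
    interval spanning inner-sigmoid values 0.05 to 0.95.
    """

    threshold: float
    width: float
    guess_rate: float
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if not 0.0 < self.guess_rate < 1.0:
            raise ValueError(f"guess_rate must be in (0, 1), got {self.guess_rate}")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError(f"lapse_rate must be in [0, 1), got {self.lapse_rate}")
        if self.guess_rate + self.lapse_rate >= 1.0:
            raise ValueError("guess_rate + lapse_rate must be < 1")


def _inner_sigmoid(x, m, w):
    """Cumulative normal with S(m) = 0.8 and S spanning 0.05..0.95 over w."""
    slope = (_Z95 - _Z05) / w
    return stats.norm.cdf(_Z80 + (np.asarray(x, dtype=float) - m) * slope)


def psychometric_value(x, model: PsychometricModel):
    """psi(x) = gamma + (1 - gamma - lambda) * S(x; m, w)."""
    g, lam = model.guess_rate, model.lapse_rate
    return g + (1.0 - g - lam) * _inner_sigmoid(x, model.threshold, model.width)


@dataclass
class BernoulliTrialSet:
    """Per-trial discriminability signals and correctness indicators."""

    signals: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.correct = np.asarray(self.correct, dtype=int)
        if self.signals.shape != self.correct.shape or self.signals.ndim != 1:
            raise ValueError("signals and correct must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")
        if not np.all((self.correct == 0) | (self.correct == 1)):
            raise ValueError("correct must be 0/1")

    @property
    def n(self) -> int:
        return len(self.signals)


def simulate_observer(model: PsychometricModel, signals, seed: int = 0) -> BernoulliTrialSet:
    """Draw y_i ~ Bernoulli(psi(x_i)) for recovery testing; seeded."""
    x = np.asarray(signals, dtype=float)
    p = psychometric_value(x, model)
    rng = stream(seed, "observer")
    return BernoulliTrialSet(signals=x, correct=(rng.random(len(x)) < p).astype(int))


@dataclass
class PsychometricFit:
    """Grid posterior over (threshold m, width w, lapse lambda), gamma fixed."""

    guess_rate: float
    grid_m: np.ndarray
    grid_w: np.ndarray
    grid_lam: np.ndarray
    posterior: np.ndarray  # (m, w, lam) normalised mass
    log_likelihood: np.ndarray  # same shape, data log-likelihood at nodes
    posterior_mean: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    ml_point: dict[str, float] = field(default_factory=dict)
    n_trials: int = 0

    def marginal(self, param: str) -> tuple[np.ndarray, np.ndarray]:
        axis_of = {"threshold": (1, 2), "width": (0, 2), "lapse": (0, 1)}
        grid_of = {"threshold": self.grid_m, "width": self.grid_w,
                   "lapse": self.grid_lam}
        return grid_of[param], self.posterior.sum(axis=axis_of[param])

    def joint_mw(self) -> np.ndarray:
        """Joint posterior mass over (threshold, width)."""
        return self.posterior.sum(axis=2)

    def map_model(self) -> PsychometricModel:
        return PsychometricModel(threshold=self.ml_point["threshold"],
                                 width=self.ml_point["width"],
                                 guess_rate=self.guess_rate,
                                 lapse_rate=self.ml_point["lapse"])

    def summary(self) -> str:
        lines = [
            "Psychometric function fit (grid posterior)",
            "=" * 58,
            f"trials: {self.n_trials}    guess rate gamma (fixed): {self.guess_rate:.4f}",
            f"grid: {len(self.grid_m)} x {len(self.grid_w)} x {len(self.grid_lam)} (m x w x lambda)",
            "-" * 58,
            f"{'param':<12}{'post. mean':>12}{'95% CrI':>24}{'ML':>10}",
        ]
        for p in ("threshold", "width", "lapse"):
            lo, hi = self.ci95[p]
            lines.append(f"{p:<12}{self.posterior_mean[p]:>12.4f}"
                         f"{f'[{lo:.4f}, {hi:.4f}]':>24}{self.ml_point[p]:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "guess_rate": self.guess_rate,
            "posterior_mean": self.posterior_mean,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "ml_point": self.ml_point,
            "n_trials": self.n_trials,
        }


def _equal_tail_ci(grid: np.ndarray, mass: np.ndarray, level: float = 0.95):
    """CrI endpoints as grid nodes bracketing the tail quantiles.

    The lower endpoint is the largest node whose cumulative mass is still
    <= 2.5%, the upper the smallest node with >= 97.5%: the interval
    brackets the continuous quantiles from outside, so grid discretisation
    can only widen it, never narrow it.
    """
    cum = np.cumsum(mass)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo_idx = max(0, int(np.searchsorted(cum, lo_q, side="right")) - 1)
    hi_idx = min(int(np.searchsorted(cum, hi_q, side="left")), len(grid) - 1)
    return float(grid[lo_idx]), float(grid[hi_idx])


def fit_psychometric(
    trials: BernoulliTrialSet,
    guess_rate: float,
    grid_shape: tuple[int, int, int] = (81, 81, 41),
    m_range: tuple[float, float] | None = None,
    w_range: tuple[float, float] | None = None,
    lam_max: float = 0.5,
) -> PsychometricFit:
    """Dense-grid Bayesian fit of the psychometric function.

    Priors: lambda ~ Beta(1, 10) truncated to [0, lam_max]; threshold
    uniform over the observed signal range padded by 10%; width log-uniform
    over [0.01, 2 x signal range].  The likelihood is Bernoulli with trials
    pooled by distinct signal value, so repeated signal levels cost nothing
    extra.
    """
    if not 0.0 < guess_rate < 1.0:
        raise ValueError(f"guess_rate must be in (0, 1), got {guess_rate}")
    x, y = trials.signals, trials.correct
    levels, inv = np.unique(x, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 distinct signal values to fit")
    n_per = np.bincount(inv)
    k_per = np.bincount(inv, weights=y)

    span = float(levels.max() - levels.min())
    if m_range is None:
        pad = 0.1 * span
        m_range = (float(levels.min()) - pad, float(levels.max()) + pad)
    if w_range is None:
        w_range = (0.01, 2.0 * span)
    nm, nw, nl = grid_shape
    grid_m = np.linspace(m_range[0], m_range[1], nm)
    grid_w = np.exp(np.linspace(np.log(w_range[0]), np.log(w_range[1]), nw))
    grid_lam = np.linspace(0.0, lam_max, nl)

    # log-likelihood over the full grid, vectorised over (m, w) x levels
    slope = (_Z95 - _Z05) / grid_w  # (nw,)
    zz = _Z80 + (levels[None, None, :] - grid_m[:, None, None]) * slope[None, :, None]
    S = stats.norm.cdf(zz)  # (nm, nw, L)
    logL = np.empty((nm, nw, nl))
    for j, lam in enumerate(grid_lam):
        psi = guess_rate + (1.0 - guess_rate - lam) * S
        psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
        logL[:, :, j] = (np.log(psi) @ k_per) + (np.log1p(-psi) @ (n_per - k_per))

    # priors: m uniform, w log-uniform (uniform on the log-spaced grid),
    # lambda ~ Beta(1, 10) evaluated at the nodes
    log_prior_lam = stats.beta(1, 10).logpdf(np.clip(grid_lam, 0.0, 1.0 - 1e-12))
    log_post = logL + log_prior_lam[None, None, :]
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()

    fit = PsychometricFit(
        guess_rate=guess_rate, grid_m=grid_m, grid_w=grid_w, grid_lam=grid_lam,
        posterior=post, log_likelihood=logL, n_trials=trials.n,
    )
    for name, grid, axes in (("threshold", grid_m, (1, 2)),
                             ("width", grid_w, (0, 2)),
                             ("lapse", grid_lam, (0, 1))):
        marg = post.sum(axis=axes)
        fit.posterior_mean[name] = float(np.sum(grid * marg))
        fit.ci95[name] = _equal_tail_ci(grid, marg)
    im, iw, il = np.unravel_index(int(np.argmax(logL)), logL.shape)
    fit.ml_point = {"threshold": float(grid_m[im]), "width": float(grid_w[iw]),
                    "lapse": float(grid_lam[il])}
    return fit


def binned_accuracy(trials: BernoulliTrialSet, n_bins: int = 10) -> list[dict]:
    """Accuracy per equal-width signal bin on [0, 1]; empty bins omitted.

    Counts are returned for proportional marker sizing in plots.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(trials.signals, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = which == b
        if not np.any(mask):
            continue
        out.append({
            "bin": b,
            "mean_signal": float(trials.signals[mask].mean()),
            "accuracy": float(trials.correct[mask].mean()),
            "count": int(mask.sum()),
        })
    return out


def aggregate_expert_confidence(labeller_confidences) -> float:
    """Mean numerical confidence over labellers.

    Levels map to 1.0 (high), 2/3 (moderate), 1/3 (low) and 0 (none).
    """
    levels = list(labeller_confidences)
    if not levels:
        raise ValueError("at least one labeller confidence required")
    try:
        return float(np.mean([CONFIDENCE_VALUE_MAP[l] for l in levels]))
    except KeyError as e:
        raise ValueError(f"unknown confidence level {e.args[0]!r}") from None


def logit_gap_confidence(logits) -> float:
    """Raw confidence of a discriminative classifier: top-logit gap.

    Largest minus second-largest pre-activation value; invariant to adding
    a constant to all logits.  Rescale with the same min-max calibrator as
    the generative confidence.
    """
    z = np.sort(np.asarray(logits, dtype=float))
    if z.size < 2:
        raise ValueError("logit gap requires >= 2 classes")
    return float(z[-1] - z[-2])
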