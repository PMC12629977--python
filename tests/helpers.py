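"""Stub denoisers and small builders shared across the test suite."""

from __future__ import annotations

import numpy as np

from celldiff.diffusion import ClassConditioning, IdentityCodec, NoiseSchedule
from celldiff.rng import stream


class CondBiasStub:
    """Predicts a constant per-class vector, ignoring z_t and t."""

    arch = "stub"
    parameter_checksum = "cond-bias-stub"

    def __init__(self, bias_by_index: np.ndarray):
        self.bias = np.asarray(bias_by_index, dtype=np.float32)  # (K, D)

    def predict(self, z_t, t, cond):
        cond = np.atleast_2d(np.asarray(cond))
        idx = np.argmax(cond, axis=1)
        out = self.bias[idx]
        return out[0] if np.asarray(z_t).ndim == 1 else out


class EpsPlusBiasStub:
    """For z0 = 0 inputs, predicts exactly eps + bias_c.

    With z0 = 0 the noised latent is z_t = sqrt(1 - ab_t) * eps, so the
    injected noise is recoverable as z_t / sqrt(1 - ab_t); per-trial errors
    are then exactly ||bias_c||^2, i.e. constant across trials.
    """

    arch = "stub"
    parameter_checksum = "eps-plus-bias-stub"

    def __init__(self, schedule: NoiseSchedule, bias_by_index: np.ndarray):
        self.schedule = schedule
        self.bias = np.asarray(bias_by_index, dtype=np.float32)

    def predict(self, z_t, t, cond):
        z = np.atleast_2d(np.asarray(z_t, dtype=np.float64))
        cond = np.atleast_2d(np.asarray(cond))
        t_arr = np.atleast_1d(np.asarray(t))
        ab = self.schedule.alpha_bar[t_arr][:, None]
        eps = z / np.sqrt(1.0 - ab)
        out = (eps + self.bias[np.argmax(cond, axis=1)]).astype(np.float32)
        return out[0] if np.asarray(z_t).ndim == 1 else out


class NoisyStub:
    """Fresh random predictions per call: identically distributed errors
    under every class condition (the elimination null)."""

    arch = "stub"
    parameter_checksum = "noisy-stub"

    def __init__(self, seed: int):
        self.rng = stream(seed, "noisy_stub")

    def predict(self, z_t, t, cond):
        z = np.atleast_2d(np.asarray(z_t))
        out = self.rng.standard_normal(z.shape).astype(np.float32)
        return out[0] if np.asarray(z_t).ndim == 1 else out


class GaussianOptimalStub:
    """Exact minimum-MSE denoiser for point-mass classes at given means.

    For an image equal to its class mean, the class-conditional error is
    zero in expectation and any wrong class scores ab/(1-ab) * ||mu_c -
    mu_c'||^2, so classification is perfect.
    """

    arch = "stub"
    parameter_checksum = "gaussian-optimal-stub"

    def __init__(self, schedule: NoiseSchedule, class_means: np.ndarray):
        self.schedule = schedule
        self.means = np.asarray(class_means, dtype=np.float64)  # (K, D)

    def predict(self, z_t, t, cond):
        z = np.atleast_2d(np.asarray(z_t, dtype=np.float64))
        cond = np.atleast_2d(np.asarray(cond))
        t_arr = np.atleast_1d(np.asarray(t))
        ab = self.schedule.alpha_bar[t_arr][:, None]
        mu = self.means[np.argmax(cond, axis=1)]
        out = ((z - np.sqrt(ab) * mu) / np.sqrt(1.0 - ab)).astype(np.float32)
        return out[0] if np.asarray(z_t).ndim == 1 else out


def tiny_schedule(T: int = 50) -> NoiseSchedule:
    from celldiff.diffusion import build_schedule

    return build_schedule(T)


def tiny_setup(K: int = 3, D: int = 12, T: int = 50):
    """(schedule, conditioning, codec(image 2x2x3 if D==12)) for stub tests."""
    sched = tiny_schedule(T)
    cond = ClassConditioning([f"c{i}" for i in range(K)])
    assert D % 3 == 0
    side = int(np.sqrt(D // 3))
    codec = IdentityCodec((side, side, 3))
    return sched, cond, codec
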