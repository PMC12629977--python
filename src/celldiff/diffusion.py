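"""Forward diffusion process, codec and conditioning contracts.

The forward process is the standard variance-preserving discrete diffusion:
``z_t = sqrt(alpha_bar_t) * z_0 + sqrt(1 - alpha_bar_t) * eps`` with
``alpha_bar_t = prod_{s<=t} (1 - beta_s)`` and ``alpha_bar_0 = 1`` (clean
input).  A pluggable latent codec decides the space the process runs in;
the default identity codec works directly on pixels, so the same classifier
code runs unchanged on top of any learned autoencoder that honours the
``LatentCodec`` contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "add_noise",
    "LatentCodec",
    "IdentityCodec",
    "ClassConditioning",
    "DenoiserModel",
    "predict_noise",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Discrete noise schedule.

    ``betas`` has length T (steps 1..T); ``alpha_bar`` has length T+1 with
    ``alpha_bar[0] = 1`` so that timestep 0 is the clean image.
    """

    betas: np.ndarray
    alpha_bar: np.ndarray

    @property
    def T(self) -> int:
        return len(self.betas)

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=np.float64)
        ab = np.asarray(self.alpha_bar, dtype=np.float64)
        if betas.ndim != 1 or len(betas) < 1:
            raise ValueError("betas must be a non-empty 1-D array")
        if np.any((betas <= 0) | (betas >= 1)):
            raise ValueError("betas must lie in (0, 1)")
        if len(ab) != len(betas) + 1 or ab[0] != 1.0:
            raise ValueError("alpha_bar must have length T+1 with alpha_bar[0] == 1")
        if np.any(np.diff(ab) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")
        if np.max(np.abs(ab - np.concatenate([[1.0], np.cumprod(1.0 - betas)]))) > 1e-12:
            raise ValueError("alpha_bar inconsistent with cumulative product of 1-beta")

    def to_dict(self) -> dict:
        return {"betas": self.betas.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        betas = np.asarray(d["betas"], dtype=np.float64)
        return cls(betas=betas, alpha_bar=np.concatenate([[1.0], np.cumprod(1.0 - betas)]))


def build_schedule(
    T: int,
    kind: str = "linear",
    beta_start: float | None = None,
    beta_end: float | None = None,
) -> NoiseSchedule:
    """Build a noise schedule.

    ``linear`` interpolates beta between the endpoints; the default endpoints
    (1e-4, 0.02) are stated for a 1000-step schedule and are rescaled by
    ``1000 / T`` so that the total amount of noise injected is comparable at
    any T.  ``cosine`` uses the squared-cosine alpha_bar profile with betas
    clipped to (0, 0.999].
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if kind == "linear":
        scale = 1000.0 / T
        # auto-scaled endpoints are capped so short schedules stay valid
        b0 = min(1e-4 * scale, 0.5) if beta_start is None else beta_start
        b1 = min(0.02 * scale, 0.8) if beta_end is None else beta_end
        for name, b in (("beta_start", b0), ("beta_end", b1)):
            if not 0.0 < b < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {b}")
        betas = np.linspace(b0, b1, T)
    elif kind == "cosine":
        s = 0.008
        ts = np.arange(T + 1) / T
        f = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        ab = f / f[0]
        betas = np.clip(1.0 - ab[1:] / ab[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha_bar = np.concatenate([[1.0], np.cumprod(1.0 - betas)])
    return NoiseSchedule(betas=betas, alpha_bar=alpha_bar)


def add_noise(
    z0: np.ndarray,
    t: int | np.ndarray,
    eps: np.ndarray,
    schedule: NoiseSchedule,
) -> np.ndarray:
    """Noise ``z0`` to timestep ``t``: sqrt(ab_t) z0 + sqrt(1 - ab_t) eps.

    ``t`` may be a scalar or an array broadcastable over the leading axis of
    a batch of latents.
    """
    z0 = np.asarray(z0)
    eps = np.asarray(eps)
    if eps.shape != z0.shape:
        raise ValueError(f"eps shape {eps.shape} != z0 shape {z0.shape}")
    t_arr = np.asarray(t)
    if np.any((t_arr < 0) | (t_arr > schedule.T)):
        raise ValueError(f"t out of range [0, {schedule.T}]")
    ab = schedule.alpha_bar[t_arr]
    if t_arr.ndim > 0:  # batch: broadcast over leading axis
        ab = ab.reshape((-1,) + (1,) * (z0.ndim - 1))
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


@runtime_checkable
class LatentCodec(Protocol):
    """Encoder/decoder pair between image space and latent space."""

    latent_shape: tuple[int, ...]

    def encode(self, image: np.ndarray) -> np.ndarray: ...

    def decode(self, latent: np.ndarray) -> np.ndarray: ...


class IdentityCodec:
    """Pixel-space codec: latent = flattened image, bit-exact round trip."""

    def __init__(self, image_shape: tuple[int, int, int] = (32, 32, 3)):
        self.image_shape = tuple(image_shape)
        self.latent_shape = (int(np.prod(image_shape)),)

    @property
    def codec_id(self) -> str:
        h, w, c = self.image_shape
        return f"identity-{h}x{w}x{c}"

    def encode(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape[-3:] != self.image_shape:
            raise ValueError(f"image shape {image.shape} != {self.image_shape}")
        return image.reshape(image.shape[:-3] + self.latent_shape)

    def decode(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent)
        if latent.shape[-1:] != self.latent_shape:
            raise ValueError(f"latent shape {latent.shape} != {self.latent_shape}")
        return latent.reshape(latent.shape[:-1] + self.image_shape)


class ClassConditioning:
    """Deterministic one-hot class conditioning.

    One embedding slot per class, no tokenizer: class k maps to the k-th
    standard basis vector of R^K.  The denoiser is free to project this
    one-hot input through a learned table, which is equivalent to a learned
    per-class embedding.
    """

    def __init__(self, class_names: Sequence[str]):
        names = list(class_names)
        if len(set(names)) != len(names):
            raise ValueError("class names must be distinct")
        if not names:
            raise ValueError("at least one class required")
        self.class_names = names
        self.index = {c: i for i, c in enumerate(names)}

    @property
    def K(self) -> int:
        return len(self.class_names)

    def embed(self, c: int | str) -> np.ndarray:
        i = self.index[c] if isinstance(c, str) else int(c)
        if not 0 <= i < self.K:
            raise ValueError(f"class index {i} out of range for K={self.K}")
        v = np.zeros(self.K, dtype=np.float32)
        v[i] = 1.0
        return v

    def embed_all(self) -> np.ndarray:
        return np.eye(self.K, dtype=np.float32)


@runtime_checkable
class DenoiserModel(Protocol):
    """Noise predictor contract: eps_hat = predict(z_t, t, cond).

    ``predict`` must be deterministic for fixed inputs and parameters and
    return an array of the latent shape.  Implementations expose a
    ``parameter_checksum`` identifying the exact parameter state.
    """

    @property
    def parameter_checksum(self) -> str: ...

    def predict(self, z_t: np.ndarray, t: int | np.ndarray, cond: np.ndarray) -> np.ndarray: ...


def predict_noise(
    model: DenoiserModel,
    z_t: np.ndarray,
    t: int | np.ndarray,
    cond: np.ndarray,
) -> np.ndarray:
    """Evaluate the denoiser; checks the output-shape contract."""
    out = model.predict(z_t, t, cond)
    if np.asarray(out).shape != np.asarray(z_t).shape:
        raise ValueError(
            f"denoiser output shape {np.asarray(out).shape} != input {np.asarray(z_t).shape}"
        )
    return out
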