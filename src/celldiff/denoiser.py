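"""Reference noise-predictor and its training loop.

The denoiser is a small fully connected network epsilon_theta(z_t, t, c):
the flattened latent, a sinusoidal timestep embedding and the one-hot class
conditioning feed two hidden layers; the conditioning enters each layer
both additively and as a multiplicative feature-wise (FiLM-style) gain, so
the class can reshape features rather than merely shift them.  Two
structured output paths carry learned timestep-dependent
scalar gates: a direct ``g(t) * z_t`` skip, and a class-template path
``s(t) * M[c]`` holding one learned latent template per class.  The skip
gives the variance-preserving identity ``eps ~ z_t`` at high noise for
free, and the template path is the load-bearing conditional term: the
minimum-MSE noise prediction for a class with mean latent ``m_c`` is
approximately ``z_t / sqrt(1-ab) - sqrt(ab/(1-ab)) * m_c``, exactly the
span of these two paths, so the class label acquires direct gradient
pressure instead of being shadowed by what the network can infer about the
class from ``z_t`` alone.  All arithmetic is float32 NumPy; gradients are
written out by hand and optimised with Adam.  Roughly 0.9 M parameters at
the default width.  Any other backbone can be swapped in behind the
``DenoiserModel`` contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .diffusion import ClassConditioning, IdentityCodec, LatentCodec, NoiseSchedule, add_noise
from .rng import stream

__all__ = [
    "MLPDenoiser",
    "TrainConfig",
    "build_denoiser",
    "train_denoiser",
    "save_checkpoint",
    "load_checkpoint",
]


def build_denoiser(config: "TrainConfig", n_classes: int, latent_dim: int,
                   image_shape: tuple[int, int, int] | None = None):
    """Instantiate the backbone named by ``config.arch``."""
    from .convnet import ConvDenoiser

    if config.arch == "conv":
        if image_shape is None or int(np.prod(image_shape)) != latent_dim:
            raise ValueError("conv backbone requires a pixel-shaped latent")
        return ConvDenoiser(image_shape=tuple(image_shape), n_classes=n_classes,
                            temb_dim=config.temb_dim, seed=config.seed,
                            width_mult=config.width_mult)
    if config.arch == "mlp":
        return MLPDenoiser(latent_dim, n_classes, hidden=config.hidden,
                           temb_dim=config.temb_dim, seed=config.seed)
    raise ValueError(f"unknown denoiser arch {config.arch!r}")


def _sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard sinusoidal timestep embedding, shape (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float32))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half, dtype=np.float32) / half)
    args = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1).astype(np.float32)


class MLPDenoiser:
    """Two-hidden-layer conditional noise predictor with a gated skip path."""

    arch = "mlp"

    def __init__(self, latent_dim: int, n_classes: int, hidden: int = 128,
                 temb_dim: int = 32, seed: int = 0):
        self.latent_dim = int(latent_dim)
        self.n_classes = int(n_classes)
        self.hidden = int(hidden)
        self.temb_dim = int(temb_dim)
        rng = stream(seed, "denoiser_init")
        D, H, K, Td = self.latent_dim, self.hidden, self.n_classes, self.temb_dim

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "W1": he((D, H), D), "Wt1": he((Td, H), Td), "Wc1": he((K, H), K),
            "b1": np.zeros(H, dtype=np.float32),
            "F1": np.zeros((K, H), dtype=np.float32),
            "W2": he((H, H), H), "Wt2": he((Td, H), Td), "Wc2": he((K, H), K),
            "b2": np.zeros(H, dtype=np.float32),
            "F2": np.zeros((K, H), dtype=np.float32),
            "W3": he((H, D), H), "b3": np.zeros(D, dtype=np.float32),
            "wg": np.zeros((Td, 1), dtype=np.float32),
            "bg": np.zeros(1, dtype=np.float32),
            # template gate opens at init (bs=1) so M is not a dead saddle
            "M": np.zeros((K, D), dtype=np.float32),
            "ws": np.zeros((Td, 1), dtype=np.float32),
            "bs": np.ones(1, dtype=np.float32),
        }

    # -- evaluation ---------------------------------------------------------

    @property
    def parameter_checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(str(self.params[k].shape).encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def _forward(self, X: np.ndarray, t: np.ndarray, C: np.ndarray,
                 keep: bool = False):
        p = self.params
        temb = _sinusoidal_embedding(t, self.temb_dim)
        Xc = X - np.float32(0.5)  # centred copy for the dense path
        a1 = Xc @ p["W1"] + temb @ p["Wt1"] + C @ p["Wc1"] + p["b1"]
        f1 = 1.0 + C @ p["F1"]
        h1 = np.maximum(a1 * f1, 0.0)
        a2 = h1 @ p["W2"] + temb @ p["Wt2"] + C @ p["Wc2"] + p["b2"]
        f2 = 1.0 + C @ p["F2"]
        h2 = np.maximum(a2 * f2, 0.0)
        g = temb @ p["wg"] + p["bg"]
        s = temb @ p["ws"] + p["bs"]
        tmpl = C @ p["M"]
        out = h2 @ p["W3"] + p["b3"] + g * X + s * tmpl
        if keep:
            return out, (X, Xc, temb, C, a1, f1, h1, a2, f2, h2, g, s, tmpl)
        return out

    def predict(self, z_t: np.ndarray, t: int | np.ndarray, cond: np.ndarray) -> np.ndarray:
        """Deterministic evaluation; accepts a single latent or a batch."""
        z_t = np.asarray(z_t, dtype=np.float32)
        cond = np.asarray(cond, dtype=np.float32)
        single = z_t.ndim == 1
        X = z_t[None, :] if single else z_t
        C = cond[None, :] if single else cond
        if X.shape[1] != self.latent_dim:
            raise ValueError(f"latent dim {X.shape[1]} != model dim {self.latent_dim}")
        if C.shape[1] != self.n_classes:
            raise ValueError(f"conditioning dim {C.shape[1]} != K={self.n_classes}")
        t_arr = np.full(len(X), t) if np.ndim(t) == 0 else np.asarray(t)
        out = self._forward(X, t_arr, C)
        return out[0] if single else out

    # -- training -----------------------------------------------------------

    def loss_and_grads(self, X, t, C, target):
        out, (X, Xc, temb, C, a1, f1, h1, a2, f2, h2, g, s, tmpl) = \
            self._forward(X, t, C, keep=True)
        p = self.params
        diff = out - target
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dout = (2.0 / diff.size) * diff
        grads = {}
        grads["W3"] = h2.T @ dout
        grads["b3"] = dout.sum(0)
        dg = (dout * X).sum(axis=1, keepdims=True)
        grads["wg"] = temb.T @ dg
        grads["bg"] = dg.sum(0)
        ds = (dout * tmpl).sum(axis=1, keepdims=True)
        grads["ws"] = temb.T @ ds
        grads["bs"] = ds.sum(0)
        grads["M"] = C.T @ (s * dout)
        dpre2 = (dout @ p["W3"].T) * (h2 > 0)
        da2 = dpre2 * f2
        grads["F2"] = C.T @ (dpre2 * a2)
        grads["W2"] = h1.T @ da2
        grads["Wt2"] = temb.T @ da2
        grads["Wc2"] = C.T @ da2
        grads["b2"] = da2.sum(0)
        dpre1 = (da2 @ p["W2"].T) * (h1 > 0)
        da1 = dpre1 * f1
        grads["F1"] = C.T @ (dpre1 * a1)
        grads["W1"] = Xc.T @ da1
        grads["Wt1"] = temb.T @ da1
        grads["Wc1"] = C.T @ da1
        grads["b1"] = da1.sum(0)
        return loss, grads


class _Adam:
    def __init__(self, params, lr=2e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, gval in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gval
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gval * gval
            params[k] -= np.float32(lr) * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


@dataclass(frozen=True)
class TrainConfig:
    """Denoiser training hyperparameters (desk-scale defaults).

    ``zoom_augment`` optionally appends ``zoom_copies`` randomly zoomed
    copies of every training image (factors uniform in the given range)
    before training, the augmentation used for zoom-robust domain-shift
    training.
    """

    steps: int = 3000
    batch_size: int = 32
    lr: float = 2e-3
    warmup: int = 100
    arch: str = "conv"  # "conv" (encoder-decoder) or "mlp"
    hidden: int = 128  # mlp width
    width_mult: float = 1.0  # conv channel multiplier
    temb_dim: int = 32
    seed: int = 0
    eval_every: int = 500
    zoom_augment: tuple[float, float] | None = None
    zoom_copies: int = 1
    #: fraction of training draws taken uniformly from {1..low_t_max} instead
    #: of {1..T}; concentrates capacity on the low-noise regime where the
    #: class-conditional error gap the classifier reads is largest. 0 = all
    #: timesteps uniform.
    low_t_frac: float = 0.0
    low_t_max: int = 100
    #: if > 0, keep a parameter snapshot every this many steps (plus the
    #: final state) in the training history for validation-based selection
    checkpoint_every: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["zoom_augment"] is not None:
            d["zoom_augment"] = list(d["zoom_augment"])
        return d


def _zoom_about_center(img: np.ndarray, factor: float) -> np.ndarray:
    size = img.shape[0]
    coords = (np.arange(size) - (size - 1) / 2.0) / factor + (size - 1) / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.map_coordinates(img[..., ch], [yy, xx], order=1,
                                               mode="nearest")
    return out


def train_denoiser(
    images: np.ndarray,
    labels: list[str],
    codec: LatentCodec,
    schedule: NoiseSchedule,
    conditioning: ClassConditioning,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPDenoiser, dict]:
    """Fit the denoiser by stochastic minimisation of ||eps - eps_theta||^2.

    Timesteps are sampled uniformly on {1..T} and eps ~ N(0, I); the run is
    a pure function of ``config.seed``.  Returns the model and a history
    dict with the running training loss and a fixed-validation-batch loss
    trace.
    """
    images = np.asarray(images)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(labels):
        raise ValueError("one label per image required")
    unknown = set(labels) - set(conditioning.class_names)
    if unknown:
        raise ValueError(f"labels outside conditioning set: {sorted(unknown)}")

    if config.zoom_augment is not None:
        zrng = stream(config.seed, "zoom_augment")
        lo, hi = config.zoom_augment
        extra, extra_labels = [], []
        for _ in range(config.zoom_copies):
            for img, lab in zip(images, labels):
                extra.append(_zoom_about_center(img, float(zrng.uniform(lo, hi))))
                extra_labels.append(lab)
        images = np.concatenate([images, np.stack(extra)])
        labels = list(labels) + extra_labels

    Z = codec.encode(images).astype(np.float32)
    N, D = Z.shape
    y = np.array([conditioning.index[l] for l in labels])
    onehot = np.eye(conditioning.K, dtype=np.float32)[y]

    model = build_denoiser(config, conditioning.K, latent_dim=D,
                           image_shape=images.shape[1:])
    opt = _Adam(model.params, lr=config.lr)
    rng = stream(config.seed, "train")

    # fixed validation batch for the loss trace
    vrng = stream(config.seed, "train_val")
    vb = min(64, N)
    vidx = vrng.integers(0, N, size=vb)
    vt = vrng.integers(1, schedule.T + 1, size=vb)
    veps = vrng.standard_normal((vb, D)).astype(np.float32)
    vzt = add_noise(Z[vidx], vt, veps, schedule).astype(np.float32)

    def val_loss() -> float:
        pred = model._forward(vzt, vt, onehot[vidx])
        return float(np.mean((pred - veps).astype(np.float64) ** 2))

    history: dict = {"step": [], "val_loss": [], "train_loss": [], "checkpoints": []}
    run_loss = None
    for step in range(config.steps):
        if step % max(1, config.eval_every) == 0 or step == config.steps - 1:
            history["step"].append(step)
            history["val_loss"].append(val_loss())
            history["train_loss"].append(run_loss)
        if config.checkpoint_every > 0 and step > 0 and step % config.checkpoint_every == 0:
            history["checkpoints"].append(
                (step, {k: v.copy() for k, v in model.params.items()}))
        idx = rng.integers(0, N, size=config.batch_size)
        t = rng.integers(1, schedule.T + 1, size=config.batch_size)
        if config.low_t_frac > 0:
            low_hi = min(config.low_t_max, schedule.T)
            low = rng.random(config.batch_size) < config.low_t_frac
            t = np.where(low, rng.integers(1, low_hi + 1,
                                           size=config.batch_size), t)
        eps = rng.standard_normal((config.batch_size, D)).astype(np.float32)
        z_t = add_noise(Z[idx], t, eps, schedule).astype(np.float32)
        loss, grads = model.loss_and_grads(z_t, t, onehot[idx], eps)
        run_loss = loss if run_loss is None else 0.98 * run_loss + 0.02 * loss
        lr = config.lr * min(1.0, (step + 1) / config.warmup) if config.warmup else config.lr
        opt.step(model.params, grads, lr=lr)
    if config.checkpoint_every > 0:
        history["checkpoints"].append(
            (config.steps, {k: v.copy() for k, v in model.params.items()}))
    history["final_val_loss"] = val_loss()
    return model, history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(
    path: str | Path,
    model: MLPDenoiser,
    schedule: NoiseSchedule,
    conditioning: ClassConditioning,
    codec: LatentCodec,
    config: TrainConfig,
    image_shape: tuple[int, int, int],
    extra: dict | None = None,
) -> Path:
    """Write parameter blob (.npz) plus a JSON sidecar describing the run."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **model.params)
    sidecar = {
        "schedule": schedule.to_dict(),
        "K": conditioning.K,
        "class_names": conditioning.class_names,
        "codec": getattr(codec, "codec_id", type(codec).__name__),
        "image_shape": list(image_shape),
        "arch": getattr(model, "arch", "mlp"),
        "hidden": getattr(model, "hidden", None),
        "width_mult": getattr(model, "width_mult", None),
        "temb_dim": model.temb_dim,
        "config": config.to_dict(),
        "seed": config.seed,
        "steps": config.steps,
        "parameter_checksum": model.parameter_checksum,
    }
    if extra:
        sidecar.update(extra)
    (path / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path):
    """Load (model, schedule, conditioning, codec, sidecar) from a checkpoint dir."""
    path = Path(path)
    sidecar = json.loads((path / "checkpoint.json").read_text())
    schedule = NoiseSchedule.from_dict(sidecar["schedule"])
    conditioning = ClassConditioning(sidecar["class_names"])
    image_shape = tuple(sidecar["image_shape"])
    if not str(sidecar["codec"]).startswith("identity"):
        raise ValueError(f"unknown codec id {sidecar['codec']!r} in sidecar")
    codec = IdentityCodec(image_shape)
    if sidecar.get("arch", "mlp") == "conv":
        from .convnet import ConvDenoiser

        model = ConvDenoiser(image_shape=image_shape, n_classes=sidecar["K"],
                             temb_dim=sidecar["temb_dim"],
                             width_mult=sidecar.get("width_mult") or 1.0)
    else:
        model = MLPDenoiser(codec.latent_shape[0], sidecar["K"],
                            hidden=sidecar["hidden"], temb_dim=sidecar["temb_dim"])
    with np.load(path / "params.npz") as blob:
        for k in model.params:
            model.params[k] = blob[k].astype(np.float32)
    if model.parameter_checksum != sidecar["parameter_checksum"]:
        raise ValueError("checkpoint parameter checksum mismatch")
    return model, schedule, conditioning, codec, sidecar
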