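"""Convolutional reference denoiser.

A small encoder-decoder with two stride-2 downsamplings, nearest-neighbour
upsampling, additive skip connections, sinusoidal timestep embedding and
one-hot class conditioning injected as per-channel biases at every level
(class embedding at the bottleneck and elsewhere).  Like the MLP backbone
it carries two gated structured output paths — ``g(t) * z_t`` and a per-
class latent template ``s(t) * M[c]`` — which span the minimum-MSE noise
prediction for a Gaussian class model, leaving the conv stack to model
spatially local structure (granules, nuclear lobes) translation-
equivariantly.

Convolutions are evaluated through im2col matrix multiplication; the input
gradient is computed as a stride-1 correlation with the flipped kernel on a
zero-dilated upstream gradient, so the whole backward pass is matmuls.
About 0.1 M parameters at the default widths.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .rng import stream

__all__ = ["ConvDenoiser"]


def _sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=np.float32))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half, dtype=np.float32) / half)
    args = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1).astype(np.float32)


def _im2col(x: np.ndarray, stride: int) -> np.ndarray:
    """3x3 same-padding im2col: (B,H,W,C) -> (B*Ho*Wo, 9*C)."""
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (B, H, W, C, 3, 3) -> (B, Ho, Wo, 3, 3, C)
    win = win[:, ::stride, ::stride].transpose(0, 1, 2, 4, 5, 3)
    Ho, Wo = win.shape[1], win.shape[2]
    return np.ascontiguousarray(win).reshape(B * Ho * Wo, 9 * C), (B, Ho, Wo)


def _conv(x: np.ndarray, W: np.ndarray, stride: int = 1):
    """Forward 3x3 conv; returns (y, cols) with y (B,Ho,Wo,Cout)."""
    cols, (B, Ho, Wo) = _im2col(x, stride)
    y = cols @ W
    return y.reshape(B, Ho, Wo, W.shape[1]), cols


def _conv_dx(dy: np.ndarray, W: np.ndarray, stride: int, x_shape) -> np.ndarray:
    """Gradient wrt conv input: dilated stride-1 correlation with flipped kernel."""
    B, H, W_in, Cin = x_shape
    Cout = W.shape[1]
    if stride > 1:
        dil = np.zeros((B, H, W_in, Cout), dtype=dy.dtype)
        dil[:, ::stride, ::stride] = dy
        dy = dil
    W4 = W.reshape(3, 3, Cin, Cout)
    Wf = np.ascontiguousarray(W4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(9 * Cout, Cin)
    dx, _ = _conv(dy, Wf, stride=1)
    return dx


def _conv_fast(x: np.ndarray, W: np.ndarray, stride: int = 1) -> np.ndarray:
    """Forward 3x3 conv as three row-stacked matmuls.

    For each vertical kernel offset the three horizontal taps of a padded
    row are contiguous in memory, so a strided view exposes (3*C)-wide
    patches without building the full 9*C im2col matrix; the whole conv is
    then three (positions x 3C) @ (3C x Cout) products.  Arithmetic is
    equivalent to the im2col route (up to float32 summation order); used on
    the prediction path where no backward cache is needed.
    """
    B, H, Wd, C = x.shape
    Cout = W.shape[1]
    xp = np.ascontiguousarray(np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0))))
    Ho, Wo = H // stride, Wd // stride
    W4 = W.reshape(3, 3 * C, Cout)
    it = xp.itemsize
    sB, sH, sW = (H + 2) * (Wd + 2) * C, (Wd + 2) * C, C
    y = np.zeros((B, Ho, Wo, Cout), dtype=np.float32)
    for di in range(3):
        v = np.lib.stride_tricks.as_strided(
            xp[:, di:], shape=(B, Ho, Wo, 3 * C),
            strides=(sB * it, stride * sH * it, stride * sW * it, it))
        y += (v.reshape(-1, 3 * C) @ W4[di]).reshape(B, Ho, Wo, Cout)
    return y


def _upsample(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample_back(dy: np.ndarray) -> np.ndarray:
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


# (name, Cin, Cout, stride, upsample-before, upsample-after)
# u2 convolves at half resolution and upsamples afterwards: the expensive
# full-resolution 3x3 would dominate inference, and the final conv still
# refines at full resolution over the c0 skip
_DEFAULT_LAYERS = [
    ("c0", 3, 12, 1, False, False),
    ("d1", 12, 24, 2, False, False),
    ("d2", 24, 32, 2, False, False),
    ("m", 32, 32, 1, False, False),
    ("u1", 32, 24, 1, True, False),   # + skip from d1
    ("u2", 24, 12, 1, False, True),   # upsampled output + skip from c0
    ("out", 12, 3, 1, False, False),
]


class ConvDenoiser:
    """U-shaped conditional noise predictor on 32x32x3 latents."""

    arch = "conv"

    def __init__(self, image_shape: tuple[int, int, int] = (32, 32, 3),
                 n_classes: int = 5, temb_dim: int = 32, seed: int = 0,
                 width_mult: float = 1.0):
        if image_shape[0] % 4 or image_shape[1] % 4:
            raise ValueError("image sides must be divisible by 4")
        self.image_shape = tuple(image_shape)
        self.latent_dim = int(np.prod(image_shape))
        self.n_classes = int(n_classes)
        self.temb_dim = int(temb_dim)
        self.width_mult = float(width_mult)
        self.layers = []
        for name, ci, co, st, up, upa in _DEFAULT_LAYERS:
            if name != "out":
                ci2 = max(3, int(round(ci * width_mult))) if name != "c0" else 3
                co2 = int(round(co * width_mult))
            else:
                ci2, co2 = int(round(ci * width_mult)), 3
            self.layers.append((name, ci2, co2, st, up, upa))
        rng = stream(seed, "conv_init")
        K, Td, D = self.n_classes, self.temb_dim, self.latent_dim
        p: dict[str, np.ndarray] = {}
        for name, ci, co, st, up, upa in self.layers:
            fan_in = 9 * ci
            p[f"W_{name}"] = (rng.standard_normal((fan_in, co))
                              * np.sqrt(2.0 / fan_in)).astype(np.float32)
            p[f"b_{name}"] = np.zeros(co, dtype=np.float32)
            if name != "out":
                p[f"At_{name}"] = np.zeros((Td, co), dtype=np.float32)
                p[f"Ac_{name}"] = np.zeros((K, co), dtype=np.float32)
        p["wg"] = np.zeros((Td, 1), dtype=np.float32)
        p["bg"] = np.zeros(1, dtype=np.float32)
        p["M"] = np.zeros((K, D), dtype=np.float32)
        p["ws"] = np.zeros((Td, 1), dtype=np.float32)
        p["bs"] = np.ones(1, dtype=np.float32)
        self.params = p

    @property
    def parameter_checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(str(self.params[k].shape).encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------------

    def _forward(self, X: np.ndarray, t: np.ndarray, C: np.ndarray, keep: bool = False):
        p = self.params
        B = X.shape[0]
        temb = _sinusoidal_embedding(t, self.temb_dim)
        x = (X - np.float32(0.5)).reshape((B,) + self.image_shape)
        cache = {"temb": temb, "C": C, "acts": {}, "cols": {}, "pre": {}}
        skips = {}
        h = x
        for name, ci, co, st, up, upa in self.layers:
            if up:
                h = _upsample(h)
            if keep:
                y, cols = _conv(h, p[f"W_{name}"], stride=st)
            else:
                y, cols = _conv_fast(h, p[f"W_{name}"], stride=st), None
            y = y + p[f"b_{name}"]
            if name != "out":
                film = temb @ p[f"At_{name}"] + C @ p[f"Ac_{name}"]
                y = y + film[:, None, None, :]
            if keep:
                cache["cols"][name] = cols
                cache["pre"][name] = y
            if name != "out":
                y = np.maximum(y, 0.0)
            if upa:
                y = _upsample(y)
            if name == "c0":
                skips["c0"] = y
            elif name == "d1":
                skips["d1"] = y
            elif name == "u1":
                y = y + skips["d1"]
            elif name == "u2":
                y = y + skips["c0"]
            cache["acts"][name] = y
            h = y
        core = h.reshape(B, self.latent_dim)
        g = temb @ p["wg"] + p["bg"]
        s = temb @ p["ws"] + p["bs"]
        tmpl = C @ p["M"]
        out = core + g * X + s * tmpl
        if keep:
            cache.update(X=X, g=g, s=s, tmpl=tmpl)
            return out, cache
        return out

    def predict(self, z_t: np.ndarray, t, cond: np.ndarray) -> np.ndarray:
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

    # ------------------------------------------------------------------

    def loss_and_grads(self, X, t, C, target):
        out, cache = self._forward(X, t, C, keep=True)
        p = self.params
        temb, C_ = cache["temb"], cache["C"]
        diff = out - target
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dout = (2.0 / diff.size) * diff
        grads = {}
        dg = (dout * cache["X"]).sum(axis=1, keepdims=True)
        grads["wg"] = temb.T @ dg
        grads["bg"] = dg.sum(0)
        ds = (dout * cache["tmpl"]).sum(axis=1, keepdims=True)
        grads["ws"] = temb.T @ ds
        grads["bs"] = ds.sum(0)
        grads["M"] = C_.T @ (cache["s"] * dout)

        B = X.shape[0]
        # input spatial shape of every conv (after any pre-upsampling)
        ins = {}
        cur = self.image_shape
        for name, ci, co, st, up, upa in self.layers:
            if up:
                cur = (cur[0] * 2, cur[1] * 2, cur[2])
            ins[name] = (B, cur[0], cur[1], ci)
            cur = (cur[0] // st, cur[1] // st, co)
            if upa:
                cur = (cur[0] * 2, cur[1] * 2, cur[2])

        # d_at_out[name]: gradient wrt the layer's final output (post-relu,
        # post-upsample-after, post-skip-add); skip adds route extra gradient
        # to their source
        skip_of = {"u1": "d1", "u2": "c0"}
        d_at_out = {name: None for name, *_ in self.layers}
        d_at_out["out"] = dout.reshape((B,) + self.image_shape)
        order = [name for name, *_ in self.layers]
        for name, ci, co, st, up, upa in reversed(self.layers):
            dh = d_at_out[name]
            if name in skip_of:  # the add passes dh to the skip source unchanged
                src = skip_of[name]
                d_at_out[src] = dh if d_at_out[src] is None else d_at_out[src] + dh
            if upa:
                dh = _upsample_back(dh)
            if name != "out":
                dh = dh * (cache["pre"][name] > 0)
                dbias = dh.sum(axis=(1, 2))
                grads[f"At_{name}"] = temb.T @ dbias
                grads[f"Ac_{name}"] = C_.T @ dbias
                grads[f"b_{name}"] = dbias.sum(0)
            else:
                grads[f"b_{name}"] = dh.sum(axis=(0, 1, 2))
            grads[f"W_{name}"] = cache["cols"][name].T @ dh.reshape(-1, co)
            dx = _conv_dx(dh, p[f"W_{name}"], st, ins[name])
            if up:
                dx = _upsample_back(dx)
            prev = order[order.index(name) - 1] if name != "c0" else None
            if prev is not None:
                d_at_out[prev] = dx if d_at_out[prev] is None else d_at_out[prev] + dx
        return loss, grads
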