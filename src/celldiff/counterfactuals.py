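"""Counterfactual heat maps.

For each candidate class c the mean signed residual over N shared-(t, eps)
trials is accumulated,

    Delta_c = (1/N) sum_n ( eps_n - eps_theta(z_{t_n}, t_n, c) ),

and re-expressed relative to the predicted class c_hat as
delta_c = Delta_c - Delta_chat, so that delta_chat is identically zero.
Decoding through the latent codec yields the heat map H_c = D(delta_c),
a picture of what would have to change in the image for the model to
prefer class c; with the pixel-space identity codec H_c is delta_c itself,
reshaped.  The signed maps are displayed on a symmetric diverging scale
centred at zero, and overlays mark the pixels whose magnitude (relative to
the per-map median background) falls in a top fraction q.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import ClassifierResult, DiffusionClassifier
from .diffusion import LatentCodec

__all__ = [
    "HeatmapSet",
    "accumulate_deltas",
    "adjust_deltas",
    "decode_heatmaps",
    "overlay",
    "explain",
    "save_heatmaps",
]


@dataclass
class HeatmapSet:
    """Counterfactual maps for one image, one entry per candidate class."""

    source_id: str
    predicted: str
    delta_by_class: dict[str, np.ndarray]
    adjusted_by_class: dict[str, np.ndarray]
    heatmap_by_class: dict[str, np.ndarray]
    n_iters: int
    classifier_result: ClassifierResult | None = None


def accumulate_deltas(
    classifier: DiffusionClassifier,
    image: np.ndarray,
    n_iters: int = 200,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], ClassifierResult]:
    """Mean signed residuals Delta_c over a shared trial stream.

    The same trials also fill the classifier's error table, so the
    prediction used for the adjustment comes from the identical stream
    (one pass, half the cost).
    """
    result = classifier.classify_exhaustive(image, n_iters=n_iters, seed=seed,
                                            accumulate_deltas=True)
    return result.delta_by_class, result


def adjust_deltas(
    delta_by_class: dict[str, np.ndarray],
    predicted: str,
) -> dict[str, np.ndarray]:
    """delta_c = Delta_c - Delta_chat; delta_chat is exactly zero."""
    if predicted not in delta_by_class:
        raise KeyError(f"predicted class {predicted!r} missing from delta map")
    ref = delta_by_class[predicted]
    out = {c: d - ref for c, d in delta_by_class.items()}
    out[predicted] = np.zeros_like(ref)
    return out


def decode_heatmaps(
    adjusted_by_class: dict[str, np.ndarray],
    codec: LatentCodec,
) -> dict[str, np.ndarray]:
    """H_c = decode(delta_c); bit-exact reshape under the identity codec."""
    return {c: codec.decode(d) for c, d in adjusted_by_class.items()}


def explain(
    classifier: DiffusionClassifier,
    image: np.ndarray,
    n_iters: int = 200,
    seed: int = 0,
    source_id: str = "",
) -> HeatmapSet:
    """Full counterfactual pass: Delta_c, delta_c and decoded H_c per class."""
    deltas, result = accumulate_deltas(classifier, image, n_iters=n_iters, seed=seed)
    adjusted = adjust_deltas(deltas, result.predicted)
    maps = decode_heatmaps(adjusted, classifier.codec)
    return HeatmapSet(
        source_id=source_id,
        predicted=result.predicted,
        delta_by_class=deltas,
        adjusted_by_class=adjusted,
        heatmap_by_class=maps,
        n_iters=n_iters,
        classifier_result=result,
    )


def overlay(
    image: np.ndarray,
    heatmap: np.ndarray,
    top_fraction: float = 0.1,
    out_path=None,
    mark_color=(1.0, 0.1, 0.1),
) -> np.ndarray:
    """Mark the strongest-|H| pixels of a heat map on the original image.

    Per-pixel magnitude is the channel 2-norm of the heat map after
    subtracting the per-map (per-channel) median, the map's "background";
    the top ``top_fraction`` of pixels with strictly positive magnitude
    are tinted, ties broken by scan order.  Returns (and optionally
    writes) the overlay image.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    image = np.asarray(image, dtype=float)
    H = np.asarray(heatmap, dtype=float)
    if H.shape[:2] != image.shape[:2]:
        raise ValueError(f"heat map spatial size {H.shape[:2]} != image {image.shape[:2]}")
    med = np.median(H.reshape(-1, H.shape[-1]), axis=0)
    mag = np.sqrt(((H - med) ** 2).sum(axis=-1))
    flat = mag.ravel()
    n_mark = int(round(top_fraction * flat.size))
    n_mark = min(n_mark, int((flat > 0).sum()))
    out = image.copy()
    if n_mark > 0:
        # stable selection: sort by (-magnitude, scan index)
        order = np.lexsort((np.arange(flat.size), -flat))
        sel = order[:n_mark]
        yy, xx = np.unravel_index(sel, mag.shape)
        out[yy, xx] = 0.45 * out[yy, xx] + 0.55 * np.asarray(mark_color)
    if out_path is not None:
        from PIL import Image

        arr8 = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr8).save(out_path)
    return out


def save_heatmaps(hs: HeatmapSet, out_dir, image: np.ndarray | None = None,
                  top_fraction: float = 0.1) -> dict:
    """Write per-class heat-map PNGs, raw arrays (.npz) and a JSON index."""
    import json

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {"predicted": hs.predicted, "n_iters": hs.n_iters,
             "source_id": hs.source_id, "maps": {}}
    arrays = {}
    for c, Hc in hs.heatmap_by_class.items():
        # symmetric diverging rendering centred at 0
        lim = float(np.max(np.abs(Hc))) or 1.0
        val = (Hc.mean(axis=-1) if Hc.ndim == 3 else Hc) / lim  # [-1, 1]
        rgb = np.stack([np.clip(1.0 + np.minimum(val, 0), 0, 1),
                        np.clip(1.0 - np.abs(val), 0, 1),
                        np.clip(1.0 - np.maximum(val, 0), 0, 1)], axis=-1)
        fname = f"H_{c}.png"
        Image.fromarray((rgb * 255).astype(np.uint8)).save(out / fname)
        arrays[f"H_{c}"] = Hc
        arrays[f"delta_{c}"] = hs.adjusted_by_class[c]
        index["maps"][c] = fname
    if image is not None:
        ov = overlay(image, hs.heatmap_by_class[min(
            (c for c in hs.heatmap_by_class if c != hs.predicted),
            key=lambda c: float(np.sum(hs.adjusted_by_class[c] ** 2)),
            default=hs.predicted)], top_fraction,
            out_path=out / "overlay.png")
        index["overlay"] = "overlay.png"
    np.savez(out / "heatmaps.npz", **arrays)
    index["arrays"] = "heatmaps.npz"
    (out / "index.json").write_text(json.dumps(index, indent=2))
    return index
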