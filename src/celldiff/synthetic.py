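"""Seeded generator of synthetic single-cell microscopy images.

The generator emulates the gross morphology that distinguishes leukocyte
classes on a stained blood smear — nucleus lobation, nuclear-to-cell area
ratio, cytoplasmic granularity, cytoplasm hue and cell size — on a small
canvas (default 32x32 RGB).  It is a structural, not photometric, stand-in
for clinical single-cell crops: classes are separable by the same kinds of
features a morphologist uses, while rendering is deliberately schematic.

Domain shifts (stain hue, contrast, focus blur, zoom, background level) are
applied as a post-processing pipeline so that the same underlying cell can
be observed under different "microscopes".  A held-out anomalous class
(ring-shaped nucleus, distinct hue, emulating a nucleated red-cell
precursor) and an artefact class (smudge without nucleus) support the
anomaly-detection protocol.

All randomness flows through named Philox streams keyed on the caller's
seed; every output is a pure function of its arguments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image
from scipy import ndimage

from .rng import child_seed, stream

__all__ = [
    "ClassSpec",
    "DomainSpec",
    "ImageSample",
    "generate_image",
    "generate_arrays",
    "generate_dataset",
    "generate_morph_continuum",
    "make_expert_panel",
    "default_class_specs",
    "anomalous_class_spec",
    "artefact_class_spec",
    "DOMAIN_PRESETS",
    "CONFIDENCE_LEVELS",
    "load_manifest_images",
]

DEFAULT_IMG_SIZE = 32
DEFAULT_BACKGROUND = 0.94

#: Confidence vocabulary used by simulated labellers, best first.
CONFIDENCE_LEVELS = ("high", "moderate", "low", "none")

#: Correct-probability bins mapping a simulated expert's reliability to a
#: reported confidence level: [0.95, 1] -> high, [0.8, 0.95) -> moderate,
#: [0.5, 0.8) -> low, below -> none.
DEFAULT_CONFIDENCE_BINS = (0.95, 0.8, 0.5)

_NUCLEUS_COLOR = hsv_to_rgb((0.75, 0.60, 0.35))


@dataclass(frozen=True)
class ClassSpec:
    """Morphological parameters of one synthetic cell class.

    ``granule_density`` is the expected number of granules per 100 px^2 of
    cell area.  ``jitter`` is the relative standard deviation applied to the
    continuous parameters per image (hue receives an absolute jitter of
    ``jitter * 36`` degrees since relative spread is meaningless on a circle).
    """

    name: str
    nucleus_lobes: int = 1
    nucleus_area_frac: float = 0.4
    granule_density: float = 0.0
    cytoplasm_hue: float = 220.0
    cell_radius_px: float = 10.0
    jitter: float = 0.08
    nucleus_ring: bool = False
    smudge: bool = False

    def __post_init__(self) -> None:
        if int(self.nucleus_lobes) < 1:
            raise ValueError(f"nucleus_lobes must be >= 1, got {self.nucleus_lobes}")
        if not 0.0 < self.nucleus_area_frac < 1.0:
            raise ValueError(
                f"nucleus_area_frac must be in (0, 1), got {self.nucleus_area_frac}"
            )
        if self.granule_density < 0:
            raise ValueError(f"granule_density must be >= 0, got {self.granule_density}")
        if not 0.0 <= self.cytoplasm_hue < 360.0:
            raise ValueError(
                f"cytoplasm_hue must be in [0, 360), got {self.cytoplasm_hue}"
            )
        if self.cell_radius_px <= 0:
            raise ValueError(f"cell_radius_px must be > 0, got {self.cell_radius_px}")
        if self.jitter < 0:
            raise ValueError(f"jitter must be >= 0, got {self.jitter}")

    def _key(self) -> str:
        vals = dataclasses.astuple(self)[1:]  # exclude name: equal fields, equal law
        return ",".join(f"{v:.17g}" if isinstance(v, float) else str(v) for v in vals)


@dataclass(frozen=True)
class DomainSpec:
    """Imaging-domain transform: zoom -> blur -> hue shift -> contrast -> background."""

    hue_shift: float = 0.0
    contrast_gain: float = 1.0
    blur_sigma: float = 0.0
    zoom: float = 1.0
    background_level: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.contrast_gain <= 0:
            raise ValueError(f"contrast_gain must be > 0, got {self.contrast_gain}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        if self.zoom <= 0:
            raise ValueError(f"zoom must be > 0, got {self.zoom}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError(
                f"background_level must be in [0, 1], got {self.background_level}"
            )

    @classmethod
    def identity(cls) -> "DomainSpec":
        return cls()

    def _key(self) -> str:
        return ",".join(f"{v:.17g}" for v in dataclasses.astuple(self))


DOMAIN_PRESETS: dict[str, DomainSpec] = {
    "identity": DomainSpec.identity(),
    # different stain batch + camera: warmer hue, harder contrast, mild defocus
    "shifted": DomainSpec(hue_shift=25.0, contrast_gain=1.25, blur_sigma=0.5,
                          zoom=1.0, background_level=0.88),
    # different optics: magnified view of the same cell
    "zoomed": DomainSpec(zoom=1.6),
}


@dataclass
class ImageSample:
    """One cell image with optional label, labeller confidences and domain tag."""

    pixels: np.ndarray  # H x W x 3, float in [0, 1]
    label: str | None = None
    labeller_confidences: list[str] | None = None
    domain: str | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)


def default_class_specs() -> list[ClassSpec]:
    """Five in-distribution classes emulating common leukocyte morphologies."""
    return [
        ClassSpec("neutrophil", nucleus_lobes=3, nucleus_area_frac=0.30,
                  granule_density=1.5, cytoplasm_hue=300.0, cell_radius_px=10.5),
        ClassSpec("lymphocyte", nucleus_lobes=1, nucleus_area_frac=0.72,
                  granule_density=0.0, cytoplasm_hue=215.0, cell_radius_px=8.0),
        ClassSpec("monocyte", nucleus_lobes=2, nucleus_area_frac=0.48,
                  granule_density=0.4, cytoplasm_hue=200.0, cell_radius_px=12.5),
        ClassSpec("eosinophil", nucleus_lobes=2, nucleus_area_frac=0.28,
                  granule_density=7.0, cytoplasm_hue=15.0, cell_radius_px=10.0),
        ClassSpec("basophil", nucleus_lobes=2, nucleus_area_frac=0.38,
                  granule_density=9.0, cytoplasm_hue=262.0, cell_radius_px=9.0),
    ]


def anomalous_class_spec() -> ClassSpec:
    """Held-out anomalous class: ring nucleus and a hue outside the training set."""
    return ClassSpec("erythroblastoid", nucleus_lobes=1, nucleus_area_frac=0.45,
                     granule_density=0.0, cytoplasm_hue=95.0, cell_radius_px=9.5,
                     nucleus_ring=True)


def artefact_class_spec() -> ClassSpec:
    """Artefact class: anucleate smudge, emulating debris on the smear."""
    return ClassSpec("artefact", nucleus_lobes=1, nucleus_area_frac=0.3,
                     granule_density=0.0, cytoplasm_hue=230.0, cell_radius_px=11.0,
                     jitter=0.2, smudge=True)


# ---------------------------------------------------------------------------
# rendering

def _disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    """Anti-aliased disc mask in [0, 1] with a ~1 px soft edge."""
    d = np.hypot(yy - cy, xx - cx)
    return np.clip(r - d + 0.5, 0.0, 1.0)


def _sample_params(spec: ClassSpec, rng: np.random.Generator, size: int) -> dict:
    j = spec.jitter

    def rel(v: float, lo: float, hi: float) -> float:
        return float(np.clip(v * (1.0 + j * rng.standard_normal()), lo, hi))

    radius = rel(spec.cell_radius_px, 2.0, size / 2.0 - 1.0)
    return {
        "radius": radius,
        "area_frac": rel(spec.nucleus_area_frac, 0.02, 0.95),
        "density": max(0.0, spec.granule_density * (1.0 + j * rng.standard_normal())),
        "hue": (spec.cytoplasm_hue + j * 36.0 * rng.standard_normal()) % 360.0,
        "cy": size / 2.0 + j * radius * rng.standard_normal(),
        "cx": size / 2.0 + j * radius * rng.standard_normal(),
        "theta0": rng.uniform(0.0, 2.0 * math.pi),
    }


def _render_cell(spec: ClassSpec, rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render the cell layer; returns (rgb, alpha, meta)."""
    p = _sample_params(spec, rng, size)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy, cx, r = p["cy"], p["cx"], p["radius"]

    cyto = hsv_to_rgb((p["hue"] / 360.0, 0.45, 0.82))
    rgb = np.zeros((size, size, 3))
    alpha = np.zeros((size, size))

    if spec.smudge:
        # anucleate irregular blob: overlapping washed-out discs
        n_blobs = 4
        for _ in range(n_blobs):
            by = cy + rng.uniform(-0.5, 0.5) * r
            bx = cx + rng.uniform(-0.5, 0.5) * r
            br = r * rng.uniform(0.4, 0.8)
            m = _disc(yy, xx, by, bx, br) * 0.7
            col = hsv_to_rgb((p["hue"] / 360.0, 0.18, 0.75))
            rgb = rgb * (1 - m[..., None]) + col * m[..., None]
            alpha = np.maximum(alpha, m)
        n_granules = 0
    else:
        m = _disc(yy, xx, cy, cx, r)
        rgb = rgb * (1 - m[..., None]) + cyto * m[..., None]
        alpha = np.maximum(alpha, m)

        # granules: Poisson count at `density` per 100 px^2 of cell area
        cell_area = math.pi * r * r
        lam = p["density"] * cell_area / 100.0
        n_granules = int(rng.poisson(lam))
        gran_col = hsv_to_rgb((p["hue"] / 360.0, 0.65, 0.40))
        for _ in range(n_granules):
            rad = r * math.sqrt(rng.uniform(0.0, 1.0)) * 0.92
            ang = rng.uniform(0.0, 2.0 * math.pi)
            gy, gx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            gr = rng.uniform(0.7, 1.3)
            g = _disc(yy, xx, gy, gx, gr) * m
            rgb = rgb * (1 - g[..., None]) + gran_col * g[..., None]

        # nucleus
        rn = r * math.sqrt(p["area_frac"])
        if spec.nucleus_ring:
            outer = _disc(yy, xx, cy, cx, rn * 1.12)
            inner = _disc(yy, xx, cy, cx, rn * 0.62)
            nmask = np.clip(outer - inner, 0.0, 1.0) * m
            rgb = rgb * (1 - nmask[..., None]) + _NUCLEUS_COLOR * nmask[..., None]
        else:
            lobes = int(spec.nucleus_lobes)
            rl = rn / math.sqrt(lobes)
            d_l = 0.0 if lobes == 1 else rn * 0.85
            for k in range(lobes):
                ang = p["theta0"] + 2.0 * math.pi * k / lobes
                ly, lx = cy + d_l * math.sin(ang), cx + d_l * math.cos(ang)
                nmask = _disc(yy, xx, ly, lx, rl) * m
                rgb = rgb * (1 - nmask[..., None]) + _NUCLEUS_COLOR * nmask[..., None]

    meta = {"n_granules": n_granules, **p}
    return rgb, alpha, meta


def _zoom_layer(arr: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the image centre, keeping the canvas size fixed."""
    if factor == 1.0:
        return arr
    size = arr.shape[0]
    coords = (np.arange(size) - (size - 1) / 2.0) / factor + (size - 1) / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    if arr.ndim == 2:
        return ndimage.map_coordinates(arr, [yy, xx], order=1, mode="constant", cval=0.0)
    out = np.empty_like(arr)
    for ch in range(arr.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            arr[..., ch], [yy, xx], order=1, mode="constant", cval=0.0
        )
    return out


def _apply_domain(rgb: np.ndarray, alpha: np.ndarray, domain: DomainSpec) -> np.ndarray:
    # 1. zoom
    rgb = _zoom_layer(rgb, domain.zoom)
    alpha = _zoom_layer(alpha, domain.zoom)
    # 2. blur
    if domain.blur_sigma > 0:
        rgb = np.stack(
            [ndimage.gaussian_filter(rgb[..., c], domain.blur_sigma) for c in range(3)],
            axis=-1,
        )
        alpha = ndimage.gaussian_filter(alpha, domain.blur_sigma)
    # 3. hue shift
    if domain.hue_shift != 0.0:
        hsv = rgb_to_hsv(np.clip(rgb, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + domain.hue_shift / 360.0) % 1.0
        rgb = hsv_to_rgb(hsv)
    # 4. contrast
    if domain.contrast_gain != 1.0:
        rgb = np.clip(0.5 + domain.contrast_gain * (rgb - 0.5), 0.0, 1.0)
    # 5. composite over uniform background
    alpha = np.clip(alpha, 0.0, 1.0)[..., None]
    out = alpha * rgb + (1.0 - alpha) * domain.background_level
    return np.clip(out, 0.0, 1.0)


def generate_image(
    spec: ClassSpec,
    domain: DomainSpec | None = None,
    seed: int = 0,
    img_size: int = DEFAULT_IMG_SIZE,
    domain_name: str | None = None,
) -> ImageSample:
    """Render one cell image; a pure function of ``(spec, domain, seed)``."""
    domain = DomainSpec.identity() if domain is None else domain
    rng = stream(seed, "generate_image", spec._key(), img_size)
    rgb, alpha, meta = _render_cell(spec, rng, img_size)
    pixels = _apply_domain(rgb, alpha, domain)
    return ImageSample(
        pixels=pixels,
        label=spec.name,
        domain=domain_name,
        source_id=f"{spec.name}-{seed}",
        meta=meta,
    )


def generate_morph_continuum(
    spec_a: ClassSpec,
    spec_b: ClassSpec,
    signal: float,
    seed: int = 0,
    img_size: int = DEFAULT_IMG_SIZE,
    domain: DomainSpec | None = None,
) -> ImageSample:
    """Image from a spec interpolated between ``spec_b`` and ``spec_a``.

    The interpolation parameter is ``(1 + signal) / 2`` toward ``spec_a``:
    ``signal = 0`` gives the exact morphological midpoint (maximally
    ambiguous), ``signal = 1`` reproduces ``spec_a``.  Integer fields are
    rounded half-up; hue interpolates along the shortest arc of the colour
    circle (so intermediates stay between the endpoint hues instead of
    sweeping through unrelated colours); boolean style flags follow the
    majority side.
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError(f"signal must be in [0, 1], got {signal}")
    a = (1.0 + signal) / 2.0

    def lerp(va: float, vb: float) -> float:
        return a * va + (1.0 - a) * vb

    hue_step = ((spec_a.cytoplasm_hue - spec_b.cytoplasm_hue + 180.0) % 360.0) - 180.0
    spec = ClassSpec(
        name=spec_a.name,
        nucleus_lobes=int(math.floor(lerp(spec_a.nucleus_lobes, spec_b.nucleus_lobes) + 0.5)),
        nucleus_area_frac=lerp(spec_a.nucleus_area_frac, spec_b.nucleus_area_frac),
        granule_density=lerp(spec_a.granule_density, spec_b.granule_density),
        cytoplasm_hue=(spec_b.cytoplasm_hue + a * hue_step) % 360.0,
        cell_radius_px=lerp(spec_a.cell_radius_px, spec_b.cell_radius_px),
        jitter=lerp(spec_a.jitter, spec_b.jitter),
        nucleus_ring=spec_a.nucleus_ring if a >= 0.5 else spec_b.nucleus_ring,
        smudge=spec_a.smudge if a >= 0.5 else spec_b.smudge,
    )
    sample = generate_image(spec, domain=domain, seed=seed, img_size=img_size)
    sample.meta["signal"] = signal
    return sample


# ---------------------------------------------------------------------------
# datasets

def generate_arrays(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    domain: DomainSpec | None = None,
    seed: int = 0,
    img_size: int = DEFAULT_IMG_SIZE,
    domain_name: str | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """In-memory stratified dataset: (images (N,H,W,3), labels, source_ids)."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names in specs")
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    images, labels, sids = [], [], []
    for ci, spec in enumerate(specs):
        for i in range(n_per_class):
            s = child_seed(seed, "dataset", ci, i)
            sample = generate_image(spec, domain=domain, seed=s, img_size=img_size,
                                    domain_name=domain_name)
            images.append(sample.pixels)
            labels.append(spec.name)
            sids.append(f"{spec.name}-{i:04d}-{s}")
    shape = (len(images), img_size, img_size, 3)
    X = np.array(images).reshape(shape) if images else np.empty(shape)
    return X, labels, sids


def generate_dataset(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    domain: DomainSpec | None = None,
    seed: int = 0,
    out_dir: str | Path = "data",
    img_size: int = DEFAULT_IMG_SIZE,
    domain_name: str = "identity",
) -> pd.DataFrame:
    """Write a stratified PNG dataset and its CSV manifest; return the manifest."""
    X, labels, sids = generate_arrays(specs, n_per_class, domain, seed, img_size,
                                      domain_name)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[str, int] = {}
    for img, label, sid in zip(X, labels, sids):
        i = counters.get(label, 0)
        counters[label] = i + 1
        fname = f"{label}_{i:04d}.png"
        arr8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr8).save(out / fname)
        rows.append({"path": fname, "label": label, "domain": domain_name,
                     "source_id": sid})
    manifest = pd.DataFrame(rows, columns=["path", "label", "domain", "source_id"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest_images(manifest: pd.DataFrame | str | Path,
                         root: str | Path | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Load the PNG images referenced by a manifest into an (N,H,W,3) array."""
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = path.parent if root is None else Path(root)
        manifest = pd.read_csv(path)
    root = Path(".") if root is None else Path(root)
    imgs = []
    for p in manifest["path"]:
        fp = Path(p)
        if not fp.is_absolute():
            fp = root / fp
        imgs.append(np.asarray(Image.open(fp).convert("RGB"), dtype=np.float64) / 255.0)
    return np.stack(imgs), manifest.reset_index(drop=True)


# ---------------------------------------------------------------------------
# simulated expert panel

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_expert_panel(
    manifest: pd.DataFrame,
    continuum_signals: Sequence[float],
    n_experts: int,
    expert_slopes: Sequence[float],
    seed: int = 0,
    class_names: Sequence[str] | None = None,
    confidence_bins: Sequence[float] = DEFAULT_CONFIDENCE_BINS,
) -> pd.DataFrame:
    """Simulate an expert labelling panel over a manifest.

    Each expert labels image ``i`` correctly with probability
    ``1/K + (1 - 1/K) * (2*sigmoid(slope * x_i) - 1)`` where ``x_i`` is the
    image's discriminability signal in [0, 1]: chance accuracy at zero slope
    or zero signal, perfection in the steep-expert high-signal limit.  The
    same probability, quantized through ``confidence_bins``, is reported as
    the expert's confidence level.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    x = np.asarray(continuum_signals, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("continuum_signals must be in [0, 1]")
    if len(x) != len(manifest):
        raise ValueError("one signal per manifest row required")
    slopes = np.asarray(expert_slopes, dtype=float)
    if len(slopes) != n_experts:
        raise ValueError("one slope per expert required")
    classes = sorted(set(manifest["label"])) if class_names is None else list(class_names)
    K = len(classes)
    out = manifest.copy()
    hi, mid, lo = confidence_bins
    for e in range(n_experts):
        rng = stream(seed, "expert_panel", e)
        with np.errstate(invalid="ignore"):
            inner = 2.0 * _sigmoid(slopes[e] * x) - 1.0
            # inf * 0 -> nan: the slope->inf limit at zero signal is chance level
            p = 1.0 / K + (1.0 - 1.0 / K) * np.where(np.isnan(inner), 0.0, inner)
        labels, confs = [], []
        for i, row in enumerate(out.itertuples(index=False)):
            true = row.label
            if rng.uniform() < p[i]:
                lab = true
            else:
                others = [c for c in classes if c != true]
                lab = others[int(rng.integers(len(others)))] if others else true
            labels.append(lab)
            if p[i] >= hi:
                confs.append("high")
            elif p[i] >= mid:
                confs.append("moderate")
            elif p[i] >= lo:
                confs.append("low")
            else:
                confs.append("none")
        out[f"label_expert_{e + 1}"] = labels
        out[f"conf_expert_{e + 1}"] = confs
    return out
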