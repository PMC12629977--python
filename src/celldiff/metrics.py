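"""Dataset splitting and classification metrics.

Macro-averaged metrics follow the convention that a class never predicted
contributes zero to the macro mean (logged); balanced accuracy is the
macro average of per-class sensitivities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .rng import stream

__all__ = ["SplitPlan", "split_manifest", "MetricsReport", "compute_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/validation/test split fractions (default 70-10-20)."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    stratify_by_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("fractions must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _apportion(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n items to the three splits."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in range(rem):
        base[order[i]] += 1
    return base


def split_manifest(manifest: pd.DataFrame, plan: SplitPlan):
    """Assign each manifest row to train/val/test; returns the three frames.

    Stratified by label when requested, seeded, disjoint and exhaustive; a
    ``split`` column is written.  A class too small to populate every
    non-zero split raises.
    """
    manifest = manifest.reset_index(drop=True).copy()
    rng = stream(plan.seed, "split")
    split_col = np.empty(len(manifest), dtype=object)
    groups = (manifest.groupby("label").indices.items()
              if plan.stratify_by_label else [("__all__", np.arange(len(manifest)))])
    wanted = [f > 0 for f in (plan.train, plan.val, plan.test)]
    for label, idx in groups:
        idx = np.asarray(idx)
        counts = _apportion(len(idx), (plan.train, plan.val, plan.test))
        if any(w and c == 0 for w, c in zip(wanted, counts)):
            raise ValueError(
                f"class {label!r} has too few images ({len(idx)}) for the split plan")
        perm = idx[rng.permutation(len(idx))]
        a, b = counts[0], counts[0] + counts[1]
        split_col[perm[:a]] = "train"
        split_col[perm[a:b]] = "val"
        split_col[perm[b:]] = "test"
    manifest["split"] = split_col
    return (manifest[manifest["split"] == s].reset_index(drop=True)
            for s in ("train", "val", "test"))


@dataclass
class MetricsReport:
    """Macro-averaged classification metrics with the confusion matrix."""

    accuracy: float
    balanced_accuracy: float
    macro_f1: float
    macro_sensitivity: float
    macro_precision: float
    confusion: np.ndarray
    classes: list[str]
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_f1": self.macro_f1,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_precision": self.macro_precision,
            "classes": self.classes,
            "confusion_matrix": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="list"),
        }

    def summary(self) -> str:
        lines = [
            "Classification metrics (macro averages)",
            "-" * 46,
            f"accuracy            {self.accuracy:.4f}",
            f"balanced accuracy   {self.balanced_accuracy:.4f}",
            f"macro F1            {self.macro_f1:.4f}",
            f"macro sensitivity   {self.macro_sensitivity:.4f}",
            f"macro precision     {self.macro_precision:.4f}",
        ]
        return "\n".join(lines)


def compute_metrics(truth, predicted, classes: list[str] | None = None) -> MetricsReport:
    """Accuracy, balanced accuracy and macro F1/sensitivity/precision.

    ``classes`` fixes the label universe (classes absent from predictions
    still enter the macro averages, with zero-division resolved to 0 and
    logged).
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if not truth:
        raise ValueError("empty input")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    unknown = (set(truth) | set(predicted)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    cm = _sk_confusion(truth, predicted, labels=classes)
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)  # true counts
    col = cm.sum(axis=0).astype(float)  # predicted counts
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(row > 0, tp / row, 0.0)
        prec = np.where(col > 0, tp / col, 0.0)
        f1 = np.where(sens + prec > 0, 2 * sens * prec / (sens + prec), 0.0)
    if np.any(col == 0):
        never = [c for c, n in zip(classes, col) if n == 0]
        logger.warning("classes never predicted (macro contribution 0): %s", never)
    per_class = pd.DataFrame({"class": classes, "n_true": row.astype(int),
                              "sensitivity": sens, "precision": prec, "f1": f1})
    present = row > 0  # macro averages over classes present in the truth
    return MetricsReport(
        accuracy=float(tp.sum() / cm.sum()),
        balanced_accuracy=float(sens[present].mean()),
        macro_f1=float(f1[present].mean()),
        macro_sensitivity=float(sens[present].mean()),
        macro_precision=float(prec[present].mean()),
        confusion=cm,
        classes=list(classes),
        per_class=per_class,
    )
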