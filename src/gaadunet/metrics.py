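"""Segmentation evaluation: overlap scores and surface distances.

Masks are integer label images over {0: background, 1: cytoplasm,
2: nucleus}. Overlap metrics (accuracy, IoU, Dice) are computed one-vs-rest
from pixel confusion counts; boundary fidelity is measured by the 95th
percentile Hausdorff distance (HD95) and the average symmetric surface
distance (ASSD) between boundary point sets, in pixel units on pixel
centers.

Conventions (documented, since reporting practice varies):

* Boundary pixels are class pixels with at least one 4-neighbor outside the
  class; the image border counts as outside.
* "Mean" scores are unweighted macro averages over the three classes
  (``include_background=False`` drops class 0); HD95/ASSD are computed for
  the two foreground classes only.
* A class absent from both masks is skipped from the macro mean; a class
  absent from exactly one mask scores IoU = DSC = 0 and is assigned the
  image diagonal as surface distance, and the report flags it.
* The 95th percentile uses linear interpolation on the sorted directed
  distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "iou",
           "dsc", "accuracy", "extract_surface", "hd95", "assd", "evaluate",
           "CLASS_NAMES"]

CLASS_NAMES = {0: "background", 1: "cytoplasm", 2: "nucleus"}
FOREGROUND_CLASSES = (1, 2)


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_aligned(pred: np.ndarray, gt: np.ndarray):
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    return pred, gt


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     class_id: int) -> ConfusionCounts:
    pred, gt = _check_aligned(pred, gt)
    p = pred == class_id
    g = gt == class_id
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def iou(c: ConfusionCounts) -> float:
    """Jaccard index tp / (tp + fp + fn); requires a nonempty union."""
    union = c.tp + c.fp + c.fn
    if union == 0:
        raise ZeroDivisionError("IoU undefined: class absent from both masks")
    return c.tp / union


def dsc(c: ConfusionCounts) -> float:
    """Dice coefficient 2·tp / (2·tp + fp + fn)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ZeroDivisionError("DSC undefined: class absent from both masks")
    return 2 * c.tp / denom


def accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of pixels with the correct label, over all classes jointly."""
    pred, gt = _check_aligned(pred, gt)
    return float(np.count_nonzero(pred == gt)) / pred.size


def extract_surface(mask: np.ndarray, class_id: int) -> np.ndarray:
    """(N, 2) array of boundary pixel coordinates (row, col) for one class.

    A class pixel is a boundary pixel if any of its 4-neighbors lies outside
    the class; pixels on the image border always qualify.
    """
    m = np.asarray(mask) == class_id
    if not m.any():
        return np.empty((0, 2), dtype=np.int64)
    inside = np.zeros_like(m)
    # pixel whose 4 neighbours (border = outside) are all in-class
    inside[1:-1, 1:-1] = (m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1]
                          & m[1:-1, :-2] & m[1:-1, 2:])
    boundary = m & ~inside
    return np.argwhere(boundary).astype(np.int64)


def _directed_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """min_b ||a − b|| for every a in A (Euclidean, via a k-d tree)."""
    d, _ = cKDTree(B).query(A, k=1)
    return np.asarray(d, dtype=np.float64)


def hd95(A: np.ndarray, B: np.ndarray) -> float:
    """95th-percentile Hausdorff distance between two surface point sets.

    Maximum of the two directed 95th-percentile nearest-neighbor distances;
    symmetric by construction.
    """
    A, B = np.asarray(A), np.asarray(B)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("hd95 requires two nonempty point sets")
    return float(max(np.percentile(_directed_distances(A, B), 95),
                     np.percentile(_directed_distances(B, A), 95)))


def assd(A: np.ndarray, B: np.ndarray) -> float:
    """Average symmetric surface distance between two surface point sets."""
    A, B = np.asarray(A), np.asarray(B)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("assd requires two nonempty point sets")
    dab = _directed_distances(A, B)
    dba = _directed_distances(B, A)
    return float((dab.sum() + dba.sum()) / (len(A) + len(B)))


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics for one prediction/ground-truth pair."""

    accuracy: float
    per_class_iou: dict[int, float | None]
    per_class_dsc: dict[int, float | None]
    per_class_hd95: dict[int, float | None]
    per_class_assd: dict[int, float | None]
    mean_iou: float
    mean_dsc: float
    mean_hd95: float | None
    mean_assd: float | None
    pixel_count: int
    include_background: bool
    flagged_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        flat = {"accuracy": self.accuracy, "mean_iou": self.mean_iou,
                "mean_dsc": self.mean_dsc, "mean_hd95": self.mean_hd95,
                "mean_assd": self.mean_assd, "pixel_count": self.pixel_count,
                "include_background": self.include_background,
                "flagged_classes": list(self.flagged_classes)}
        for c, name in CLASS_NAMES.items():
            flat[f"iou_{name}"] = self.per_class_iou.get(c)
            flat[f"dsc_{name}"] = self.per_class_dsc.get(c)
            if c in FOREGROUND_CLASSES:
                flat[f"hd95_{name}"] = self.per_class_hd95.get(c)
                flat[f"assd_{name}"] = self.per_class_assd.get(c)
        return flat


def _macro_mean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def evaluate(pred: np.ndarray, gt: np.ndarray,
             include_background: bool = True) -> MetricsReport:
    """Full per-image evaluation.

    Overlap scores are macro-averaged over the three classes (or the two
    foreground classes with ``include_background=False``); HD95/ASSD cover
    foreground classes only.
    """
    pred, gt = _check_aligned(pred, gt)
    diag = math.hypot(*pred.shape)
    per_iou: dict[int, float | None] = {}
    per_dsc: dict[int, float | None] = {}
    per_hd: dict[int, float | None] = {}
    per_as: dict[int, float | None] = {}
    flagged: list[int] = []

    for c in CLASS_NAMES:
        counts = confusion_counts(pred, gt, c)
        in_pred = counts.tp + counts.fp > 0
        in_gt = counts.tp + counts.fn > 0
        if not in_pred and not in_gt:
            per_iou[c] = per_dsc[c] = None  # absent everywhere: skip
            if c in FOREGROUND_CLASSES:
                per_hd[c] = per_as[c] = None
            continue
        if in_pred != in_gt:  # total miss: worst scores, flagged
            per_iou[c] = per_dsc[c] = 0.0
            if c in FOREGROUND_CLASSES:
                per_hd[c] = per_as[c] = diag
            flagged.append(c)
            continue
        per_iou[c] = iou(counts)
        per_dsc[c] = dsc(counts)
        if c in FOREGROUND_CLASSES:
            A = extract_surface(gt, c)
            B = extract_surface(pred, c)
            per_hd[c] = hd95(A, B)
            per_as[c] = assd(A, B)

    overlap_classes = list(CLASS_NAMES) if include_background else \
        list(FOREGROUND_CLASSES)
    mean_iou = _macro_mean(per_iou[c] for c in overlap_classes)
    mean_dsc = _macro_mean(per_dsc[c] for c in overlap_classes)
    return MetricsReport(
        accuracy=accuracy(pred, gt),
        per_class_iou=per_iou, per_class_dsc=per_dsc,
        per_class_hd95=per_hd, per_class_assd=per_as,
        mean_iou=mean_iou if mean_iou is not None else float("nan"),
        mean_dsc=mean_dsc if mean_dsc is not None else float("nan"),
        mean_hd95=_macro_mean(per_hd.values()),
        mean_assd=_macro_mean(per_as.values()),
        pixel_count=pred.size, include_background=include_background,
        flagged_classes=flagged)
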