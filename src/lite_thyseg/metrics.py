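"""Confusion-count segmentation metrics.

All metrics derive from per-pixel TP/FP/FN/TN tallies:

    DSC = 2TP / (2TP + FP + FN)        IoU = TP / (TP + FP + FN)
    SE  = TP / (TP + FN)               SP  = TN / (TN + FP)
    ACC = (TP + TN) / total            JSC = IoU

DSC and IoU are algebraically linked by DSC = 2*IoU / (1 + IoU), which
doubles as a consistency oracle for externally reported metric pairs.
Degenerate denominators (e.g. sensitivity on an image with no foreground
anywhere) evaluate to 1: a correct rejection of an empty image is not
penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "dsc_from_iou",
    "aggregate",
    "binarize",
]

THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary segmentation against ground truth."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    iou: float
    se: float
    sp: float
    acc: float

    @property
    def jsc(self) -> float:
        return self.iou

    def as_dict(self, percent: bool = False) -> dict:
        d = {"dsc": self.dsc, "iou": self.iou, "se": self.se,
             "sp": self.sp, "acc": self.acc, "jsc": self.jsc}
        if percent:
            d = {k: round(100.0 * v, 2) for k, v in d.items()}
        return d


def binarize(probs: np.ndarray, threshold: float = THRESHOLD) -> np.ndarray:
    """Threshold a probability map to a {0, 1} mask."""
    return (np.asarray(probs) > threshold).astype(np.uint8)


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth mask must be binary (values in {0, 1})")
    if not np.isin(pred, (0, 1)).all():
        raise ValueError("prediction mask must be binary; threshold probabilities first")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def _ratio(num: int, den: int) -> float:
    return 1.0 if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        se=_ratio(c.tp, c.tp + c.fn),
        sp=_ratio(c.tn, c.tn + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )


def dsc_from_iou(iou: float) -> float:
    """The exact DSC implied by an IoU value: 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou <= 1.0:
        raise ValueError(f"IoU must be in [0, 1], got {iou}")
    return 2.0 * iou / (1.0 + iou)


def aggregate(counts: Sequence[ConfusionCounts] | Iterable[ConfusionCounts],
              mode: str = "global_pool") -> MetricsReport:
    """Dataset-level metrics.

    ``global_pool`` sums confusion counts over all images before computing
    metrics; ``per_image_mean`` averages the per-image metric values.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("cannot aggregate an empty dataset")
    if mode == "global_pool":
        total = ConfusionCounts()
        for c in counts:
            total = total + c
        return compute_metrics(total)
    if mode == "per_image_mean":
        reports = [compute_metrics(c) for c in counts]
        return MetricsReport(*(float(np.mean([getattr(r, f) for r in reports]))
                               for f in ("dsc", "iou", "se", "sp", "acc")))
    raise ValueError("mode must be 'global_pool' or 'per_image_mean'")
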