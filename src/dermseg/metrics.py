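"""Pixelwise segmentation metrics from confusion counts.

All reported overlap statistics derive from per-pixel TP/FP/FN/TN tallies:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* Dice      = 2 TP / (2 TP + FP + FN)
* IoU       = TP / (TP + FP + FN)

Dice and IoU are linked by the exact identity ``Dice = 2 IoU / (1 + IoU)``,
so Dice >= IoU always.  Probability maps are binarised at a threshold
(default 0.5) with the strict-greater rule: values equal to the threshold
map to background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionCounts",
    "binarize",
    "confusion_counts",
    "accuracy",
    "dice_score",
    "iou_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against a binary reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability raster; strictly-greater wins, ties go to 0."""
    return (np.asarray(p) > threshold).astype(np.uint8)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValidationError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty raster")
    return (c.tp + c.tn) / c.total


def dice_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("Dice undefined when both masks are empty")
    return 2 * c.tp / denom


def iou_score(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("IoU undefined when both masks are empty")
    return c.tp / denom
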