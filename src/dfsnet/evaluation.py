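"""Segmentation metrics: confusion matrix, overall accuracy, and mIoU.

Accuracy is the fraction of points whose predicted class matches the true
class.  mIoU computes, per class i, IoU_i = S_ii / (sum_j S_ij + sum_j S_ji
- S_ii) from the confusion matrix S (S_ij = points of true class i
predicted as j), then averages over classes.  Classes absent from both
truth and prediction contribute an undefined 0/0 IoU; by default they are
excluded from the mean (``include_empty=False`` skips them either way —
the flag only controls whether the denominator counts all C classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ValidationError

__all__ = ["ConfusionMatrix", "confusion", "accuracy", "miou", "per_class_iou"]


@dataclass
class ConfusionMatrix:
    """C x C count matrix; entry [i, j] = points of true class i predicted j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(truth, pred, n_classes: int) -> ConfusionMatrix:
    """Tally prediction-vs-truth counts for labels in 0..C-1."""
    truth = np.asarray(truth, dtype=np.int64).ravel()
    pred = np.asarray(pred, dtype=np.int64).ravel()
    if truth.shape != pred.shape:
        raise ValidationError(
            f"truth and pred lengths differ: {truth.shape} vs {pred.shape}"
        )
    for name, arr in (("truth", truth), ("pred", pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(f"{name} labels outside 0..{n_classes - 1}")
    counts = np.bincount(
        truth * n_classes + pred, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall point accuracy: trace / total."""
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts)) / total


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU per class; NaN for classes absent from both truth and prediction."""
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    union = counts.sum(axis=1) + counts.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, tp / np.maximum(union, 1e-300), np.nan)
    return iou


def miou(cm: ConfusionMatrix, include_empty: bool = False) -> float:
    """Mean IoU over classes.

    ``include_empty=False`` (default): average over classes present in
    truth or prediction.  ``include_empty=True``: divide by all C classes,
    with empty classes skipped from the numerator (their IoU is undefined).
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    iou = per_class_iou(cm)
    present = ~np.isnan(iou)
    if not present.any():
        raise ValidationError("no class present in truth or prediction")
    denom = cm.n_classes if include_empty else int(present.sum())
    return float(np.nansum(iou) / denom)
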