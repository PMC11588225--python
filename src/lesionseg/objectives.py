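"""Training loss and evaluation metrics for binary lesion segmentation.

The training objective combines pixelwise binary cross-entropy with soft
Dice::

    L_B = -(1/N) sum_i [ t_i log p_i + (1 - t_i) log(1 - p_i) ]
    L_D = 1 - 2 sum_i p_i t_i / (sum_i p_i^2 + sum_i t_i^2)
    L   = L_D + L_B / 2

where ``p`` are predicted probabilities, ``t`` the binary targets and ``N``
the pixel count.  BCE judges each pixel independently; Dice measures region
overlap and is what keeps boundaries coherent under class imbalance.  The
Dice denominator uses squared terms; a smoothing constant ``smooth``
(default 1.0) is added to numerator and denominator so empty images are
well defined — pass ``smooth=0`` to evaluate the raw closed form.

Evaluation works on hard masks through pixel confusion counts::

    IoU = TP / (TP + FP + FN)        DSC = 2 TP / (2 TP + FP + FN)
    Acc = (TP + TN) / total          Sen = TP / (TP + FN)

A metric whose denominator is zero is reported as NaN ("undefined"), never
silently as 0.

All loss functions accept either numpy arrays (returning a float) or
autograd tensors (returning a differentiable tensor).  For rank-4
(batch, channel, row, col) inputs the batch loss is the mean of per-image
losses.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "EPSILON",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics",
    "write_metric_rows",
]

#: probabilities are clipped to [EPSILON, 1 - EPSILON] before the logarithm
EPSILON = 1e-7


def _prepare(pred, target) -> tuple[Tensor, Tensor, bool, tuple[int, ...]]:
    want_tensor = isinstance(pred, Tensor)
    p = ag.as_tensor(pred)
    t = ag.as_tensor(target)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    if p.size == 0:
        raise ValueError("empty prediction")
    # per-image axes: everything but the batch axis for rank-4 input
    axes = tuple(range(1, p.ndim)) if p.ndim == 4 else None
    return p, t, want_tensor, axes


def _finish(value: Tensor, want_tensor: bool):
    return value if want_tensor else float(value.item())


def bce_loss(pred, target):
    """Mean binary cross-entropy over pixels (mean of per-image means)."""
    p, t, want, axes = _prepare(pred, target)
    p = ag.clip(p, EPSILON, 1.0 - EPSILON)
    ll = t * ag.log(p) + (1.0 - t) * ag.log(1.0 - p)
    per_image = -ll.mean(axis=axes) if axes else -ll.mean()
    return _finish(per_image.mean() if axes else per_image, want)


def dice_loss(pred, target, smooth: float = 1.0):
    """Soft Dice loss on raw probabilities (squared-denominator form)."""
    p, t, want, axes = _prepare(pred, target)
    if axes:
        inter = (p * t).sum(axis=axes)
        denom = (p * p).sum(axis=axes) + (t * t).sum(axis=axes)
    else:
        inter = (p * t).sum()
        denom = (p * p).sum() + (t * t).sum()
    dice = (2.0 * inter + smooth) / (denom + smooth)
    loss = 1.0 - dice
    return _finish(loss.mean() if axes else loss, want)


def combined_loss(pred, target, smooth: float = 1.0):
    """Combined objective ``dice + bce / 2``."""
    p, t, want, _ = _prepare(pred, target)
    total = dice_loss(p, t, smooth=smooth) + bce_loss(p, t) * 0.5
    return _finish(total, want)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary segmentation against its ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricReport:
    """IoU, Dice, accuracy and sensitivity; NaN marks an undefined metric."""

    iou: float
    dsc: float
    acc: float
    sen: float

    def as_dict(self) -> dict[str, float]:
        return {"iou": self.iou, "dsc": self.dsc, "acc": self.acc, "sen": self.sen}


def confusion(pred, truth, threshold: float = 0.5) -> ConfusionCounts:
    """Pixel confusion counts after binarising `pred` at `threshold` (>= is
    positive)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {t.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    tset = np.unique(t)
    if not np.all(np.isin(tset, (0, 1))):
        raise ValueError("truth mask must be binary (0/1)")
    hard = p >= threshold
    pos = t.astype(bool)
    tp = int(np.count_nonzero(hard & pos))
    fp = int(np.count_nonzero(hard & ~pos))
    fn = int(np.count_nonzero(~hard & pos))
    tn = int(np.count_nonzero(~hard & ~pos))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate IoU/DSC/Acc/Sen from confusion counts.

    Raises ``ValueError`` when every count is zero (nothing was compared);
    individual metrics with zero denominators come back as NaN.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero; no pixels compared")
    return MetricReport(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        acc=_ratio(c.tp + c.tn, c.total),
        sen=_ratio(c.tp, c.tp + c.fn),
    )


def write_metric_rows(path, rows: Iterable[tuple[str, MetricReport]]) -> None:
    """Serialise per-image metric reports as CSV (image_id, iou, dsc, acc, sen)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "iou", "dsc", "acc", "sen"])
        for image_id, report in rows:
            writer.writerow([image_id, report.iou, report.dsc, report.acc, report.sen])
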