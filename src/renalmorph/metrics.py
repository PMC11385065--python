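"""Segmentation evaluation: Dice score, confusion matrix, mAP@[0.5:0.95].

Dice is the mask-overlap statistic 2TP/(2TP+FN+FP). The confusion matrix
follows the convention with columns as ground-truth classes and rows as
predicted classes, optionally column-normalized. Average precision uses
COCO-style greedy matching over the IoU thresholds 0.50:0.05:0.95 with an
all-point interpolated precision-recall curve; mAP is the plain mean of the
per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import ClassLabel, LabelMap
from .masks import InstanceMask, mask_iou

__all__ = [
    "ConfusionCounts",
    "dice_score",
    "dice_band",
    "confusion_matrix",
    "COCO_IOU_THRESHOLDS",
    "average_precision",
    "mean_average_precision",
    "APResult",
]

#: COCO-style matching thresholds, 0.50 to 0.95 in steps of 0.05.
COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class pixel confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if pred.shape != truth.shape:
            raise ValueError("masks must have the same shape")
        return cls(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
        )


def dice_score(counts: ConfusionCounts) -> float:
    """Dice = 2TP / (2TP + FN + FP); two empty masks score 1.0 by convention."""
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def dice_band(dice: float) -> str:
    """Qualitative band: > 0.8 good, 0.6-0.8 acceptable, < 0.6 bad."""
    if dice > 0.8:
        return "good"
    if dice >= 0.6:
        return "acceptable"
    return "bad"


def confusion_matrix(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    classes: Sequence[ClassLabel],
    normalize: bool = False,
) -> np.ndarray:
    """Pixel confusion matrix; rows are predicted, columns ground truth.

    Pixels whose predicted or true label is outside ``classes`` are
    ignored. With ``normalize`` each column is divided by its sum (empty
    columns stay zero).
    """
    p = pred.raster if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.raster if isinstance(truth, LabelMap) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"rasters not aligned: {p.shape} vs {t.shape}")
    codes = np.array([int(c) for c in classes])
    k = len(codes)
    lut = np.full(int(max(p.max(initial=0), t.max(initial=0), codes.max())) + 1, -1)
    lut[codes] = np.arange(k)
    pi = lut[p.ravel()]
    ti = lut[t.ravel()]
    keep = (pi >= 0) & (ti >= 0)
    m = np.bincount(pi[keep] * k + ti[keep], minlength=k * k).reshape(k, k).astype(float)
    if normalize:
        sums = m.sum(axis=0, keepdims=True)
        np.divide(m, sums, out=m, where=sums > 0)
    return m


@dataclass
class APResult:
    """Per-class average precision over the COCO IoU thresholds."""

    per_class: dict[ClassLabel, float | None] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return sum(1 for v in self.per_class.values() if v is not None)

    @property
    def mAP(self) -> float:
        defined = [v for v in self.per_class.values() if v is not None]
        if not defined:
            return float("nan")
        return float(np.mean(defined))


def _ap_at_threshold(
    preds: Sequence[InstanceMask], truths: Sequence[InstanceMask], thr: float
) -> float:
    """AP at one IoU threshold: greedy matching, all-point interpolation."""
    if not truths:
        return 0.0 if preds else float("nan")
    if not preds:
        return 0.0
    ious = np.array([[mask_iou(p, g) for g in truths] for p in preds])
    # descending score; ties broken by larger best-IoU, then input order
    best = ious.max(axis=1)
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, -best[i], i))
    matched = [False] * len(truths)
    tp = np.zeros(len(preds))
    for rank, i in enumerate(order):
        cand = [
            (ious[i, j], j)
            for j in range(len(truths))
            if not matched[j] and ious[i, j] >= thr
        ]
        if cand:
            _, j = max(cand)
            matched[j] = True
            tp[rank] = 1
    cum_tp = np.cumsum(tp)
    recall = cum_tp / len(truths)
    precision = cum_tp / np.arange(1, len(preds) + 1)
    # all-point interpolation: precision envelope from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    return float(np.sum((r[1:] - r[:-1]) * env))


def average_precision(
    preds: Sequence[InstanceMask],
    truths: Sequence[InstanceMask],
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> float | None:
    """Single-class AP averaged over IoU thresholds.

    Returns None (undefined) when both prediction and truth lists are
    empty; an empty truth with predictions scores 0.
    """
    classes = {p.class_label for p in preds} | {t.class_label for t in truths}
    if len(classes) > 1:
        raise ValueError("average_precision is per class; mixed classes passed")
    if not preds and not truths:
        return None
    vals = [_ap_at_threshold(preds, truths, thr) for thr in iou_thresholds]
    return float(np.mean(vals))


def mean_average_precision(
    preds: Sequence[InstanceMask],
    truths: Sequence[InstanceMask],
    classes: Sequence[ClassLabel] | None = None,
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> APResult:
    """mAP over classes: mean of per-class APs; absent classes are undefined."""
    if classes is None:
        classes = sorted(
            {p.class_label for p in preds} | {t.class_label for t in truths}
        )
    result = APResult()
    for cls in classes:
        result.per_class[cls] = average_precision(
            [p for p in preds if p.class_label is cls],
            [t for t in truths if t.class_label is cls],
            iou_thresholds,
        )
    return result
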