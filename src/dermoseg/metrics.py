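"""Count-based evaluation: confusion counts, IoU, mean IoU, ROC.

Evaluation is deliberately separate from the differentiable losses: here
predictions are thresholded to hard masks and scored with integer pixel
counts, ``IoU = TP / (TP + FP + FN)``.  For a binary per-attribute model the
"mean IoU" averages the foreground and background class IoUs; a
foreground-only figure is also reported since several published baselines
quote the foreground Jaccard alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "iou_score",
    "mean_iou",
    "binarize",
    "roc_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion totals (tn kept for ROC rates)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class EvalReport:
    """Per-class IoU, their mean, and the ROC sweep of one evaluation."""

    per_class_iou: Mapping[str, float]
    mean_iou: float
    roc_points: Sequence[tuple[float, float, float]] = field(default_factory=list)
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "per_class_iou": dict(self.per_class_iou),
            "mean_iou": self.mean_iou,
            "auc": self.auc,
            "roc_points": [list(pt) for pt in self.roc_points],
        }


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two binary arrays of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def iou_score(counts: ConfusionCounts) -> float:
    """``TP / (FP + TP + FN)``; 1.0 for a class absent from both masks."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def mean_iou(per_class: Mapping[str, float]) -> float:
    """Unweighted arithmetic mean of per-class IoU values."""
    if not per_class:
        raise ValueError("mean_iou of an empty class map")
    vals = list(per_class.values())
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("IoU values must lie in [0, 1]")
    return float(np.mean(vals))


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard mask: 1 where ``p >= threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    p = np.asarray(p)
    return (p >= threshold).astype(np.uint8)


def roc_points(
    p: np.ndarray | Iterable[np.ndarray],
    y: np.ndarray | Iterable[np.ndarray],
) -> tuple[list[tuple[float, float, float]], float]:
    """Full ROC sweep over the distinct predicted values.

    Returns ``(points, auc)`` where each point is ``(fpr, tpr, threshold)``
    ordered by decreasing threshold, and the AUC is the trapezoid-rule area.
    Accepts either single arrays or iterables of per-image arrays, which are
    pooled pixel-wise.
    """
    if not isinstance(p, np.ndarray):
        p = np.concatenate([np.ravel(a) for a in p])
        y = np.concatenate([np.ravel(a) for a in y])
    scores = np.ravel(np.asarray(p, dtype=np.float64))
    labels = np.ravel(np.asarray(y)).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("probability and truth arrays must match in size")
    npos = int(labels.sum())
    if npos == 0 or npos == labels.size:
        raise ValueError("ROC undefined: truth must contain both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return [(float(f), float(t), float(th)) for f, t, th in zip(fpr, tpr, thr)], auc
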