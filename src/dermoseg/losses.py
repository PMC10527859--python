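"""Hybrid segmentation loss: focal Tversky + differentiable soft-IoU.

Dermoscopic attributes occupy a vanishing fraction of the pixels in a lesion
image, so a per-pixel cross-entropy gradient is dominated by the background
class.  The hybrid loss used here combines two overlap-based terms that are
insensitive to that imbalance:

* the **focal Tversky loss** ``(1 - TI)^(1/gamma)``, where the Tversky index
  ``TI`` generalises soft Dice with separate false-negative (``alpha``) and
  false-positive (``beta``) weights, and the focal exponent sharpens the
  penalty on low-overlap predictions;
* the **soft IoU loss** ``1 - I(X)/U(X)``, a differentiable surrogate of the
  Jaccard index built from the probability-weighted intersection
  ``I = sum(x*y)`` and union ``U = sum(x + y - x*y)``.

All functions are pure: they consume a probability map ``p`` (floats in
[0, 1]) and a binary ground-truth mask ``g`` of identical shape and return
plain floats / arrays, with no dependency on the training framework.  Sums
run over every pixel supplied, so passing a batch pools pixels globally;
``reduction="per_image"`` averages the per-image losses instead (leading
axis = image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TverskyParams",
    "LossBreakdown",
    "tversky_index",
    "focal_tversky_loss",
    "soft_iou_loss",
    "soft_iou_gradient",
    "hybrid_loss",
    "hybrid_loss_gradient",
]


@dataclass(frozen=True)
class TverskyParams:
    """Hyperparameters of the (focal) Tversky term.

    alpha weighs the soft false-negative mass ``sum((1-p)*g)``, beta the soft
    false-positive mass ``sum(p*(1-g))``; alpha > beta pushes the model to
    recall sparse foreground.  gamma in [1, 3] is the focal exponent, applied
    as ``(1 - TI)**(1/gamma)``; 4/3 is the value reported to work best for
    this task.  epsilon smooths the ratio on empty masks.
    """

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 4.0 / 3.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not (1.0 <= self.gamma <= 3.0):
            raise ValueError("gamma must lie in [1, 3]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class LossBreakdown:
    """Every intermediate of one hybrid-loss evaluation."""

    tversky_index: float
    focal_tversky: float
    soft_intersection: float
    soft_union: float
    iou_loss: float
    hybrid: float


def _validate_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs mask {g.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite probability values")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all((g == 0) | (g == 1)):
        raise ValueError("ground-truth mask must be binary {0, 1}")
    return p, g


def _per_image_mean(fn, p: np.ndarray, g: np.ndarray, *args):
    return float(np.mean([fn(pi, gi, *args) for pi, gi in zip(p, g)]))


def tversky_index(
    p: np.ndarray,
    g: np.ndarray,
    params: TverskyParams = TverskyParams(),
) -> float:
    """Soft Tversky overlap index.

    ``TI = (sum(p*g) + eps) / (sum(p*g) + alpha*sum((1-p)*g)
    + beta*sum(p*(1-g)) + eps)``; equals soft Dice at alpha = beta = 0.5 and
    soft Jaccard at alpha = beta = 1.
    """
    p, g = _validate_pair(p, g)
    tp = float(np.sum(p * g))
    fn = float(np.sum((1.0 - p) * g))
    fp = float(np.sum(p * (1.0 - g)))
    return (tp + params.epsilon) / (tp + params.alpha * fn + params.beta * fp + params.epsilon)


def focal_tversky_loss(
    p: np.ndarray,
    g: np.ndarray,
    params: TverskyParams = TverskyParams(),
    reduction: str = "global",
) -> float:
    """``(1 - TI)**(1/gamma)`` for the (single) foreground class.

    The per-attribute models are binary, so the class sum collapses to one
    term; a multi-class map can be handled by calling once per class channel
    and summing.
    """
    if reduction == "per_image":
        return _per_image_mean(focal_tversky_loss, *_validate_pair(p, g), params)
    ti = tversky_index(p, g, params)
    return float((1.0 - ti) ** (1.0 / params.gamma))


def soft_iou_loss(x: np.ndarray, y: np.ndarray, reduction: str = "global") -> float:
    """``1 - I(X)/U(X)`` with ``I = sum(x*y)``, ``U = sum(x + y - x*y)``.

    On binary ``x`` this reduces exactly to ``1 - TP/(TP+FP+FN)``.  When both
    inputs are identically zero the mask is perfectly predicted absent and
    the loss is 0.
    """
    if reduction == "per_image":
        return _per_image_mean(soft_iou_loss, *_validate_pair(x, y))
    x, y = _validate_pair(x, y)
    inter = float(np.sum(x * y))
    union = float(np.sum(x + y - x * y))
    if union == 0.0:
        return 0.0
    return 1.0 - inter / union


def soft_iou_gradient(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic per-pixel gradient of :func:`soft_iou_loss`.

    ``dL/dx_v = -1/U`` where ``y_v = 1`` and ``I/U**2`` where ``y_v = 0``
    (treating I and U as totals; both expressions follow from the quotient
    rule since ``dI/dx_v = y_v`` and ``dU/dx_v = 1 - y_v``).
    """
    x, y = _validate_pair(x, y)
    inter = float(np.sum(x * y))
    union = float(np.sum(x + y - x * y))
    if union == 0.0:
        raise ValueError("soft-IoU gradient undefined for two empty masks (U = 0)")
    grad = np.where(y == 1.0, -1.0 / union, inter / union**2)
    return grad.astype(np.float64)


def hybrid_loss(
    p: np.ndarray,
    g: np.ndarray,
    params: TverskyParams = TverskyParams(),
    reduction: str = "global",
) -> LossBreakdown:
    """Unweighted sum of the focal Tversky and soft-IoU losses."""
    p, g = _validate_pair(p, g)
    if reduction not in ("global", "per_image"):
        raise ValueError(f"unknown reduction {reduction!r}")
    ftl = focal_tversky_loss(p, g, params, reduction=reduction)
    iou = soft_iou_loss(p, g, reduction=reduction)
    # breakdown intermediates are always the batch-global quantities
    ti = tversky_index(p, g, params)
    inter = float(np.sum(p * g))
    union = float(np.sum(p + g - p * g))
    return LossBreakdown(
        tversky_index=ti,
        focal_tversky=ftl,
        soft_intersection=inter,
        soft_union=union,
        iou_loss=iou,
        hybrid=ftl + iou,
    )


def _tversky_gradient(p: np.ndarray, g: np.ndarray, params: TverskyParams) -> np.ndarray:
    # quotient rule on TI = (I + eps) / (D + eps) with
    # D = I + alpha*FN + beta*FP; dI/dp_v = g_v,
    # dD/dp_v = g_v - alpha*g_v + beta*(1 - g_v)
    tp = float(np.sum(p * g))
    fn = float(np.sum((1.0 - p) * g))
    fp = float(np.sum(p * (1.0 - g)))
    num = tp + params.epsilon
    den = tp + params.alpha * fn + params.beta * fp + params.epsilon
    d_num = g
    d_den = g - params.alpha * g + params.beta * (1.0 - g)
    return (d_num * den - num * d_den) / den**2


def hybrid_loss_gradient(
    p: np.ndarray,
    g: np.ndarray,
    params: TverskyParams = TverskyParams(),
) -> np.ndarray:
    """Per-pixel gradient of the batch-global hybrid loss w.r.t. ``p``.

    Used by the training loop; the soft-IoU part is the closed form of
    :func:`soft_iou_gradient`, the focal Tversky part chains the focal
    exponent through the Tversky quotient.  At a perfectly predicted batch
    (TI -> 1) the focal factor ``(1-TI)^(1/gamma - 1)`` diverges for
    gamma > 1; the epsilon smoothing keeps TI < 1 for any non-degenerate
    input and the factor is additionally capped for numerical safety.
    """
    p, g = _validate_pair(p, g)
    ti = tversky_index(p, g, params)
    one_minus = max(1.0 - ti, 1e-12)
    focal_factor = (1.0 / params.gamma) * one_minus ** (1.0 / params.gamma - 1.0)
    focal_factor = min(focal_factor, 1e6)
    grad_ftl = -focal_factor * _tversky_gradient(p, g, params)

    union = float(np.sum(p + g - p * g))
    if union == 0.0:
        grad_iou = np.zeros_like(p)
    else:
        grad_iou = soft_iou_gradient(p, g)
    return grad_ftl + grad_iou
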