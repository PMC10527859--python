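"""Unit and property tests for the hybrid loss components.

Every loss is checked against an independent per-pixel brute-force loop,
and the closed-form soft-IoU gradient against central finite differences.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermoseg.losses import (
    LossBreakdown,
    TverskyParams,
    focal_tversky_loss,
    hybrid_loss,
    hybrid_loss_gradient,
    soft_iou_gradient,
    soft_iou_loss,
    tversky_index,
)

EPS0 = TverskyParams(alpha=0.7, beta=0.3, gamma=4.0 / 3.0, epsilon=1e-12)


# ---------------------------------------------------------------------------
# independent scalar-loop oracles


def _loop_tversky(p, g, params):
    tp = fn = fp = 0.0
    for pv, gv in zip(np.ravel(p), np.ravel(g)):
        tp += pv * gv
        fn += (1 - pv) * gv
        fp += pv * (1 - gv)
    return (tp + params.epsilon) / (tp + params.alpha * fn + params.beta * fp + params.epsilon)


def _loop_soft_iou(x, y):
    inter = union = 0.0
    for xv, yv in zip(np.ravel(x), np.ravel(y)):
        inter += xv * yv
        union += xv + yv - xv * yv
    return 0.0 if union == 0 else 1.0 - inter / union


def _random_pair(rng, shape=(8, 8)):
    p = rng.random(shape)
    g = (rng.random(shape) < 0.3).astype(float)
    return p, g


# ---------------------------------------------------------------------------


def test_worked_example_hand_summation():
    """p=(1,.5,.5,0), g=(1,1,0,0), alpha=.7, beta=.3: TI = 1.5/2.0 = 0.75."""
    p = np.array([1.0, 0.5, 0.5, 0.0])
    g = np.array([1.0, 1.0, 0.0, 0.0])
    assert tversky_index(p, g, EPS0) == pytest.approx(0.75, abs=1e-9)
    assert focal_tversky_loss(p, g, EPS0) == pytest.approx(0.25**0.75, abs=1e-9)
    assert soft_iou_loss(p, g) == pytest.approx(0.4, abs=1e-12)
    bd = hybrid_loss(p, g, EPS0)
    assert bd.hybrid == pytest.approx(0.25**0.75 + 0.4, abs=1e-9)
    assert bd.soft_intersection == pytest.approx(1.5)
    assert bd.soft_union == pytest.approx(2.5)


def test_perfect_match_identities(rng):
    g = (rng.random((6, 6)) < 0.4).astype(float)
    g[0, 0] = 1.0  # ensure at least one positive
    assert tversky_index(g, g, TverskyParams(alpha=1.3, beta=0.1)) == pytest.approx(1.0)
    assert focal_tversky_loss(g, g) == pytest.approx(0.0, abs=1e-4)
    assert soft_iou_loss(g, g) == 0.0
    assert hybrid_loss(g, g).hybrid == pytest.approx(0.0, abs=1e-4)


def test_complement_prediction_is_maximal(rng):
    g = (rng.random((6, 6)) < 0.4).astype(float)
    g[0, 0] = 1.0
    p = 1.0 - g
    assert soft_iou_loss(p, g) == pytest.approx(1.0)
    assert focal_tversky_loss(p, g, EPS0) == pytest.approx(1.0, abs=1e-6)
    assert hybrid_loss(p, g, EPS0).hybrid == pytest.approx(2.0, abs=1e-6)


def test_focal_exponent_examples():
    # TI = 0 -> loss 1 for any gamma; exponent applied as 1/gamma
    for gamma in (1.0, 4.0 / 3.0, 2.0, 3.0):
        params = TverskyParams(gamma=gamma, epsilon=1e-12)
        p = np.array([1.0, 0.0])
        g = np.array([0.0, 1.0])
        assert focal_tversky_loss(p, g, params) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_losses_match_bruteforce_loops(seed):
    rng = np.random.default_rng(seed)
    p, g = _random_pair(rng)
    params = TverskyParams(alpha=rng.uniform(0, 2), beta=rng.uniform(0, 2), gamma=rng.uniform(1, 3))
    assert tversky_index(p, g, params) == pytest.approx(_loop_tversky(p, g, params), abs=1e-12)
    assert soft_iou_loss(p, g) == pytest.approx(_loop_soft_iou(p, g), abs=1e-12)
    bd = hybrid_loss(p, g, params)
    expected = (1 - _loop_tversky(p, g, params)) ** (1 / params.gamma) + _loop_soft_iou(p, g)
    assert bd.hybrid == pytest.approx(expected, abs=1e-12)


def test_soft_iou_gradient_closed_form():
    x = np.array([1.0, 0.5, 0.5, 0.0])
    y = np.array([1.0, 1.0, 0.0, 0.0])
    grad = soft_iou_gradient(x, y)
    np.testing.assert_allclose(grad, [-0.4, -0.4, 0.24, 0.24], atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_soft_iou_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(seed)
    x, y = _random_pair(rng)
    y[0, 0] = 1.0
    grad = soft_iou_gradient(x, y)
    h = 1e-6
    for idx in [(0, 0), (3, 4), (7, 7), (2, 1)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        num = (soft_iou_loss(xp, y) - soft_iou_loss(xm, y)) / (2 * h)
        assert grad[idx] == pytest.approx(num, rel=1e-5)


@pytest.mark.parametrize("seed", range(3))
def test_hybrid_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(seed)
    x, y = _random_pair(rng, shape=(6, 6))
    y[0, 0] = 1.0
    x = np.clip(x, 0.05, 0.95)
    params = TverskyParams()
    grad = hybrid_loss_gradient(x, y, params)
    h = 1e-6
    for idx in [(0, 0), (2, 3), (5, 5)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        num = (hybrid_loss(xp, y, params).hybrid - hybrid_loss(xm, y, params).hybrid) / (2 * h)
        assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_dice_limit():
    """alpha = beta = 0.5 reduces the Tversky index to soft Dice."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        p, g = _random_pair(rng)
        params = TverskyParams(alpha=0.5, beta=0.5, epsilon=1e-12)
        inter = np.sum(p * g)
        dice = inter / (inter + 0.5 * np.sum((1 - p) * g) + 0.5 * np.sum(p * (1 - g)))
        assert tversky_index(p, g, params) == pytest.approx(dice, abs=1e-12)


def test_binary_limit_equals_count_iou():
    """On {0,1} inputs the soft IoU loss is exactly 1 - TP/(TP+FP+FN)."""
    from dermoseg.metrics import confusion_counts, iou_score

    rng = np.random.default_rng(10)
    for _ in range(10):
        x = (rng.random((8, 8)) < 0.4).astype(float)
        y = (rng.random((8, 8)) < 0.4).astype(float)
        if not (x + y).any():
            continue
        assert soft_iou_loss(x, y) == pytest.approx(
            1.0 - iou_score(confusion_counts(x, y)), abs=1e-14
        )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0, 2), beta=st.floats(0, 2))
def test_permutation_invariance(seed, alpha, beta):
    rng = np.random.default_rng(seed)
    p, g = _random_pair(rng, shape=(25,))
    params = TverskyParams(alpha=alpha, beta=beta)
    perm = rng.permutation(p.size)
    assert hybrid_loss(p, g, params).hybrid == pytest.approx(
        hybrid_loss(p[perm], g[perm], params).hybrid, abs=1e-12
    )


def test_raising_positive_pixel_never_increases_hybrid(rng):
    for _ in range(10):
        p, g = _random_pair(rng)
        g[2, 2] = 1.0
        p[2, 2] = 0.4
        before = hybrid_loss(p, g).hybrid
        p2 = p.copy()
        p2[2, 2] = 0.7
        assert hybrid_loss(p2, g).hybrid <= before + 1e-12


def test_reduction_modes_differ_but_agree_on_uniform_batches(rng):
    p, g = _random_pair(rng, shape=(3, 5, 5))
    glob = hybrid_loss(p, g, reduction="global").hybrid
    per = hybrid_loss(p, g, reduction="per_image").hybrid
    assert np.isfinite(glob) and np.isfinite(per)
    # identical images => the two reductions coincide (up to the epsilon
    # smoothing, whose relative weight shrinks with the pooled pixel mass)
    p1 = np.stack([p[0]] * 3)
    g1 = np.stack([g[0]] * 3)
    assert hybrid_loss(p1, g1, reduction="global").hybrid == pytest.approx(
        hybrid_loss(p1, g1, reduction="per_image").hybrid, abs=1e-6
    )


def test_breakdown_internal_consistency(rng):
    p, g = _random_pair(rng)
    bd = hybrid_loss(p, g)
    assert isinstance(bd, LossBreakdown)
    assert bd.hybrid == pytest.approx(bd.focal_tversky + bd.iou_loss, abs=1e-14)
    assert bd.iou_loss == pytest.approx(1 - bd.soft_intersection / bd.soft_union, abs=1e-12)


def test_empty_masks_and_degenerate_inputs():
    z = np.zeros(4)
    assert soft_iou_loss(z, z) == 0.0
    with pytest.raises(ValueError):
        soft_iou_gradient(z, z)
    with pytest.raises(ValueError):
        tversky_index(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError):
        soft_iou_loss(np.array([np.nan, 0.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        tversky_index(np.array([1.5]), np.array([1.0]))
    with pytest.raises(ValueError):
        tversky_index(np.array([0.5]), np.array([0.5]))  # non-binary mask


@pytest.mark.parametrize(
    "kwargs",
    [
        {"alpha": -0.1},
        {"beta": -1.0},
        {"gamma": 0.5},
        {"gamma": 3.5},
        {"epsilon": 0.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        TverskyParams(**kwargs)
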