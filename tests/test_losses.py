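"""Loss functions against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from lirads_auto.losses import (
    LossConfig,
    LovaszSchedule,
    PredictionBatch,
    adaptive_multitask_loss,
    focal_term,
    hybrid_loss,
    lovasz_softmax,
    scheduled_loss,
    soft_dice_term,
    segmentation_loss_and_grad,
)


# ---------------------------------------------------------------------------
# independent oracles: literal per-pixel loops, no shared code with the module
# ---------------------------------------------------------------------------

def oracle_dice(y, p, eps):
    out = []
    for c in range(y.shape[1]):
        num = den = 0.0
        for n in range(y.shape[0]):
            num += 2 * y[n, c] * p[n, c]
            den += y[n, c] ** 2 + p[n, c] ** 2
        out.append((num + eps) / (den + eps))
    return np.array(out)


def oracle_focal(y, p, alpha, gamma):
    total = 0.0
    for n in range(y.shape[0]):
        for c in range(y.shape[1]):
            a = alpha if (y.shape[1] != 2 or c == 1) else 1 - alpha
            pc = min(max(p[n, c], 1e-7), 1 - 1e-7)
            total += a * (1 - pc) ** gamma * y[n, c] * np.log(pc)
    return -total / y.shape[0]


def oracle_lovasz_binary_hard(y_fg, pred_fg):
    """Mean over present classes of 1 - IoU for hard predictions."""
    vals = []
    for truth, pred in (((1 - y_fg), (1 - pred_fg)), (y_fg, pred_fg)):
        if truth.sum() == 0 and pred.sum() == 0:
            continue
        inter = float((truth * pred).sum())
        union = float(((truth + pred) > 0).sum())
        vals.append(1.0 - inter / union)
    return float(np.mean(vals)) if vals else 0.0


def oracle_lovasz_extension(y_c, m):
    """Direct Lovasz-extension evaluation from the Jaccard set function.

    Sort errors descending; the extension value telescopes over prefix error
    sets S_i: sum_i m_(i) * (Delta(S_i) - Delta(S_{i-1})) where
    Delta(S) = 1 - |G \\ S| / |G u S| for ground-truth set G.
    """
    order = np.argsort(-m, kind="stable")
    G = set(np.flatnonzero(y_c))
    total, prev = 0.0, 0.0

    def delta(S):
        if not G and not S:
            return 0.0
        inter = len(G - S)
        union = len(G | S)
        return 1.0 - inter / union

    S = set()
    for i in order:
        S.add(int(i))
        d = delta(S)
        total += m[i] * (d - prev)
        prev = d
    return total


def _random_batch(rng, n, hard=False):
    y = (rng.random(n) < 0.5).astype(float)
    p = np.round(rng.random(n)) if hard else rng.random(n)
    return PredictionBatch.from_binary(y, p)


def test_soft_dice_matches_loop_oracle_and_examples():
    rng = np.random.default_rng(0)
    for _ in range(20):
        b = _random_batch(rng, int(rng.integers(2, 17)))
        np.testing.assert_allclose(
            soft_dice_term(b, 0.5), oracle_dice(b.targets, b.probs, 0.5), atol=1e-12
        )
    # perfect one-hot prediction -> dice 1 per class as eps -> 0
    y = np.array([1.0, 0, 1, 1])
    b = PredictionBatch.from_binary(y, y)
    np.testing.assert_allclose(soft_dice_term(b, 1e-12), [1.0, 1.0], atol=1e-9)
    # 50 px truth, 50 px predicted, 25 overlap, hard probabilities -> 0.5
    y = np.zeros(100)
    p = np.zeros(100)
    y[:50] = 1
    p[25:75] = 1
    b = PredictionBatch.from_binary(y, p)
    assert soft_dice_term(b, 1e-12)[1] == pytest.approx(2 * 25 / 100, abs=1e-9)


def test_focal_term_examples_and_monotone_damping():
    # gamma=0 -> class-weighted cross-entropy on a 3-pixel toy (hand arithmetic;
    # the weight is alpha on the foreground class and 1-alpha on background)
    y = np.array([1.0, 1, 0])
    p = np.array([0.8, 0.6, 0.3])
    b = PredictionBatch.from_binary(y, p)
    expected = -(0.25 * (np.log(0.8) + np.log(0.6)) + 0.75 * np.log(0.7)) / 3
    assert focal_term(b, alpha=0.25, gamma=0.0) == pytest.approx(expected, abs=1e-12)
    # alpha=1 puts all weight on the foreground class
    expected_fg = -(np.log(0.8) + np.log(0.6)) / 3
    assert focal_term(b, alpha=1.0, gamma=0.0) == pytest.approx(expected_fg, abs=1e-12)
    # matches the loop oracle on random batches
    rng = np.random.default_rng(1)
    for _ in range(10):
        b = _random_batch(rng, 8)
        assert focal_term(b, 0.25, 2.0) == pytest.approx(
            oracle_focal(b.targets, b.probs, 0.25, 2.0), abs=1e-12
        )
    # true-class probability -> 1 drives the term to 0
    b = PredictionBatch.from_binary(np.ones(4), np.full(4, 1 - 1e-9))
    assert focal_term(b, 0.25, 2.0) < 1e-12
    # increasing gamma never increases the term
    b = _random_batch(rng, 12)
    vals = [focal_term(b, 0.25, g) for g in (0.0, 0.5, 1.0, 2.0, 5.0)]
    assert all(a >= b_ - 1e-12 for a, b_ in zip(vals, vals[1:]))


def test_hybrid_loss_oracle_and_monotonicity():
    """Hybrid loss equals (1 - mean oracle dice) + oracle focal to 1e-10."""
    rng = np.random.default_rng(2)
    cfg = LossConfig(alpha=0.25, gamma=2.0, epsilon=1.0)
    for _ in range(30):
        b = _random_batch(rng, int(rng.integers(1, 17)))
        expected = (1 - oracle_dice(b.targets, b.probs, cfg.epsilon).mean()) + oracle_focal(
            b.targets, b.probs, cfg.alpha, cfg.gamma
        )
        assert hybrid_loss(b, cfg) == pytest.approx(expected, abs=1e-10)
    # single pixel, p_true = 0.5, alpha=.25 gamma=2 vs literal evaluation
    b = PredictionBatch.from_binary(np.array([1.0]), np.array([0.5]))
    expected = (1 - oracle_dice(b.targets, b.probs, 1.0).mean()) + oracle_focal(
        b.targets, b.probs, 0.25, 2.0
    )
    assert hybrid_loss(b, cfg) == pytest.approx(expected, abs=1e-12)
    # near-perfect prediction -> loss ~ 0 with tiny epsilon
    y = np.array([1.0, 0, 0, 1])
    b = PredictionBatch.from_binary(y, np.abs(y - 1e-9))
    assert hybrid_loss(b, LossConfig(epsilon=1e-9)) < 1e-6
    # decreasing in the true-class probability
    one = np.array([1.0])
    l_good = hybrid_loss(PredictionBatch.from_binary(one, np.array([0.9])), cfg)
    l_bad = hybrid_loss(PredictionBatch.from_binary(one, np.array([0.6])), cfg)
    assert l_good < l_bad


def test_hybrid_loss_nonnegative_property():
    rng = np.random.default_rng(3)
    cfg = LossConfig()
    for _ in range(50):
        b = _random_batch(rng, int(rng.integers(1, 33)))
        assert hybrid_loss(b, cfg) >= 0.0


def test_hybrid_loss_shape_mismatch_errors():
    with pytest.raises(ValueError):
        PredictionBatch(targets=np.ones((3, 2)), probs=np.ones((4, 2)) / 2)


def test_lovasz_exhaustive_equals_one_minus_iou():
    """All 2^8 hard predictions on an 8-pixel binary toy equal mean 1 - IoU."""
    y = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=float)
    for bits in itertools.product((0.0, 1.0), repeat=8):
        p = np.array(bits)
        b = PredictionBatch.from_binary(y, p)
        assert lovasz_softmax(b) == pytest.approx(oracle_lovasz_binary_hard(y, p), abs=1e-12)


def test_lovasz_matches_direct_extension_on_soft_predictions():
    """Sorted-gradient algorithm vs direct telescoped Lovasz-extension
    evaluation on random soft <=8-pixel instances, per class."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = int(rng.integers(2, 9))
        y = (rng.random(n) < 0.5).astype(float)
        p = rng.random(n)
        b = PredictionBatch.from_binary(y, p)
        pred_class = b.probs.argmax(axis=1)
        expected_terms = []
        for c in (0, 1):
            y_c = b.targets[:, c]
            if not (y_c.any() or (pred_class == c).any()):
                continue
            m = np.abs(y_c - b.probs[:, c])
            expected_terms.append(oracle_lovasz_extension(y_c, m))
        expected = float(np.mean(expected_terms)) if expected_terms else 0.0
        assert lovasz_softmax(b) == pytest.approx(expected, abs=1e-10)
    # perfect hard prediction -> 0
    y = np.array([1.0, 0, 1, 0])
    assert lovasz_softmax(PredictionBatch.from_binary(y, y)) == pytest.approx(0.0, abs=1e-12)


def test_scheduled_loss_latches():
    cfg = LossConfig(lovasz_trigger=0.3)
    rng = np.random.default_rng(5)
    b = _random_batch(rng, 10)
    base = hybrid_loss(b, cfg)
    lov = lovasz_softmax(b)
    sched = LovaszSchedule()
    assert scheduled_loss(b, cfg, current_train_loss=0.9, schedule=sched) == pytest.approx(base)
    assert scheduled_loss(b, cfg, current_train_loss=0.1, schedule=sched) == pytest.approx(base + lov)
    # latched: stays on even when the running loss rises again
    assert scheduled_loss(b, cfg, current_train_loss=0.9, schedule=sched) == pytest.approx(base + lov)
    # trigger +inf -> active from step 0
    cfg_inf = LossConfig(lovasz_trigger=float("inf"))
    assert scheduled_loss(b, cfg_inf, current_train_loss=1e9) == pytest.approx(base + lov)


def test_adaptive_multitask_loss_exactness():
    assert adaptive_multitask_loss(0.3, 0.2, 0.5, x=0) == pytest.approx(0.3)
    assert adaptive_multitask_loss(0.3, 0.2, 0.5, x=1) == pytest.approx(0.7)
    assert adaptive_multitask_loss(0.0, 0.0, 0.0, x=0) == 0.0
    assert adaptive_multitask_loss(0.0, 0.0, 0.0, x=1) == 0.0
    with pytest.raises(ValueError):
        adaptive_multitask_loss(0.1, 0.1, 0.1, x=0.5)


def test_adaptive_loss_batch_mixing_property():
    """A mixed batch's total equals the per-sample loop over the routed sums."""
    rng = np.random.default_rng(6)
    losses = rng.random((20, 3))
    xs = rng.integers(0, 2, size=20)
    total = sum(adaptive_multitask_loss(*losses[i], x=int(xs[i])) for i in range(20))
    oracle = 0.0
    for i in range(20):
        if xs[i] == 0:
            oracle += losses[i, 0]
        else:
            oracle += losses[i, 1] + losses[i, 2]
    assert total == pytest.approx(oracle, abs=1e-12)


def test_segmentation_loss_gradient_matches_finite_differences():
    """The trainer's analytic d(loss)/dp agrees with central differences,
    including the latched Lovasz term."""
    rng = np.random.default_rng(7)
    y = (rng.random(12) < 0.4).astype(float)
    p = rng.uniform(0.05, 0.95, 12)
    cfg = LossConfig(lovasz_trigger=float("inf"))  # all three terms active
    sched = LovaszSchedule()
    loss, grad = segmentation_loss_and_grad(y, p, cfg, sched, current_train_loss=0.0)
    eps = 1e-7
    for i in range(12):
        pp, pm = p.copy(), p.copy()
        pp[i] += eps
        pm[i] -= eps
        lp, _ = segmentation_loss_and_grad(y, pp, cfg, LovaszSchedule(True), 0.0)
        lm, _ = segmentation_loss_and_grad(y, pm, cfg, LovaszSchedule(True), 0.0)
        assert grad[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
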