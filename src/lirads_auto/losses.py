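"""Segmentation and multi-task training losses.

Three pieces:

* a hybrid segmentation loss combining a per-class soft dice term (aggregated
  over the batch, smoothed by ``epsilon``) with a focal cross-entropy term
  ``-(1/N) sum_c sum_n alpha_c (1 - p)^gamma y log p``;
* a Lovasz–Softmax term — the convex Lovasz extension of the Jaccard (IoU)
  loss — that a schedule adds once the training loss first falls below a
  trigger threshold (latched: once on, it stays on);
* a phase-adaptive multi-task loss ``L_all = (1 - x) L_aphe + x L_washout +
  x L_capsule`` that routes gradients by contrast phase: arterial samples
  (x = 0) train only the APHE head, portal-venous/delayed samples (x = 1)
  train only the washout and capsule heads.

Targets are one-hot {0, 1}; the hybrid loss is written ``(1 - dice) + focal``
so it is nonnegative and zero (up to ``epsilon``) at a perfect prediction,
with the same gradients as the signed form ``-(dice - focal)``.

All losses come with analytic gradients with respect to the predicted
probabilities so the numpy network layers can train on them; the gradient
functions are private helpers used by the trainers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_P_CLIP = 1e-7


@dataclass
class LossConfig:
    """Hyper-parameters of the segmentation loss.

    alpha: focal class-weighting factor in [0, 1] (foreground weight alpha,
        background 1 - alpha).  Default 0.25, the originating focal-loss
        convention.
    gamma: focal focusing exponent, >= 0.  Default 2.
    epsilon: dice smoothing constant added to numerator and denominator.
    lovasz_trigger: training-loss threshold below which the Lovasz term is
        added (latched).  ``inf`` activates it from step 0, ``-inf`` never.
    n_classes: number of classes (2: lesion / non-lesion).
    """

    alpha: float = 0.25
    gamma: float = 2.0
    epsilon: float = 1.0
    lovasz_trigger: float = 0.3
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class PredictionBatch:
    """Per-pixel targets and predicted class probabilities.

    ``targets`` and ``probs`` are (N, C) arrays; targets one-hot, per-pixel
    probabilities summing to 1.
    """

    targets: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.targets.shape != self.probs.shape:
            raise ValueError(
                f"targets shape {self.targets.shape} != probs shape {self.probs.shape}"
            )
        if self.targets.ndim != 2:
            raise ValueError("expected (n_pixels, n_classes) arrays")
        if np.any((self.probs < -1e-9) | (self.probs > 1 + 1e-9)):
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("per-pixel class probabilities must sum to 1")
        onehot = np.isin(self.targets, (0.0, 1.0)).all() and np.allclose(
            self.targets.sum(axis=1), 1.0
        )
        if not onehot:
            raise ValueError("targets must be one-hot")

    @property
    def n_pixels(self) -> int:
        return self.targets.shape[0]

    @classmethod
    def from_binary(cls, y_fg: np.ndarray, p_fg: np.ndarray) -> "PredictionBatch":
        """Build a two-class batch from foreground labels and probabilities."""
        y = np.asarray(y_fg, dtype=float).ravel()
        p = np.asarray(p_fg, dtype=float).ravel()
        return cls(
            targets=np.stack([1 - y, y], axis=1),
            probs=np.stack([1 - p, p], axis=1),
        )


def soft_dice_term(batch: PredictionBatch, epsilon: float = 1.0) -> np.ndarray:
    """Per-class soft dice score, aggregated over the batch.

    ``(2 sum(y p) + eps) / (sum(y^2) + sum(p^2) + eps)`` per class; 1 for a
    perfect one-hot prediction as eps -> 0, and symmetric under swapping the
    roles of targets and predictions.
    """
    y, p = batch.targets, batch.probs
    num = 2.0 * (y * p).sum(axis=0) + epsilon
    den = (y * y).sum(axis=0) + (p * p).sum(axis=0) + epsilon
    return num / den


def focal_term(batch: PredictionBatch, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Focal cross-entropy ``-(1/N) sum alpha_c (1-p)^gamma y log p``.

    The class weight is ``alpha`` for the last (foreground) class and
    ``1 - alpha`` for the first (background) class; with more than two
    classes every class uses ``alpha``.  Reduces to weighted cross-entropy
    at gamma = 0 and vanishes as the true-class probability approaches 1.
    """
    y = batch.targets
    p = np.clip(batch.probs, _P_CLIP, 1.0 - _P_CLIP)
    n, c = y.shape
    alphas = np.full(c, alpha)
    if c == 2:
        alphas[0] = 1.0 - alpha
    term = alphas[None, :] * (1.0 - p) ** gamma * y * np.log(p)
    return float(-term.sum() / n)


def hybrid_loss(batch: PredictionBatch, config: LossConfig) -> float:
    """Hybrid segmentation loss ``(1 - mean soft dice) + focal``.

    Nonnegative, minimized (to within ``epsilon`` smoothing) at a perfect
    prediction, and decreasing in the predicted probability of the true
    class.
    """
    dice = soft_dice_term(batch, config.epsilon).mean()
    return float(1.0 - dice) + focal_term(batch, config.alpha, config.gamma)


def _lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovasz extension of the Jaccard loss w.r.t. sorted errors."""
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    out = jaccard.copy()
    out[1:] = jaccard[1:] - jaccard[:-1]
    return out


def lovasz_softmax(batch: PredictionBatch) -> float:
    """Lovasz–Softmax loss: mean over present classes of the Lovasz-extended
    Jaccard loss of the error vector ``m(c) = |y_c - p_c|``.

    For hard (0/1) predictions it equals ``1 - IoU`` exactly, per class.  A
    class absent from both the target and the (argmax) prediction is skipped.
    """
    y, p = batch.targets, batch.probs
    pred_class = p.argmax(axis=1)
    losses = []
    for c in range(y.shape[1]):
        y_c = y[:, c]
        present = y_c.any() or (pred_class == c).any()
        if not present:
            continue
        m = np.abs(y_c - p[:, c])
        order = np.argsort(-m, kind="stable")
        losses.append(float(m[order] @ _lovasz_grad(y_c[order])))
    return float(np.mean(losses)) if losses else 0.0


@dataclass
class LovaszSchedule:
    """Latched switch adding the Lovasz term once training loss dips below
    ``lovasz_trigger``."""

    active: bool = False

    def update(self, current_train_loss: float, trigger: float) -> bool:
        if current_train_loss < trigger:
            self.active = True
        return self.active


def scheduled_loss(
    batch: PredictionBatch,
    config: LossConfig,
    current_train_loss: float,
    schedule: LovaszSchedule | None = None,
) -> float:
    """Hybrid loss, plus the Lovasz term once training has progressed.

    The Lovasz term joins the loss when ``current_train_loss`` first falls
    below ``config.lovasz_trigger`` and stays on afterwards ("add one more
    loss for fine-tuning").  Pass a persistent :class:`LovaszSchedule` to get
    the latch across calls; without one the decision is memoryless.
    """
    schedule = schedule if schedule is not None else LovaszSchedule()
    base = hybrid_loss(batch, config)
    if schedule.update(current_train_loss, config.lovasz_trigger):
        return base + lovasz_softmax(batch)
    return base


def adaptive_multitask_loss(
    l_aphe: float, l_washout: float, l_capsule: float, x: int
) -> float:
    """Phase-adaptive multi-task loss ``(1-x) L_aphe + x L_washout + x L_capsule``.

    ``x`` is the phase indicator: 0 for an arterial sample (only the APHE
    head contributes), 1 for a portal-venous/delayed sample (only the washout
    and capsule heads contribute).
    """
    if x not in (0, 1):
        raise ValueError(f"phase indicator x must be 0 or 1, got {x!r}")
    return (1 - x) * float(l_aphe) + x * (float(l_washout) + float(l_capsule))


# ---------------------------------------------------------------------------
# Analytic gradients used by the trainers (binary foreground formulation).
# ---------------------------------------------------------------------------


def _dice_and_grad(y_fg: np.ndarray, p_fg: np.ndarray, epsilon: float):
    """(1 - mean two-class soft dice, d/dp_fg) for flat binary arrays."""
    y = y_fg.ravel()
    p = p_fg.ravel()
    grads = np.zeros_like(p)
    dice_sum = 0.0
    for y_c, p_c, sign in ((1 - y, 1 - p, -1.0), (y, p, 1.0)):
        num = 2.0 * (y_c * p_c).sum() + epsilon
        den = (y_c * y_c).sum() + (p_c * p_c).sum() + epsilon
        dice_sum += num / den
        d_dice = (2.0 * y_c * den - num * 2.0 * p_c) / den**2
        grads += sign * d_dice
    loss = 1.0 - dice_sum / 2.0
    return loss, -grads / 2.0


def _focal_and_grad(y_fg: np.ndarray, p_fg: np.ndarray, alpha: float, gamma: float):
    """(focal loss, d/dp_fg) for flat binary arrays."""
    y = y_fg.ravel()
    p = np.clip(p_fg.ravel(), _P_CLIP, 1.0 - _P_CLIP)
    n = p.size
    loss = 0.0
    grad = np.zeros_like(p)
    for y_c, p_c, a_c, sign in ((1 - y, 1 - p, 1 - alpha, -1.0), (y, p, alpha, 1.0)):
        mod = (1.0 - p_c) ** gamma
        loss -= (a_c * mod * y_c * np.log(p_c)).sum() / n
        if gamma == 0:
            d = a_c * y_c / p_c
        else:
            d = a_c * y_c * (
                -gamma * (1.0 - p_c) ** (gamma - 1.0) * np.log(p_c) + mod / p_c
            )
        grad += sign * (-d / n)
    return float(loss), grad


def _lovasz_and_grad(y_fg: np.ndarray, p_fg: np.ndarray):
    """(lovasz-softmax loss, d/dp_fg) for flat binary arrays.

    The sorting permutation is treated as locally constant, the standard
    (almost-everywhere exact) subgradient.
    """
    y = y_fg.ravel()
    p = p_fg.ravel()
    pred_fg = p >= 0.5
    loss = 0.0
    grad = np.zeros_like(p)
    terms = 0
    for y_c, p_c, pred_c, sign in (
        (1 - y, 1 - p, ~pred_fg, -1.0),
        (y, p, pred_fg, 1.0),
    ):
        if not (y_c.any() or pred_c.any()):
            continue
        m = np.abs(y_c - p_c)
        order = np.argsort(-m, kind="stable")
        g = _lovasz_grad(y_c[order])
        loss += float(m[order] @ g)
        dm = np.zeros_like(p)
        dm[order] = g
        grad += sign * dm * np.sign(p_c - y_c)
        terms += 1
    if terms:
        loss /= terms
        grad /= terms
    return loss, grad


def segmentation_loss_and_grad(
    y_fg: np.ndarray,
    p_fg: np.ndarray,
    config: LossConfig,
    schedule: LovaszSchedule,
    current_train_loss: float,
):
    """Scheduled segmentation loss and its gradient w.r.t. p_fg (same shape)."""
    shape = np.asarray(p_fg).shape
    d_loss, d_grad = _dice_and_grad(np.asarray(y_fg, float), np.asarray(p_fg, float), config.epsilon)
    f_loss, f_grad = _focal_and_grad(np.asarray(y_fg, float), np.asarray(p_fg, float), config.alpha, config.gamma)
    loss = d_loss + f_loss
    grad = d_grad + f_grad
    if schedule.update(current_train_loss, config.lovasz_trigger):
        l_loss, l_grad = _lovasz_and_grad(np.asarray(y_fg, float), np.asarray(p_fg, float))
        loss += l_loss
        grad += l_grad
    return float(loss), grad.reshape(shape)


def bce_and_grad(y: float, p: float):
    """Binary cross-entropy of a single sigmoid output, with d/dp."""
    pc = float(np.clip(p, _P_CLIP, 1.0 - _P_CLIP))
    loss = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    grad = -(y / pc) + (1.0 - y) / (1.0 - pc)
    return float(loss), float(grad)
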