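"""Supervised and semi-supervised loss functions.

Supervised: weighted cross-entropy (thin layers up-weighted), soft Dice, and
their 1:1 combination.  Semi-supervised: the cross-pseudo-supervision (CPS)
objective — a labeled term summing both models' cross-entropies against the
ground truth, plus an unlabeled term in which each model's hard argmax
prediction serves as the other's pseudo ground truth —

    L_labeled(X, Y)  = CE(s1(X), Y) + CE(s2(X), Y)
    L_unlabeled(X)   = CE(s1(X), argmax s2(X)) + CE(s2(X), argmax s1(X))
    L_CPS            = L_labeled + lambda * L_unlabeled      (lambda = 1)

— and the Mean Teacher pieces: an exponential-moving-average weight update and
a softmax mean-squared-error consistency loss.  Pseudo-labels and teacher
outputs are constants: no gradient flows through their producers.

Public functions accept channels-last score arrays ((H, W, C) or (N, H, W, C))
with integer target masks; the ``*_grad`` variants additionally return the
gradient w.r.t. the scores for the training loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, LabelError, ValidationError
from .preprocess import ClassMask, as_labels
from .segmenters import ScoreMap, softmax

ArrayLike = Union[np.ndarray, ScoreMap]


def _scores(s: ArrayLike) -> np.ndarray:
    if isinstance(s, ScoreMap):
        return s.scores
    return np.asarray(s)


def _flatten(scores: np.ndarray, target: Optional[np.ndarray] = None):
    s = np.asarray(scores, dtype=np.float64)
    c = s.shape[-1]
    s2 = s.reshape(-1, c)
    if target is None:
        return s2, None, s.shape
    t = as_labels(target).reshape(-1)
    if t.shape[0] != s2.shape[0]:
        raise ValidationError("score and target spatial shapes differ")
    return s2, t.astype(np.int64), s.shape


# --------------------------------------------------------------------------
# cross entropy


def weighted_cross_entropy_grad(
    scores: ArrayLike,
    target: Union[ClassMask, np.ndarray],
    weights: Optional[Sequence[float]] = None,
) -> tuple[float, np.ndarray]:
    """Weighted CE and its gradient w.r.t. the scores.

    Mean over pixels of ``w[y] * (-log softmax[y])``, normalized by the mean
    pixel weight so that unit weights reduce to plain cross-entropy.
    """
    s2, t, shape = _flatten(_scores(scores), target)
    c = s2.shape[1]
    if t.min(initial=0) < 0 or t.max(initial=0) >= c:
        raise LabelError(
            f"target contains class ids outside 0..{c - 1} "
            "(post-processed classes cannot be CE targets)"
        )
    if weights is None:
        w = np.ones(c)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (c,):
            raise ValidationError(f"need one weight per class ({c})")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValidationError("class weights must be positive and finite")
    p = softmax(s2, axis=-1)
    n = s2.shape[0]
    wy = w[t]
    logp = np.log(np.clip(p[np.arange(n), t], 1e-300, None))
    denom = wy.sum()
    loss = float(-(wy * logp).sum() / denom)
    grad = p
    grad[np.arange(n), t] -= 1.0
    grad *= wy[:, None] / denom
    return loss, grad.reshape(shape)


def weighted_cross_entropy(scores, target, weights=None) -> float:
    loss, _ = weighted_cross_entropy_grad(scores, target, weights)
    return loss


def cross_entropy(scores, target) -> float:
    return weighted_cross_entropy(scores, target, None)


def compute_class_weights(
    masks: Sequence[Union[ClassMask, np.ndarray]],
    n_classes: int,
    clip: tuple[float, float] = (0.5, 20.0),
) -> np.ndarray:
    """Inverse-mean-thickness class weights from labeled training masks.

    Thickness of a class in one mask is its pixel count divided by the image
    width (mean rows per column).  Weights are 1/thickness, clipped, then
    renormalized to mean 1 so the CE scale stays comparable to unweighted CE.
    """
    if not masks:
        raise ValidationError("need at least one mask to derive class weights")
    thickness = np.zeros(n_classes)
    for m in masks:
        labels = as_labels(m)
        width = labels.shape[1]
        counts = np.bincount(labels.reshape(-1), minlength=n_classes)[:n_classes]
        thickness += counts / width
    thickness /= len(masks)
    with np.errstate(divide="ignore"):
        w = np.where(thickness > 0, 1.0 / np.clip(thickness, 1e-12, None), np.inf)
    w = np.clip(w, clip[0], clip[1])
    return w / w.mean()


# --------------------------------------------------------------------------
# Dice

DICE_EPS = 1e-6


def dice_loss_grad(
    scores: ArrayLike, target: Union[ClassMask, np.ndarray]
) -> tuple[float, np.ndarray]:
    """Soft Dice loss: 1 - mean over classes of (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps).

    A class absent from both prediction and target contributes Dice 1 through
    the epsilon, leaving the loss unaffected.
    """
    s2, t, shape = _flatten(_scores(scores), target)
    c = s2.shape[1]
    if t.max(initial=0) >= c:
        raise LabelError(f"target contains class ids outside 0..{c - 1}")
    p = softmax(s2, axis=-1)
    onehot = np.zeros_like(p)
    onehot[np.arange(p.shape[0]), t] = 1.0
    inter = (p * onehot).sum(axis=0)
    num = 2.0 * inter + DICE_EPS
    den = p.sum(axis=0) + onehot.sum(axis=0) + DICE_EPS
    loss = float(1.0 - (num / den).mean())
    # d(loss)/dp_c(x) = -(1/C) * (2*t_c(x)*den_c - num_c) / den_c^2
    dp = -(2.0 * onehot * den[None, :] - num[None, :]) / (c * den[None, :] ** 2)
    grad = p * (dp - (dp * p).sum(axis=1, keepdims=True))  # through softmax
    return loss, grad.reshape(shape)


def dice_loss(scores, target) -> float:
    loss, _ = dice_loss_grad(scores, target)
    return loss


def ce_dice_loss_grad(scores, target, weights=None) -> tuple[float, np.ndarray]:
    """CrossEntropy + Dice at fixed 1:1 weight."""
    l1, g1 = weighted_cross_entropy_grad(scores, target, weights)
    l2, g2 = dice_loss_grad(scores, target)
    return l1 + l2, g1 + g2


def ce_dice_loss(scores, target, weights=None) -> float:
    loss, _ = ce_dice_loss_grad(scores, target, weights)
    return loss


# --------------------------------------------------------------------------
# cross pseudo supervision


@dataclass
class LossBreakdown:
    """CPS loss components (nats per pixel): total = labeled + lambda*unlabeled."""

    labeled: float
    unlabeled: float
    total: float
    lambda_u: float = 1.0


def _hard_argmax(scores: np.ndarray) -> np.ndarray:
    """Pseudo-label: hard argmax, constant w.r.t. its producer."""
    return np.argmax(scores, axis=-1)


def cps_labeled_loss(s1: ArrayLike, s2: ArrayLike, y) -> float:
    """Labeled CPS term: CE(s1, y) + CE(s2, y) (plain, unweighted CE)."""
    return cross_entropy(s1, y) + cross_entropy(s2, y)


def cps_unlabeled_loss(s1: ArrayLike, s2: ArrayLike) -> float:
    """Unlabeled CPS term: each model is scored against the other's hard
    argmax pseudo-mask; no gradient flows through the argmax producer."""
    a1, a2 = _scores(s1), _scores(s2)
    return cross_entropy(a1, _hard_argmax(a2)) + cross_entropy(a2, _hard_argmax(a1))


def cps_unlabeled_loss_grads(
    s1: ArrayLike, s2: ArrayLike
) -> tuple[float, np.ndarray, np.ndarray]:
    """Unlabeled CPS term with per-model gradients (pseudo-labels constant)."""
    a1, a2 = _scores(s1), _scores(s2)
    l1, g1 = weighted_cross_entropy_grad(a1, _hard_argmax(a2))
    l2, g2 = weighted_cross_entropy_grad(a2, _hard_argmax(a1))
    return l1 + l2, g1, g2


def cps_total_loss(
    s1: ArrayLike,
    s2: ArrayLike,
    y=None,
    lambda_u: float = 1.0,
) -> LossBreakdown:
    """Full CPS objective; the labeled term is 0 for unlabeled batches."""
    labeled = cps_labeled_loss(s1, s2, y) if y is not None else 0.0
    unlabeled = cps_unlabeled_loss(s1, s2)
    return LossBreakdown(
        labeled=labeled,
        unlabeled=unlabeled,
        total=labeled + lambda_u * unlabeled,
        lambda_u=lambda_u,
    )


# --------------------------------------------------------------------------
# Mean Teacher


def ema_update(student_weights, teacher_weights, decay: float):
    """teacher <- decay * teacher + (1 - decay) * student, elementwise.

    Accepts scalars, arrays, or (nested) lists/tuples of them; returns the
    updated teacher structure.
    """
    if not 0.0 <= decay <= 1.0:
        raise ConfigError("EMA decay must lie in [0, 1]")
    return _ema_rec(student_weights, teacher_weights, decay)


def _ema_rec(s, t, decay):
    if isinstance(t, (list, tuple)):
        if not isinstance(s, (list, tuple)) or len(s) != len(t):
            raise ConfigError("student/teacher weight structures differ")
        out = [_ema_rec(si, ti, decay) for si, ti in zip(s, t)]
        return type(t)(out) if isinstance(t, tuple) else out
    ts = np.asarray(t)
    ss = np.asarray(s)
    if ts.shape != ss.shape:
        raise ConfigError(
            f"student/teacher weight shapes differ: {ss.shape} vs {ts.shape}"
        )
    out = decay * ts + (1.0 - decay) * ss
    return out if ts.ndim else float(out)


def mt_consistency_loss(student_scores: ArrayLike, teacher_scores: ArrayLike) -> float:
    """Mean squared difference of the softmax probability maps."""
    ps = softmax(_scores(student_scores), axis=-1)
    pt = softmax(_scores(teacher_scores), axis=-1)
    if ps.shape != pt.shape:
        raise ValidationError("student/teacher score shapes differ")
    return float(np.mean((ps - pt) ** 2))


def mt_consistency_loss_grad(
    student_scores: ArrayLike, teacher_scores: ArrayLike
) -> tuple[float, np.ndarray]:
    """Consistency loss and its gradient w.r.t. the student scores; the
    teacher's output is a constant target."""
    s = _scores(student_scores)
    ps = softmax(s, axis=-1)
    pt = softmax(_scores(teacher_scores), axis=-1)
    if ps.shape != pt.shape:
        raise ValidationError("student/teacher score shapes differ")
    diff = ps - pt
    loss = float(np.mean(diff**2))
    dp = 2.0 * diff / diff.size
    grad = ps * (dp - (dp * ps).sum(axis=-1, keepdims=True))
    return loss, grad
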