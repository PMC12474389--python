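"""Classification losses: cross entropy, label smoothing, distillation.

All losses use the natural logarithm and clamp probabilities at a floor of
1e-12 before taking logs.  Label smoothing replaces a one-hot target ``y``
with ``(1 - eps) * y + eps / K``; the smoothed loss is the cross entropy
against that soft target.  The distillation objective is the Hinton-style
combination

    alpha * T^2 * KL(softmax(t / T) || softmax(s / T))
        + (1 - alpha) * CE(softmax(s), y)

with teacher logits ``t`` treated as constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmoothingSpec",
    "DistillSpec",
    "smooth_labels",
    "label_smoothing_loss",
    "cross_entropy",
    "distillation_loss",
    "softmax",
]

_P_FLOOR = 1e-12


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(logits, np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class SmoothingSpec:
    """Label-smoothing coefficient and class count (eps defaults to 0.1)."""

    eps: float = 0.1
    num_classes: int = 5

    def __post_init__(self):
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must lie in [0, 1]")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")


@dataclass(frozen=True)
class DistillSpec:
    """Distillation temperature and soft-loss weight."""

    temperature: float = 4.0
    alpha: float = 0.7

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def _check_one_hot(y: np.ndarray, k: int | None = None) -> np.ndarray:
    y = np.asarray(y, np.float64)
    if y.ndim != 1:
        raise ValueError("y must be a one-hot vector")
    if k is not None and y.size != k:
        raise ValueError(f"y has {y.size} entries, expected {k}")
    if not (np.isin(y, (0.0, 1.0)).all() and y.sum() == 1.0):
        raise ValueError("y must be one-hot")
    return y


def _check_probs(p: np.ndarray, k: int | None = None) -> np.ndarray:
    p = np.asarray(p, np.float64)
    if p.ndim != 1:
        raise ValueError("p must be a probability vector")
    if k is not None and p.size != k:
        raise ValueError(f"p has {p.size} entries, expected {k}")
    if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector summing to 1")
    return p


def smooth_labels(y: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Soften a one-hot target: ``(1 - eps) * y + eps / K``."""
    y = _check_one_hot(y, spec.num_classes)
    return (1.0 - spec.eps) * y + spec.eps / spec.num_classes


def label_smoothing_loss(p: np.ndarray, y: np.ndarray,
                         spec: SmoothingSpec) -> float:
    """Cross entropy of the prediction against the smoothed target."""
    p = _check_probs(p, spec.num_classes)
    ytilde = smooth_labels(y, spec)
    return float(-(ytilde * np.log(np.maximum(p, _P_FLOOR))).sum())


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """``-log p_true`` for a one-hot target."""
    y = _check_one_hot(y)
    p = _check_probs(p, y.size)
    return float(-(y * np.log(np.maximum(p, _P_FLOOR))).sum())


def distillation_loss(student_logits: np.ndarray, teacher_logits: np.ndarray,
                      y: np.ndarray, spec: DistillSpec) -> float:
    """Temperature-softened teacher KL plus hard-label cross entropy."""
    s = np.asarray(student_logits, np.float64)
    t = np.asarray(teacher_logits, np.float64)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("student and teacher logits must be equal-length vectors")
    y = _check_one_hot(y, s.size)
    big_t, alpha = spec.temperature, spec.alpha
    ps = softmax(s / big_t)
    pt = softmax(t / big_t)
    kl = float((pt * (np.log(np.maximum(pt, _P_FLOOR))
                      - np.log(np.maximum(ps, _P_FLOOR)))).sum())
    hard = cross_entropy(softmax(s), y)
    return alpha * big_t**2 * kl + (1.0 - alpha) * hard
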