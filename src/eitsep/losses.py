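"""Sigmoid, binary cross-entropy, and the multi-weighted two-task loss.

The training objective is E = W_lung * BCE(lung) + W_heart * BCE(heart),
where each BCE is the pixel-mean binary cross-entropy between the
sigmoid-activated head output and its binary target map.  Raising the
heart weight (the ratio Wc = W_heart / W_lung) penalizes heart errors more
heavily, forcing the network to learn the low-amplitude cardiac signal
that lung conductivity changes otherwise dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import stable_sigmoid

EPS_DEFAULT = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Task weights; ``wc`` is the heart-to-lung weight ratio."""

    w_lung: float = 1.0
    w_heart: float = 1.0

    def __post_init__(self) -> None:
        if self.w_lung < 0 or self.w_heart < 0:
            raise ValueError("loss weights must be non-negative")
        if self.w_lung == 0 and self.w_heart == 0:
            raise ValueError("at least one loss weight must be positive")

    @property
    def wc(self) -> float:
        if self.w_lung == 0:
            return np.inf
        return self.w_heart / self.w_lung


def sigmoid(x):
    """S(x) = 1 / (1 + exp(-x)), numerically stable for large |x|."""
    return stable_sigmoid(x)


def bce(predictions: np.ndarray, targets: np.ndarray,
        eps: float = EPS_DEFAULT) -> float:
    """Pixel-mean binary cross-entropy.

    ``predictions`` are probabilities in (0, 1) (clipped to
    [eps, 1 - eps] for the logs); ``targets`` in [0, 1].
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not 0 < eps < 0.5:
        raise ValueError("clipping epsilon must be in (0, 0.5)")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def total_loss(lung_pred: np.ndarray, lung_target: np.ndarray,
               heart_pred: np.ndarray, heart_target: np.ndarray,
               weights: LossWeights, eps: float = EPS_DEFAULT) -> float:
    """E = W_lung * BCE_lung + W_heart * BCE_heart."""
    return (weights.w_lung * bce(lung_pred, lung_target, eps)
            + weights.w_heart * bce(heart_pred, heart_target, eps))


def bce_grad_logits(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of the pixel-mean BCE w.r.t. the pre-sigmoid logits."""
    return (probs - targets).astype(np.float32) / probs.size
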