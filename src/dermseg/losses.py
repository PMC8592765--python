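"""Segmentation losses: BCE, soft Dice, and their convex combination.

The training objective is

    loss = (1 - alpha) * BCE(p, y) + alpha * DiceLoss(p, y)

with ``alpha`` in [0, 1] weighting the overlap (Dice) term against the
per-pixel cross-entropy.  The soft Dice loss is computed globally over the
raster, ``1 - (2 Σ p·y + ε) / (Σ p + Σ y + ε)`` with ε = 1e-6; BCE clamps
probabilities to [ε_p, 1 - ε_p], ε_p = 1e-7.  The combination counters the
foreground/background imbalance typical of lesion masks, where plain BCE is
dominated by the background class.

Two parallel implementations are provided: plain-NumPy functions (the
reference used for evaluation and tests) and autodiff-graph variants on
:class:`~dermseg.nn.tensor.Tensor` used inside the training loop.  Both
compute the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .nn.tensor import Tensor

__all__ = [
    "EPS_DICE",
    "EPS_PROB",
    "LossWeights",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "bce_loss_t",
    "dice_loss_t",
    "combined_loss_t",
]

EPS_PROB = 1e-7
EPS_DICE = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """alpha = weight of the Dice term; (1 - alpha) weights BCE."""

    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")


def _check_pair(p: np.ndarray, y: np.ndarray):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValidationError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    return p, y


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy; p clamped to [EPS_PROB, 1 - EPS_PROB]."""
    p, y = _check_pair(p, y)
    pc = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def dice_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Global soft Dice loss, 1 - (2 Σ p·y + ε)/(Σ p + Σ y + ε)."""
    p, y = _check_pair(p, y)
    inter = float((p * y).sum())
    return 1.0 - (2.0 * inter + EPS_DICE) / (float(p.sum()) + float(y.sum()) + EPS_DICE)


def combined_loss(p: np.ndarray, y: np.ndarray, weights: LossWeights) -> float:
    a = weights.alpha
    if a == 0.0:
        return bce_loss(p, y)
    if a == 1.0:
        return dice_loss(p, y)
    return (1.0 - a) * bce_loss(p, y) + a * dice_loss(p, y)


# -- autodiff variants (identical formulas on the Tensor graph) -----------


def bce_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    y = np.asarray(y, dtype=p.dtype)
    pc = p.clip(EPS_PROB, 1.0 - EPS_PROB)
    return -(
        (Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).mean()
    )


def dice_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    y = np.asarray(y, dtype=p.dtype)
    inter = (p * Tensor(y)).sum()
    return 1.0 - (2.0 * inter + EPS_DICE) / (p.sum() + float(y.sum()) + EPS_DICE)


def combined_loss_t(p: Tensor, y: np.ndarray, weights: LossWeights) -> Tensor:
    a = weights.alpha
    if a == 0.0:
        return bce_loss_t(p, y)
    if a == 1.0:
        return dice_loss_t(p, y)
    return (1.0 - a) * bce_loss_t(p, y) + a * dice_loss_t(p, y)
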