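"""Training objective: smoothed soft Dice plus binary cross-entropy.

    L_Dice = 1 - (2|X ∩ Y| + λ) / (|X| + |Y| + λ)
    L_BCE  = -mean[ y·log(p) + (1-y)·log(1-p) ]
    L      = 0.5·L_Dice + L_BCE

The Dice term uses soft (probability) sums so it is differentiable; λ > 0
rescues the empty-mask 0/0 case and damps the gradient on very small
targets, which is what keeps training stable when nodules occupy a tiny
fraction of the image. Both losses accept numpy arrays (returning floats) or
engine tensors (returning a scalar tensor on the autodiff graph); when
``from_logits`` is set, BCE is evaluated in score space with the
log-sum-exp stabilization and Dice on the sigmoid of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as E
from .engine.tensor import Tensor
from .errors import ShapeError

EPS = 1e-7  # probability clamp for log terms


@dataclass
class LossConfig:
    dice_smoothing: float = 1.0
    dice_weight: float = 0.5
    eps: float = EPS

    def __post_init__(self):
        if self.dice_smoothing <= 0:
            raise ValueError(f"dice_smoothing must be > 0, got {self.dice_smoothing}")


def _check_shapes(pred, target):
    ps = pred.data.shape if isinstance(pred, Tensor) else np.shape(pred)
    ts = target.data.shape if isinstance(target, Tensor) else np.shape(target)
    if ps != ts:
        raise ShapeError(f"prediction shape {ps} does not match target shape {ts}")


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def dice_loss(pred, target, smoothing: float = 1.0, from_logits: bool = False):
    """Soft Dice loss; result in [0, 1)."""
    _check_shapes(pred, target)
    p, was_tensor = _wrap(pred)
    t, _ = _wrap(target)
    if from_logits:
        p = E.sigmoid(p)
    inter = (p * t).sum()
    total = p.sum() + t.sum()
    loss = 1.0 - (2.0 * inter + smoothing) / (total + smoothing)
    return loss if was_tensor else loss.item()


def bce_loss(pred, target, from_logits: bool = False, eps: float = EPS):
    """Mean binary cross-entropy (negative Bernoulli log-likelihood)."""
    _check_shapes(pred, target)
    p, was_tensor = _wrap(pred)
    t, _ = _wrap(target)
    if from_logits:
        loss = E.bce_with_logits(p, t).mean()
    else:
        p = E.clip(p, eps, 1.0 - eps)
        loss = -(t * E.log(p) + (1.0 - t) * E.log(1.0 - p)).mean()
    return loss if was_tensor else loss.item()


def combined_loss(pred, target, cfg: LossConfig | None = None, from_logits: bool = False):
    """0.5 * Dice + BCE (the dice weight is configurable but defaults to 0.5)."""
    cfg = cfg or LossConfig()
    d = dice_loss(pred, target, smoothing=cfg.dice_smoothing, from_logits=from_logits)
    b = bce_loss(pred, target, from_logits=from_logits, eps=cfg.eps)
    return cfg.dice_weight * d + b
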