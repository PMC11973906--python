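"""Training objectives: binary cross-entropy and the Tversky loss.

Nodule masks are heavily imbalanced (most pixels are background, and a
third of the images contain no nodule at all), so the default objective
is the Tversky loss

    T(alpha, beta) = sum(p*g) / (sum(p*g) + alpha*sum(p*(1-g)) + beta*sum((1-p)*g))

with ``beta = 0.7 > alpha = 0.3`` weighting false negatives more than
false positives, which raises sensitivity.  ``alpha = beta = 0.5``
recovers the soft Dice coefficient.  A smoothing constant of 1 is added
to numerator and denominator so an empty ground-truth mask with an empty
prediction scores index 1 (loss 0) instead of 0/0.

All functions accept either plain NumPy arrays (returning floats) or
autograd :class:`~lite_thyseg.nn.Tensor` values (returning differentiable
scalars used by the training loop).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["TverskyParams", "bce_loss", "tversky_index", "tversky_loss"]

_EPS = 1e-7


@dataclass(frozen=True)
class TverskyParams:
    """False-positive (alpha) and false-negative (beta) weights."""

    alpha: float = 0.3
    beta: float = 0.7

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


def _check_shapes(probs, truth):
    if probs.shape != np.shape(truth):
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {np.shape(truth)}")


def _clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _sum(x):
    return x.sum()


def _as_float(x):
    return x if isinstance(x, Tensor) else float(x)


def bce_loss(probs, truth, reduction: str = "mean"):
    """Binary cross-entropy -sum[y ln p + (1-y) ln(1-p)] over all pixels.

    Probabilities are clipped to [eps, 1-eps] so a confident wrong
    prediction yields a finite -ln(eps) term.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    _check_shapes(probs, truth)
    truth = np.asarray(truth, dtype=np.float32)
    p = _clip(probs, _EPS, 1.0 - _EPS)
    total = -_sum(truth * _log(p) + (1.0 - truth) * _log(1.0 - p))
    if reduction == "mean":
        total = total / float(truth.size)
    return _as_float(total)


def tversky_index(probs, truth, params: TverskyParams = TverskyParams(),
                  smooth: float = 1.0):
    """Asymmetric overlap index; 1 is a perfect match."""
    _check_shapes(probs, truth)
    truth = np.asarray(truth, dtype=np.float32)
    tp = _sum(probs * truth)
    fp = _sum(probs * (1.0 - truth))
    fn = _sum((1.0 - probs) * truth)
    index = (tp + smooth) / (tp + params.alpha * fp + params.beta * fn + smooth)
    return _as_float(index)


def tversky_loss(probs, truth, params: TverskyParams = TverskyParams(),
                 smooth: float = 1.0):
    """1 - Tversky index; differentiable in the predicted probabilities."""
    return 1.0 - tversky_index(probs, truth, params, smooth)
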