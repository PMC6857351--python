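"""Detection training losses: focal loss and smooth-L1 box regression loss.

Framework-independent scalar reference implementations, useful for checking
a training pipeline's loss plumbing against closed forms.

The smooth-L1 comes in two variants because the common printed form,

    0.5 * (sigma * x)^2        if |x| < 1
    (|x| - 0.5) / sigma^2      otherwise,

is discontinuous at |x| = 1 whenever sigma != 1.  The Detectron-style
continuous form moves the branch point to |x| < 1/sigma^2.  The printed
form is the default for fidelity; ``continuous=True`` selects the standard
variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["FocalLossParams", "SmoothL1Params", "focal_loss", "smooth_l1"]

_EPS = 1e-12


@dataclass(frozen=True)
class FocalLossParams:
    """alpha balances classes; gamma down-weights easy examples."""

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.gamma < 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class SmoothL1Params:
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def focal_loss(
    p: float, y: int, params: FocalLossParams = FocalLossParams()
) -> float:
    """FL(p_t) = -alpha * (1 - p_t)^gamma * ln(p_t).

    ``p`` is the predicted foreground probability; ``y`` in {+1, -1} is the
    ground-truth class, and ``p_t = p`` for y = +1, else ``1 - p``.  With
    alpha = 1, gamma = 0 this reduces exactly to cross-entropy -ln(p_t).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if y not in (1, -1):
        raise ValueError(f"y must be +1 or -1, got {y}")
    p_t = p if y == 1 else 1.0 - p
    p_t = min(max(p_t, _EPS), 1.0 - _EPS)
    return -params.alpha * (1.0 - p_t) ** params.gamma * math.log(p_t)


def _smooth_l1_scalar(x: float, sigma: float, continuous: bool) -> float:
    if continuous:
        # Detectron form: branch at |x| = 1/sigma^2, continuous join
        if abs(x) < 1.0 / (sigma * sigma):
            return 0.5 * (sigma * x) ** 2
        return abs(x) - 0.5 / (sigma * sigma)
    # as commonly printed: branch at |x| = 1 (discontinuous for sigma != 1)
    if abs(x) < 1.0:
        return 0.5 * (sigma * x) ** 2
    return (abs(x) - 0.5) / (sigma * sigma)


def smooth_l1(
    t: Sequence[float],
    v: Sequence[float],
    params: SmoothL1Params = SmoothL1Params(),
    *,
    continuous: bool = False,
) -> float:
    """Smooth-L1 box regression loss summed over the (x, y, w, h) coordinates.

    Depends only on the absolute coordinate differences, so it is symmetric
    in (t, v) and zero iff t == v.
    """
    if len(t) != len(v):
        raise ValueError("t and v must have equal length")
    return sum(
        _smooth_l1_scalar(ti - vi, params.sigma, continuous)
        for ti, vi in zip(t, v)
    )
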