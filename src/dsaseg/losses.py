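"""Hybrid Dice + cross-entropy training objective.

The loss compares the foreground probability map P with the binary
ground truth G:

    L     = L_dc + omega * L_ce
    L_dc  = 1 - (2 * sum(P*G) + eps) / (sum(P) + sum(G) + eps)
    L_ce  = -mean(G * log P + (1 - G) * log(1 - P))

The Dice term drives regional overlap and is robust to the extreme
class imbalance of small lesions; the cross-entropy term supervises
every voxel.  omega defaults to 1.  Cross-entropy is averaged over
voxels so omega keeps the same meaning across patch sizes.

All three functions accept either plain arrays (returning a float) or
autodiff Tensors (returning a differentiable Tensor).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor
from .config import LossConfig
from .volumes import BinaryLesionMask, ShapeError

__all__ = ["dice_loss", "ce_loss", "hybrid_loss"]


def _prep(p, g):
    wrap = isinstance(p, Tensor)
    if isinstance(g, BinaryLesionMask):
        g = g.values
    p_t = p if wrap else Tensor(np.asarray(p, dtype=float))
    g_t = as_tensor(np.asarray(g if not isinstance(g, Tensor) else g.data, dtype=float))
    if p_t.shape != g_t.shape:
        raise ShapeError(f"prediction shape {p_t.shape} != ground-truth shape {g_t.shape}")
    return p_t, g_t, wrap


def dice_loss(p, g, epsilon: float = 1e-5):
    """Soft Dice loss; 0 at perfect overlap, approaching 1 at none."""
    p_t, g_t, wrap = _prep(p, g)
    inter = (p_t * g_t).sum()
    denom = p_t.sum() + g_t.sum()
    loss = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return loss if wrap else loss.item()


def ce_loss(p, g, prob_floor: float = 1e-7, reduction: str = "mean"):
    """Binary cross-entropy of the foreground probability map."""
    p_t, g_t, wrap = _prep(p, g)
    p_c = p_t.clip(prob_floor, 1.0 - prob_floor)
    terms = -(g_t * p_c.log() + (1.0 - g_t) * (1.0 - p_c).log())
    if reduction == "mean":
        loss = terms.mean()
    elif reduction == "sum":
        loss = terms.sum()
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return loss if wrap else loss.item()


def hybrid_loss(p, g, cfg: LossConfig | None = None, return_parts: bool = False):
    """L = L_dc + omega * L_ce (omega defaults to 1)."""
    cfg = cfg or LossConfig()
    l_dc = dice_loss(p, g, epsilon=cfg.epsilon)
    l_ce = ce_loss(p, g, prob_floor=cfg.prob_floor)
    total = l_dc + cfg.omega * l_ce
    if return_parts:
        return total, l_dc, l_ce
    return total
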