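"""Composite Dice + Focal objective with deep supervision.

Microbleeds occupy a vanishing fraction of each slice, so plain
cross-entropy is dominated by easy background voxels.  The training
objective therefore combines

* Dice loss, ``1 − (2Σ p·g + ε) / (Σp + Σg + ε)``, which directly optimizes
  overlap and is insensitive to the foreground/background imbalance, and
* Focal loss, ``mean(−α·(1−p_t)^γ·log p_t)`` with ``p_t = p`` on lesion
  voxels and ``1−p`` elsewhere, which down-weights well-classified
  background and concentrates gradient on hard voxels (γ = 2 by default).

The total loss sums Dice + Focal over the four decoder outputs with weights
λ = (0.4, 0.3, 0.2, 0.1) ordered final → deepest; auxiliary targets are
obtained by 2×2 max-pooling so that even single-voxel lesions survive at
every supervision scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn.layers import sigmoid
from .nn.ops import maxpool2_target

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    epsilon: float = 1e-5
    gamma: float = 2.0
    alpha: float = 0.25
    lambdas: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if len(self.lambdas) != 4:
            raise ValueError("lambdas must have length 4")


def _check(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Soft Dice loss on a probability map ``p`` against binary ``g``."""
    p, g = _check(p, g)
    num = 2.0 * (p * g).sum() + cfg.epsilon
    den = p.sum() + g.sum() + cfg.epsilon
    return float(1.0 - num / den)


def dice_loss_grad(p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """d(dice_loss)/dp, same shape as ``p``."""
    p, g = _check(p, g)
    num = 2.0 * (p * g).sum() + cfg.epsilon
    den = p.sum() + g.sum() + cfg.epsilon
    return (num / den**2 - 2.0 * g / den).astype(np.float64)


def focal_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Voxel-averaged focal loss on a probability map ``p``."""
    p, g = _check(p, g)
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    pt = np.where(g > 0.5, p, 1.0 - p)
    return float(np.mean(-cfg.alpha * (1.0 - pt) ** cfg.gamma * np.log(pt)))


def focal_loss_grad(p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """d(focal_loss)/dp; zero where ``p`` sits outside the clamp range."""
    p, g = _check(p, g)
    inside = (p > _CLAMP) & (p < 1.0 - _CLAMP)
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    pt = np.where(g > 0.5, pc, 1.0 - pc)
    om = 1.0 - pt
    dl_dpt = cfg.alpha * (cfg.gamma * om ** max(cfg.gamma - 1.0, 0.0) * np.log(pt) - om**cfg.gamma / pt)
    sign = np.where(g > 0.5, 1.0, -1.0)
    return (dl_dpt * sign * inside) / p.size


def combine_losses(per_output: Sequence[float], lambdas: Sequence[float]) -> float:
    """λ-weighted sum of per-output (Dice + Focal) losses, final → deepest."""
    if len(per_output) != len(lambdas):
        raise ValueError("per_output and lambdas must have equal length")
    return float(sum(l * v for l, v in zip(lambdas, per_output)))


def _prepare(outputs: Sequence[np.ndarray], target: np.ndarray):
    if len(outputs) != 4:
        raise ValueError(f"expected 4 decoder outputs, got {len(outputs)}")
    target = np.asarray(target)
    outs = []
    for k, o in enumerate(outputs):
        o = np.asarray(o)
        o2 = o.reshape(o.shape[0], o.shape[-2], o.shape[-1]) if o.ndim == 4 else o[None] if o.ndim == 2 else o
        outs.append(o2)
    tgt = target[None] if target.ndim == 2 else target
    return outs, tgt


def total_loss(
    outputs: Sequence[np.ndarray],
    target: np.ndarray,
    cfg: LossConfig = LossConfig(),
    with_grad: bool = False,
):
    """Deeply supervised total loss over four logit maps.

    ``outputs`` are logits ordered final → deepest with spatial sizes H,
    H/2, H/4, H/8; ``target`` is the full-resolution binary mask (one per
    batch element).  Dice and Focal are computed per slice and averaged over
    the batch.  With ``with_grad=True``, also returns the gradient with
    respect to each logit map.
    """
    outs, tgt = _prepare(outputs, target)
    B = outs[0].shape[0]
    total = 0.0
    grads = []
    for k, logits in enumerate(outs):
        gk = maxpool2_target(tgt, k) if k else tgt
        lam = cfg.lambdas[k]
        p = sigmoid(logits.astype(np.float32)).astype(np.float64)
        loss_k = 0.0
        if with_grad:
            gl = np.zeros_like(p)
        for b in range(B):
            loss_k += dice_loss(p[b], gk[b], cfg) + focal_loss(p[b], gk[b], cfg)
            if with_grad:
                dp = dice_loss_grad(p[b], gk[b], cfg) + focal_loss_grad(p[b], gk[b], cfg)
                gl[b] = dp * p[b] * (1.0 - p[b])  # chain through the sigmoid
        total += lam * loss_k / B
        if with_grad:
            grads.append((lam / B) * gl)
    if with_grad:
        return total, [g.astype(np.float32) for g in grads]
    return total
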