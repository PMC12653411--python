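"""Multi-class soft Dice training objective.

For class c with predicted probabilities p_c and one-hot ground truth g_c,

    dice_c = (2 Σ p_c g_c + ε) / (Σ p_c + Σ g_c + ε),   ε = 1e-6

and the loss is 1 − mean_c dice_c, averaged per image over the batch.
With an absent class (Σ g_c = 0) and vanishing prediction mass the smoothed
ratio tends to 1, i.e. absent classes are not penalized.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["dice_loss", "deep_supervision_loss", "one_hot"]

EPS = 1e-6


def one_hot(gt: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """(B, H, W) integer masks → (B, C, H, W) one-hot float32."""
    gt = np.asarray(gt)
    if gt.ndim == 2:
        gt = gt[None]
    out = np.zeros((gt.shape[0], num_classes) + gt.shape[1:], dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = gt == c
    return out


def dice_loss(probs: Tensor, gt: np.ndarray, eps: float = EPS) -> Tensor:
    """Soft Dice loss of a probability map against an integer class mask.

    ``probs``: (B, C, H, W) with per-pixel class sums of 1; ``gt``: (B, H, W)
    or (H, W) labels. Raises if the probabilities are not normalized.
    """
    num_classes = probs.shape[1]
    sums = probs.data.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-3:
        raise ValueError("dice_loss expects normalized per-pixel probabilities")
    g = one_hot(gt, num_classes)
    if g.shape != probs.shape:
        raise ValueError(f"mask shape {g.shape} does not match probabilities "
                         f"{probs.shape}")
    gt_t = Tensor(g)
    inter = (probs * gt_t).sum(axis=(2, 3))      # (B, C)
    denom = probs.sum(axis=(2, 3)) + gt_t.sum(axis=(2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice.mean()


def deep_supervision_loss(final: Tensor, out1: Tensor, out2: Tensor,
                          gt: np.ndarray, weights=(1.0, 1.0, 1.0)) -> Tensor:
    """Weighted sum of Dice losses over the Phase-1, Phase-2 and fused maps."""
    w1, w2, wf = weights
    return (w1 * dice_loss(out1, gt) + w2 * dice_loss(out2, gt)
            + wf * dice_loss(final, gt))
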