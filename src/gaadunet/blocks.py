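"""Building blocks of the gated attention-augmented Double U-Net.

* :class:`MultiHeadSelfAttention2d` — 2-D multi-head self-attention over all
  pixel positions with learnable relative row/column position embeddings.
* :class:`AAConv2d` — attention-augmented convolution: a standard convolution
  and the self-attention branch concatenated along channels.
* :class:`GatingBlock` — multiplicative feature gate
  ``z = x ⊙ σ(Conv(ReLU(BN(Conv(x)))))`` suppressing irrelevant activations.
* :class:`SEBlock` — squeeze-and-excitation channel recalibration.
* :class:`ASPP` — atrous spatial pyramid pooling for multi-scale context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Tensor, concat, upsample_bilinear2d

__all__ = ["AACConfig", "MultiHeadSelfAttention2d", "AAConv2d", "GatingBlock",
           "SEBlock", "ASPP", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a block's configuration or input shape is inconsistent."""


@dataclass
class AACConfig:
    """Hyperparameters of the attention-augmented convolution.

    ``dk_total``/``dv_total`` are key/value dimensions summed over heads
    (each head gets ``dk_total // num_heads``). The convolution branch emits
    ``out_channels - dv_total`` channels so the concatenated output has
    exactly ``out_channels``.
    """

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    dk_total: int = 32
    dv_total: int = 32
    num_heads: int = 4
    relative: bool = True
    spatial_shape: tuple[int, int] = (28, 28)
    stride: int = 1

    def __post_init__(self):
        if self.dk_total % self.num_heads or self.dv_total % self.num_heads:
            raise ConfigurationError(
                "dk_total and dv_total must be divisible by num_heads")
        if self.dv_total >= self.out_channels:
            raise ConfigurationError(
                f"dv_total ({self.dv_total}) must be smaller than "
                f"out_channels ({self.out_channels})")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")

    @property
    def dk_head(self) -> int:
        return self.dk_total // self.num_heads

    @property
    def dv_head(self) -> int:
        return self.dv_total // self.num_heads


_OFFSET_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _offset_indices(H, W, Ht, Wt):
    """(L, L) tables of relative row/col offset indices between pixel pairs.

    Offsets are key minus query position shifted by table center, so equal
    displacements always address the same embedding row.
    """
    key = (H, W, Ht, Wt)
    cached = _OFFSET_CACHE.get(key)
    if cached is None:
        rows = np.repeat(np.arange(H), W)
        cols = np.tile(np.arange(W), H)
        idx_r = (rows[None, :] - rows[:, None]) + (Ht - 1)
        idx_c = (cols[None, :] - cols[:, None]) + (Wt - 1)
        cached = (idx_r, idx_c)
        _OFFSET_CACHE[key] = cached
    return cached


def relative_logits(q: Tensor, rel_row: Tensor, rel_col: Tensor,
                    H: int, W: int) -> Tensor:
    """Relative-position attention logits.

    ``q``: (B, heads, H·W, dk_head), already scaled by 1/√dk_head.
    ``rel_row``/``rel_col``: (2·Ht−1, dk_head) / (2·Wt−1, dk_head) embedding
    tables shared across heads. Returns (B, heads, H·W, H·W) logits where the
    entry for query p and key q is ``q_p · (r_row[Δrow] + r_col[Δcol])``.
    """
    Ht = (rel_row.data.shape[0] + 1) // 2
    Wt = (rel_col.data.shape[0] + 1) // 2
    if H > Ht or W > Wt:
        raise ConfigurationError(
            f"spatial size {(H, W)} exceeds relative embedding tables "
            f"sized for {(Ht, Wt)}")
    idx_r, idx_c = _offset_indices(H, W, Ht, Wt)
    R = rel_row.data[idx_r] + rel_col.data[idx_c]  # (L, L, dk_head)
    out = np.einsum("bhpd,pqd->bhpq", q.data, R, optimize=True)

    def backward(g):
        gq = np.einsum("bhpq,pqd->bhpd", g, R, optimize=True)
        gR = np.einsum("bhpq,bhpd->pqd", g, q.data, optimize=True)
        d = gR.shape[-1]
        g_row = np.zeros_like(rel_row.data)
        g_col = np.zeros_like(rel_col.data)
        np.add.at(g_row, idx_r.ravel(), gR.reshape(-1, d))
        np.add.at(g_col, idx_c.ravel(), gR.reshape(-1, d))
        return gq, g_row, g_col

    return Tensor._make(out, (q, rel_row, rel_col), backward)


class MultiHeadSelfAttention2d(nn.Module):
    """Multi-head self-attention over all spatial positions of a feature map.

    Logits are ``(q/√dk)·kᵀ`` plus, when ``cfg.relative``, learnable relative
    row/column offset terms; softmax normalizes over key positions per head.
    """

    def __init__(self, cfg: AACConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.wq = nn.Conv2d(cfg.in_channels, cfg.dk_total, 1, bias=False, rng=rng)
        self.wk = nn.Conv2d(cfg.in_channels, cfg.dk_total, 1, bias=False, rng=rng)
        self.wv = nn.Conv2d(cfg.in_channels, cfg.dv_total, 1, bias=False, rng=rng)
        self.out_proj = nn.Conv2d(cfg.dv_total, cfg.dv_total, 1, bias=False,
                                  rng=rng)
        if cfg.relative:
            Ht, Wt = cfg.spatial_shape
            std = cfg.dk_head ** -0.5
            self.rel_row = nn.Parameter(
                rng.normal(0.0, std, (2 * Ht - 1, cfg.dk_head)))
            self.rel_col = nn.Parameter(
                rng.normal(0.0, std, (2 * Wt - 1, cfg.dk_head)))

    def attention_weights(self, x: Tensor) -> Tensor:
        """(B, heads, L, L) softmax attention map (rows sum to 1)."""
        return self._attend(x)[1]

    def _attend(self, x: Tensor):
        cfg = self.cfg
        B, C, H, W = x.shape
        if C != cfg.in_channels:
            raise ConfigurationError(
                f"attention expected {cfg.in_channels} channels, got {C}")
        L = H * W
        nh, dkh, dvh = cfg.num_heads, cfg.dk_head, cfg.dv_head
        q = self.wq(x).reshape(B, nh, dkh, L).permute(0, 1, 3, 2)
        q = q * (1.0 / math.sqrt(dkh))
        k = self.wk(x).reshape(B, nh, dkh, L)
        logits = q @ k  # (B, nh, L, L)
        if cfg.relative:
            logits = logits + relative_logits(q, self.rel_row, self.rel_col, H, W)
        attn = logits.softmax(axis=-1)
        v = self.wv(x).reshape(B, nh, dvh, L).permute(0, 1, 3, 2)
        out = (attn @ v).permute(0, 1, 3, 2).reshape(B, cfg.dv_total, H, W)
        return out, attn

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self._attend(x)
        return self.out_proj(out)


class AAConv2d(nn.Module):
    """Attention-augmented convolution.

    Channel-axis concatenation of a ``kernel_size`` convolution producing
    ``out_channels - dv_total`` channels and the self-attention branch
    producing ``dv_total`` channels. With ``post_norm`` a BatchNorm+ReLU is
    applied to the concatenated output.
    """

    def __init__(self, cfg: AACConfig, post_norm: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.conv = nn.Conv2d(cfg.in_channels, cfg.out_channels - cfg.dv_total,
                              cfg.kernel_size, stride=cfg.stride,
                              bias=not post_norm, rng=rng)
        self.attn = MultiHeadSelfAttention2d(cfg, rng=rng)
        self.post_norm = post_norm
        if post_norm:
            self.bn = nn.BatchNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"AAC expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        out = concat([self.conv(x), self.attn(x)], axis=1)
        if self.post_norm:
            out = self.bn(out).relu()
        return out


class GatingBlock(nn.Module):
    """Elementwise multiplicative gate z = x ⊙ σ(Conv₂(ReLU(BN(Conv₁(x))))).

    Conv₁ (1×1) halves the channel count (floor, minimum 1); Conv₂ (1×1)
    restores it. The sigmoid keeps every gate in (0, 1), so |z| ≤ |x|
    elementwise.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        mid = max(1, channels // 2)
        self.conv1 = nn.Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, channels, 1, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        return self.conv2(self.bn(self.conv1(x)).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"gating expected {self.channels} channels, got {x.shape[1]}")
        return x * self.gate(x)


class SEBlock(nn.Module):
    """Squeeze-and-excitation: global average pool → bottleneck MLP → sigmoid
    per-channel scale."""

    def __init__(self, channels: int, reduction: int = 8, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(1, math.ceil(channels / reduction))
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        # small positive bias keeps excitation units off the dead-ReLU
        # boundary at init (inputs are nonnegative pooled activations)
        self.fc1.bias.data[:] = 0.1
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def scales(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))  # (B, C)
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[0], x.shape[1]
        return x * self.scales(x).reshape(B, C, 1, 1)


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, dilation=1, rng=None):
        super().__init__()
        # bias-free: the following BatchNorm's mean subtraction would cancel it
        self.conv = nn.Conv2d(cin, cout, k, dilation=dilation, bias=False,
                              rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling.

    Parallel branches — 1×1 convolution, one 3×3 dilated convolution per
    rate, and global image pooling — concatenated and projected back to
    ``out_channels`` by a 1×1 convolution.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates=(6, 12, 18), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if any(r < 1 for r in rates):
            raise ConfigurationError("ASPP dilation rates must be >= 1")
        self.rates = tuple(rates)
        self.branch1 = _ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        self.dilated = nn.ModuleList(
            [_ConvBNReLU(in_channels, out_channels, 3, dilation=r, rng=rng)
             for r in rates])
        self.pool_conv = _ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        self.project = _ConvBNReLU(out_channels * (len(rates) + 2),
                                   out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        branches = [self.branch1(x)]
        branches += [b(x) for b in self.dilated]
        branches.append(upsample_bilinear2d(self.pool_conv(pooled), (H, W)))
        return self.project(concat(branches, axis=1))
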