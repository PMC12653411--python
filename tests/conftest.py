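"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (explicit loops,
all-pairs distance matrices) kept separate from the library code paths they
validate.
"""

import numpy as np
import pytest

from gaadunet.blocks import AACConfig, MultiHeadSelfAttention2d
from gaadunet.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_model_config(**overrides):
    """A minimal valid ModelConfig for fast structural tests."""
    kwargs = dict(input_size=(32, 32), encoder1_widths=(4, 6, 8, 12),
                  encoder2_widths=(4, 6, 8, 12), decoder_widths=(8, 6, 4, 4),
                  aspp_out=8, aspp_rates=(1, 2), dk_total=4, dv_total=4,
                  num_heads=2, se_reduction=1)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def attention_oracle(block: MultiHeadSelfAttention2d, x: np.ndarray) -> np.ndarray:
    """Explicit double-loop multi-head self-attention with relative terms.

    Loops over every (query, key) pixel pair, forms q·k/√dk plus the
    relative row/col embedding terms, applies softmax, and sums values;
    finally applies the block's output projection. Independent of the
    vectorized implementation.
    """
    cfg = block.cfg
    B, C, H, W = x.shape
    nh, dkh, dvh = cfg.num_heads, cfg.dk_head, cfg.dv_head
    Wq = block.wq.weight.data.reshape(cfg.dk_total, C)
    Wk = block.wk.weight.data.reshape(cfg.dk_total, C)
    Wv = block.wv.weight.data.reshape(cfg.dv_total, C)
    Wo = block.out_proj.weight.data.reshape(cfg.dv_total, cfg.dv_total)
    Ht, Wt = cfg.spatial_shape if cfg.relative else (H, W)
    out = np.zeros((B, cfg.dv_total, H, W))
    coords = [(r, c) for r in range(H) for c in range(W)]
    for b in range(B):
        feat = x[b].reshape(C, H * W)
        q_all, k_all, v_all = Wq @ feat, Wk @ feat, Wv @ feat
        attn_out = np.zeros((cfg.dv_total, H * W))
        for h in range(nh):
            qh = q_all[h * dkh:(h + 1) * dkh] / np.sqrt(dkh)
            kh = k_all[h * dkh:(h + 1) * dkh]
            vh = v_all[h * dvh:(h + 1) * dvh]
            for p, (pr, pc) in enumerate(coords):
                logits = np.empty(H * W)
                for qi, (qr, qc) in enumerate(coords):
                    logit = float(qh[:, p] @ kh[:, qi])
                    if cfg.relative:
                        rel = (block.rel_row.data[qr - pr + Ht - 1]
                               + block.rel_col.data[qc - pc + Wt - 1])
                        logit += float(qh[:, p] @ rel)
                    logits[qi] = logit
                weights = np.exp(logits - logits.max())
                weights /= weights.sum()
                attn_out[h * dvh:(h + 1) * dvh, p] = vh @ weights
        out[b] = (Wo @ attn_out).reshape(cfg.dv_total, H, W)
    return out


def random_attention_case(seed: int):
    """Random attention configuration with H, W ≤ 6 and heads ∈ {1, 2, 4}."""
    r = np.random.default_rng(seed)
    heads = int(r.choice([1, 2, 4]))
    H, W = int(r.integers(1, 7)), int(r.integers(1, 7))
    C = int(r.integers(2, 7))
    dkh, dvh = int(r.integers(1, 5)), int(r.integers(1, 5))
    cfg = AACConfig(in_channels=C, out_channels=heads * dvh + 1,
                    dk_total=heads * dkh, dv_total=heads * dvh,
                    num_heads=heads, relative=bool(r.integers(0, 2)),
                    spatial_shape=(H, W))
    block = MultiHeadSelfAttention2d(cfg, rng=r)
    x = r.standard_normal((1, C, H, W)).astype(np.float32)
    return block, x
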