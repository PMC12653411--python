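"""Unit tests of the attention, gating, SE and ASPP blocks against
independent scalar/loop oracles."""

import numpy as np
import pytest

from gaadunet.blocks import (AACConfig, AAConv2d, ASPP, ConfigurationError,
                             GatingBlock, MultiHeadSelfAttention2d, SEBlock)
from gaadunet.tensor import Tensor, conv2d, no_grad

from conftest import attention_oracle, random_attention_case


def small_aac_cfg(**kw):
    base = dict(in_channels=4, out_channels=6, dk_total=4, dv_total=4,
                num_heads=2, spatial_shape=(4, 4))
    base.update(kw)
    return AACConfig(**base)


class TestAACConfig:
    @pytest.mark.parametrize("bad", [
        dict(dk_total=5),                       # not divisible by heads
        dict(dv_total=6),                       # dv >= out_channels
        dict(kernel_size=2),                    # even kernel
        dict(stride=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            small_aac_cfg(**bad)

    def test_paper_channel_split(self):
        """512 output channels with 32 value dims leave 480 for convolution."""
        cfg = AACConfig(in_channels=512, out_channels=512, dk_total=32,
                        dv_total=32, num_heads=4, spatial_shape=(28, 28))
        assert cfg.out_channels - cfg.dv_total == 480
        assert cfg.dk_head == cfg.dv_head == 8


class TestSelfAttention:
    def test_single_pixel_is_value_projection(self, rng):
        cfg = small_aac_cfg(spatial_shape=(1, 1))
        block = MultiHeadSelfAttention2d(cfg, rng=rng).eval()
        x = rng.standard_normal((2, 4, 1, 1)).astype(np.float32)
        with no_grad():
            out = block(Tensor(x))
        v = conv2d(Tensor(x), block.wv.weight)
        ref = conv2d(v, block.out_proj.weight)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-5)

    def test_zero_query_attends_uniformly(self, rng):
        """With WQ = 0 and zero relative tables every query averages the
        value projections over all pixels."""
        cfg = small_aac_cfg()
        block = MultiHeadSelfAttention2d(cfg, rng=rng)
        block.wq.weight.data[:] = 0
        block.rel_row.data[:] = 0
        block.rel_col.data[:] = 0
        x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        with no_grad():
            out = block(Tensor(x))
            v = conv2d(Tensor(x), block.wv.weight).data
            mean_v = np.broadcast_to(v.mean(axis=(2, 3), keepdims=True), v.shape)
            ref = conv2d(Tensor(np.ascontiguousarray(mean_v)),
                         block.out_proj.weight)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-4, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        block, x = random_attention_case(7)
        with no_grad():
            attn = block.attention_weights(Tensor(x)).data
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        block, x = random_attention_case(seed)
        with no_grad():
            out = block(Tensor(x)).data
        ref = attention_oracle(block, x)
        np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)

    def test_relative_term_translation_consistent(self, rng):
        """Query/key pairs with equal (row, col) offsets share the same
        relative logit contribution."""
        from gaadunet.blocks import relative_logits
        cfg = small_aac_cfg(spatial_shape=(3, 3))
        block = MultiHeadSelfAttention2d(cfg, rng=rng)
        q = np.ones((1, cfg.num_heads, 9, cfg.dk_head), dtype=np.float32)
        rel = relative_logits(Tensor(q), block.rel_row, block.rel_col, 3, 3).data
        # offset (0, +1): pairs (p=(0,0), q=(0,1)) and (p=(1,1), q=(1,2))
        assert rel[0, 0, 0, 1] == pytest.approx(rel[0, 0, 4, 5], abs=1e-6)
        # offset (+1, -1): (0,1)->(1,0) i.e. 1->3 and (1,2)->(2,1) i.e. 5->7
        assert rel[0, 0, 1, 3] == pytest.approx(rel[0, 0, 5, 7], abs=1e-6)

    def test_oversized_input_rejected_with_relative(self, rng):
        cfg = small_aac_cfg(spatial_shape=(2, 2))
        block = MultiHeadSelfAttention2d(cfg, rng=rng)
        with pytest.raises(ConfigurationError):
            block(Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32)))

    def test_channel_mismatch_rejected(self, rng):
        block = MultiHeadSelfAttention2d(small_aac_cfg(), rng=rng)
        with pytest.raises(ConfigurationError):
            block(Tensor(np.zeros((1, 5, 4, 4), dtype=np.float32)))


class TestAAConv:
    def test_output_channel_count(self, rng):
        block = AAConv2d(small_aac_cfg(), rng=rng).eval()
        x = rng.standard_normal((2, 4, 4, 4)).astype(np.float32)
        with no_grad():
            out = block(Tensor(x))
        assert out.shape == (2, 6, 4, 4)

    def test_zero_input_zero_output(self, rng):
        block = AAConv2d(small_aac_cfg(), rng=rng).eval()
        with no_grad():
            out = block(Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_equals_concatenated_branches(self, rng):
        """Without the post-concat normalization the output is exactly the
        channel concatenation of the two branch outputs."""
        block = AAConv2d(small_aac_cfg(), post_norm=False, rng=rng).eval()
        x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        with no_grad():
            out = block(Tensor(x)).data
            conv_part = block.conv(Tensor(x)).data
            attn_part = block.attn(Tensor(x)).data
        np.testing.assert_array_equal(
            out, np.concatenate([conv_part, attn_part], axis=1))


class TestGating:
    def make(self, channels=6, rng=None):
        return GatingBlock(channels, rng=rng).eval()

    def test_zero_input_zero_output(self, rng):
        g = self.make(rng=rng)
        with no_grad():
            out = g(Tensor(np.zeros((1, 6, 3, 3), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_conv2_gives_sigmoid_bias_scaling(self, rng):
        """With Conv₂ weights zero the gate is the constant σ(b); with b = 0
        the block exactly halves its input."""
        g = self.make(rng=rng)
        g.conv2.weight.data[:] = 0
        b = np.array([0.0, 1.0, -1.0, 0.5, 0.0, 2.0], dtype=np.float32)
        g.conv2.bias.data[:] = b
        x = rng.standard_normal((2, 6, 4, 4)).astype(np.float32)
        with no_grad():
            out = g(Tensor(x)).data
        expected = x * (1 / (1 + np.exp(-b))).reshape(1, 6, 1, 1)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-7)
        g.conv2.bias.data[:] = 0
        with no_grad():
            out = g(Tensor(x)).data
        np.testing.assert_allclose(out, 0.5 * x, rtol=1e-6)

    @pytest.mark.parametrize("trial", range(5))
    def test_elementwise_bounded_and_matches_scalar_recomputation(self, trial):
        rng = np.random.default_rng(100 + trial)
        C = int(rng.integers(2, 9))
        g = GatingBlock(C, rng=rng).eval()
        g.bn.running_mean = rng.standard_normal(max(1, C // 2)).astype(np.float32)
        g.bn.running_var = rng.uniform(0.5, 2, max(1, C // 2)).astype(np.float32)
        x = rng.standard_normal((1, C, 5, 5)).astype(np.float32)
        with no_grad():
            z = g(Tensor(x)).data
        assert np.all(np.abs(z) <= np.abs(x) + 1e-7)
        assert np.all(np.sign(z[x != 0]) == np.sign(x[x != 0]))
        # scalar recomputation of the whole gate, pixel by pixel
        w1 = g.conv1.weight.data.reshape(g.conv1.out_channels, C)
        w2 = g.conv2.weight.data.reshape(C, g.conv1.out_channels)
        for r in range(5):
            for c in range(5):
                y1 = w1 @ x[0, :, r, c]
                y2 = (y1 - g.bn.running_mean) / np.sqrt(
                    g.bn.running_var + g.bn.eps)
                y2 = y2 * g.bn.gamma.data + g.bn.beta.data
                y3 = np.maximum(y2, 0)
                y4 = w2 @ y3 + g.conv2.bias.data
                gate = 1 / (1 + np.exp(-y4))
                np.testing.assert_allclose(z[0, :, r, c],
                                           x[0, :, r, c] * gate,
                                           rtol=1e-4, atol=1e-6)

    def test_odd_channel_count_supported(self, rng):
        g = GatingBlock(5, rng=rng).eval()
        with no_grad():
            out = g(Tensor(np.ones((1, 5, 2, 2), dtype=np.float32)))
        assert out.shape == (1, 5, 2, 2)


class TestSE:
    def test_zero_input_zero_output(self, rng):
        se = SEBlock(8, rng=rng)
        with no_grad():
            out = se(Tensor(np.zeros((1, 8, 3, 3), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_excitation_halves_channels(self, rng):
        se = SEBlock(8, rng=rng)
        se.fc1.weight.data[:] = 0
        se.fc2.weight.data[:] = 0
        x = rng.standard_normal((2, 8, 3, 3)).astype(np.float32)
        with no_grad():
            out = se(Tensor(x)).data
        np.testing.assert_allclose(out, 0.5 * x, rtol=1e-6)

    def test_matches_scalar_path_oracle(self, rng):
        se = SEBlock(8, reduction=4, rng=rng)
        x = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
        with no_grad():
            out = se(Tensor(x)).data
        for b in range(2):
            pooled = x[b].mean(axis=(1, 2))
            h = np.maximum(pooled @ se.fc1.weight.data + se.fc1.bias.data, 0)
            s = 1 / (1 + np.exp(-(h @ se.fc2.weight.data + se.fc2.bias.data)))
            np.testing.assert_allclose(out[b], x[b] * s[:, None, None],
                                       rtol=1e-4, atol=1e-6)


class TestASPP:
    def test_branch_count_and_shape(self, rng):
        aspp = ASPP(6, 8, rates=(1, 2, 3), rng=rng).eval()
        assert aspp.project.conv.in_channels == 8 * (3 + 2)
        x = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        with no_grad():
            out = aspp(Tensor(x))
        assert out.shape == (2, 8, 8, 8)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ASPP(4, 4, rates=(0,), rng=rng)

    def test_constant_preserved_by_averaging_kernels(self, rng):
        """With every kernel an averaging filter (and identity BN) a constant
        input stays constant through all branches and the projection."""
        aspp = ASPP(3, 4, rates=(1,), rng=rng).eval()
        for mod in (aspp.branch1, aspp.dilated[0], aspp.pool_conv,
                    aspp.project):
            w = mod.conv.weight
            fan = np.prod(w.data.shape[1:])
            w.data[:] = 1.0 / fan
        x = np.full((1, 3, 6, 6), 0.7, dtype=np.float32)
        with no_grad():
            out = aspp(Tensor(x)).data
        # interior only: zero padding perturbs the one-pixel border
        np.testing.assert_allclose(out[:, :, 1:-1, 1:-1], 0.7, rtol=1e-4)

    def test_dilated_branch_impulse_response(self, rng):
        """A dilation-r convolution of a centered impulse reproduces the
        kernel at spacing r — verified against an explicit loop."""
        r = 2
        x = np.zeros((1, 1, 9, 9), dtype=np.float32)
        x[0, 0, 4, 4] = 1.0
        w = rng.standard_normal((1, 1, 3, 3)).astype(np.float32)
        out = conv2d(Tensor(x), Tensor(w), padding=r, dilation=r).data[0, 0]
        ref = np.zeros((9, 9))
        for i in range(3):
            for j in range(3):
                rr, cc = 4 + (1 - i) * r, 4 + (1 - j) * r
                ref[rr, cc] = w[0, 0, i, j]  # flipped: cross-correlation
        np.testing.assert_allclose(out, ref, atol=1e-6)
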