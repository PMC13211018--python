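"""Frequency decoupling identities, the high-frequency branch, CPE and the
full MFDA block."""

import numpy as np
import pytest

from mfda_unet import BlockParams, CPE, FDMela, HighFreqBranch, MFDABlock
from mfda_unet import engine as eg
from mfda_unet import freq_decouple, naive_attention_oracle
from mfda_unet.attention_core import (AttentionTriplet, kernel_map, lepe,
                                      map_to_tokens, tokens_to_map)
from mfda_unet.engine import Tensor, box_filter3, zero_learned_weights


class TestFreqDecouple:
    def test_constant_input_dc_rejection(self):
        """Constants pass to the low branch untouched; high is exactly 0,
        borders included."""
        x = np.full((2, 36, 8), 0.37)
        pair = freq_decouple(x, (6, 6))
        np.testing.assert_array_equal(pair.low, x[:, :, :4])
        np.testing.assert_array_equal(pair.high, 0.0)

    def test_reconstruction_identity(self, rng):
        """high is the float-exact difference half2 - AvgPool(half2)."""
        x = rng.standard_normal((2, 36, 8))
        pair = freq_decouple(x, (6, 6))
        half2 = tokens_to_map(x[:, :, 4:], (6, 6))
        pool = box_filter3(Tensor(half2)).data
        high = tokens_to_map(pair.high, (6, 6))
        np.testing.assert_array_equal(high, half2 - pool)
        # re-adding the smoothed part recovers half2 to machine precision
        np.testing.assert_allclose(high + pool, half2, rtol=0, atol=1e-14)

    def test_checkerboard_high_frequency(self):
        """+-1 checkerboard: interior 3x3 averages are +-1/9, so the high
        component is +-8/9 there."""
        size = 5
        board = (-1.0) ** (np.add.outer(np.arange(size), np.arange(size)))
        tokens = np.tile(board.reshape(1, size * size, 1), (1, 1, 2))
        pair = freq_decouple(tokens, (size, size))
        high = pair.high[0, :, 0].reshape(size, size)
        np.testing.assert_allclose(high[1:-1, 1:-1],
                                   board[1:-1, 1:-1] * 8.0 / 9.0, rtol=1e-12)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            freq_decouple(rng.standard_normal((1, 4, 3)), (2, 2))


class TestHighFreqBranch:
    def test_constant_input_collapses_to_bias_path(self, rng):
        """InstanceNorm maps constants to exactly zero, so only the conv
        biases survive."""
        eg.manual_seed(0)
        hb = HighFreqBranch(4)
        x = np.full((1, 16, 4), 2.5)
        out = hb(Tensor(x), (4, 4)).data
        silu = lambda a: a / (1.0 + np.exp(-a))
        bias_resp = silu(hb.dwconv.bias.data)  # constant over space
        want = bias_resp @ hb.proj.weight.data[:, :, 0, 0].T + hb.proj.bias.data
        np.testing.assert_allclose(out, np.broadcast_to(want, out.shape),
                                   rtol=1e-10)

    def test_matches_stepwise_composition(self, rng):
        eg.manual_seed(3)
        hb = HighFreqBranch(4)
        x = rng.standard_normal((2, 16, 4))
        got = hb(Tensor(x), (4, 4)).data
        m = tokens_to_map(x, (4, 4))
        mu = m.mean(axis=(2, 3), keepdims=True)
        var = ((m - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        normed = (m - mu) / np.sqrt(var + 1e-5)
        conv = eg.conv2d(Tensor(normed), hb.dwconv.weight, hb.dwconv.bias,
                         padding=2, groups=4).data
        act = conv / (1.0 + np.exp(-conv))
        proj = eg.conv2d(Tensor(act), hb.proj.weight, hb.proj.bias).data
        want, _ = map_to_tokens(proj)
        np.testing.assert_allclose(got, want, rtol=1e-8)


class TestCPE:
    def test_zero_weights_identity(self, rng):
        cpe = CPE(3)
        cpe.dwconv.weight.data[...] = 0.0
        cpe.dwconv.bias.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 9, 3)))
        np.testing.assert_array_equal(cpe(x, (3, 3)).data, x.data)

    def test_delta_kernel_doubles_input(self, rng):
        cpe = CPE(3)
        cpe.dwconv.weight.data[...] = 0.0
        cpe.dwconv.weight.data[:, 0, 1, 1] = 1.0
        cpe.dwconv.bias.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 9, 3)))
        np.testing.assert_allclose(cpe(x, (3, 3)).data, 2 * x.data, rtol=1e-12)

    def test_single_pixel_spatial(self, rng):
        """On a 1x1 map only the centre tap and bias act: x + w_c x + b."""
        eg.manual_seed(5)
        cpe = CPE(2)
        x = rng.standard_normal((1, 1, 2))
        got = cpe(Tensor(x), (1, 1)).data
        w_c = cpe.dwconv.weight.data[:, 0, 1, 1]
        want = x + w_c * x + cpe.dwconv.bias.data
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestFDMela:
    def test_fusion_masking_isolates_low_path(self, rng):
        """Fusion = identity on the low half, zero on the high half, and
        the output reduces to the MELA path alone."""
        eg.manual_seed(11)
        p = BlockParams(channels=8)
        mod = FDMela(p).eval()
        C = 8
        mod.fuse.weight.data[...] = 0.0
        mod.fuse.weight.data[:C // 2, :C // 2] = np.eye(C // 2)
        mod.fuse.bias.data[...] = 0.0
        x = rng.standard_normal((1, 16, 8))
        got = mod(Tensor(x), (4, 4)).data
        pair = freq_decouple(x, (4, 4))
        low = mod.cpe_low(Tensor(pair.low), (4, 4))
        want = np.zeros_like(got)
        want[:, :, :C // 2] = mod.mela(low, (4, 4)).data
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-10)

    def test_matches_stepwise_composition(self, rng):
        eg.manual_seed(13)
        p = BlockParams(channels=8)
        mod = FDMela(p).eval()
        x = rng.standard_normal((1, 64, 8))
        got = mod(Tensor(x), (8, 8)).data
        pair = freq_decouple(x, (8, 8))
        low = mod.cpe_low(Tensor(pair.low), (8, 8))
        low_out = mod.mela(low, (8, 8)).data
        high_out = mod.high_branch(Tensor(pair.high), (8, 8)).data
        cat = np.concatenate([low_out, high_out], axis=-1)
        want = cat @ mod.fuse.weight.data + mod.fuse.bias.data
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_without_fd_has_more_parameters(self):
        """Attention over all C channels costs strictly more parameters
        than the split variant at equal width."""
        for C in (8, 16, 32):
            eg.manual_seed(0)
            with_fd = FDMela(BlockParams(channels=C)).num_parameters()
            eg.manual_seed(0)
            without = FDMela(BlockParams(channels=C,
                                         frequency_decoupling=False)
                             ).num_parameters()
            assert without > with_fd


class TestMFDABlock:
    def test_residual_skeleton_identity(self, rng):
        """All learned weights zeroed -> the block is the identity map."""
        eg.manual_seed(17)
        blk = MFDABlock(BlockParams(channels=8)).eval()
        zero_learned_weights(blk)
        x = rng.standard_normal((2, 16, 8))
        out = blk(Tensor(x), (4, 4)).data
        assert np.max(np.abs(out - x)) < 1e-6

    def test_drop_path_one_leaves_cpe_only(self, rng):
        """With both residual branches dropped, only the CPE step acts."""
        eg.manual_seed(19)
        blk = MFDABlock(BlockParams(channels=8, drop_path=0.0))
        blk.drop_path1 = eg.DropPath(1.0)
        blk.drop_path2 = eg.DropPath(1.0)
        blk.mixer.mela.drop_path = eg.DropPath(0.0)
        blk.train()
        x = rng.standard_normal((1, 16, 8))
        got = blk(Tensor(x), (4, 4)).data
        want = blk.cpe(Tensor(x), (4, 4)).data
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_matches_equation_by_equation_recomputation(self, rng):
        eg.manual_seed(23)
        blk = MFDABlock(BlockParams(channels=8)).eval()
        x = rng.standard_normal((1, 16, 8))
        got = blk(Tensor(x), (4, 4)).data
        x1 = x + blk.mixer(blk.norm1(Tensor(x)), (4, 4)).data
        x2 = blk.cpe(Tensor(x1), (4, 4)).data
        mlp = blk.mlp(blk.norm2(Tensor(x2))).data
        want = x2 + mlp
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_gradients_reach_every_parameter(self, rng):
        eg.manual_seed(29)
        blk = MFDABlock(BlockParams(channels=8)).train()
        x = Tensor(rng.standard_normal((2, 16, 8)))
        loss = eg.tsum(blk(x, (4, 4)) ** 2)
        loss.backward()
        for name, p in blk.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.all(np.isfinite(p.grad)), f"non-finite grad for {name}"

    def test_invalid_block_params_rejected(self):
        with pytest.raises(ValueError):
            BlockParams(channels=7)
        with pytest.raises(ValueError):
            BlockParams(channels=8, drop_path=1.0)
        with pytest.raises(ValueError):
            BlockParams(channels=8, mlp_ratio=0)
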