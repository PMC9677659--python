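"""Convolutional encoder: GELU/LN closed forms, depthwise isolation,
residual blocks, length preservation, parameter arithmetic."""

import numpy as np
import pytest
from scipy.stats import norm

from convner import ConvStageConfig, count_parameters, gelu, layer_norm
from convner.autograd import Tensor
from convner.convnet import (Conv1d, ConvBlock, ConvEncoder, DepthwiseConv,
                             DownsampleLayer, depthwise_param_count,
                             standard_conv_param_count)

REDUCED = ConvStageConfig(channels=(16, 32, 64, 128))


class TestGelu:
    def test_zero_and_limits(self):
        assert gelu(np.array(0.0)) == 0.0
        assert np.isclose(gelu(np.array(30.0)), 30.0)
        assert np.isclose(gelu(np.array(-30.0)), 0.0)

    def test_known_value(self):
        # x * Phi(x) at x = 1
        assert abs(gelu(np.array(1.0)) - 0.841345) < 1e-6

    def test_matches_normal_cdf_oracle_on_grid(self):
        x = np.linspace(-8, 8, 10_000)
        assert np.max(np.abs(gelu(x) - x * norm.cdf(x))) < 1e-6

    def test_tensor_gradient_matches_finite_difference(self, rng):
        x = rng.standard_normal(50)
        t = Tensor(x, requires_grad=True)
        t.gelu().sum().backward()
        eps = 1e-6
        num = (gelu(x + eps) - gelu(x - eps)) / (2 * eps)
        assert np.max(np.abs(num - t.grad)) < 1e-8


class TestLayerNorm:
    def test_constant_vector_maps_to_zero(self):
        assert np.allclose(layer_norm(np.full(16, 3.7)), 0.0)

    def test_hand_case(self):
        # E = 0, Var = 1 -> unchanged at eps = 0
        assert np.allclose(layer_norm(np.array([1.0, -1.0]), eps=0.0), [1.0, -1.0])

    def test_mean_zero_variance_one(self, rng):
        x = rng.standard_normal(64) * 5 + 2
        y = layer_norm(x, eps=1e-6)
        assert abs(y.mean()) < 1e-6
        assert 1 - 1e-3 <= y.var() <= 1.0


class TestDepthwiseConv:
    def test_identity_kernels(self, rng):
        dw = DepthwiseConv(4, 3, rng)
        dw.weight.data[:] = 0.0
        dw.weight.data[1, 1, :] = 1.0  # centre tap
        x = rng.standard_normal((2, 6, 4))
        assert np.allclose(dw(Tensor(x)).data, x)

    def test_channel_isolation(self, rng):
        dw = DepthwiseConv(4, 7, rng)
        x = rng.standard_normal((1, 10, 4))
        base = dw(Tensor(x)).data
        x2 = x.copy()
        x2[0, :, 0] += rng.standard_normal(10)
        pert = dw(Tensor(x2)).data
        assert np.allclose(base[..., 1:], pert[..., 1:])
        assert not np.allclose(base[..., 0], pert[..., 0])

    def test_parameter_arithmetic(self):
        assert depthwise_param_count(7, 128) == 6272
        # depthwise is 1/N of a standard convolution, for several (M, N, Dk)
        for m, n, dk in [(4, 8, 3), (16, 32, 7), (64, 4, 5)]:
            assert depthwise_param_count(dk, m) * n == standard_conv_param_count(dk, m, n)

    def test_weight_tensor_carries_full_2d_count(self, rng):
        dw = DepthwiseConv(128, 7, rng)
        assert dw.weight.data.size == 6272


class TestConvBlock:
    def test_residual_passthrough_at_zero_weights(self, rng):
        blk = ConvBlock(8, REDUCED, rng)
        for lin in (blk.pw1, blk.pw2):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        blk.dw.weight.data[:] = 0.0
        blk.dw.bias.data[:] = 0.0
        x = rng.standard_normal((2, 10, 8))
        assert np.allclose(blk(Tensor(x)).data, x)

    def test_shape_preserved(self, rng):
        blk = ConvBlock(16, REDUCED, rng)
        out = blk(Tensor(rng.standard_normal((1, 10, 16))))
        assert out.shape == (1, 10, 16)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic gradient of a scalar functional of the block output
        agrees with central differences for every parameter (3 x 8 map)."""
        blk = ConvBlock(8, ConvStageConfig(channels=(8, 8, 8, 8),
                                           block_dw_kernel=3), rng)
        x = rng.standard_normal((1, 3, 8))
        w = rng.standard_normal((1, 3, 8))  # fixed probe direction

        def objective():
            return float((blk(Tensor(x)).data * w).sum())

        out = blk(Tensor(x))
        (out * Tensor(w)).sum().backward()
        eps = 1e-6
        for p in blk.parameters():
            g = np.zeros_like(p.data) if p.grad is None else p.grad
            flat = p.data.reshape(-1)
            idxs = np.linspace(0, flat.size - 1, min(10, flat.size)).astype(int)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = objective()
                flat[i] = orig - eps
                down = objective()
                flat[i] = orig
                num = (up - down) / (2 * eps)
                assert abs(num - g.reshape(-1)[i]) < 1e-4


class TestDownsample:
    def test_widens_channels_keeps_length(self, rng):
        ds = DownsampleLayer(128, 256, ConvStageConfig(), rng)
        out = ds(Tensor(rng.standard_normal((1, 10, 128))))
        assert out.shape == (1, 10, 256)

    @pytest.mark.parametrize("L", [1, 2, 9])
    def test_stride_one_any_length(self, rng, L):
        ds = DownsampleLayer(4, 8, REDUCED, rng)
        assert ds(Tensor(rng.standard_normal((1, L, 4)))).shape == (1, L, 8)


class TestEncoder:
    @pytest.mark.parametrize("L", [1, 7, 20])
    def test_spliced_output_width(self, rng, L):
        enc = ConvEncoder(16, REDUCED, rng)
        out = enc(Tensor(rng.standard_normal((1, L, 16))),
                  np.ones((1, L), dtype=bool))
        assert out.shape == (1, L, 16 + 32 + 64 + 128)

    def test_block_count(self, rng):
        enc = ConvEncoder(8, REDUCED, rng)
        assert sum(len(s) for s in enc.stages) == 18 == REDUCED.n_blocks

    def test_closed_form_count_matches_instantiation(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            cfg = ConvStageConfig(
                depths=tuple(int(d) for d in r.integers(0, 4, size=3)),
                channels=tuple(int(c) for c in r.integers(2, 12, size=3)),
                block_dw_kernel=int(r.choice([3, 5, 7])),
                expansion=int(r.integers(1, 5)),
            )
            d_in = int(r.integers(2, 10))
            enc = ConvEncoder(d_in, cfg, rng)
            assert enc.n_parameters() == count_parameters(cfg, d_in), cfg
        enc = ConvEncoder(16, REDUCED, rng)
        assert enc.n_parameters() == count_parameters(REDUCED, 16)

    def test_zero_depth_stack_is_stem_only(self, rng):
        cfg = ConvStageConfig(depths=(0, 0, 0, 0), channels=(8, 16, 32, 64))
        enc = ConvEncoder(4, cfg, rng)
        stem_count = (cfg.stem_kernel * 4 * 8 + 8) + 2 * 8
        assert enc.n_parameters() == count_parameters(cfg, 4) == stem_count
        out = enc(Tensor(rng.standard_normal((1, 5, 4))), np.ones((1, 5), bool))
        assert out.shape == (1, 5, 8)

    def test_padding_cannot_leak_into_real_positions(self, rng):
        """Perturbing values at masked cells leaves unmasked outputs unchanged."""
        enc = ConvEncoder(6, ConvStageConfig(depths=(1, 1, 1, 1),
                                             channels=(4, 4, 4, 4)), rng)
        mask = np.zeros((1, 8), dtype=bool)
        mask[0, :5] = True
        x = rng.standard_normal((1, 8, 6))
        base = enc(Tensor(x), mask).data
        x2 = x.copy()
        x2[0, 5:, :] = 100.0  # garbage in the padding
        pert = enc(Tensor(x2), mask).data
        assert np.allclose(base[0, :5], pert[0, :5])

    def test_even_kernel_length_one_input(self, rng):
        conv = Conv1d(3, 5, 4, rng)
        assert conv(Tensor(rng.standard_normal((1, 1, 3)))).shape == (1, 1, 5)
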