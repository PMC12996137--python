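"""Network architecture: attention oracles, shapes, residual identities,
and finite-difference verification of the hand-written backward passes."""

import numpy as np
import pytest

from cmbseg.loss import LossConfig, total_loss
from cmbseg.network import (
    AttentionGate,
    ChannelAttention,
    NetworkConfig,
    RLKBlock,
    RLKUNet,
    SpatialAttention,
)
from cmbseg.nn.ops import conv2d, conv2d_backward, upsample2, upsample2_backward

from conftest import numerical_gradient


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestConvPrimitive:
    @pytest.mark.parametrize("k,stride", [(1, 1), (3, 1), (3, 2), (7, 1), (13, 1)])
    def test_gradients_match_finite_differences(self, k, stride):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
        w = (rng.standard_normal((3, 2, k, k)) * 0.3).astype(np.float32)
        b = (rng.standard_normal(3) * 0.1).astype(np.float32)
        cache = {}
        y = conv2d(x, w, b, stride, cache)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx, dw, db = conv2d_backward(x, w, dy, stride, cache)

        def loss():
            return float((conv2d(x, w, b, stride) * dy).sum())

        for ana, arr in [(dx, x), (dw, w), (db, b)]:
            num = numerical_gradient(loss, arr, eps=1e-3)
            assert np.abs(ana - num).max() <= 2e-3 * max(1.0, np.abs(num).max())

    def test_same_padding_preserves_shape(self):
        x = np.zeros((1, 4, 32, 32), dtype=np.float32)
        w = np.zeros((4, 4, 13, 13), dtype=np.float32)
        assert conv2d(x, w).shape == (1, 4, 32, 32)

    def test_fft_and_direct_paths_agree(self):
        rng = np.random.default_rng(1)
        from cmbseg.nn.ops import _conv_fft_forward, _conv_im2col

        x = rng.standard_normal((2, 3, 12, 12)).astype(np.float32)
        w = rng.standard_normal((4, 3, 5, 5)).astype(np.float32)
        y_fft, _ = _conv_fft_forward(x, w)
        y_dir = _conv_im2col(x, w, 1)
        np.testing.assert_allclose(y_fft, y_dir, atol=1e-4)

    def test_upsample_adjoint_identity(self):
        # <up(x), y> == <x, up^T(y)> for random vectors: exact adjoint pair
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 2, 5, 7)).astype(np.float32)
        y = rng.standard_normal((1, 2, 10, 14)).astype(np.float32)
        lhs = float((upsample2(x) * y).sum())
        rhs = float((x * upsample2_backward(y)).sum())
        assert abs(lhs - rhs) < 1e-3


class TestChannelAttention:
    def test_zero_mlp_gives_half(self):
        rng = np.random.default_rng(0)
        ca = ChannelAttention(4, 2, rng, "ca")
        for p in (ca.w1, ca.b1, ca.w2, ca.b2):
            p.value[...] = 0.0
        mc = ca.attention(rng.standard_normal((2, 4, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(mc, 0.5, atol=1e-7)

    def test_constant_channels_make_pools_degenerate(self):
        rng = np.random.default_rng(0)
        ca = ChannelAttention(2, 1, rng, "ca")
        x = np.ones((1, 2, 4, 4), dtype=np.float32)
        x[0, 1] = 2.0  # spatially constant per channel
        v = np.array([[1.0, 2.0]], dtype=np.float32)
        h = np.maximum(v @ ca.w1.value + ca.b1.value, 0)
        expected = sigmoid(2.0 * (h @ ca.w2.value + ca.b2.value))
        np.testing.assert_allclose(ca.attention(x), expected, atol=1e-6)

    def test_hand_computed_oracle_2x2x2(self):
        # explicit arithmetic on a 2-channel 2x2 tensor with hand-set weights
        rng = np.random.default_rng(0)
        ca = ChannelAttention(2, 1, rng, "ca")
        ca.w1.value[...] = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        ca.b1.value[...] = 0.0
        ca.w2.value[...] = np.array([[2.0, 0.0], [0.0, -1.0]], dtype=np.float32)
        ca.b2.value[...] = np.array([0.5, -0.5], dtype=np.float32)
        x = np.array(
            [[[[1.0, 2.0], [3.0, 4.0]], [[-1.0, 0.0], [1.0, -2.0]]]], dtype=np.float32
        )
        avg = np.array([2.5, -0.5])
        mx = np.array([4.0, 1.0])

        def mlp(v):
            h = np.maximum(v, 0.0)  # identity w1
            return np.array([2.0 * h[0] + 0.5, -1.0 * h[1] - 0.5])

        expected = sigmoid(mlp(avg) + mlp(mx))
        np.testing.assert_allclose(ca.attention(x)[0], expected, atol=1e-6)

    def test_values_strictly_in_unit_interval(self):
        rng = np.random.default_rng(0)
        ca = ChannelAttention(8, 4, rng, "ca")
        mc = ca.attention(rng.standard_normal((3, 8, 5, 5)).astype(np.float32) * 10)
        assert np.all(mc > 0) and np.all(mc < 1)


class TestSpatialAttention:
    def test_zero_conv_gives_half(self):
        rng = np.random.default_rng(0)
        sa = SpatialAttention(7, rng, "sa")
        sa.conv.w.value[...] = 0.0
        sa.conv.b.value[...] = 0.0
        ms = sa.attention(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
        np.testing.assert_allclose(ms, 0.5, atol=1e-7)

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        sa = SpatialAttention(7, rng, "sa")
        x = rng.standard_normal((1, 5, 6, 6)).astype(np.float32)
        a = sa.attention(x)
        b = sa.attention(x[:, [3, 1, 4, 0, 2]])
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_hand_convolution_oracle(self):
        rng = np.random.default_rng(0)
        sa = SpatialAttention(7, rng, "sa")
        x = rng.standard_normal((1, 1, 3, 3)).astype(np.float32)
        ms = sa.attention(x)
        # single channel: avg == max == x; build the padded 2x3x3 input and
        # correlate with the 7x7 filter by explicit loops
        cat = np.concatenate([x, x], axis=1)[0]
        pad = np.pad(cat, ((0, 0), (3, 3), (3, 3)))
        w = sa.conv.w.value[0]
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                expected[i, j] = (pad[:, i : i + 7, j : j + 7] * w).sum() + sa.conv.b.value[0]
        np.testing.assert_allclose(ms[0, 0], sigmoid(expected), atol=1e-5)


class TestAttentionGate:
    def test_zero_weights_halve_skip(self):
        rng = np.random.default_rng(0)
        gate = AttentionGate(3, 2, rng, "g")
        for conv in (gate.theta, gate.phi, gate.psi):
            conv.w.value[...] = 0.0
            if conv.b is not None:
                conv.b.value[...] = 0.0
        skip = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        gating = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        out = gate.forward(skip, gating)
        np.testing.assert_allclose(out, 0.5 * skip, atol=1e-6)

    def test_hand_arithmetic_single_channel(self):
        rng = np.random.default_rng(0)
        gate = AttentionGate(1, 1, rng, "g")
        gate.theta.w.value[...] = 2.0
        gate.phi.w.value[...] = -1.0
        gate.phi.b.value[...] = 0.25
        gate.psi.w.value[...] = 1.5
        gate.psi.b.value[...] = -0.5
        skip = np.full((1, 1, 2, 2), 0.8, dtype=np.float32)
        gating = np.full((1, 1, 1, 1), 0.4, dtype=np.float32)
        # upsampled gating is constant 0.4; s = 2*0.8 + (-0.4 + 0.25) = 1.45
        alpha = sigmoid(1.5 * max(1.45, 0.0) - 0.5)
        np.testing.assert_allclose(gate.forward(skip, gating), 0.8 * alpha, atol=1e-6)

    def test_spatial_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        gate = AttentionGate(1, 1, rng, "g")
        with pytest.raises(ValueError):
            gate.forward(np.zeros((1, 1, 8, 8), np.float32), np.zeros((1, 1, 3, 3), np.float32))


class TestRLKBlock:
    def _block(self, rate=0.0):
        cfg = NetworkConfig(
            stage_channels=(4, 4, 4, 4), rlk_kernel=5,
            droppath_rates=(0, 0, 0, 0), blocks_per_stage=(1, 1, 1, 1),
        )
        return RLKBlock(4, cfg, rate, np.random.default_rng(0), "b")

    def test_droppath_rate_one_is_identity(self):
        blk = self._block(rate=1.0)
        x = np.random.default_rng(1).standard_normal((2, 4, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(
            blk.forward(x, train=True, rng=np.random.default_rng(0)), x
        )

    def test_zero_weights_are_identity(self):
        blk = self._block()
        blk.pw.w.value[...] = 0.0
        blk.pw.b.value[...] = 0.0
        x = np.random.default_rng(1).standard_normal((2, 4, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(blk.forward(x, False, None), x, atol=1e-7)


class TestRLKUNet:
    def test_output_shapes_64(self, micro_net):
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        shapes = [o.shape for o in micro_net.forward(x)]
        assert shapes == [(1, 1, 64, 64), (1, 1, 32, 32), (1, 1, 16, 16), (1, 1, 8, 8)]

    def test_indivisible_dims_rejected(self, micro_net):
        with pytest.raises(ValueError):
            micro_net.forward(np.zeros((1, 3, 60, 60), dtype=np.float32))

    def test_eval_forward_deterministic(self, micro_net):
        x = np.random.default_rng(0).standard_normal((2, 3, 16, 16)).astype(np.float32)
        a = micro_net.forward(x)
        b = micro_net.forward(x)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_cbam_ablation_changes_outputs_not_shapes(self, micro_net_cfg):
        from dataclasses import replace

        x = np.random.default_rng(0).standard_normal((1, 3, 16, 16)).astype(np.float32)
        on = RLKUNet(replace(micro_net_cfg, cbam_enabled_skips=frozenset({1, 2, 3})), seed=5)
        off = RLKUNet(replace(micro_net_cfg, cbam_enabled_skips=frozenset()), seed=5)
        yo, yf = on.forward(x), off.forward(x)
        assert [a.shape for a in yo] == [b.shape for b in yf]
        assert not np.allclose(yo[0], yf[0])

    def test_param_count_stable_function_of_config(self, micro_net_cfg):
        a = RLKUNet(micro_net_cfg, seed=0).n_params()
        b = RLKUNet(micro_net_cfg, seed=99).n_params()
        assert a == b
        assert "parameters" in RLKUNet(micro_net_cfg).summary()

    def test_attention_coefficients_strictly_in_unit_interval(self, micro_net):
        x = np.random.default_rng(3).standard_normal((1, 3, 16, 16)).astype(np.float32)
        micro_net.forward(x)
        for stage in (micro_net.dec1, micro_net.dec2, micro_net.dec3):
            alpha = stage.gate.coefficients()
            assert np.all(alpha > 0) and np.all(alpha < 1)
            mc = stage.cbam.channel._cache[-1]
            assert np.all(mc > 0) and np.all(mc < 1)

    def test_state_round_trip(self, micro_net_cfg):
        net = RLKUNet(micro_net_cfg, seed=7)
        x = np.random.default_rng(0).standard_normal((1, 3, 16, 16)).astype(np.float32)
        y0 = net.forward(x)[0]
        clone = RLKUNet(micro_net_cfg, seed=123)
        clone.set_state(net.get_state())
        np.testing.assert_array_equal(clone.forward(x)[0], y0)

    def test_full_backward_matches_finite_differences(self, micro_net):
        """Spot-check every parameter tensor of the full model against
        central differences through the composite Dice+Focal loss."""
        net = micro_net
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3, 16, 16)).astype(np.float32)
        y = (rng.random((2, 16, 16)) < 0.1).astype(np.float32)
        lcfg = LossConfig()

        def loss_fn():
            outs = net.forward(x, train=False)
            return total_loss([o[:, 0] for o in outs], y, lcfg)

        outs = net.forward(x, train=False)
        _, grads = total_loss([o[:, 0] for o in outs], y, lcfg, with_grad=True)
        net.zero_grad()
        net.backward([g[:, None] for g in grads])
        check_rng = np.random.default_rng(7)
        eps = 1e-4
        for p in net.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for i in check_rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                fp = loss_fn()
                flat[i] = orig - eps
                fm = loss_fn()
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                ana = gflat[i]
                assert abs(num - ana) <= 0.02 * max(1.0, abs(num), abs(ana)) + 2e-3, (
                    f"{p.name}[{i}]: numerical {num} vs analytic {ana}"
                )
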