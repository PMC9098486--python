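"""Architecture blocks: shape contracts, oracles and ablation switches."""

import numpy as np
import pytest

import meanet.tensor as T
from meanet.network import (DecodingBlock, EFEModule, EncodingBlock, MAGModule,
                            MEANet, NetworkConfig, SEBlock, efe_forward,
                            mag_aggregate)
from meanet.nn import ConvReLUBN
from meanet.tensor import Tensor

from oracles import loop_conv2d, loop_mag_aggregate, loop_se, loop_upsample2x

BN_EPS_SCALE = 1.0 / np.sqrt(1.0 + 1e-5)  # fresh eval-mode BN is this affine


def _zero_biases(module):
    for name, p in module.named_parameters():
        if name.endswith("bias") or name.endswith("beta"):
            p.data[...] = 0.0


class TestEncodingBlock:
    def test_output_channels_and_size_preserved(self, rng):
        block = EncodingBlock(3, 64, rng).eval()
        out = block(Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 64, 32, 32)

    def test_zeroed_residual_leaves_main_path(self, rng):
        block = EncodingBlock(2, 4, rng).eval()
        x = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        full = block(x).numpy()
        for p in block.residual.named_parameters():
            p[1].data[...] = 0.0
        main_only = block(x).numpy()
        main_direct = block.conv13(block.conv31(block.conv3(x))).numpy()
        np.testing.assert_allclose(main_only, main_direct, atol=1e-6)
        assert not np.allclose(full, main_only)  # residual did contribute

    def test_main_path_matches_loop_conv_oracle(self, rng):
        """Fixed tiny weights on a 1x4x4 input vs nested-loop convolution."""
        block = EncodingBlock(1, 2, rng).eval()
        x = rng.normal(size=(1, 4, 4)).astype(np.float32)
        got = block(Tensor(x[None])).numpy()[0]

        def crbn(inp, conv):
            pad = conv.padding
            out = loop_conv2d(inp, conv.weight.data, conv.bias.data, pad)
            return np.maximum(out, 0.0) * BN_EPS_SCALE

        main = crbn(crbn(crbn(x, block.conv3.conv), block.conv31.conv),
                    block.conv13.conv)
        res = crbn(x, block.residual.conv)
        np.testing.assert_allclose(got, main + res, rtol=1e-5, atol=1e-5)

    def test_nonpositive_out_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            EncodingBlock(3, 0, rng)


class TestEncoder:
    def test_stage_shapes_halve(self, rng):
        cfg = NetworkConfig(input_channels=3, stage_widths=(64, 128, 256, 512))
        net = MEANet(cfg, seed=0).eval()
        feats = net.encoder(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        assert feats["E1"].shape == (1, 64, 64, 64)
        assert feats["E2"].shape == (1, 128, 32, 32)
        assert feats["E3"].shape == (1, 256, 16, 16)
        assert feats["E4"].shape == (1, 512, 8, 8)

    def test_minimal_input_reaches_1x1(self, rng, tiny_cfg):
        net = MEANet(tiny_cfg, seed=0).eval()
        feats = net.encoder(Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32)))
        assert feats["E4"].shape[2:] == (1, 1)

    def test_indivisible_size_raises_naming_rule(self, rng, tiny_cfg):
        net = MEANet(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="divisible by 8"):
            net.encoder(Tensor(rng.normal(size=(1, 1, 60, 60)).astype(np.float32)))


class TestEFE:
    def test_stack_has_exactly_n_maps_at_e1_resolution(self, rng):
        cfg = NetworkConfig(input_channels=3)
        net = MEANet(cfg, seed=1).eval()
        feats = net.encoder(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        stack = net.efe(feats)
        assert stack.shape == (1, 16, 64, 64)

    def test_zeroed_x2_branch_leaves_x1_branch(self, rng):
        b1 = ConvReLUBN(2, 3, 3, rng).eval()
        b2 = ConvReLUBN(4, 3, 3, rng).eval()
        for _, p in b2.named_parameters():
            p.data[...] = 0.0
        x1 = rng.normal(size=(2, 4, 4)).astype(np.float32)
        x2 = rng.normal(size=(4, 2, 2)).astype(np.float32)
        out = efe_forward(x1, x2, b1, b2).numpy()
        np.testing.assert_allclose(out, b1(Tensor(x1[None])).numpy()[0], atol=1e-7)

    def test_matches_loop_conv_plus_upsample_oracle(self, rng):
        b1 = ConvReLUBN(1, 2, 3, rng).eval()
        b2 = ConvReLUBN(1, 2, 3, rng).eval()
        x1 = rng.normal(size=(1, 4, 4)).astype(np.float32)
        x2 = rng.normal(size=(1, 2, 2)).astype(np.float32)
        got = efe_forward(x1, x2, b1, b2).numpy()

        def crbn(inp, conv):
            out = loop_conv2d(inp, conv.weight.data, conv.bias.data, conv.padding)
            return np.maximum(out, 0.0) * BN_EPS_SCALE

        expected = crbn(x1, b1.conv) + loop_upsample2x(crbn(x2, b2.conv))
        np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-5)

    def test_resolution_other_than_double_rejected(self, rng):
        b = ConvReLUBN(1, 2, 3, rng)
        with pytest.raises(ValueError, match="half"):
            efe_forward(np.zeros((1, 4, 4), np.float32),
                        np.zeros((1, 3, 3), np.float32), b, b)

    def test_deep_stage_variants_restore_e1_resolution(self, rng):
        for stages in (("E1",), ("E3",), ("E1", "E2", "E3", "E4"), ("E2", "E4")):
            cfg = NetworkConfig(input_channels=1, stage_widths=(4, 8, 12, 16),
                                attention_maps=4, efe_stages=stages)
            net = MEANet(cfg, seed=0).eval()
            feats = net.encoder(Tensor(rng.normal(size=(1, 1, 16, 16)).astype(np.float32)))
            assert net.efe(feats).shape == (1, 4, 16, 16)


class TestMAG:
    def test_all_ones_attention_scales_by_n(self, rng):
        x1 = rng.normal(size=(4, 2, 2)).astype(np.float32)
        a = np.ones((16, 2, 2), dtype=np.float32)
        out = mag_aggregate(a, x1).numpy()
        np.testing.assert_allclose(out, 16.0 * x1, rtol=1e-6)

    def test_zero_attention_gives_zero(self, rng):
        out = mag_aggregate(np.zeros((3, 2, 2), np.float32),
                            rng.normal(size=(4, 2, 2)).astype(np.float32))
        np.testing.assert_array_equal(out.numpy(), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.normal(size=(3, 2, 2)).astype(np.float32)
        x1 = rng.normal(size=(4, 2, 2)).astype(np.float32)
        np.testing.assert_allclose(mag_aggregate(a, x1).numpy(),
                                   loop_mag_aggregate(a, x1), rtol=1e-5, atol=1e-6)

    def test_linearity_in_attention(self, rng):
        for _ in range(5):
            n, c, hw = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 4)
            a = rng.normal(size=(n, hw, hw)).astype(np.float32)
            x1 = rng.normal(size=(c, hw, hw)).astype(np.float32)
            np.testing.assert_allclose(mag_aggregate(2.5 * a, x1).numpy(),
                                       2.5 * mag_aggregate(a, x1).numpy(),
                                       rtol=1e-5, atol=1e-6)
            np.testing.assert_allclose(mag_aggregate(a, x1).numpy(),
                                       loop_mag_aggregate(a, x1),
                                       rtol=1e-4, atol=1e-5)

    def test_spatial_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            mag_aggregate(np.zeros((2, 3, 3), np.float32),
                          np.zeros((2, 4, 4), np.float32))

    def test_full_module_emits_one_channel_edge_logits(self, rng):
        cfg = NetworkConfig(input_channels=3)
        net = MEANet(cfg, seed=2).eval()
        x1 = Tensor(rng.normal(size=(1, 64, 16, 16)).astype(np.float32))
        a = Tensor(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        out = net.mag(a, x1)
        assert out.y2_logits.shape == (1, 1, 16, 16)
        assert out.y1.shape == (1, 64, 16, 16)

    def test_zero_features_depend_only_on_biases(self, rng):
        cfg = NetworkConfig(input_channels=1, stage_widths=(4, 8, 12, 16),
                            attention_maps=4, se_reduction=2)
        net = MEANet(cfg, seed=3).eval()
        _zero_biases(net.mag)
        a = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        out = net.mag(a, Tensor(np.zeros((1, 4, 8, 8), np.float32)))
        np.testing.assert_allclose(out.y1.numpy(), 0.0, atol=1e-7)
        np.testing.assert_allclose(out.y2_logits.numpy(), 0.0, atol=1e-7)


class TestSE:
    def test_constant_channel_squeezes_to_constant(self, rng):
        se = SEBlock(3, 2, rng)
        u = np.stack([np.full((4, 4), c, np.float32) for c in (1.0, -2.0, 0.5)])
        z = T.global_avg_pool(Tensor(u[None])).numpy()
        np.testing.assert_allclose(z[0], [1.0, -2.0, 0.5], rtol=1e-6)

    def test_zero_weights_gate_at_half(self, rng):
        se = SEBlock(4, 2, rng)
        se.reduce.weight.data[...] = 0.0
        se.expand.weight.data[...] = 0.0
        u = rng.normal(size=(1, 4, 3, 3)).astype(np.float32)
        out = se(Tensor(u)).numpy()
        np.testing.assert_allclose(out, 0.5 * u, rtol=1e-6)

    def test_matches_scalar_loop_oracle(self, rng):
        se = SEBlock(4, 2, rng)
        u = rng.normal(size=(4, 3, 3)).astype(np.float32)
        got = se(Tensor(u[None])).numpy()[0]
        expected, s = loop_se(u, se.reduce.weight.data, se.expand.weight.data)
        np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-6)
        assert np.all((s >= 0) & (s <= 1))

    def test_gates_bounded_and_unit_gate_is_identity(self, rng):
        se = SEBlock(6, 16, rng)  # reduction floors to width 1
        u = Tensor(rng.normal(size=(2, 6, 4, 4)).astype(np.float32) * 10)
        s = se.gates(u).numpy()
        assert np.all((s >= 0.0) & (s <= 1.0))
        # forcing s = 1 makes rescaling the identity
        ones = Tensor(np.ones_like(s).reshape(2, 6, 1, 1))
        np.testing.assert_array_equal((ones * u).numpy(), u.numpy())


class TestDecodingBlock:
    def test_resolution_contract(self, rng):
        block = DecodingBlock(64, 128, rng).eval()
        low = Tensor(rng.normal(size=(1, 64, 32, 32)).astype(np.float32))
        high = Tensor(rng.normal(size=(1, 128, 16, 16)).astype(np.float32))
        assert block(low, high).shape == (1, 64, 32, 32)

    def test_zero_high_branch_leaves_low_branch(self, rng):
        block = DecodingBlock(4, 8, rng).eval()
        _zero_biases(block)
        low = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        high = Tensor(np.zeros((1, 8, 4, 4), np.float32))
        np.testing.assert_allclose(block(low, high).numpy(),
                                   block.low_proj(low).numpy(), atol=1e-7)

    def test_gate_weights_in_unit_interval(self, rng):
        block = DecodingBlock(4, 8, rng).eval()
        high = Tensor((rng.normal(size=(2, 8, 4, 4)) * 50).astype(np.float32))
        w = block.gate_weights(high).numpy()
        assert np.all((w >= 0.0) & (w <= 1.0))

    def test_shape_mismatch_rejected(self, rng):
        block = DecodingBlock(4, 8, rng)
        with pytest.raises(ValueError, match="half"):
            block(Tensor(np.zeros((1, 4, 8, 8), np.float32)),
                  Tensor(np.zeros((1, 8, 8, 8), np.float32)))


class TestMEANet:
    def test_output_shapes_and_range(self, rng, tiny_cfg):
        net = MEANet(tiny_cfg, seed=0).eval()
        out = net(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
        assert out.seg_prob.shape == (1, 1, 64, 64)
        assert out.edge_prob.shape == (1, 1, 64, 64)
        for arr in (out.seg_prob.numpy(), out.edge_prob.numpy()):
            assert np.all((arr >= 0.0) & (arr <= 1.0))

    @pytest.mark.parametrize("hw", [(8, 8), (16, 8), (8, 24), (32, 16), (40, 40)])
    def test_shape_preserved_across_sizes(self, rng, tiny_cfg, hw):
        net = MEANet(tiny_cfg, seed=0).eval()
        out = net(rng.normal(size=(1, 1, *hw)).astype(np.float32))
        assert out.seg_prob.shape[2:] == hw

    def test_every_parameter_receives_gradient(self, rng, tiny_cfg):
        from meanet.losses import SupervisionBundle, joint_loss

        net = MEANet(tiny_cfg, seed=0).train()
        # accumulate over a few random batches: a ReLU may be dead for
        # one input, but a structurally connected branch never for all
        for k in range(3):
            x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
            g = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float32)
            out = net(x)
            total, _, _ = joint_loss(SupervisionBundle(out.seg_prob, g,
                                                       out.edge_prob, g))
            total.backward()
        dead = [n for n, p in net.named_parameters()
                if p.grad is None or np.abs(p.grad).max() == 0.0]
        assert dead == []

    def test_forward_is_deterministic_in_eval_mode(self, rng, tiny_cfg):
        net = MEANet(tiny_cfg, seed=7).eval()
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        a = net(x).seg_prob.numpy()
        b = net(x).seg_prob.numpy()
        np.testing.assert_array_equal(a, b)

    def test_same_seed_builds_identical_weights(self, tiny_cfg):
        n1 = MEANet(tiny_cfg, seed=11)
        n2 = MEANet(tiny_cfg, seed=11)
        for (k1, p1), (k2, p2) in zip(n1.named_parameters(), n2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)


class TestAblation:
    @pytest.mark.parametrize("use_efe,use_mag", [(False, False), (True, False),
                                                 (False, True), (True, True)])
    def test_all_flag_combinations_run(self, rng, use_efe, use_mag):
        cfg = NetworkConfig(input_channels=1, stage_widths=(4, 8, 12, 16),
                            attention_maps=4, se_reduction=2,
                            use_efe=use_efe, use_mag=use_mag)
        net = MEANet(cfg, seed=0).eval()
        out = net(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
        assert out.seg_prob.shape == (1, 1, 16, 16)
        if use_efe or use_mag:
            assert out.edge_prob is not None
        else:
            assert out.edge_prob is None

    def test_edge_module_parameter_parity(self):
        """With additive Y1 fusion, enabling the edge module adds exactly
        the edge module's parameters to the baseline count."""
        base = dict(input_channels=1, stage_widths=(4, 8, 12, 16),
                    attention_maps=4, se_reduction=2, y1_fusion="add")
        full = MEANet(NetworkConfig(**base), seed=0)
        baseline = MEANet(NetworkConfig(**base, use_efe=False, use_mag=False), seed=0)
        edge_params = sum(p.data.size for n, p in full.named_parameters()
                          if n.startswith(("efe.", "mag.")))
        assert full.n_parameters() - baseline.n_parameters() == edge_params

    def test_y1_fusion_modes_and_decoder_merge_modes(self, rng):
        for y1_fusion in ("concat", "add"):
            for merge in ("add", "concat"):
                cfg = NetworkConfig(input_channels=1, stage_widths=(4, 8, 12, 16),
                                    attention_maps=4, se_reduction=2,
                                    y1_fusion=y1_fusion, decoder_merge=merge)
                net = MEANet(cfg, seed=0).eval()
                out = net(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
                assert out.seg_prob.shape == (1, 1, 16, 16)
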