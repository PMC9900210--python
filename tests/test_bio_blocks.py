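"""Closed-form and loop-oracle tests for the encoder blocks."""

import numpy as np
import pytest

from dtamix.bio_blocks import (BioCNNBlock, BioCNNIndividual, BioMLPBlock,
                               BioMLPIndividual, DrugEncoder,
                               GlobalFeatureExtractor, ProteinEncoder,
                               SpatialAttention, affine)
from dtamix.config import load_config
from dtamix.nn import Tensor


def set_identity(linear):
    linear.weight.data = np.eye(*linear.weight.shape)
    linear.bias.data[:] = 0.0


def zero_conv(conv):
    conv.weight.data[:] = 0.0
    conv.bias.data[:] = 0.0


class TestAffine:
    def test_identity(self, rng):
        x = Tensor(rng.normal(size=(4, 3)))
        out = affine(x, np.ones(3), np.zeros(3))
        np.testing.assert_array_equal(out.data, x.data)

    def test_constant(self, rng):
        x = Tensor(rng.normal(size=(4, 3)))
        b = np.array([1.0, 2.0, 3.0])
        out = affine(x, np.zeros(3), b)
        np.testing.assert_array_equal(out.data, np.tile(b, (4, 1)))

    def test_elementwise_oracle(self, rng):
        x = rng.normal(size=(5, 4))
        out = affine(Tensor(x), np.full(4, 2.0), np.ones(4))
        # naive loop oracle
        expected = np.empty_like(x)
        for i in range(5):
            for c in range(4):
                expected[i, c] = 2.0 * x[i, c] + 1.0
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            affine(Tensor(rng.normal(size=(4, 3))), np.ones(2), np.zeros(2))


class TestGlobalFeatureExtractor:
    def test_zero_everything_gives_zero(self, rng):
        g = GlobalFeatureExtractor(4, 3, rng)
        for fc in (g.fc1, g.fc2, g.fc3):
            fc.weight.data[:] = 0.0
            fc.bias.data[:] = 0.0
        g.af_out.beta.data[:] = 0.0
        x = Tensor(np.zeros((1, 4, 3)))
        np.testing.assert_array_equal(g(x).data, 0.0)

    def test_identity_stack_doubles_input(self, rng):
        g = GlobalFeatureExtractor(4, 3, rng)
        for fc in (g.fc1, g.fc2, g.fc3):
            set_identity(fc)
        x = Tensor(np.abs(rng.normal(size=(2, 4, 3))))  # ReLU transparent
        np.testing.assert_allclose(g(x).data, 2 * x.data, atol=1e-12)

    def test_matches_matrix_oracle(self, rng):
        g = GlobalFeatureExtractor(4, 3, rng)
        g.af_in.alpha.data = rng.normal(size=3)
        g.af_in.beta.data = rng.normal(size=3)
        g.af_out.alpha.data = rng.normal(size=3)
        g.af_out.beta.data = rng.normal(size=3)
        x = rng.normal(size=(4, 3))
        out = g(Tensor(x[np.newaxis])).data[0]
        # explicit matrix oracle, length-axis mixing
        h = x * g.af_in.alpha.data + g.af_in.beta.data
        h = h.T  # C x L
        h = np.maximum(h @ g.fc1.weight.data + g.fc1.bias.data, 0)
        h = np.maximum(h @ g.fc2.weight.data + g.fc2.bias.data, 0)
        h = h @ g.fc3.weight.data + g.fc3.bias.data
        expected = x + (h.T * g.af_out.alpha.data + g.af_out.beta.data)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        g = GlobalFeatureExtractor(4, 3, rng)
        with pytest.raises(ValueError):
            g(Tensor(np.zeros((1, 5, 3))))


class TestSpatialAttention:
    def test_zero_conv_halves_input(self, rng):
        att = SpatialAttention(3, rng)
        zero_conv(att.conv)
        x = Tensor(rng.normal(size=(2, 5, 4)))
        np.testing.assert_allclose(att(x).data, 0.5 * x.data, atol=1e-12)

    def test_zero_input_gives_zero(self, rng):
        att = SpatialAttention(3, rng)
        np.testing.assert_array_equal(att(Tensor(np.zeros((1, 5, 4)))).data, 0.0)

    def test_matches_loop_oracle(self, rng):
        att = SpatialAttention(3, rng)
        x = rng.normal(size=(5, 4))
        out = att(Tensor(x[np.newaxis])).data[0]
        w = att.conv.weight.data[:, :, 0, 0]
        bias = att.conv.bias.data[0]
        gate = np.zeros_like(x)
        for l in range(5):
            for c in range(4):
                acc = bias
                for i in range(3):
                    for j in range(3):
                        li, cj = l + i - 1, c + j - 1
                        if 0 <= li < 5 and 0 <= cj < 4:
                            acc += w[i, j] * x[li, cj]
                gate[l, c] = 1.0 / (1.0 + np.exp(-acc))
        np.testing.assert_allclose(out, x * gate, atol=1e-10)


class TestBioMLPIndividual:
    def test_zero_input_zero_biases(self, rng):
        blk = BioMLPIndividual(4, 3, rng)
        for fc in (blk.fc_a, blk.fc_b, blk.fc_final):
            fc.bias.data[:] = 0.0
        zero_conv(blk.att.conv)
        blk.af_in.beta.data[:] = 0.0
        blk.af_out.beta.data[:] = 0.0
        out = blk(Tensor(np.zeros((1, 5, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_identity_sublayers_with_unit_gate(self, rng):
        # all FCs identity; gate saturated to ~1 by a large conv bias
        blk = BioMLPIndividual(4, 3, rng)
        for fc in (blk.fc_a, blk.fc_b, blk.fc_final):
            set_identity(fc)
        blk.att.conv.weight.data[:] = 0.0
        blk.att.conv.bias.data[:] = 500.0
        x = np.abs(rng.normal(size=(1, 5, 4)))
        out = blk(Tensor(x))
        np.testing.assert_allclose(out.data, 2 * x, atol=1e-9)

    def test_matches_composition_oracle(self, rng):
        blk = BioMLPIndividual(4, 3, rng)
        x = rng.normal(size=(6, 4))
        out = blk(Tensor(x[np.newaxis])).data[0]

        def lin(m, h):
            return h @ m.weight.data + m.bias.data

        def af(m, h):
            return h * m.alpha.data + m.beta.data

        h = af(blk.af_in, x)
        h = lin(blk.fc_b, np.maximum(lin(blk.fc_a, h), 0))
        h = af(blk.af_out, h)
        gated = blk.att(Tensor(h[np.newaxis])).data[0]
        expected = lin(blk.fc_final, x + gated)
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestBioCNNIndividual:
    def test_delta_kernels_identity_through_convs(self, rng):
        # centered delta kernels, batch norm bypassed via gamma/beta override
        blk = BioCNNIndividual(4, (3, 3, 3), 2, 3, rng)
        for conv in blk.convs:
            conv.weight.data[:] = 0.0
            mid = conv.kernel_size // 2
            for g in range(conv.groups):
                for i in range(2):
                    conv.weight.data[mid, g, i, i] = 1.0
            conv.bias.data[:] = 0.0
        x = np.abs(rng.normal(size=(2, 6, 4)))
        h = Tensor(x)
        for conv in blk.convs:
            h = conv(h)
        np.testing.assert_allclose(h.data, x, atol=1e-12)

    @pytest.mark.parametrize("kernel", [3, 7, 15])
    def test_length_preserved(self, rng, kernel):
        blk = BioCNNIndividual(4, (kernel,) * 3, 2, 3, rng)
        out = blk(Tensor(rng.normal(size=(1, 9, 4))))
        assert out.shape == (1, 9, 4)

    def test_groups_one_matches_naive_conv(self, rng):
        blk = BioCNNIndividual(8, (3, 3, 3), 1, 3, rng)
        conv = blk.convs[0]
        x = rng.normal(size=(1, 16, 8))
        out = conv(Tensor(x)).data[0]
        w = conv.weight.data[:, 0]  # (K, Cin, Cout)
        expected = np.zeros((16, 8))
        for l in range(16):
            for o in range(8):
                acc = conv.bias.data[o]
                for k in range(3):
                    src = l + k - 1
                    if 0 <= src < 16:
                        for i in range(8):
                            acc += x[0, src, i] * w[k, i, o]
                expected[l, o] = acc
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_channel_group_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            BioCNNIndividual(6, (3, 3, 3), 4, 3, rng)


class TestEncoders:
    def test_dn_one_equals_single_block(self, tiny_cfg, rng):
        enc = DrugEncoder(tiny_cfg, np.random.default_rng(0))
        assert len(enc.blocks) == tiny_cfg.dn == 1
        x = Tensor(rng.normal(size=(1, tiny_cfg.l_d, tiny_cfg.c_d)))
        np.testing.assert_array_equal(enc(x).data, enc.blocks[0](x).data)

    def test_published_shape_contract(self):
        # full-size configuration: 1200 x 100 protein map survives the stack
        cfg = load_config(preset="davis")
        rng = np.random.default_rng(0)
        block = BioCNNBlock(cfg.l_p, cfg.c_p, cfg.kernel_lk, cfg.conv_groups,
                            cfg.kernel_2d, rng)
        out = block(Tensor(rng.normal(size=(1, cfg.l_p, cfg.c_p))))
        assert out.shape == (1, 1200, 100)

    def test_stacking_preserves_shape(self, tiny_cfg):
        rng = np.random.default_rng(1)
        cfg = load_config(preset="desk", l_p=16, l_d=8, c_p=8, c_d=8, c_s=8,
                          pn=3, dn=2, kernel_lk=(3, 5, 7), kernel_2d=3,
                          conv_groups=2)
        penc = ProteinEncoder(cfg, rng)
        denc = DrugEncoder(cfg, rng)
        xp = Tensor(np.random.default_rng(2).normal(size=(2, 16, 8)))
        xd = Tensor(np.random.default_rng(3).normal(size=(2, 8, 8)))
        assert penc(xp).shape == (2, 16, 8)
        assert denc(xd).shape == (2, 8, 8)

    def test_gradient_reaches_every_parameter(self, rng):
        cfg = load_config(preset="desk", l_p=10, l_d=6, c_p=4, c_d=4, c_s=4,
                          kernel_lk=(3, 3, 3), kernel_2d=3, conv_groups=2)
        block = BioMLPBlock(cfg.l_d, cfg.c_d, cfg.kernel_2d,
                            np.random.default_rng(5))
        x = Tensor(rng.normal(size=(3, cfg.l_d, cfg.c_d)))
        loss = (block(x) ** 2).sum()
        loss.backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            assert np.any(p.grad != 0), f"dead parameter {name}"
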