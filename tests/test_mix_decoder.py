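"""Loop-oracle and closed-form tests for the interaction decoder."""

import numpy as np
import pytest

from dtamix import featurize as fz
from dtamix.config import load_config
from dtamix.mix_decoder import (AffinityHead, CrossAttend, DrugKernelSampler,
                                MixDecoder, SelfEnhance,
                                compute_response_vector, inject_adj_info,
                                inject_region_info, pool_interaction,
                                predict_binding_region)
from dtamix.nn import Tensor


def response_oracle(fp: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Naive double-loop correlation with zero padding (independent oracle)."""
    l, c = fp.shape
    half = c // 2
    s = np.zeros(l)
    for i in range(l):
        for m in range(c):
            src = i + m - half
            if 0 <= src < l:
                for n in range(c):
                    s[i] += k[m, n] * fp[src, n]
    return s


class TestDrugKernelSampler:
    def test_zero_weight_gives_zero(self, rng):
        sampler = DrugKernelSampler(5, 3, rng)
        sampler.weight.data[:] = 0.0
        out = sampler(Tensor(rng.normal(size=(1, 5, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_identity_weight_passthrough(self, rng):
        sampler = DrugKernelSampler(3, 3, rng)
        sampler.weight.data = np.eye(3)
        fd = rng.normal(size=(1, 3, 3))
        np.testing.assert_allclose(sampler(Tensor(fd)).data, fd, atol=1e-12)

    def test_matches_matrix_product(self, rng):
        sampler = DrugKernelSampler(5, 3, rng)
        fd = rng.normal(size=(1, 5, 3))
        expected = sampler.weight.data.T @ fd[0]
        np.testing.assert_allclose(sampler(Tensor(fd)).data[0], expected,
                                   atol=1e-12)

    def test_shape_mismatch(self, rng):
        sampler = DrugKernelSampler(5, 3, rng)
        with pytest.raises(ValueError):
            sampler(Tensor(np.zeros((1, 4, 3))))


class TestResponseVector:
    def test_zero_kernel(self, rng):
        s = compute_response_vector(Tensor(rng.normal(size=(8, 3))),
                                    Tensor(np.zeros((3, 3))))
        np.testing.assert_array_equal(s.data, 0.0)

    def test_delta_kernel_selects_channel(self, rng):
        fp = rng.normal(size=(8, 3))
        k = np.zeros((3, 3))
        k[1, 2] = 1.0  # center row (3//2 == 1), channel 2
        s = compute_response_vector(Tensor(fp), Tensor(k))
        np.testing.assert_allclose(s.data, fp[:, 2], atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        fp = rng.normal(size=(8, 3))
        k = rng.normal(size=(3, 3))
        s = compute_response_vector(Tensor(fp), Tensor(k))
        np.testing.assert_allclose(s.data, response_oracle(fp, k), atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_property_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(4, 20))
        c = int(rng.integers(2, 8))
        fp = rng.normal(size=(l, c))
        k = rng.normal(size=(c, c))
        s = compute_response_vector(Tensor(fp), Tensor(k))
        np.testing.assert_allclose(s.data, response_oracle(fp, k), atol=1e-6)

    def test_batched_equals_stacked(self, rng):
        fp = rng.normal(size=(3, 8, 4))
        k = rng.normal(size=(3, 4, 4))
        s = compute_response_vector(Tensor(fp), Tensor(k))
        for b in range(3):
            np.testing.assert_allclose(s.data[b], response_oracle(fp[b], k[b]),
                                       atol=1e-10)


class TestPredictBindingRegion:
    def test_one_hot_center(self):
        s = np.zeros(20)
        s[7] = 1.0
        assert predict_binding_region(s, 5) == (5, 10)

    def test_clipped_at_origin(self):
        s = np.zeros(20)
        s[0] = 1.0
        assert predict_binding_region(s, 15) == (0, 8)

    def test_clipped_at_end(self):
        s = np.zeros(10)
        s[9] = 1.0
        assert predict_binding_region(s, 6) == (6, 10)

    def test_tie_takes_smallest_index(self):
        s = np.ones(10)
        start, end = predict_binding_region(s, 4)
        assert start <= 0 + 2 and 0 >= start  # argmax at 0

    @pytest.mark.parametrize("seed", range(25))
    def test_contains_argmax_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=50)
        start, end = predict_binding_region(s, 10)
        c = int(np.argmax(s))
        assert start <= c < end
        assert end - start <= 10
        assert 0 <= start and end <= 50

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            predict_binding_region(np.zeros(5), 0)


class TestInjection:
    def test_region_identity_and_zero(self, rng):
        fp = Tensor(rng.normal(size=(6, 4)))
        np.testing.assert_array_equal(
            inject_region_info(fp, Tensor(np.ones(6))).data, fp.data)
        np.testing.assert_array_equal(
            inject_region_info(fp, Tensor(np.zeros(6))).data, 0.0)

    def test_region_rowwise_scaling_oracle(self, rng):
        fp = rng.normal(size=(6, 4))
        s = rng.normal(size=6)
        out = inject_region_info(Tensor(fp), Tensor(s)).data
        expected = np.array([[s[i] * fp[i, c] for c in range(4)]
                             for i in range(6)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_adj_identity_matrix(self, rng):
        xd = rng.normal(size=(5, 3))
        out = inject_adj_info(Tensor(xd), np.eye(5)).data
        np.testing.assert_allclose(out, xd / 5.0, atol=1e-12)

    def test_adj_all_ones(self, rng):
        xd = rng.normal(size=(5, 3))
        out = inject_adj_info(Tensor(xd), np.ones((5, 5))).data
        np.testing.assert_allclose(out, xd, atol=1e-12)

    def test_adj_ethanol_row_means(self, rng):
        _, adj, _ = fz.smiles_to_graph("CCO", 3)
        conn = adj.mean(axis=1)
        np.testing.assert_allclose(conn, [2 / 3, 1.0, 2 / 3])
        xd = rng.normal(size=(3, 2))
        out = inject_adj_info(Tensor(xd), adj).data
        np.testing.assert_allclose(out, xd * conn[:, None], atol=1e-12)


class TestSelfEnhance:
    def test_constant_input_uniform_gate(self, rng):
        se = SelfEnhance(3, rng)
        x = Tensor(np.ones((1, 5, 3)) * 2.7)
        np.testing.assert_allclose(se.gate(x).data, 1 / 5, atol=1e-12)

    def test_zero_mix_weight_gives_x_over_l(self, rng):
        se = SelfEnhance(3, rng)
        se.w1.data = np.eye(3)
        se.wm.data[:] = 0.0
        x = rng.normal(size=(1, 4, 3))
        np.testing.assert_allclose(se(Tensor(x)).data, x / 4, atol=1e-12)

    def test_matches_formula_oracle(self, rng):
        se = SelfEnhance(3, rng)
        x = rng.normal(size=(4, 3))
        out = se(Tensor(x[np.newaxis])).data[0]
        z = (x @ se.wm.data) / 3.0
        e = np.exp(z - z.max(axis=0))
        fa = e / e.sum(axis=0)
        np.testing.assert_allclose(out, (x @ se.w1.data) * fa, atol=1e-10)

    def test_gate_columns_sum_to_one(self, rng):
        se = SelfEnhance(4, rng)
        g = se.gate(Tensor(rng.normal(size=(2, 7, 4)))).data
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-6)


class TestCrossAttend:
    def test_zero_mix_pure_residual(self, rng):
        ca = CrossAttend(6, 3, rng)
        ca.wm1.data[:] = 0.0
        xp = rng.normal(size=(1, 4, 3))
        xd = rng.normal(size=(1, 2, 3))
        out = ca(Tensor(xp), Tensor(xd)).data[0]
        np.testing.assert_allclose(out, np.vstack([xp[0], xd[0]]), atol=1e-12)

    def test_identity_weights_unit_gate_doubles(self, rng):
        ca = CrossAttend(6, 3, rng)
        ca.wm1.data = np.eye(3)
        ca.wm2.data = np.eye(6)
        xp = rng.normal(size=(1, 4, 3))
        xd = rng.normal(size=(1, 2, 3))
        xm = np.vstack([xp[0], xd[0]])
        out = ca(Tensor(xp), Tensor(xd)).data[0]
        # with identity mixing, output = xm + xm * gate
        z = (xm @ ca.wm.data) / 3.0
        e = np.exp(z - z.max(axis=0))
        fa = e / e.sum(axis=0)
        np.testing.assert_allclose(out, xm + xm * fa, atol=1e-10)

    def test_matches_matrix_oracle(self, rng):
        ca = CrossAttend(6, 3, rng)
        xp = rng.normal(size=(1, 4, 3))
        xd = rng.normal(size=(1, 2, 3))
        out = ca(Tensor(xp), Tensor(xd)).data[0]
        xm = np.vstack([xp[0], xd[0]])
        mixed = ((xm @ ca.wm1.data).T @ ca.wm2.data).T
        z = (xm @ ca.wm.data) / 3.0
        e = np.exp(z - z.max(axis=0))
        fa = e / e.sum(axis=0)
        np.testing.assert_allclose(out, xm + mixed * fa, atol=1e-10)


class TestPooling:
    def test_all_ones(self):
        y = Tensor(np.ones((1, 7, 3)))
        v = pool_interaction(y)
        assert v.shape == (1, 10)
        np.testing.assert_allclose(v.data, 1.0, atol=1e-12)

    def test_published_interaction_length(self):
        cfg = load_config(preset="davis")
        assert cfg.interaction_dim == 1200 + 51 + 75 == 1326

    def test_matches_mean_by_loop(self, rng):
        y = rng.normal(size=(7, 3))
        v = pool_interaction(Tensor(y)).data
        expected = np.concatenate([
            [y[i].sum() / 3 for i in range(7)],
            [y[:, c].sum() / 7 for c in range(3)]])
        np.testing.assert_allclose(v, expected, atol=1e-12)


class TestAffinityHead:
    def test_zero_weights_zero_output(self, rng):
        head = AffinityHead(10, (4, 3), 0.0, rng)
        for fc in (head.fc1, head.fc2, head.fc3):
            fc.weight.data[:] = 0.0
            fc.bias.data[:] = 0.0
        out = head(Tensor(rng.normal(size=(2, 10))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_eval_mode_deterministic(self, rng):
        head = AffinityHead(10, (4, 3), 0.5, rng)
        head.eval()
        x = Tensor(rng.normal(size=(2, 10)))
        np.testing.assert_array_equal(head(x).data, head(x).data)

    def test_train_mode_seeded_masks_identical(self):
        x = Tensor(np.random.default_rng(4).normal(size=(2, 10)))
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            head = AffinityHead(10, (4, 3), 0.5, rng)
            outs.append(head(x).data)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestEndToEnd:
    def test_forward_finite_over_seeds(self, tiny_cfg):
        decoder = MixDecoder(tiny_cfg, np.random.default_rng(0))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fp = Tensor(rng.normal(size=(1, tiny_cfg.l_p, tiny_cfg.c_s)))
            fd = Tensor(rng.normal(size=(1, tiny_cfg.l_d, tiny_cfg.c_s)))
            adj = np.eye(tiny_cfg.l_d)
            pred, s = decoder(fp, fd, adj)
            assert np.all(np.isfinite(pred.data))
            assert np.all(np.isfinite(s.data))
            assert s.shape == (1, tiny_cfg.l_p)
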