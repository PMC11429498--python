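"""Layer oracles: every network operation against an independent
brute-force implementation, plus analytic SE checks, baseline reduction,
shape conservation and parameter-count economy."""

import numpy as np
import pytest

from abnet._autograd import Tensor, parameter
from abnet.graph import (
    NoiseConfig,
    build_skeleton_graph,
    partition_adjacency,
    sample_noise_matrix,
)
from abnet.network import (
    STGCN,
    ModelConfig,
    classify,
    conv1x1,
    mtcn,
    se_recalibrate,
    se_squeeze,
    spatial_graph_conv,
    temporal_conv,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the autograd implementation)
# ---------------------------------------------------------------------------

def oracle_graph_conv(x, partitions, weights, masks, noise=None):
    """Per-node summation loop for the spatial graph convolution."""
    N, C_in, T, V = x.shape
    C_out = weights[0].shape[0]
    out = np.zeros((N, C_out, T, V))
    for Ak, W, M in zip(partitions, weights, masks):
        mix = (Ak + (noise if noise is not None else 0.0)) * M
        for n in range(N):
            for t in range(T):
                for j in range(V):  # output joint
                    agg = np.zeros(C_in)
                    for i in range(V):  # input joint
                        agg += x[n, :, t, i] * mix[i, j]
                    out[n, :, t, j] += W @ agg
    return out


def oracle_squeeze(u):
    N, C, T, V = u.shape
    z = np.zeros((N, C))
    for n in range(N):
        for c in range(C):
            s = 0.0
            for t in range(T):
                for v in range(V):
                    s += u[n, c, t, v]
            z[n, c] = s / (T * V)
    return z


def oracle_se(u, w1, w2):
    z = oracle_squeeze(u)
    h = np.maximum(z @ w1.T, 0.0)
    s = 1.0 / (1.0 + np.exp(-(h @ w2.T)))
    return u * s[:, :, None, None], s


def oracle_dilated_conv(x, w, dilation, stride=1):
    """Explicit sliding-window sum with gaps, same padding."""
    N, C_in, T, V = x.shape
    C_out, _, K = w.shape
    out_len = -(-T // stride)
    pad_total = (K - 1) * dilation
    left = pad_total // 2
    out = np.zeros((N, C_out, out_len, V))
    for n in range(N):
        for v in range(V):
            for ot in range(out_len):
                for k in range(K):
                    t_in = ot * stride - left + k * dilation
                    if 0 <= t_in < T:
                        out[n, :, ot, v] += w[:, :, k] @ x[n, :, t_in, v]
    return out


def oracle_maxpool(x, window=3, stride=1):
    N, C, T, V = x.shape
    out_len = -(-T // stride)
    left = (window - 1) // 2
    out = np.full((N, C, out_len, V), -np.inf)
    for ot in range(out_len):
        for k in range(window):
            t_in = ot * stride - left + k
            if 0 <= t_in < T:
                out[:, :, ot, :] = np.maximum(out[:, :, ot, :], x[:, :, t_in, :])
    return out


def _rand_graph(rng, k):
    edges = [(i, j) for i in range(k) for j in range(i + 1, k) if rng.random() < 0.5]
    g = build_skeleton_graph(k, edges)
    partition_adjacency(g, "distance")
    return g


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestSpatialGraphConv:
    def test_matches_per_node_loop_oracle(self, rng):
        for trial in range(30):
            k = int(rng.integers(2, 6))
            g = _rand_graph(rng, k)
            C_in, C_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            N, T = 2, int(rng.integers(1, 6))
            x = rng.normal(size=(N, C_in, T, k))
            weights = [rng.normal(size=(C_out, C_in)) for _ in g.partitions]
            masks = [rng.normal(size=(k, k)) for _ in g.partitions]
            noise = rng.normal(size=(k, k)) if trial % 2 else None
            out = spatial_graph_conv(
                Tensor(x), g.partitions, [Tensor(w) for w in weights],
                [Tensor(m) for m in masks], noise,
            )
            expected = oracle_graph_conv(x, g.partitions, weights, masks, noise)
            np.testing.assert_allclose(out.value, expected, rtol=1e-5, atol=1e-8)

    def test_single_channel_identity_weight_is_adjacency_sum(self, rng):
        g = _rand_graph(rng, 4)
        uniform = partition_adjacency(g, "uniform")
        x = rng.normal(size=(2, 1, 3, 4))
        out = spatial_graph_conv(
            Tensor(x), uniform, [Tensor(np.eye(1))], [Tensor(np.ones((4, 4)))], None
        )
        expected = np.einsum("nctv,vw->nctw", x, uniform[0])
        np.testing.assert_allclose(out.value, expected, rtol=1e-10)

    def test_zero_input_zero_output(self, small_graph):
        x = np.zeros((1, 2, 4, 5))
        out = spatial_graph_conv(
            Tensor(x), small_graph.partitions,
            [Tensor(np.ones((2, 2)))] * 2, [Tensor(np.ones((5, 5)))] * 2, None,
        )
        np.testing.assert_array_equal(out.value, 0.0)

    def test_joint_mismatch_rejected(self, small_graph):
        x = np.zeros((1, 2, 4, 7))
        with pytest.raises(ValueError):
            spatial_graph_conv(
                Tensor(x), small_graph.partitions,
                [Tensor(np.ones((2, 2)))] * 2, [Tensor(np.ones((5, 5)))] * 2, None,
            )


class TestSqueezeExcitation:
    def test_squeeze_constant_map(self):
        u = np.full((2, 3, 4, 5), 7.0)
        np.testing.assert_allclose(se_squeeze(Tensor(u)).value, 7.0)

    def test_squeeze_2x2_worked_example(self):
        u = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
        assert se_squeeze(Tensor(u)).value[0, 0] == pytest.approx(2.5)

    def test_squeeze_matches_loop_oracle(self, rng):
        for _ in range(100):
            u = rng.normal(size=(2, int(rng.integers(1, 5)), int(rng.integers(1, 6)), 3))
            np.testing.assert_allclose(
                se_squeeze(Tensor(u)).value, oracle_squeeze(u), rtol=1e-10, atol=1e-12
            )

    def test_zero_weights_gate_half(self, rng):
        u = rng.normal(size=(2, 4, 3, 5))
        w1, w2 = np.zeros((2, 4)), np.zeros((4, 2))
        out = se_recalibrate(Tensor(u), Tensor(w1), Tensor(w2))
        np.testing.assert_allclose(out.value, 0.5 * u, rtol=1e-12)

    def test_gates_strictly_in_unit_interval(self, rng):
        # strict bounds hold for any finite weights; magnitudes kept where
        # float64 can still represent the strictness
        for _ in range(20):
            u = rng.normal(size=(2, 4, 3, 4))
            w1 = rng.normal(size=(2, 4))
            w2 = rng.normal(size=(4, 2))
            _, s = oracle_se(u, w1, w2)
            assert np.all(s > 0) and np.all(s < 1)

    def test_recalibrate_matches_direct_formula(self, rng):
        for _ in range(50):
            C = int(rng.integers(1, 4)) * 2
            u = rng.normal(size=(3, C, 4, 5))
            w1 = rng.normal(size=(C // 2, C))
            w2 = rng.normal(size=(C, C // 2))
            out = se_recalibrate(Tensor(u), Tensor(w1), Tensor(w2))
            expected, s = oracle_se(u, w1, w2)
            np.testing.assert_allclose(out.value, expected, rtol=1e-6, atol=1e-9)

    def test_se_never_amplifies(self, rng):
        u = rng.normal(size=(2, 6, 5, 4))
        w1 = rng.normal(size=(3, 6))
        w2 = rng.normal(size=(6, 3))
        out = se_recalibrate(Tensor(u), Tensor(w1), Tensor(w2))
        assert np.all(
            np.abs(out.value).max(axis=(2, 3)) <= np.abs(u).max(axis=(2, 3)) + 1e-12
        )


class TestTemporalConv:
    @pytest.mark.parametrize("dilation", [1, 2, 3, 4])
    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_direct_dilated_convolution(self, rng, dilation, stride):
        for _ in range(15):
            T = int(rng.integers(3, 9))
            C_in, C_out = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            x = rng.normal(size=(2, C_in, T, 3))
            w = rng.normal(size=(C_out, C_in, 3))
            out = temporal_conv(Tensor(x), Tensor(w), kernel=3, dilation=dilation, stride=stride)
            expected = oracle_dilated_conv(x, w, dilation, stride)
            np.testing.assert_allclose(out.value, expected, rtol=1e-6, atol=1e-9)

    def test_kernel9_matches_oracle(self, rng):
        x = rng.normal(size=(2, 3, 12, 4))
        w = rng.normal(size=(2, 3, 9))
        out = temporal_conv(Tensor(x), Tensor(w), kernel=9)
        np.testing.assert_allclose(
            out.value, oracle_dilated_conv(x, w, 1), rtol=1e-6, atol=1e-9
        )


class TestMtcn:
    def test_branch_width_is_one_sixth(self):
        # 192 working channels -> 32 per branch
        assert 192 // 6 == 32
        cfg = ModelConfig(channels=(192,), strides=(1,), mtcn_on=True)
        g = build_skeleton_graph(3, [(0, 1), (1, 2)])
        partition_adjacency(g, "distance")
        model = STGCN(cfg, g, seed=0)
        assert model.blocks[0].temporal.branch_conv1x1.value.shape == (32, 32)

    def test_stride1_preserves_length(self, rng):
        from abnet.network import MTCNLayer

        layer = MTCNLayer(6, 12, rng)
        x = Tensor(rng.normal(size=(2, 6, 50, 4)))
        assert layer(x, 1).value.shape == (2, 12, 50, 4)
        assert layer(x, 2).value.shape == (2, 12, 25, 4)

    def test_maxpool_branch_matches_oracle(self, rng):
        from abnet._autograd import maxpool_time

        for stride in (1, 2):
            x = rng.normal(size=(2, 3, 9, 4))
            out = maxpool_time(Tensor(x), 3, stride)
            np.testing.assert_allclose(out.value, oracle_maxpool(x, 3, stride))

    def test_full_mtcn_matches_branch_composition(self, rng):
        """MTCN output == entry conv, six explicit branches, concat, exit conv."""
        from abnet.network import MTCNLayer

        layer = MTCNLayer(6, 12, rng)
        x = rng.normal(size=(2, 6, 8, 3))
        out = layer(Tensor(x), 1)
        h = np.einsum("oc,nctv->notv", layer.entry.value, x)
        w = 2  # 12 // 6
        groups = [h[:, i * w : (i + 1) * w] for i in range(6)]
        branches = [
            np.einsum("oc,nctv->notv", layer.branch_conv1x1.value, groups[0]),
            oracle_maxpool(groups[1], 3, 1),
        ]
        for i, d in enumerate((1, 2, 3, 4)):
            branches.append(
                oracle_dilated_conv(groups[2 + i], layer.branch_dilated[i].value, d)
            )
        cat = np.concatenate(branches, axis=1)
        expected = np.einsum("oc,nctv->notv", layer.exit_w.value, cat)
        np.testing.assert_allclose(out.value, expected, rtol=1e-6, atol=1e-9)

    def test_indivisible_width_rejected(self, rng):
        from abnet.network import MTCNLayer

        with pytest.raises(ValueError):
            MTCNLayer(6, 16, rng)

    def test_fewer_parameters_than_kernel9(self):
        """The six-branch stage is cheaper than one kernel-9 conv at equal width."""
        from abnet.network import MTCNLayer, TemporalConvLayer

        rng = np.random.default_rng(0)
        for c in (12, 24, 48, 192):
            m = MTCNLayer(c, c, rng)
            k9 = TemporalConvLayer(c, c, 9, rng)
            n_m = sum(p.value.size for p in m.parameters())
            n_k9 = sum(p.value.size for p in k9.parameters())
            assert n_m < n_k9


class TestBlock:
    def _build_block(self, rng, cfg, c_in=4, c_out=6):
        from abnet.network import STGCNBlock

        g = _rand_graph(rng, 5)
        return STGCNBlock(c_in, c_out, 1, cfg, g, rng), g

    def test_block_equals_manual_composition(self, rng):
        cfg = ModelConfig(
            channels=(6,), strides=(1,), mtcn_on=True, se_on=True, noise_on=False,
            se_reduction=2, dtype="float64",
        )
        block, g = self._build_block(rng, cfg)
        x = rng.normal(size=(2, 4, 8, 5))
        out = block(Tensor(x), g.partitions, None, False)

        h = block.gcn(Tensor(x), g.partitions, None)
        h = block.bn1(h, False).relu()
        h = block.se(h)
        h = block.temporal(h, 1)
        h = block.bn2(h, False)
        res = block.res_bn(conv1x1(Tensor(x), block.res_conv, 1), False)
        expected = (h + res).relu()
        np.testing.assert_allclose(out.value, expected.value, rtol=1e-10)

    def test_identity_residual_when_shapes_match(self, rng):
        cfg = ModelConfig(channels=(6,), strides=(1,), mtcn_on=False, se_on=False,
                          noise_on=False, dtype="float64")
        from abnet.network import STGCNBlock

        g = _rand_graph(rng, 4)
        block = STGCNBlock(6, 6, 1, cfg, g, rng)
        assert block.res_conv is None

    def test_stride1_preserves_time_and_joints(self, rng):
        cfg = ModelConfig(channels=(6,), strides=(1,), mtcn_on=True, se_on=True,
                          noise_on=False, se_reduction=2)
        block, g = self._build_block(rng, cfg)
        out = block(Tensor(rng.normal(size=(2, 4, 10, 5)).astype(np.float32)),
                    g.partitions, None, False)
        assert out.value.shape == (2, 6, 10, 5)

    def test_seeded_noise_reproducible(self, rng):
        cfg = ModelConfig(channels=(6,), strides=(1,), mtcn_on=False, se_on=False,
                          noise_on=True, dtype="float64")
        block, g = self._build_block(rng, cfg)
        x = rng.normal(size=(2, 4, 8, 5))
        noise1 = sample_noise_matrix(g, NoiseConfig(sigma=0.1), np.random.default_rng(5))
        noise2 = sample_noise_matrix(g, NoiseConfig(sigma=0.1), np.random.default_rng(5))
        out1 = block(Tensor(x), g.partitions, noise1, False)
        out2 = block(Tensor(x), g.partitions, noise2, False)
        np.testing.assert_array_equal(out1.value, out2.value)


class TestBaselineReduction:
    def test_toggles_off_equals_noise_sigma_zero_bitwise(self):
        """σ=μ=0 noise and noise-off produce bit-identical forward passes."""
        g = build_skeleton_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        partition_adjacency(g, "distance")
        base = dict(channels=(8, 8), strides=(1, 1), num_classes=3,
                    se_on=False, mtcn_on=False, dtype="float64")
        m_off = STGCN(ModelConfig(noise_on=False, **base), g, seed=3)
        m_zero = STGCN(
            ModelConfig(noise_on=True, noise=NoiseConfig(mu=0.0, sigma=0.0), **base),
            g, seed=3,
        )
        for p, q in zip(m_off.parameters(), m_zero.parameters()):
            np.testing.assert_array_equal(p.value, q.value)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 10, 5, 1))
        m_off.train_mode()
        m_zero.train_mode()
        out_off = m_off.forward_embedding(x, rng=np.random.default_rng(1))
        out_zero = m_zero.forward_embedding(x, rng=np.random.default_rng(1))
        assert np.array_equal(out_off.value, out_zero.value)

    def test_vanilla_forward_matches_independent_reimplementation(self):
        """Toggles-off model == hand-written plain ST-GCN forward pass."""
        g = build_skeleton_graph(4, [(0, 1), (1, 2), (1, 3)])
        partition_adjacency(g, "distance")
        cfg = ModelConfig(channels=(6, 8), strides=(1, 2), num_classes=2,
                          noise_on=False, se_on=False, mtcn_on=False,
                          temporal_kernel=9, dtype="float64")
        m = STGCN(cfg, g, seed=1).eval_mode()
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 3, 12, 4, 1))

        def bn_eval(h, bn):
            C = h.shape[1]
            mu = bn.running_mean.reshape(1, C, 1, 1)
            inv = 1.0 / np.sqrt(bn.running_var + bn.eps).reshape(1, C, 1, 1)
            return (h - mu) * inv * bn.gamma.value.reshape(1, C, 1, 1) + bn.beta.value.reshape(1, C, 1, 1)

        h = np.moveaxis(x, 4, 1).reshape(3, 3, 12, 4)
        h = bn_eval(h, m.input_bn)
        for block in m.blocks:
            gc = np.zeros((h.shape[0], block.gcn.weights[0].value.shape[0], h.shape[2], h.shape[3]))
            for Ak, W, M in zip(g.partitions, block.gcn.weights, block.gcn.masks):
                agg = np.einsum("nctv,vw->nctw", h, Ak * M.value)
                gc += np.einsum("oc,nctv->notv", W.value, agg)
            gc = np.maximum(bn_eval(gc, block.bn1), 0.0)
            tc = oracle_dilated_conv(gc, block.temporal.weight.value, 1, block.stride)
            tc = bn_eval(tc, block.bn2)
            if block.res_conv is None:
                res = h
            else:
                res = np.einsum("oc,nctv->notv", block.res_conv.value, h)
                res = res[:, :, :: block.stride]
                res = bn_eval(res, block.res_bn)
            h = np.maximum(tc + res, 0.0)
        expected = h.mean(axis=(2, 3))
        got = m.forward_embedding(x).value
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)


class TestEncodeClassify:
    def test_eval_encode_deterministic(self, rng):
        g = build_skeleton_graph(4, [(0, 1), (1, 2), (2, 3)])
        cfg = ModelConfig(channels=(6,), strides=(1,), num_classes=2,
                          se_on=True, se_reduction=2, mtcn_on=True)
        m = STGCN(cfg, g, seed=0).eval_mode()
        x = rng.normal(size=(3, 3, 10, 4, 1))
        np.testing.assert_array_equal(m.encode(x), m.encode(x))

    def test_embedding_length_is_final_width(self, rng):
        g = build_skeleton_graph(3, [(0, 1), (1, 2)])
        cfg = ModelConfig(channels=(6, 12), strides=(1, 1), num_classes=2,
                          se_on=False, mtcn_on=True)
        m = STGCN(cfg, g, seed=0).eval_mode()
        emb = m.encode(rng.normal(size=(2, 3, 8, 3, 1)))
        assert emb.shape == (2, cfg.embedding_dim) == (2, 12)

    def test_batch_permutation_permutes_embeddings(self, rng):
        """Eval-mode encoding is per-clip: batching order cannot matter."""
        g = build_skeleton_graph(4, [(0, 1), (1, 2), (2, 3)])
        cfg = ModelConfig(channels=(6,), strides=(1,), num_classes=2,
                          se_on=True, se_reduction=2, mtcn_on=False, dtype="float64")
        m = STGCN(cfg, g, seed=0).eval_mode()
        x = rng.normal(size=(5, 3, 8, 4, 1))
        emb = m.encode(x)
        perm = np.array([3, 1, 4, 0, 2])
        emb_perm = m.encode(x[perm])
        np.testing.assert_allclose(emb_perm, emb[perm], rtol=1e-10)
        singles = np.concatenate([m.encode(x[i : i + 1]) for i in range(5)])
        np.testing.assert_allclose(singles, emb, rtol=1e-10)

    def test_classify_uniform_logits(self):
        emb = np.zeros((2, 4))
        w = np.zeros((3, 4))
        b = np.zeros(3)
        probs = classify(emb, w, b)
        np.testing.assert_allclose(probs, 1 / 3)

    def test_classify_normalized_and_argmax_consistent(self, rng):
        for _ in range(100):
            emb = rng.normal(size=(4, 6))
            w = rng.normal(size=(5, 6))
            b = rng.normal(size=5)
            probs = classify(emb, w, b)
            logits = emb @ w.T + b
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-9)
            assert np.all(probs >= 0)
            np.testing.assert_array_equal(probs.argmax(axis=1), logits.argmax(axis=1))

    def test_wrong_joint_count_rejected(self, rng):
        g = build_skeleton_graph(4, [(0, 1)])
        cfg = ModelConfig(channels=(6,), strides=(1,), se_on=False, mtcn_on=False)
        m = STGCN(cfg, g, seed=0)
        with pytest.raises(ValueError):
            m.encode(rng.normal(size=(1, 3, 8, 7, 1)))


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, tmp_path, rng):
        from abnet.network import load_checkpoint, save_checkpoint

        g = build_skeleton_graph(4, [(0, 1), (1, 2), (2, 3)])
        cfg = ModelConfig(channels=(6, 12), strides=(1, 2), num_classes=3,
                          se_on=True, se_reduction=2, mtcn_on=True)
        m = STGCN(cfg, g, seed=0).eval_mode()
        x = rng.normal(size=(2, 3, 10, 4, 1))
        before = m.encode(x)
        save_checkpoint(m, tmp_path / "model.npz")
        m2 = load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_array_equal(m2.encode(x), before)
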