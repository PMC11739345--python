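import numpy as np
import pytest

from eegmind.autodiff import Tensor
from eegmind.hgra import (Hierarchy, LevelGraph, alignment_loss, build_hierarchy,
                          hgra_forward, init_hgra_params, learn_adjacency,
                          level_graph_conv, pad_aggregate, pad_distribute,
                          pool_to_next_level, sym_normalized)


def _two_level(c=8):
    return [{i: (0 if i < c // 2 else 1) for i in range(c)}]


class TestBuildHierarchy:
    def test_two_level_partition(self):
        h = build_hierarchy(8, _two_level())
        assert h.L == 2
        assert h.levels[1].n_nodes == 2

    def test_empty_spec_single_level(self):
        h = build_hierarchy(8)
        assert h.L == 1

    def test_orphan_node_rejected(self):
        with pytest.raises(ValueError, match="orphan"):
            build_hierarchy(4, [{0: 0, 1: 0, 2: 1}])  # node 3 missing

    def test_region_adjacency_aggregated(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 2.0  # intra-group
        a[1, 2] = a[2, 1] = 3.0  # inter-group
        h = build_hierarchy(4, [{0: 0, 1: 0, 2: 1, 3: 1}], adjacency=a)
        up = h.levels[1].adjacency
        assert up[0, 1] == up[1, 0] == 3.0


class TestSymNormalization:
    def test_matches_dense_oracle_on_random_graphs(self, rng):
        # explicit D^{-1/2}(A+I)D^{-1/2} H W by loops, <= 10 nodes
        for _ in range(100):
            n = int(rng.integers(2, 11))
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            h = rng.standard_normal((n, 5))
            w = rng.standard_normal((5, 5))
            a_tilde = a + np.eye(n)
            d = a_tilde.sum(axis=1)
            expected = np.zeros((n, 5))
            for i in range(n):
                for j in range(n):
                    expected[i] += (
                        a_tilde[i, j] / np.sqrt(d[i] * d[j])
                    ) * (h[j] @ w)
            g = LevelGraph(1, n, a, None, embeddings=Tensor(h))
            out = level_graph_conv(g, [Tensor(w)], "identity")
            assert np.abs(out.data - expected).max() < 1e-10

    def test_self_loops_only_identity(self, rng):
        n = 4
        h = rng.standard_normal((n, 3))
        g = LevelGraph(1, n, np.zeros((n, n)), None, embeddings=Tensor(h))
        out = level_graph_conv(g, [Tensor(np.eye(3))], "identity")
        assert np.allclose(out.data, h, atol=1e-12)

    def test_symmetry_preserved_for_equal_inputs(self, rng):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        row = rng.standard_normal(3)
        g = LevelGraph(1, 2, a, None, embeddings=Tensor(np.stack([row, row])))
        out = level_graph_conv(g, [Tensor(np.eye(3))], "identity")
        assert np.allclose(out.data[0], out.data[1])

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sym_normalized(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestPooling:
    def _hier(self, emb):
        h = build_hierarchy(4, [{0: 0, 1: 0, 2: 1, 3: 1}])
        h.levels[0].embeddings = Tensor(emb)
        return h

    def test_mean_of_identical_children(self, rng):
        v = rng.standard_normal(3)
        h = self._hier(np.tile(v, (4, 1)))
        out = pool_to_next_level(h, 1, "mean")
        assert np.allclose(out.data, np.tile(v, (2, 1)))

    def test_max_of_one_hot_children(self):
        emb = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        h = self._hier(emb)
        out = pool_to_next_level(h, 1, "max")
        assert np.allclose(out.data, [[1, 1, 0], [0, 1, 1]])

    def test_uniform_attention_equals_mean(self, rng):
        emb = rng.standard_normal((4, 3))
        h1 = self._hier(emb)
        h2 = self._hier(emb)
        mean = pool_to_next_level(h1, 1, "mean")
        att = pool_to_next_level(h2, 1, "attention",
                                 attention_scores=np.zeros(4))
        assert np.abs(mean.data - att.data).max() < 1e-6

    def test_unknown_mode_rejected(self, rng):
        h = self._hier(rng.standard_normal((4, 3)))
        with pytest.raises(ValueError, match="mode"):
            pool_to_next_level(h, 1, "median")


class TestPad:
    def _hier_with_embeddings(self, rng, d=3):
        h = build_hierarchy(4, [{0: 0, 1: 0, 2: 1, 3: 1}])
        h.levels[0].embeddings = Tensor(rng.standard_normal((4, d)))
        h.levels[1].embeddings = Tensor(rng.standard_normal((2, d)))
        return h

    def test_single_level_aggregate_is_that_summary(self, rng):
        h = build_hierarchy(4)
        emb = rng.standard_normal((4, 3))
        h.levels[0].embeddings = Tensor(emb)
        s = pad_aggregate(h, Tensor(np.zeros((3, 3))), "mean")
        assert np.allclose(s.h_global.data, emb.mean(axis=0))

    def test_sum_is_l_times_mean_for_equal_summaries(self, rng):
        h = build_hierarchy(4, [{0: 0, 1: 0, 2: 1, 3: 1}])
        v = rng.standard_normal(3)
        h.levels[0].embeddings = Tensor(np.tile(v, (4, 1)))
        h.levels[1].embeddings = Tensor(np.tile(v, (2, 1)))
        w = Tensor(np.zeros((3, 3)))
        s_sum = pad_aggregate(h, w, "sum")
        s_mean = pad_aggregate(h, w, "mean")
        assert np.allclose(s_sum.h_global.data, 2 * s_mean.h_global.data)

    def test_attention_with_equal_scores_equals_mean(self, rng):
        h = self._hier_with_embeddings(rng)
        w = Tensor(np.zeros((3, 3)))
        # equal per-level summaries force uniform attention scores
        v = rng.standard_normal(3)
        h.levels[0].embeddings = Tensor(np.tile(v, (4, 1)))
        h.levels[1].embeddings = Tensor(np.tile(v, (2, 1)))
        s_att = pad_aggregate(h, w, "attention")
        s_mean = pad_aggregate(h, w, "mean")
        assert np.abs(s_att.h_global.data - s_mean.h_global.data).max() < 1e-6

    def test_zero_wpad_distribute_identity(self, rng):
        h = self._hier_with_embeddings(rng)
        before = [g.embeddings.data.copy() for g in h.levels]
        s = pad_aggregate(h, Tensor(np.zeros((3, 3))), "mean")
        enhanced = pad_distribute(h, s)
        for b, e in zip(before, enhanced):
            assert np.allclose(e.data, b)

    def test_identity_wpad_shifts_every_node(self, rng):
        h = self._hier_with_embeddings(rng)
        before = [g.embeddings.data.copy() for g in h.levels]
        s = pad_aggregate(h, Tensor(np.eye(3)), "mean")
        v = s.h_global.data
        enhanced = pad_distribute(h, s)
        for b, e in zip(before, enhanced):
            assert np.allclose(e.data, b + v)


class TestLearnedAdjacency:
    def _scorer(self, rng, d=6, p=3):
        mk = lambda *s: Tensor(rng.standard_normal(s) * 0.3, requires_grad=True)
        return dict(theta=mk(d, p), a_vec=mk(2 * p), bias=mk(1),
                    m_bilinear=mk(p, p))

    def test_identical_features_constant_matrix(self, rng):
        sc = self._scorer(rng)
        x = np.tile(rng.standard_normal(6), (5, 1))
        w = learn_adjacency(x, **sc).data
        assert np.allclose(w, w[0, 0])

    def test_symmetric_for_100_random_inputs(self, rng):
        sc = self._scorer(rng)
        for _ in range(100):
            w = learn_adjacency(rng.standard_normal((4, 6)), **sc).data
            assert np.allclose(w, w.T, atol=1e-12)
            assert (w > 0).all()

    def test_zero_theta_gives_softplus_bias(self, rng):
        sc = self._scorer(rng)
        sc["theta"] = Tensor(np.zeros((6, 3)))
        sc["bias"] = Tensor(np.array([0.5]))
        w = learn_adjacency(rng.standard_normal((4, 6)), **sc).data
        assert np.allclose(w, np.log1p(np.exp(0.5)), atol=1e-12)


class TestAlignmentLoss:
    def test_zero_when_equal(self, rng):
        c = rng.uniform(0, 1, (4, 4))
        assert float(alignment_loss(c, Tensor(c)).data) == 0.0

    def test_all_ones_vs_zero_closed_form(self):
        n = 5
        w = Tensor(np.ones((n, n)))
        assert float(alignment_loss(np.zeros((n, n)), w).data) == n * n

    def test_matches_elementwise_oracle(self, rng):
        c = rng.uniform(0, 1, (6, 6))
        w = rng.uniform(0, 1, (6, 6))
        expected = sum(
            (c[i, j] - w[i, j]) ** 2 for i in range(6) for j in range(6)
        )
        assert abs(float(alignment_loss(c, Tensor(w)).data) - expected) < 1e-12

    def test_nonnegative(self, rng):
        for _ in range(20):
            val = float(alignment_loss(
                rng.standard_normal((3, 3)), Tensor(rng.standard_normal((3, 3)))
            ).data)
            assert val >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            alignment_loss(np.zeros((3, 3)), Tensor(np.zeros((4, 4))))


class TestHgraForward:
    def _setup(self, rng, c=8, w=64, d=8):
        hier = build_hierarchy(c, _two_level(c))
        params = init_hgra_params(rng, c, w, d=d, n_levels=2)
        return hier, params

    def test_deterministic(self, rng):
        hier, params = self._setup(rng)
        x = rng.standard_normal((2, 8, 64))
        a = hgra_forward(x, params, hier)
        b = hgra_forward(x.copy(), params, hier)
        assert np.array_equal(a.data, b.data)

    def test_output_width(self, rng):
        hier, params = self._setup(rng, d=8)
        out = hgra_forward(rng.standard_normal((3, 8, 64)), params, hier)
        assert out.shape == (3, 8)

    def test_channel_permutation_with_partition_invariance(self, rng):
        # permute channels within each region: readout unchanged because all
        # per-level readouts are permutation-invariant means
        c = 8
        hier, params = self._setup(rng, c=c)
        x = rng.standard_normal((1, c, 64))
        perm = np.array([2, 0, 3, 1, 6, 7, 4, 5])  # within-region shuffle
        h1 = hgra_forward(x, params, hier, adjacency_source="full")
        hier2 = build_hierarchy(c, _two_level(c))
        h2 = hgra_forward(x[:, perm], params, hier2, adjacency_source="full")
        assert np.abs(h1.data - h2.data).max() < 1e-10

    def test_pad_with_zero_weight_equals_no_pad(self, rng):
        hier, params = self._setup(rng)
        params["w_pad"] = Tensor(np.zeros_like(params["w_pad"].data))
        x = rng.standard_normal((2, 8, 64))
        with_pad = hgra_forward(x, params, hier, use_pad=True)
        hier2 = build_hierarchy(8, _two_level(8))
        without = hgra_forward(x, params, hier2, use_pad=False)
        assert np.array_equal(with_pad.data, without.data)
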