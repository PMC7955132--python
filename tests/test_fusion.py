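import networkx as nx
import numpy as np
import pytest
from scipy import integrate

from fusenet.fusion import (
    CommunityPartition,
    ConvergenceError,
    FusedNetwork,
    detect_communities,
    diffusion_step,
    disparity_alpha,
    disparity_filter,
    knn_kernel,
    select_ic_genes,
    snf_fuse,
)


def random_connected_weights(n, rng, density=0.4):
    """Symmetric non-negative adjacency with a guaranteed connected support."""
    w = np.where(rng.random((n, n)) < density, rng.uniform(0.1, 1.0, (n, n)), 0.0)
    for i in range(n - 1):  # spanning path keeps it connected and aperiodic
        w[i, i + 1] = rng.uniform(0.5, 1.0)
    w[0, 2 % n] = 0.9  # triangle -> non-bipartite
    w = np.triu(w, k=1)
    w = w + w.T
    return w


class TestKnnKernel:
    def test_three_equal_neighbors(self):
        w = np.zeros((4, 4))
        for j in (1, 2, 3):
            w[0, j] = w[j, 0] = 2.0
        s = knn_kernel(w, K=3)
        assert np.allclose(s[0, 1:], 1.0 / 3.0)

    def test_k_one_strongest(self):
        w = np.array([[0, 1, 3, 2], [1, 0, 0, 0], [3, 0, 0, 0], [2, 0, 0, 0]], float)
        s = knn_kernel(w, K=1)
        assert s[0, 2] == 1.0
        assert s[0, [1, 3]].sum() == 0.0

    def test_five_node_toy_brute_force(self, rng):
        w = random_connected_weights(5, rng)
        s = knn_kernel(w, K=2)
        for i in range(5):
            row = [(w[i, j], -j) for j in range(5) if j != i and w[i, j] > 0]
            top = sorted(row, reverse=True)[:2]
            neighbors = [-j for _, j in top]
            total = sum(v for v, _ in top)
            expected = np.zeros(5)
            for v, negj in top:
                expected[-negj] = v / total
            assert np.allclose(s[i], expected)

    def test_rows_sum_to_one(self, rng):
        w = random_connected_weights(12, rng)
        s = knn_kernel(w, K=4)
        sums = s.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-10)

    def test_isolated_node_zero_row(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        s = knn_kernel(w, K=2)
        assert np.all(s[2] == 0)


class TestSnfFuse:
    def test_identical_inputs_fused_equals_iterate(self, rng):
        w = random_connected_weights(8, rng)
        for mixing in (0.0, 0.3):
            fused = snf_fuse(w, w, K=3, identity_mixing=mixing, max_iter=500)
            # replicate one chain manually: with W_n = W_c both sequences
            # coincide, so the fused average equals either iterate
            s = knn_kernel(w, 3)
            wn = w.copy()
            eye = np.eye(8)
            for _ in range(fused.t_star):
                nxt = s @ wn @ s.T
                if mixing:
                    nxt = (1 - mixing) * nxt + mixing * eye
                wn = (nxt + nxt.T) / 2.0
            np.fill_diagonal(wn, 0.0)
            assert np.array_equal(fused.weights, wn)

    def test_three_node_literal_oracle(self, rng):
        wn = random_connected_weights(3, rng)
        wc = random_connected_weights(3, rng)
        sn, sc = knn_kernel(wn, 2), knn_kernel(wc, 2)

        def matmul3(a, b):
            out = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    out[i, j] = sum(a[i, k] * b[k, j] for k in range(3))
            return out

        wn1, wc1 = diffusion_step(sn, sc, wn, wc)
        exp_n1 = matmul3(matmul3(sn, wc), sn.T)
        exp_c1 = matmul3(matmul3(sc, wn), sc.T)
        assert np.allclose(wn1, exp_n1, atol=1e-12)
        assert np.allclose(wc1, exp_c1, atol=1e-12)
        wn2, wc2 = diffusion_step(sn, sc, wn1, wc1)
        assert np.allclose(wn2, matmul3(matmul3(sn, wc1), sn.T), atol=1e-12)
        assert np.allclose(wc2, matmul3(matmul3(sc, wn1), sc.T), atol=1e-12)

    def test_tolerance_monotonicity(self, rng):
        wn = random_connected_weights(10, rng)
        wc = random_connected_weights(10, rng)
        loose = snf_fuse(wn, wc, K=3, tolerance=1e-5, max_iter=500)
        tight = snf_fuse(wn, wc, K=3, tolerance=1e-8, max_iter=500)
        assert tight.t_star >= loose.t_star
        rel = np.linalg.norm(tight.weights - loose.weights) / np.linalg.norm(tight.weights)
        assert rel < 1e-4

    def test_convergence_below_tolerance(self, rng):
        wn = random_connected_weights(10, rng)
        wc = random_connected_weights(10, rng)
        fused = snf_fuse(wn, wc, K=3, tolerance=1e-5)
        assert fused.final_rel_diff < 1e-5
        assert np.abs(fused.weights - fused.weights.T).max() < 1e-10

    def test_max_iter_error_carries_rel_diff(self, rng):
        wn = random_connected_weights(6, rng)
        wc = random_connected_weights(6, rng)
        with pytest.raises(ConvergenceError) as err:
            snf_fuse(wn, wc, K=2, tolerance=1e-12, max_iter=2)
        assert err.value.last_rel_diff > 0

    def test_mismatched_universe(self, rng):
        from fusenet.coexpression import WeightedGeneNetwork

        a = WeightedGeneNetwork(genes=["a", "b"], weights=np.array([[0, 1.0], [1.0, 0]]))
        b = WeightedGeneNetwork(genes=["a", "c"], weights=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            snf_fuse(a, b)


class TestDisparityFilter:
    def test_degree_one_alpha_one(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 5.0
        alpha = disparity_alpha(w)
        assert alpha[0, 1] == 1.0
        assert alpha[1, 0] == 1.0

    def test_two_equal_edges_alpha_half(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 2.0
        w[0, 2] = w[2, 0] = 2.0
        alpha = disparity_alpha(w)
        assert alpha[0, 1] == pytest.approx(0.5)
        assert alpha[0, 2] == pytest.approx(0.5)

    def test_equal_weight_closed_form(self):
        k = 7
        w = np.zeros((k + 1, k + 1))
        for j in range(1, k + 1):
            w[0, j] = w[j, 0] = 3.0
        alpha = disparity_alpha(w)
        assert alpha[0, 1] == pytest.approx((1 - 1 / k) ** (k - 1))

    def test_quadrature_oracle_random_stars(self, rng):
        # closed form equals 1 - (k-1) * int_0^p (1-x)^(k-2) dx
        for _ in range(25):
            k = int(rng.integers(3, 12))
            weights = rng.uniform(0.1, 5.0, size=k)
            w = np.zeros((k + 1, k + 1))
            w[0, 1:] = weights
            w[1:, 0] = weights
            alpha = disparity_alpha(w)
            s = weights.sum()
            for j, wt in enumerate(weights, start=1):
                p = wt / s
                integral, _ = integrate.quad(lambda x: (1 - x) ** (k - 2), 0, p)
                expected = 1 - (k - 1) * integral
                assert alpha[0, j] == pytest.approx(expected, abs=1e-8)

    def test_backbone_subset_and_cutoff(self, rng):
        w = random_connected_weights(30, rng)
        fused = FusedNetwork(genes=[f"g{i}" for i in range(30)], weights=w, t_star=1)
        out = disparity_filter(fused, percentile=90)
        assert (out.backbone["alpha"] <= out.alpha_cutoff).all()
        total_edges = int((w[np.triu_indices(30, 1)] > 0).sum())
        assert len(out.backbone) <= total_edges


class TestCommunities:
    @staticmethod
    def two_cliques(size=8):
        g = nx.disjoint_union(nx.complete_graph(size), nx.complete_graph(size))
        nx.set_edge_attributes(g, 1.0, "weight")
        return g

    def test_two_cliques_q_half(self):
        part = detect_communities(self.two_cliques(), seed=0)
        assert len(part.sizes()) == 2
        # hand derivation: Q = sum(e_c - a_c^2) = 2 * (1/2 - 1/4) = 0.5
        assert part.modularity == pytest.approx(0.5)

    def test_single_clique_one_community(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_communities(g, seed=0)
        assert len(part.sizes()) == 1

    def test_sbm_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        successes = 0
        for seed in range(20):
            g = nx.stochastic_block_model(
                [50] * 4, np.full((4, 4), 0.01) + np.eye(4) * 0.29, seed=seed
            )
            nx.set_edge_attributes(g, 1.0, "weight")
            part = detect_communities(g, seed=seed)
            truth = [n // 50 for n in range(200)]
            found = [part.assignment[n] for n in range(200)]
            if adjusted_rand_score(truth, found) >= 0.9:
                successes += 1
        assert successes >= 16

    def test_empty_backbone_errors(self):
        with pytest.raises(ValueError):
            detect_communities(nx.Graph(), seed=0)

    def test_determinism(self, rng):
        w = random_connected_weights(40, rng)
        fused = FusedNetwork(genes=[f"g{i}" for i in range(40)], weights=w, t_star=1)
        bb = disparity_filter(fused, percentile=50)
        p1 = detect_communities(bb, seed=3)
        p2 = detect_communities(bb, seed=3)
        assert p1.assignment == p2.assignment


class TestSelectIcGenes:
    @staticmethod
    def partition_with_sizes(sizes):
        assignment = {}
        idx = 0
        for cid, size in enumerate(sizes):
            for _ in range(size):
                assignment[f"g{idx}"] = cid
                idx += 1
        return CommunityPartition(assignment=assignment, modularity=0.0)

    def test_giant_plus_singletons(self):
        part = self.partition_with_sizes([100] + [1] * 50)
        out = select_ic_genes(part, min_size_fraction=0.01)
        assert out.selected_communities == [0]
        assert len(out.ic_genes) == 100

    def test_fraction_zero_keeps_all(self):
        part = self.partition_with_sizes([5, 3, 1])
        out = select_ic_genes(part, min_size_fraction=0.0)
        assert len(out.ic_genes) == 9

    def test_arithmetic_cutoff(self):
        # 846 nodes, fraction 0.01 -> cutoff 8.46 -> sizes {500, 300, 40} pass
        part = self.partition_with_sizes([500, 300, 40, 3, 2, 1])
        out = select_ic_genes(part, min_size_fraction=0.01)
        assert out.selected_communities == [0, 1, 2]
        assert len(out.ic_genes) == 840
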