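import numpy as np
import pytest

from fusenet.coexpression import (
    PermutationBounds,
    WeightedGeneNetwork,
    combine_measures,
    euclidean_network,
    pearson_network,
    permutation_bounds,
    threshold_euclidean,
    threshold_pearson,
)

from conftest import make_matrix


def interp_percentile_oracle(values, q):
    """Independent linear-interpolation percentile (numpy-free arithmetic)."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(pos)
    frac = pos - lo
    return v[lo] if lo + 1 >= len(v) else v[lo] * (1 - frac) + v[lo + 1] * frac


class TestEuclideanNetwork:
    def test_identical_profiles_zero(self):
        m = make_matrix([[1, 2, 3], [1, 2, 3]])
        assert euclidean_network(m).weights[0, 1] == 0.0

    def test_constant_offset_closed_form(self):
        c, samples = 2.5, 4
        m = make_matrix([[0] * samples, [c] * samples])
        assert euclidean_network(m).weights[0, 1] == pytest.approx(c * np.sqrt(samples))

    def test_matches_brute_force(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(10, 5)))
        net = euclidean_network(m)
        x = m.values.to_numpy()
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(sum((x[i, k] - x[j, k]) ** 2 for k in range(5)))
                assert net.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            euclidean_network(make_matrix([[1.0], [2.0]]))


class TestThresholdEuclidean:
    def _network_with_weights(self, weights):
        # embed an arbitrary weight multiset into a symmetric adjacency
        n = int(np.ceil((1 + np.sqrt(1 + 8 * len(weights))) / 2))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        w[iu[0][: len(weights)], iu[1][: len(weights)]] = weights
        w = w + w.T
        return WeightedGeneNetwork(genes=[f"g{i}" for i in range(n)], weights=w)

    def test_99th_of_100_distinct_keeps_one(self, rng):
        weights = rng.permutation(np.arange(1.0, 101.0))
        # n = 15 gives 105 pairs; pad the rest with zeros -> use exactly 100 weights
        n = 15
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        w[iu[0][:100], iu[1][:100]] = weights
        w = w + w.T
        net = WeightedGeneNetwork(genes=[f"g{i}" for i in range(n)], weights=w)
        # percentile runs over the 100 nonzero edge weights only
        cut = interp_percentile_oracle(list(weights), 99)
        expected = int((weights > cut).sum())
        out = threshold_euclidean(net, percentile=99)
        assert out.n_edges == expected == 1

    def test_percentile_zero_keeps_all(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(8, 5)))
        net = euclidean_network(m)
        assert threshold_euclidean(net, percentile=0).n_edges == net.n_edges

    def test_strict_inequality_boundary_sort_oracle(self):
        weights = list(range(1, 1036))  # 1035 distinct weights fill n=46 exactly
        net = self._network_with_weights([float(x) for x in weights])
        out = threshold_euclidean(net, percentile=99)
        cut = interp_percentile_oracle(weights, 99)
        expected = sum(1 for x in weights if x > cut)
        assert out.n_edges == expected
        kept = sorted(out.weights[np.triu_indices(46, k=1)][out.weights[np.triu_indices(46, k=1)] > 0])
        assert min(kept) > cut


class TestPearsonNetwork:
    def test_affine_copy_r_one(self):
        m = make_matrix([[1, 2, 3, 4], [3, 5, 7, 9]])
        net = pearson_network(m)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_negation_r_minus_one(self):
        m = make_matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert pearson_network(m).weights[0, 1] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        x, y = rng.normal(10, 1, size=8), rng.normal(10, 1, size=8)
        m = make_matrix([x, y])
        net = pearson_network(m)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert net.weights[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_named(self):
        m = make_matrix([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="g0"):
            pearson_network(m)

    def test_drop_constant_mode(self):
        m = make_matrix([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        net = pearson_network(m, drop_constant=True)
        assert net.genes == ["g1", "g2"]


class TestPermutationBounds:
    def test_determinism(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(20, 30)))
        b1 = permutation_bounds(m, seed=5)
        b2 = permutation_bounds(m, seed=5)
        assert (b1.lower, b1.upper) == (b2.lower, b2.upper)

    def test_roughly_symmetric_null(self):
        asymmetries = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(10, 1, size=(30, 200)))
            b = permutation_bounds(m, seed=seed)
            asymmetries.append(b.lower + b.upper)
        assert abs(np.mean(asymmetries)) < 0.05

    def test_more_shuffles_wider_in_expectation(self):
        widths1, widths10 = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(10, 1, size=(10, 25)))
            b1 = permutation_bounds(m, n_shuffles=1, seed=seed)
            b10 = permutation_bounds(m, n_shuffles=10, seed=seed)
            widths1.append(b1.upper - b1.lower)
            widths10.append(b10.upper - b10.lower)
        assert np.mean(widths10) >= np.mean(widths1)

    def test_averaged_mode_narrower(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(20, 40)))
        pooled = permutation_bounds(m, seed=1, mode="pooled")
        averaged = permutation_bounds(m, seed=1, mode="averaged")
        assert averaged.upper - averaged.lower <= pooled.upper - pooled.lower


class TestThresholdPearson:
    def test_all_inside_bounds_empty(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(10, 20)))
        net = pearson_network(m)
        bounds = PermutationBounds(lower=-1.0, upper=1.0)
        out = threshold_pearson(net, bounds, target_edge_count=5)
        assert out.n_edges == 0

    def test_exact_target_smallest_p_sort_oracle(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(50, 12)))  # 1225 pairs, permissive bounds
        net = pearson_network(m)
        bounds = PermutationBounds(lower=-1e-9, upper=1e-9)
        target = 100
        out = threshold_pearson(net, bounds, target_edge_count=target)
        assert out.n_edges == target
        # full-sort oracle over (p, gene pair)
        iu, ju = np.triu_indices(50, k=1)
        entries = sorted(
            (net.pvalues[i, j], net.genes[i], net.genes[j]) for i, j in zip(iu, ju)
        )
        expected = {(a, b) for _, a, b in entries[:target]}
        kept = {
            (net.genes[i], net.genes[j])
            for i, j in zip(*np.nonzero(np.triu(out.weights, k=1)))
        }
        assert kept == expected

    def test_target_above_survivors_keeps_all(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(6, 10)))
        net = pearson_network(m)
        bounds = PermutationBounds(lower=-1e-9, upper=1e-9)
        with pytest.warns(UserWarning):
            out = threshold_pearson(net, bounds, target_edge_count=1000)
        assert out.n_edges == 15

    def test_perfect_pair_survives(self):
        m = make_matrix([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 1, 4, 2, 3]])
        net = pearson_network(m)
        bounds = PermutationBounds(lower=-0.3, upper=0.3)
        out = threshold_pearson(net, bounds, target_edge_count=1)
        assert out.weights[0, 1] == pytest.approx(1.0)


class TestCombineMeasures:
    def _pair(self, eucl_w, pears_w, genes=None):
        genes = genes or ["a", "b", "c"]
        eucl = WeightedGeneNetwork(genes=genes, weights=np.array(eucl_w, dtype=float))
        pears = WeightedGeneNetwork(
            genes=genes, weights=np.array(pears_w, dtype=float), measure="pearson"
        )
        return eucl, pears

    def test_pearson_only_abs(self):
        eucl, pears = self._pair(
            [[0, 5, 0], [5, 0, 0], [0, 0, 0]],
            [[0, 0, -0.8], [0, 0, 0], [-0.8, 0, 0]],
        )
        out = combine_measures(eucl, pears)
        assert out.weights[0, 2] == pytest.approx(0.8)

    def test_max_distance_normalization_fixed_point(self):
        eucl, pears = self._pair(
            [[0, 5, 2], [5, 0, 0], [2, 0, 0]],
            [[0, 0, 0], [0, 0, 0], [0, 0, 0]],
        )
        out = combine_measures(eucl, pears)
        assert out.weights[0, 1] == pytest.approx(1.0)
        assert 0 < out.weights[0, 2] < 1

    def test_union_edge_count_set_algebra(self, rng):
        n = 6
        ew = np.zeros((n, n))
        pw = np.zeros((n, n))
        e_edges = {(0, 1), (1, 2), (3, 4)}
        p_edges = {(1, 2), (2, 3), (4, 5)}
        for i, j in e_edges:
            ew[i, j] = ew[j, i] = rng.uniform(1, 5)
        for i, j in p_edges:
            pw[i, j] = pw[j, i] = rng.uniform(0.5, 0.99)
        genes = [f"g{i}" for i in range(n)]
        out = combine_measures(
            WeightedGeneNetwork(genes=genes, weights=ew),
            WeightedGeneNetwork(genes=genes, weights=pw, measure="pearson"),
        )
        expected = len(e_edges) + len(p_edges) - len(e_edges & p_edges)
        assert out.n_edges == expected

    def test_weights_bounded(self, rng):
        m = make_matrix(rng.lognormal(1, 1, size=(12, 10)))
        eucl = threshold_euclidean(euclidean_network(m), percentile=50)
        pears = pearson_network(m)
        out = combine_measures(eucl, pears)
        assert out.weights.min() >= 0
        assert out.weights.max() <= 2.0 + 1e-12

    def test_symmetry_zero_diag(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(8, 6)))
        for net in (euclidean_network(m), pearson_network(m)):
            assert np.allclose(net.weights, net.weights.T)
            assert np.all(np.diag(net.weights) == 0)
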