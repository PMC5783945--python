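"""Block densities, assortativity scores, and the maximally assortative set."""

from itertools import combinations

import numpy as np
import pytest

from mesoscope import (
    BlockDensityMatrix,
    Partition,
    WeightedNetwork,
    all_community_assortativity,
    assortativity_size_curve,
    block_densities,
    community_assortativity,
    delta_regional_assortativity,
    mas_node_frequency,
    maximally_assortative_set,
    motif_preset,
    regional_assortativity,
    sample_planted_network,
)

from conftest import make_random_network, make_random_partition


def oracle_block_densities(net, part):
    K = part.K
    omega = np.zeros((K, K))
    for r in range(1, K + 1):
        for s in range(1, K + 1):
            members_r = np.flatnonzero(part.labels == r)
            members_s = np.flatnonzero(part.labels == s)
            total = sum(net.weights[i, j] for i in members_r for j in members_s)
            omega[r - 1, s - 1] = total / (len(members_r) * len(members_s))
    return omega


def oracle_mas(omega, sizes):
    """Independent subset-enumeration oracle (different code path)."""
    K = omega.shape[0]
    best, best_key = frozenset(), None
    for k in range(2, K + 1):
        for sub in combinations(range(K), k):
            within = [omega[i, i] for i in sub]
            between = [omega[i, j] for i in sub for j in sub if i != j]
            if min(within) > max(between):
                nn = sum(sizes[i] for i in sub)
                margin = min(within) - max(between)
                key = (nn, margin, tuple(-i for i in sub))
                if best_key is None or key > best_key:
                    best, best_key = frozenset(c + 1 for c in sub), key
    return best


class TestBlockDensities:
    def test_saturated_between_block(self):
        mat = np.zeros((4, 4))
        mat[:2, 2:] = 1.0
        mat[2:, :2] = 1.0
        net = WeightedNetwork(mat)
        part = Partition(np.array([1, 1, 2, 2]))
        omega = block_densities(net, part).omega
        assert omega[0, 1] == pytest.approx(1.0)

    def test_single_within_edge_ordered_pair_convention(self):
        # one undirected unit edge in a size-2 community: 2 / (2*2) = 0.5
        mat = np.zeros((4, 4))
        mat[0, 1] = mat[1, 0] = 1.0
        net = WeightedNetwork(mat)
        part = Partition(np.array([1, 1, 2, 2]))
        bdm = block_densities(net, part)
        assert bdm.omega[0, 0] == pytest.approx(0.5)
        # exclude-diagonal mode: denominator n_r (n_r - 1) = 2
        bdm2 = block_densities(net, part, include_diagonal=False)
        assert bdm2.omega[0, 0] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            net = make_random_network(rng, n=9, density=0.5)
            part = make_random_partition(rng, 9, 3)
            np.testing.assert_allclose(
                block_densities(net, part).omega, oracle_block_densities(net, part)
            )

    def test_homogeneity_under_weight_scaling(self, rng):
        net = make_random_network(rng, n=10)
        part = make_random_partition(rng, 10, 3)
        scaled = WeightedNetwork(net.weights * 3.5)
        np.testing.assert_allclose(
            block_densities(scaled, part).omega,
            3.5 * block_densities(net, part).omega,
        )


class TestCommunityAssortativity:
    def _bdm(self, omega, sizes):
        return BlockDensityMatrix(omega=np.asarray(omega, float), sizes=np.asarray(sizes))

    def test_direct_substitution(self):
        bdm = self._bdm([[0.5, 0.1], [0.1, 0.4]], [5, 5])
        assert community_assortativity(bdm, 1) == pytest.approx(0.4)

    def test_disassortative_block_is_negative(self):
        bdm = self._bdm([[0.05, 0.4], [0.4, 0.05]], [5, 5])
        assert community_assortativity(bdm, 1) == pytest.approx(-0.35)

    def test_equal_densities_boundary(self):
        bdm = self._bdm([[0.3, 0.3], [0.3, 0.3]], [5, 5])
        assert community_assortativity(bdm, 1) == pytest.approx(0.0)

    def test_singleton_returns_missing_marker(self):
        bdm = self._bdm([[0.5, 0.1], [0.1, 0.4]], [1, 5])
        assert np.isnan(community_assortativity(bdm, 1))
        assert np.isfinite(community_assortativity(bdm, 2))


class TestRegionalAssortativity:
    def test_direct_substitution_and_sign(self):
        # node 0: all weight into its own size-2 community
        mat = np.zeros((4, 4))
        mat[0, 1] = mat[1, 0] = 1.2
        mat[2, 3] = mat[3, 2] = 0.4
        net = WeightedNetwork(mat)
        part = Partition(np.array([1, 1, 2, 2]))
        phi = regional_assortativity(net, part)
        assert phi[0] == pytest.approx(1.2 / 2 - 0.0)
        # node whose weight all goes to the foreign community
        mat2 = np.zeros((4, 4))
        mat2[0, 2] = mat2[2, 0] = 1.0
        net2 = WeightedNetwork(mat2)
        phi2 = regional_assortativity(net2, part)
        assert phi2[0] < 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(15):
            net = make_random_network(rng, n=10, density=0.5)
            part = make_random_partition(rng, 10, 3)
            phi = regional_assortativity(net, part)
            for i in range(10):
                a_ir = np.array(
                    [
                        net.weights[i, part.labels == r].sum() / (part.labels == r).sum()
                        for r in range(1, 4)
                    ]
                )
                own = part.labels[i]
                expected = a_ir[own - 1] - max(
                    a_ir[r] for r in range(3) if r != own - 1
                )
                if part.sizes[own - 1] < 2:
                    assert np.isnan(phi[i])
                else:
                    assert phi[i] == pytest.approx(expected)

    def test_homogeneity_and_relabel_invariance(self, rng):
        net = make_random_network(rng, n=12)
        part = make_random_partition(rng, 12, 3)
        phi = regional_assortativity(net, part)
        scaled = regional_assortativity(WeightedNetwork(net.weights * 2.0), part)
        np.testing.assert_allclose(scaled, 2.0 * phi)
        relab = Partition(np.array([{1: 3, 2: 1, 3: 2}[z] for z in part.labels]))
        np.testing.assert_allclose(regional_assortativity(net, relab), phi)


class TestDeltaRegionalAssortativity:
    def test_identical_ensembles_give_zero(self, rng):
        net = make_random_network(rng, n=10)
        ens = [make_random_partition(rng, 10, 3) for _ in range(3)]
        np.testing.assert_allclose(
            delta_regional_assortativity(ens, list(ens), net), 0.0, atol=1e-12
        )

    def test_mean_is_linear_in_partition_scores(self, rng):
        net = make_random_network(rng, n=10)
        p1 = make_random_partition(rng, 10, 3)
        p2 = make_random_partition(rng, 10, 3)
        q = make_random_partition(rng, 10, 3)
        delta = delta_regional_assortativity([p1, p2], [q], net)
        expected = (
            regional_assortativity(net, p1) + regional_assortativity(net, p2)
        ) / 2 - regional_assortativity(net, q)
        np.testing.assert_allclose(delta, expected)


class TestMaximallyAssortativeSet:
    def test_worked_three_community_example(self):
        omega = np.array([[0.6, 0.1, 0.3], [0.1, 0.5, 0.05], [0.3, 0.05, 0.2]])
        bdm = BlockDensityMatrix(omega=omega, sizes=np.array([12, 10, 8]))
        assert maximally_assortative_set(bdm) == frozenset({1, 2})

    def test_perfectly_assortative_takes_all(self):
        omega = np.full((4, 4), 0.05)
        np.fill_diagonal(omega, 0.6)
        bdm = BlockDensityMatrix(omega=omega, sizes=np.array([5, 5, 5, 5]))
        assert maximally_assortative_set(bdm) == frozenset({1, 2, 3, 4})

    def test_disassortative_returns_empty(self):
        omega = np.full((3, 3), 0.6)
        np.fill_diagonal(omega, 0.05)
        bdm = BlockDensityMatrix(omega=omega, sizes=np.array([5, 5, 5]))
        assert maximally_assortative_set(bdm) == frozenset()

    def test_matches_enumeration_oracle_and_inequality(self, rng):
        for _ in range(200):
            K = int(rng.integers(2, 11))
            omega = rng.random((K, K))
            omega = (omega + omega.T) / 2
            sizes = rng.integers(1, 20, K)
            bdm = BlockDensityMatrix(omega=omega, sizes=sizes)
            mas = maximally_assortative_set(bdm)
            assert mas == oracle_mas(omega, sizes)
            if mas:
                idx = np.array(sorted(mas)) - 1
                within = omega[idx, idx].min()
                off = np.array(
                    [omega[i, j] for i in idx for j in idx if i != j]
                )
                assert within > off.max()


class TestMasNodeFrequency:
    def test_counting(self, planted_assortative):
        net, planted = planted_assortative
        freq = mas_node_frequency([planted], net)
        # fully assortative planted partition: every node's community in MAS
        np.testing.assert_allclose(freq, 1.0)

    def test_disassortative_preset_near_zero(self):
        net, planted = sample_planted_network(
            motif_preset("disassortative"), seed=3
        )
        freq = mas_node_frequency([planted], net)
        np.testing.assert_allclose(freq, 0.0)


class TestAssortativitySizeCurve:
    def test_flat_and_two_point_curves(self):
        sizes, means = assortativity_size_curve([(5, 0.3), (5, 0.3), (5, 0.3)])
        assert sizes.tolist() == [5]
        assert means.tolist() == [0.3]
        sizes, means = assortativity_size_curve([(3, 0.2), (3, 0.4), (7, 1.0)])
        assert sizes.tolist() == [3, 7]
        np.testing.assert_allclose(means, [0.3, 1.0])

    def test_matches_groupby_oracle(self, rng):
        data = [(int(rng.integers(2, 6)), float(rng.normal())) for _ in range(100)]
        sizes, means = assortativity_size_curve(data)
        for s, m in zip(sizes, means):
            vals = [a for n, a in data if n == s]
            assert m == pytest.approx(np.mean(vals))
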