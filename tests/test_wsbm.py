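"""Weighted stochastic blockmodel likelihoods and variational inference."""

import numpy as np
import pytest

from mesoscope import (
    Partition,
    WSBMParams,
    WeightedNetwork,
    fit_wsbm,
    motif_preset,
    sample_planted_network,
    sbm_log_likelihood,
    variation_of_information,
    wsbm_log_likelihood,
)

from conftest import make_random_network, make_random_partition


def oracle_sbm_ll(net, part, theta):
    """Independent per-dyad product oracle."""
    z = part.labels - 1
    total = 0.0
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            t = theta[z[i], z[j]]
            p = t if net.weights[i, j] > 0 else 1.0 - t
            if p == 0:
                return float("-inf")
            total += np.log(p)
    return total


def oracle_wsbm_ll(net, part, params):
    """Dyad-by-dyad Bernoulli + normal-kernel oracle."""
    z = part.labels - 1
    bern = oracle_sbm_ll(net, part, params.edge_theta)
    weight = 0.0
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            x = net.weights[i, j]
            if x > 0:
                mu = params.mu[z[i], z[j]]
                s2 = params.sigma2[z[i], z[j]]
                weight += -((x - mu) ** 2) / (2 * s2)
    return params.alpha * bern + (1 - params.alpha) * weight


class TestSbmLogLikelihood:
    def test_single_bernoulli_term(self):
        net = WeightedNetwork(np.array([[0, 1.0], [1.0, 0]]))
        part = Partition(np.array([1, 1]))
        assert sbm_log_likelihood(net, part, np.array([[0.5]])) == pytest.approx(
            np.log(0.5)
        )

    def test_complete_graph_theta_one_is_zero(self):
        mat = np.ones((4, 4)) - np.eye(4)
        net = WeightedNetwork(mat)
        part = Partition(np.array([1, 2, 1, 2]))
        assert sbm_log_likelihood(net, part, np.ones((2, 2))) == 0.0

    def test_contradicting_boundary_theta_is_minus_inf(self):
        net = WeightedNetwork(np.array([[0, 1.0], [1.0, 0]]))
        part = Partition(np.array([1, 1]))
        assert sbm_log_likelihood(net, part, np.array([[0.0]])) == -np.inf

    def test_matches_per_dyad_oracle(self, rng):
        for _ in range(25):
            net = make_random_network(rng, n=6, density=0.5)
            part = make_random_partition(rng, 6, 2)
            theta = rng.uniform(0.05, 0.95, (2, 2))
            theta = (theta + theta.T) / 2
            assert sbm_log_likelihood(net, part, theta) == pytest.approx(
                oracle_sbm_ll(net, part, theta)
            )


class TestWsbmLogLikelihood:
    def _params(self, rng, K, alpha):
        theta = rng.uniform(0.1, 0.9, (K, K))
        mu = rng.uniform(0.5, 2.0, (K, K))
        s2 = rng.uniform(0.1, 1.0, (K, K))
        return WSBMParams(
            K=K, edge_theta=(theta + theta.T) / 2, mu=(mu + mu.T) / 2,
            sigma2=(s2 + s2.T) / 2, alpha=alpha,
        )

    def test_alpha_one_reduces_to_sbm(self, rng):
        net = make_random_network(rng, n=6)
        part = make_random_partition(rng, 6, 2)
        params = self._params(rng, 2, alpha=1.0)
        assert wsbm_log_likelihood(net, part, params) == pytest.approx(
            sbm_log_likelihood(net, part, params.edge_theta)
        )

    def test_alpha_zero_single_edge_is_normal_kernel(self):
        net = WeightedNetwork(np.array([[0, 1.7], [1.7, 0]]))
        part = Partition(np.array([1, 1]))
        mu, s2 = 1.2, 0.3
        params = WSBMParams(
            K=1, edge_theta=np.array([[0.5]]), mu=np.array([[mu]]),
            sigma2=np.array([[s2]]), alpha=0.0,
        )
        kernel = 1.7 * mu / s2 - 1.7**2 / (2 * s2) - mu**2 / (2 * s2)
        assert wsbm_log_likelihood(net, part, params) == pytest.approx(kernel)

    def test_matches_per_dyad_oracle_two_blocks(self, rng):
        for _ in range(20):
            net = make_random_network(rng, n=5, density=0.6)
            part = make_random_partition(rng, 5, 2)
            params = self._params(rng, 2, alpha=0.5)
            # oracle uses the completed-square kernel; equal up to the
            # x-independent -mu^2/(2 s2) + x mu/s2 expansion, i.e. exactly
            assert wsbm_log_likelihood(net, part, params) == pytest.approx(
                oracle_wsbm_ll(net, part, params), rel=1e-10
            )


class TestFitWsbm:
    def test_recovers_planted_assortative_partition(self, planted_assortative):
        net, planted = planted_assortative
        fit = fit_wsbm(net, 2, restarts=5, seed=0)
        assert variation_of_information(fit.map_partition, planted) < 0.1

    def test_recovers_core_periphery_parameter_ordering(self, planted_core_periphery):
        net, planted = planted_core_periphery
        fit = fit_wsbm(net, 2, restarts=5, seed=0)
        assert variation_of_information(fit.map_partition, planted) < 0.1
        th = fit.params.edge_theta
        core = int(np.argmax(np.diag(th)))
        peri = 1 - core
        assert th[core, core] > th[core, peri] > th[peri, peri]

    def test_two_cliques_found_and_bound_monotone(self):
        mat = np.zeros((10, 10))
        mat[:5, :5] = 1.0
        mat[5:, 5:] = 1.0
        np.fill_diagonal(mat, 0.0)
        net = WeightedNetwork(mat)
        fit = fit_wsbm(net, 2, restarts=4, seed=1)
        expected = Partition(np.repeat([1, 2], 5))
        assert variation_of_information(fit.map_partition, expected) == pytest.approx(0.0)
        assert np.all(np.diff(fit.elbo_history) >= -1e-8)

    def test_responsibility_rows_are_probability_vectors(self, planted_assortative):
        net, _ = planted_assortative
        fit = fit_wsbm(net, 3, restarts=2, seed=2)
        assert np.all(fit.responsibilities >= 0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_label_permutation_symmetry_of_bound(self, planted_assortative):
        net, _ = planted_assortative
        rng = np.random.default_rng(3)
        tau0 = rng.dirichlet(np.ones(3), size=net.n_nodes)
        f1 = fit_wsbm(net, 3, seed=0, initial_tau=tau0, max_iter=40)
        f2 = fit_wsbm(net, 3, seed=0, initial_tau=tau0[:, [2, 0, 1]], max_iter=40)
        # identical up to float summation order under the column permutation
        assert f1.log_evidence == pytest.approx(f2.log_evidence, rel=1e-6)

    def test_parameter_recovery_given_planted_partition(self, planted_assortative):
        net, planted = planted_assortative
        spec = motif_preset("assortative")
        tau0 = planted.indicator() * 0.98 + 0.01
        fit = fit_wsbm(net, 2, seed=0, initial_tau=tau0)
        n = np.asarray(spec.sizes, dtype=float)
        for r in range(2):
            for s in range(2):
                theta = spec.edge_prob[r, s]
                n_dyads = n[r] * (n[r] - 1) / 2 if r == s else n[r] * n[s]
                se = np.sqrt(theta * (1 - theta) / n_dyads)
                assert abs(fit.params.edge_theta[r, s] - theta) < 3 * se

    def test_argument_validation(self, planted_assortative):
        net, _ = planted_assortative
        with pytest.raises(ValueError, match="K must"):
            fit_wsbm(net, 1)
        with pytest.raises(ValueError, match="K must"):
            fit_wsbm(net, net.n_nodes + 1)
        with pytest.raises(ValueError, match="sigma2"):
            WSBMParams(K=1, edge_theta=np.array([[0.5]]), mu=np.array([[1.0]]),
                       sigma2=np.array([[0.0]]))
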