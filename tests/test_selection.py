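"""Penalty selection: StARS instability, EBIC, parametric bootstrap."""

import numpy as np
import pytest

from hbmnet import (
    DataError,
    bootstrap_median_network,
    ebic_score,
    ebic_select,
    edge_instability,
    empirical_covariance,
    glasso,
    instability_from_adjacencies,
    lambda_path,
    stars_select,
)
from hbmnet.selection import default_subsample_size


def planted_single_edge_data(n=500, p=5, rho=0.5, seed=3):
    P = np.eye(p)
    P[0, 1] = P[1, 0] = -rho
    sigma = np.linalg.inv(P)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(p), sigma, n)
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestInstability:
    def test_half_presence_attains_maximum(self):
        # an edge present in exactly half the subsample graphs contributes
        # 2 * 0.5 * 0.5 = 0.5, the top of the statistic's range
        adj = np.zeros((20, 2, 2))
        adj[:10, 0, 1] = adj[:10, 1, 0] = 1
        assert instability_from_adjacencies(adj) == pytest.approx(0.5)
        assert edge_instability(0.5) == pytest.approx(0.5)

    def test_identical_graphs_give_zero(self):
        one_graph = np.ones((3, 3)) - np.eye(3)
        assert instability_from_adjacencies(np.stack([one_graph] * 15)) == 0.0

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((120, 6))
        res = stars_select(X, seed=1, n_subsamples=10)
        assert np.all(res.instability >= 0)
        assert np.all(res.instability <= 0.5)
        assert np.all(np.diff(res.monotonized) >= -1e-15)


class TestStars:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((150, 5)) @ np.diag([1, 1, 1, 1, 1])
        r1 = stars_select(X, seed=9)
        r2 = stars_select(X, seed=9)
        assert np.array_equal(r1.instability, r2.instability)
        assert r1.selected_lambda == r2.selected_lambda
        assert np.array_equal(r1.estimate.theta, r2.estimate.theta)

    def test_default_subsample_size(self):
        assert default_subsample_size(400) == 200  # floor(10*sqrt(400))
        assert default_subsample_size(50) == 49    # capped below n

    def test_selected_lambda_on_path(self):
        X = planted_single_edge_data(n=200, seed=5)
        res = stars_select(X, seed=2)
        assert res.selected_lambda in res.lambdas
        assert res.estimate.lam == res.selected_lambda

    def test_strong_single_edge_is_recovered(self):
        X = planted_single_edge_data(n=400, rho=0.5, seed=6)
        res = stars_select(X, seed=3)
        assert (0, 1) in res.estimate.edges

    def test_invalid_subsample_size(self):
        with pytest.raises(DataError):
            stars_select(np.random.default_rng(0).standard_normal((50, 4)),
                         subsample_size=50)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        X = planted_single_edge_data(n=300, seed=7)
        S = empirical_covariance(X)
        est = glasso(S, 0.1)
        n = X.shape[0]
        sign, logdet = np.linalg.slogdet(est.theta)
        ll = 0.5 * n * (logdet - np.trace(S @ est.theta))
        bic = -2 * ll + est.n_edges * np.log(n)
        assert ebic_score(est, S, n, gamma=0.0) == pytest.approx(bic)

    def test_hand_computed_three_node_score(self):
        # chain precision, S = identity: logdet, trace and penalty by hand
        theta = np.array([[1.0, -0.2, 0.0], [-0.2, 1.0, -0.2], [0.0, -0.2, 1.0]])
        S = np.eye(3)
        n, p, E = 100, 3, 2
        from hbmnet.glasso import PrecisionEstimate

        est = PrecisionEstimate(theta=theta, lam=0.0, covariance=np.linalg.inv(theta),
                                converged=True, iterations=1)
        logdet = np.log(np.linalg.det(theta))
        expected = -2 * (n / 2) * (logdet - 3.0) + E * np.log(n) + 4 * 0.5 * E * np.log(p)
        assert ebic_score(est, S, n, gamma=0.5) == pytest.approx(expected)

    def test_extra_edge_without_likelihood_gain_raises_score(self):
        X = planted_single_edge_data(n=300, seed=8)
        S = empirical_covariance(X)
        est = glasso(S, 0.3, tol=1e-8)
        theta2 = est.theta.copy()
        theta2[2, 3] = theta2[3, 2] = 1e-6  # negligible weight, one more edge
        from hbmnet.glasso import PrecisionEstimate

        est2 = PrecisionEstimate(theta=theta2, lam=est.lam, covariance=est.covariance,
                                 converged=True, iterations=1)
        n = X.shape[0]
        assert ebic_score(est2, S, n) > ebic_score(est, S, n)

    def test_pure_noise_selects_near_empty_graph(self):
        counts = []
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((500, 10))
            counts.append(ebic_select(X).estimate.n_edges)
        assert np.mean(counts) <= 0.5

    def test_single_lambda_path_returns_that_fit(self):
        X = planted_single_edge_data(n=200, seed=9)
        S = empirical_covariance(X)
        lam = lambda_path(S)[4]
        res = ebic_select(X, path=[lam])
        assert res.selected_lambda == pytest.approx(lam)

    def test_planted_edge_recovered(self):
        X = planted_single_edge_data(n=400, rho=0.5, seed=10)
        res = ebic_select(X)
        assert (0, 1) in res.estimate.edges


class TestBootstrap:
    def test_zero_signal_truth_gives_zero_medians(self):
        X = np.random.default_rng(11).standard_normal((300, 6))
        bn = bootstrap_median_network(X, n_iterations=200, seed=5)
        assert np.abs(bn.median_weights).max() == 0.0

    def test_single_edge_median_concentrates(self):
        X = planted_single_edge_data(n=500, rho=0.5, seed=3)
        single = ebic_select(X).estimate
        bn = bootstrap_median_network(X, n_iterations=200, seed=9)
        assert abs(bn.median_weights[0, 1] - single.partial_corr[0, 1]) < 0.1

    def test_deterministic_given_seed(self):
        X = planted_single_edge_data(n=200, seed=12)
        b1 = bootstrap_median_network(X, n_iterations=50, seed=4)
        b2 = bootstrap_median_network(X, n_iterations=50, seed=4)
        assert np.array_equal(b1.median_weights, b2.median_weights)

    def test_symmetric_zero_diagonal(self):
        X = planted_single_edge_data(n=200, seed=13)
        bn = bootstrap_median_network(X, n_iterations=50, seed=1)
        assert np.allclose(bn.median_weights, bn.median_weights.T)
        assert np.all(np.diag(bn.median_weights) == 0)
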