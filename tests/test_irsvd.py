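"""The iteratively reweighted SVD fitting loop."""

import numpy as np
import pytest
from scipy.optimize import minimize

import countfactor as cf
from countfactor.irsvd import (
    IRSVDConfig,
    initialize,
    svd_soft_threshold,
    update_intercepts,
    working_update,
)
from countfactor.model_core import as_count_matrix

from conftest import positive_count_instance


class TestInitialize:
    def test_uniform_matrix(self):
        fit = initialize(np.ones((2, 2), int), IRSVDConfig(M=1))
        assert np.allclose(fit.alpha, 0)
        assert np.allclose(fit.beta, 0)
        assert np.allclose(cf.mean_matrix(fit), 1.0)
        assert fit.M == 0

    def test_depth_enters_beta_on_log_scale(self):
        # cell intercepts are centered log depths: beta_j - beta_k = log(S_j/S_k)
        Y = np.array([[2, 5], [2, 6]])
        fit = initialize(Y, IRSVDConfig(M=1))
        S = Y.sum(0)
        assert np.allclose(np.diff(fit.beta), np.diff(np.log(S)))
        assert np.allclose(fit.beta.mean(), 0.0)

    def test_margin_identity(self):
        Y = np.array([[4, 1, 3, 2], [2, 5, 1, 1], [6, 2, 2, 7]])
        fit = initialize(Y, IRSVDConfig(M=2))
        expected = np.outer(Y.sum(1), Y.sum(0)) / Y.sum()
        assert np.allclose(cf.mean_matrix(fit), expected, rtol=1e-10)

    def test_zero_margins_rejected(self):
        with pytest.raises(ValueError):
            initialize(np.array([[0, 0], [1, 2]]), IRSVDConfig(M=1))


class TestSVDSoftThreshold:
    @pytest.mark.parametrize(
        "M,tau,expected",
        [(2, 0.0, [5.0, 3.0]), (2, 2.0, [3.0, 1.0]), (3, 4.0, [1.0])],
    )
    def test_diagonal_cases(self, M, tau, expected):
        A = np.diag([5.0, 3.0, 1.0])
        U, s, V = svd_soft_threshold(A, M, tau)
        assert np.allclose(s, expected)
        assert U.shape == (3, len(expected))
        assert np.allclose(U.T @ U, np.eye(len(expected)), atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            svd_soft_threshold(np.array([[np.nan, 0], [0, 1.0]]), 1, 0.0)


class TestWorkingUpdate:
    def test_fixed_point_when_counts_equal_means(self):
        # mu = [[4,1],[1,4]] = exp(X) with alpha = log 2, rank-1 X
        c = np.log(2.0)
        u = np.array([[1.0], [-1.0]]) / np.sqrt(2)
        fit = cf.GBMFit([c, c], [0.0, 0.0], u, [2 * c], u)
        Y = np.array([[4, 1], [1, 4]])
        assert np.allclose(cf.mean_matrix(fit), Y)
        out = working_update(as_count_matrix(Y), fit, IRSVDConfig(M=1, tau=0.0))
        assert np.allclose(out.interaction(), fit.interaction(), atol=1e-10)

    def test_hand_svd_of_residual(self):
        # X=0, alpha=beta=0 => mu=1, mu*=1; argument is [[1,-1],[-1,1]]
        fit = cf.GBMFit(np.zeros(2), np.zeros(2), np.zeros((2, 1)),
                        [1e-300], np.zeros((2, 1)))
        Y = np.array([[2, 0], [0, 2]])
        out = working_update(as_count_matrix(Y), fit, IRSVDConfig(M=1, tau=0.0))
        assert np.allclose(out.sigma, [2.0])
        assert np.allclose(out.interaction(), [[1, -1], [-1, 1]], atol=1e-10)

    def test_residual_scaling_linearity(self):
        # mu = 3 fixed; tripling Y - mu triples the pre-threshold sigma
        fit = cf.GBMFit(np.full(2, np.log(3.0)), np.zeros(2), np.zeros((2, 1)),
                        [1e-300], np.zeros((2, 1)))
        cfg = IRSVDConfig(M=1, tau=0.0)
        s1 = working_update(as_count_matrix([[4, 2], [2, 4]]), fit, cfg).sigma
        s3 = working_update(as_count_matrix([[6, 0], [0, 6]]), fit, cfg).sigma
        assert np.allclose(s3, 3 * s1)


class TestUpdateIntercepts:
    def test_fixed_point_on_uniform(self):
        fit = initialize(np.ones((2, 2), int), IRSVDConfig(M=1))
        out = update_intercepts(np.ones((2, 2), int), fit)
        assert np.allclose(out.alpha, 0)
        assert np.allclose(out.beta, 0)

    def test_log_mean_alpha(self):
        Y = np.array([[7, 3], [1, 0]])
        fit = cf.GBMFit(np.zeros(2), np.zeros(2), np.zeros((2, 0)),
                        np.zeros(0), np.zeros((2, 0)))
        out = update_intercepts(Y, fit)
        assert np.allclose(out.alpha, [np.log(5.0), np.log(0.5)])

    def test_sweep_never_decreases_likelihood(self, rng):
        Y = rng.poisson(3.0, size=(5, 8)) + 1
        U = cf.sample_stiefel(5, 1, rng)
        V = cf.sample_stiefel(8, 1, rng)
        fit = cf.GBMFit(rng.standard_normal(5) * 0.3,
                        rng.standard_normal(8) * 0.3, U, [0.5], V)
        before = cf.log_likelihood(Y, fit)
        after = cf.log_likelihood(Y, update_intercepts(Y, fit))
        assert after >= before - 1e-10


class TestFitGBM:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(5)
        I, J = 50, 80
        U0 = cf.sample_stiefel(I, 1, rng)
        V0 = cf.sample_stiefel(J, 1, rng)
        sigma = np.array([8.0 * (np.sqrt(I) + np.sqrt(J))])  # strong signal
        truth = cf.GBMFit(0.5 + 0.3 * rng.standard_normal(I),
                          0.5 + 0.3 * rng.standard_normal(J), U0, sigma, V0)
        Y = rng.poisson(cf.mean_matrix(truth))
        fit = cf.fit_gbm(Y, M=1, seed=0, max_iter=1500, tol=1e-8)
        assert cf.subspace_distance(fit.V, V0) < 0.2

    def test_m_zero_is_margin_model(self):
        Y = np.array([[4, 1, 3], [2, 5, 1]])
        fit = cf.fit_gbm(Y, M=0)
        assert fit.M == 0
        assert np.allclose(cf.mean_matrix(fit),
                           np.outer(Y.sum(1), Y.sum(0)) / Y.sum(), rtol=1e-8)

    def test_stability_after_convergence(self, small_sim):
        """One extra iteration after convergence barely moves the means.

        The stopping rule bounds the objective change by tol*(|obj|+1); by
        the Poisson curvature (Hessian scale sum(mu) in relative-mu units)
        that allows an rms relative mean change of about
        sqrt(2 tol (|obj|+1) / sum(mu)).
        """
        Y, _ = small_sim
        cfg = IRSVDConfig(M=2, seed=0, max_iter=400, tol=1e-6)
        fit = cf.fit_gbm(Y, cfg)
        assert fit.converged
        mu1 = cf.mean_matrix(fit)
        again = working_update(Y, fit, cfg)
        again = update_intercepts(Y, again)
        mu2 = cf.mean_matrix(again)
        rel = np.linalg.norm(mu2 - mu1) / np.linalg.norm(mu1)
        bound = np.sqrt(2 * cfg.tol * (abs(fit.trace[-1]) + 1) / mu1.sum())
        assert rel < 10 * bound

    def test_orthonormal_every_iteration(self, small_sim):
        Y, _ = small_sim
        cfg = IRSVDConfig(M=2, seed=0)
        fit = initialize(Y, cfg)
        for _ in range(5):
            fit = working_update(Y, fit, cfg)
            fit = update_intercepts(Y, fit)
            assert np.allclose(fit.U.T @ fit.U, np.eye(fit.M), atol=1e-8)
            assert np.allclose(fit.V.T @ fit.V, np.eye(fit.M), atol=1e-8)

    def test_deterministic_given_seed(self, small_sim):
        Y, _ = small_sim
        f1 = cf.fit_gbm(Y, M=2, seed=3, max_iter=50)
        f2 = cf.fit_gbm(Y, M=2, seed=3, max_iter=50)
        assert np.array_equal(f1.V, f2.V)
        assert f1.trace == f2.trace

    def test_objective_trace_monotone(self, small_fit):
        diffs = np.diff(small_fit.trace)
        assert np.all(diffs >= -1e-6)

    def test_nonconvergence_warns_and_returns_best(self, small_sim):
        Y, _ = small_sim
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = cf.fit_gbm(Y, M=2, seed=0, max_iter=3)
        assert not fit.converged

    def test_matches_direct_optimizer_on_tiny_instance(self, rng):
        """Deviance agreement with generic numerical maximization, M=1."""
        Y = positive_count_instance(rng, 5, 6)
        fit = cf.fit_gbm(Y, M=1, seed=0, max_iter=3000, tol=1e-12)
        oracle = direct_mle_loglik(Y)
        assert cf.log_likelihood(Y, fit) >= oracle - 1e-3


def direct_mle_loglik(Y: np.ndarray) -> float:
    """Rank-1 Poisson bilinear log-likelihood maximized by L-BFGS.

    Independent of the IRSVD path: optimizes (alpha, beta, p, q) directly
    with X = outer(p, q).
    """
    I, J = Y.shape

    def negll(x):
        al, be = x[:I], x[I:I + J]
        p, q = x[I + J:I + J + I], x[I + J + I:]
        eta = al[:, None] + be[None, :] + np.outer(p, q)
        return -(np.sum(Y * eta) - np.sum(np.exp(eta)))

    best = np.inf
    for s in range(3):
        r = np.random.default_rng(s)
        x0 = np.concatenate([
            np.log(Y.sum(1) / np.sqrt(Y.sum())),
            np.log(Y.sum(0) / np.sqrt(Y.sum())),
            0.1 * r.standard_normal(I + J),
        ])
        res = minimize(negll, x0, method="L-BFGS-B",
                       options=dict(maxiter=20000, ftol=1e-15, gtol=1e-10))
        best = min(best, res.fun)
    return -best
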