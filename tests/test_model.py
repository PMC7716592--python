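"""M-matrix algebra, link function, binomial likelihood and log-posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import binom

import podsmooth as ps
from podsmooth.model import bernoulli_style_log_likelihood

from conftest import random_connected_graph


class TestBuildM:
    def test_rho_zero_is_identity(self):
        assert np.array_equal(ps.build_M(0.0, 3), np.eye(3))

    def test_two_by_two_closed_form(self):
        M = ps.build_M(0.6, 2)
        assert M == pytest.approx(np.array([[1.0, 0.6], [0.0, 0.8]]))
        # agrees with a generic Cholesky factorization of the AR(1) matrix
        L = np.linalg.cholesky(np.array([[1.0, 0.6], [0.6, 1.0]])[::-1, ::-1])
        assert np.allclose(M, L[::-1, ::-1].T) or np.allclose(M.T @ M, [[1, 0.6], [0.6, 1]])

    @given(
        rho=st.floats(-0.99, 0.99),
        A=st.integers(1, 12),
    )
    @settings(max_examples=100, deadline=None)
    def test_mtm_reconstructs_ar1_correlation(self, rho, A):
        M = ps.build_M(rho, A)
        ij = np.arange(A)
        Sigma = rho ** np.abs(ij[:, None] - ij[None, :])
        assert np.abs(M.T @ M - Sigma).max() < 1e-12
        assert np.allclose(np.tril(M, -1), 0.0)

    @pytest.mark.parametrize("rho", [-1.0, 1.0, 1.7])
    def test_rho_out_of_range(self, rho):
        with pytest.raises(ValueError):
            ps.build_M(rho, 4)


class TestThetaFrom:
    def test_identity_mixing(self):
        Phi = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(ps.theta_from(Phi, np.eye(3)), Phi)

    def test_single_latent_pattern(self):
        rng = np.random.default_rng(1)
        Phi = np.zeros((5, 3))
        Phi[:, 1] = rng.standard_normal(5)
        M = ps.build_M(0.4, 3)
        Theta = ps.theta_from(Phi, M)
        for j in range(3):
            assert Theta[:, j] == pytest.approx(Phi[:, 1] * M[1, j])

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        Phi = rng.standard_normal((4, 3))
        M = ps.build_M(0.5, 3)
        expected = np.zeros((4, 3))
        for s in range(4):
            for j in range(3):
                for i in range(3):
                    expected[s, j] += Phi[s, i] * M[i, j]
        assert ps.theta_from(Phi, M) == pytest.approx(expected, abs=1e-14)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ps.theta_from(np.zeros((4, 3)), np.zeros((2, 2)))


class TestLinearPredictor:
    def test_zero_gives_half(self):
        P = ps.linear_predictor(np.zeros(2), np.zeros((3, 2)))
        assert np.all(P == 0.5)

    def test_cancellation(self):
        mu = np.array([1.3, -0.4])
        Theta = -np.tile(mu, (5, 1))
        assert np.all(ps.linear_predictor(mu, Theta) == 0.5)

    def test_inverts_exact_logits(self):
        mu = logit(np.array([0.01, 0.2]))
        P = ps.linear_predictor(mu, np.zeros((2, 2)))
        assert P[:, 0] == pytest.approx(0.01, rel=1e-12)
        assert P[:, 1] == pytest.approx(0.2, rel=1e-12)

    def test_saturation_is_safe(self):
        P = ps.linear_predictor(np.array([700.0, -700.0]), np.zeros((1, 2)))
        assert 0.0 < P[0, 1] < P[0, 0] < 1.0
        assert np.isfinite(np.log(P)).all() and np.isfinite(np.log1p(-P)).all()


class TestBinomialLogLikelihood:
    def test_hand_example(self):
        got = ps.binomial_log_likelihood(np.array([[1.0]]), np.array([[2.0]]), np.array([[0.5]]))
        assert got == pytest.approx(math.log(0.5), abs=1e-12)

    def test_empty_cells_contribute_zero(self):
        Y = np.array([[0.0, 3.0]])
        N = np.array([[0.0, 10.0]])
        P = np.array([[0.7, 0.3]])
        with_empty = ps.binomial_log_likelihood(Y, N, P)
        alone = ps.binomial_log_likelihood(Y[:, 1:], N[:, 1:], P[:, 1:])
        assert with_empty == pytest.approx(alone, abs=1e-14)

    def test_matches_scipy_cellwise_oracle(self):
        rng = np.random.default_rng(3)
        N = rng.integers(0, 50, size=(5, 4)).astype(float)
        Y = rng.binomial(N.astype(int), 0.2).astype(float)
        P = rng.uniform(0.05, 0.95, size=(5, 4))
        expected = sum(
            binom.logpmf(Y[s, a], N[s, a], P[s, a])
            for s in range(5)
            for a in range(4)
            if N[s, a] > 0
        )
        assert ps.binomial_log_likelihood(Y, N, P) == pytest.approx(expected, abs=1e-10)

    def test_deaths_exceeding_population_rejected(self):
        with pytest.raises(ValueError):
            ps.binomial_log_likelihood(np.array([[3.0]]), np.array([[2.0]]), np.array([[0.5]]))


class TestMortalityTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            ps.MortalityTable(("a",), (0.0, 5.0), Y=[[2, 1]], N=[[1, 1]])
        with pytest.raises(ValueError, match="increasing"):
            ps.MortalityTable(("a",), (5.0, 0.0), Y=[[0, 0]], N=[[1, 1]])
        with pytest.raises(ValueError, match="T"):
            ps.MortalityTable(("a",), (0.0, 5.0), Y=[[0, 0]], N=[[1, 1]], T=0.5)


def _monolithic_log_posterior(state, data, graph, priors):
    """Independent single-formula evaluation of the joint log-posterior."""
    A = data.n_ages
    M = ps.build_M(state.rho, A) if priors.interaction else np.ones((1, A))
    eta = state.mu[None, :] + state.Phi @ M
    P = expit(eta)
    ll = float(binom.logpmf(data.Y, data.N, P)[data.N > 0].sum())
    gam = np.broadcast_to(np.asarray(state.gamma, dtype=float), (state.Phi.shape[1],))
    lp = 0.0
    for a in range(state.Phi.shape[1]):
        Q = (np.diag(graph.D) - gam[a] * graph.W) / state.sigma**2
        sign, logdet = np.linalg.slogdet(Q)
        lp += 0.5 * logdet - 0.5 * graph.n_areas * np.log(2 * np.pi)
        lp -= 0.5 * state.Phi[:, a] @ Q @ state.Phi[:, a]
    return ll + lp


class TestLogPosterior:
    def _state(self, rng, S, A, interaction=True):
        n_cols = A if interaction else 1
        return ps.ParameterState(
            mu=rng.normal(-3.0, 1.0, size=A),
            Phi=0.5 * rng.standard_normal((S, n_cols)),
            rho=float(rng.uniform(-0.8, 0.8)),
            sigma=float(rng.uniform(0.2, 2.0)),
            gamma=float(rng.uniform(-0.5, 0.9)),
        )

    def test_matches_monolithic_oracle(self):
        rng = np.random.default_rng(8)
        g = ps.make_lattice(2, 2)
        truth = ps.simulate_dataset(g, A=2, populations=(50, 500), seed=4)
        priors = ps.PriorConfig()
        for _ in range(5):
            state = self._state(rng, 4, 2)
            got = ps.log_posterior(state, truth.table, g, priors)
            want = _monolithic_log_posterior(state, truth.table, g, priors)
            assert got == pytest.approx(want, abs=1e-10)

    def test_no_interaction_decomposition(self):
        g = ps.make_lattice(2, 2)
        truth = ps.simulate_dataset(g, A=2, populations=(50, 500), seed=4)
        priors = ps.PriorConfig(interaction=False)
        mu = logit(truth.table.pooled_pods())
        state = ps.ParameterState(mu=mu, Phi=np.zeros((4, 1)), rho=0.0, sigma=1.0, gamma=0.0)
        got = ps.log_posterior(state, truth.table, g, priors)
        P = ps.linear_predictor(mu, np.zeros((4, 2)))
        ll = ps.binomial_log_likelihood(truth.table.Y, truth.table.N, P)
        const = ps.pcar_log_density(np.zeros(4), 0.0, 1.0, g)
        assert got == pytest.approx(ll + const, abs=1e-10)

    def test_flat_prior_means_mu_changes_are_pure_likelihood(self):
        rng = np.random.default_rng(9)
        g = ps.make_lattice(2, 2)
        truth = ps.simulate_dataset(g, A=2, populations=(50, 500), seed=4)
        priors = ps.PriorConfig()
        s1 = self._state(rng, 4, 2)
        s2 = ps.ParameterState(
            mu=s1.mu + rng.standard_normal(2),
            Phi=s1.Phi,
            rho=s1.rho,
            sigma=s1.sigma,
            gamma=s1.gamma,
        )
        M = ps.build_M(s1.rho, 2)
        dlik = ps.binomial_log_likelihood(
            truth.table.Y, truth.table.N, ps.linear_predictor(s2.mu, s2.Phi @ M)
        ) - ps.binomial_log_likelihood(
            truth.table.Y, truth.table.N, ps.linear_predictor(s1.mu, s1.Phi @ M)
        )
        dpost = ps.log_posterior(s2, truth.table, g, priors) - ps.log_posterior(
            s1, truth.table, g, priors
        )
        assert dpost == pytest.approx(dlik, abs=1e-10)

    def test_out_of_support_raises(self):
        g = ps.make_lattice(2, 2)
        truth = ps.simulate_dataset(g, A=2, populations=(50, 500), seed=4)
        state = ps.ParameterState(
            mu=np.zeros(2), Phi=np.zeros((4, 2)), rho=1.2, sigma=1.0, gamma=0.0
        )
        with pytest.raises(ValueError):
            ps.log_posterior(state, truth.table, g, ps.PriorConfig())

    def test_finite_inside_supports(self):
        rng = np.random.default_rng(10)
        g = ps.make_lattice(3, 3)
        truth = ps.simulate_dataset(g, A=3, populations=(10, 1000), seed=6)
        for _ in range(10):
            state = self._state(rng, 9, 3)
            assert np.isfinite(ps.log_posterior(state, truth.table, g, ps.PriorConfig()))


class TestPriorStructure:
    """Simulation checks of the prior covariance induced by Theta = Phi M."""

    @pytest.mark.parametrize("rho", [0.3, 0.8])
    def test_theta_row_correlation_is_ar1(self, rho):
        rng = np.random.default_rng(12)
        g = ps.make_lattice(3, 3)
        A, n_draws = 4, 4000
        M = ps.build_M(rho, A)
        cov = np.linalg.inv(np.diag(g.D) - 0.5 * g.W)
        L = np.linalg.cholesky(cov)
        rows = []
        for _ in range(n_draws):
            Phi = L @ rng.standard_normal((9, A))
            rows.append(Phi @ M)
        stacked = np.concatenate(rows, axis=0)  # (draws*S, A) rows of Theta
        corr = np.corrcoef(stacked.T)
        ij = np.arange(A)
        expected = rho ** np.abs(ij[:, None] - ij[None, :])
        assert np.abs(corr - expected).max() < 0.05

    def test_rho_zero_gives_independent_columns(self):
        rng = np.random.default_rng(13)
        g = ps.make_lattice(3, 3)
        M = ps.build_M(0.0, 3)
        cov = np.linalg.inv(np.diag(g.D) - 0.5 * g.W)
        L = np.linalg.cholesky(cov)
        stacked = np.concatenate(
            [(L @ rng.standard_normal((9, 3))) @ M for _ in range(3000)], axis=0
        )
        corr = np.corrcoef(stacked.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05


def test_fast_loglik_matches_reference():
    """The constant-free kernel likelihood differs only by the binomial coefficients."""
    rng = np.random.default_rng(14)
    N = rng.integers(1, 40, size=(3, 2)).astype(float)
    Y = rng.binomial(N.astype(int), 0.3).astype(float)
    eta = rng.standard_normal((3, 2))
    P = expit(eta)
    from scipy.special import gammaln

    const = (gammaln(N + 1) - gammaln(Y + 1) - gammaln(N - Y + 1)).sum()
    assert bernoulli_style_log_likelihood(Y, N, eta) + const == pytest.approx(
        ps.binomial_log_likelihood(Y, N, P), abs=1e-9
    )
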