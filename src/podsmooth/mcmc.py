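"""MCMC fitting of the age-space model and convergence/model-comparison tools.

The sampler is an adaptive Metropolis-within-Gibbs scheme targeting the
log-posterior defined in :mod:`podsmooth.model`:

* the latent spatial fields Phi are updated row-wise (one area, all columns)
  with random-walk proposals applied simultaneously to a whole *color class*
  of the adjacency graph.  Areas with the same color are pairwise
  non-adjacent, so — the PCAR prior being Markov on the graph and the
  binomial likelihood area-local — their full conditionals are independent
  and each row's accept/reject decision is valid; the whole class is
  processed in one vectorized step;
* the age intercepts mu_a have independent full conditionals (cell (s, a)
  involves only mu_a) and are updated simultaneously;
* rho and gamma move as random-walk scalars on unconstrained scales (atanh
  and scaled logit) with the Jacobian corrections that make flat priors on
  the natural scales correct, repeated a few times per sweep because they
  are the slowest-mixing directions;
* sigma^2 is drawn exactly from its truncated inverse-gamma full
  conditional;
* a translation ("recentering") Gibbs move shifts each column of Phi by a
  constant while moving the opposite shift into the intercepts mu — the
  likelihood is invariant and the flat prior on mu makes the shift's
  conditional Gaussian, which decouples the otherwise slowly mixing pair
  (mu_a, column means of Phi).

Every proposal scale adapts by Robbins-Monro with a diminishing rate, so the
chain remains ergodic while reaching sensible acceptance rates.  All
randomness flows from a single seed via ``numpy`` seed sequences with
per-chain offsets, making runs bit-reproducible.

Diagnostics follow the classic (non-split) Brooks-Gelman-Rubin potential
scale reduction, an initial-positive-sequence effective sample size, and DIC
with the plug-in deviance at the posterior mean of P* (probability scale).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit, log_expit, logit

from .graph import GAMMA_MARGIN, SpatialGraph
from .model import (
    MortalityTable,
    ParameterState,
    PriorConfig,
    binomial_log_likelihood,
    build_M,
    linear_predictor,
    log_posterior,
)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "Diagnostics",
    "run_mcmc",
    "rhat",
    "ess",
    "dic",
    "diagnose",
]


@dataclass(frozen=True)
class McmcConfig:
    """Chain lengths and seeding. Defaults mirror a 3 x 30000 WinBUGS-era run."""

    n_chains: int = 3
    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 75
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned multi-chain posterior sample of the model.

    Array shapes: ``mu`` (chains, draws, A); ``rho``/``sigma`` (chains,
    draws); ``gamma`` (chains, draws, G) with G = 1 (shared) or A;
    ``pstar`` (chains, draws, S, A), each entry strictly in (0, 1).
    """

    mu: np.ndarray
    rho: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray
    pstar: np.ndarray
    area_ids: tuple
    age_lowers: tuple
    priors: PriorConfig
    config: McmcConfig
    runtime_seconds: float = float("nan")

    @property
    def n_chains(self) -> int:
        return self.pstar.shape[0]

    @property
    def n_draws(self) -> int:
        return self.pstar.shape[1]

    def pstar_flat(self) -> np.ndarray:
        """All chains concatenated: (chains*draws, S, A)."""
        c, d, S, A = self.pstar.shape
        return self.pstar.reshape(c * d, S, A)

    def pstar_mean(self) -> np.ndarray:
        return self.pstar_flat().mean(axis=0)

    def scalar_traces(self) -> dict[str, np.ndarray]:
        """Per-parameter (chains, draws) traces for diagnostics.

        Includes every stored scalar: each mu_a, rho (interaction model
        only), sigma, each gamma, and every P*_sa cell keyed ``pstar[area:age]``.
        """
        out: dict[str, np.ndarray] = {}
        for a, lo in enumerate(self.age_lowers):
            out[f"mu[{lo:g}]"] = self.mu[:, :, a]
        if self.priors.interaction:
            out["rho"] = self.rho
        out["sigma"] = self.sigma
        if self.gamma.shape[2] == 1:
            out["gamma"] = self.gamma[:, :, 0]
        else:
            for a, lo in enumerate(self.age_lowers):
                out[f"gamma[{lo:g}]"] = self.gamma[:, :, a]
        for s, aid in enumerate(self.area_ids):
            for a, lo in enumerate(self.age_lowers):
                out[f"pstar[{aid}:{lo:g}]"] = self.pstar[:, :, s, a]
        return out


@dataclass
class Diagnostics:
    """Convergence and fit summaries with pass/fail flags."""

    rhat: dict[str, float]
    ess: dict[str, float]
    dic: float
    mean_deviance: float
    plugin_deviance: float
    p_d: float
    rhat_threshold: float = 1.1
    ess_threshold: float = 100.0

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())

    @property
    def rhat_ok(self) -> bool:
        return self.max_rhat < self.rhat_threshold

    @property
    def ess_ok(self) -> bool:
        return self.min_ess > self.ess_threshold

    @property
    def converged(self) -> bool:
        return self.rhat_ok and self.ess_ok


# ---------------------------------------------------------------------------
# sampler internals


def _color_classes(W: np.ndarray) -> list[np.ndarray]:
    g = nx.from_numpy_array(W)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    return [
        np.array(sorted(v for v, c in coloring.items() if c == k), dtype=int)
        for k in range(n_colors)
    ]


def _row_loglik(Y, N, eta):
    """Per-row binomial log-likelihood (constants dropped), vectorized."""
    return (Y * log_expit(eta) + (N - Y) * log_expit(-eta)).sum(axis=1)


class _GammaTransform:
    """Scaled-logit bijection from the real line onto the open gamma support."""

    def __init__(self, graph: SpatialGraph, margin: float = GAMMA_MARGIN):
        lo, hi = graph.gamma_support
        self.lo = lo + margin
        self.hi = hi - margin
        self.width = self.hi - self.lo

    def to_gamma(self, z):
        return self.lo + self.width * expit(z)

    def from_gamma(self, gamma):
        return logit((np.asarray(gamma) - self.lo) / self.width)

    def log_jacobian(self, z):
        # d gamma / d z = width * expit(z) * expit(-z)
        return np.log(self.width) + log_expit(z) + log_expit(-z)


def run_mcmc(
    data: MortalityTable,
    graph: SpatialGraph,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorDraws:
    """Fit the age-space model by adaptive Metropolis-within-Gibbs.

    Chains are initialized overdispersed (pooled-logit intercepts plus
    per-chain jitter) and re-drawn up to a retry cap if the starting
    log-posterior is not finite.  Given identical inputs and seed the result
    is bit-identical.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    if tuple(data.area_ids) != tuple(graph.area_ids):
        raise ValueError("mortality table and spatial graph must share area order")
    t0 = time.perf_counter()
    chains = [
        _run_chain(data, graph, priors, mcmc, chain_idx) for chain_idx in range(mcmc.n_chains)
    ]
    out = PosteriorDraws(
        mu=np.stack([c["mu"] for c in chains]),
        rho=np.stack([c["rho"] for c in chains]),
        sigma=np.stack([c["sigma"] for c in chains]),
        gamma=np.stack([c["gamma"] for c in chains]),
        pstar=np.stack([c["pstar"] for c in chains]),
        area_ids=data.area_ids,
        age_lowers=data.age_lowers,
        priors=priors,
        config=mcmc,
        runtime_seconds=time.perf_counter() - t0,
    )
    return out


def _initial_state(
    data: MortalityTable,
    graph: SpatialGraph,
    priors: PriorConfig,
    rng: np.random.Generator,
    tf: _GammaTransform,
    n_cols: int,
    jitter: float = 0.5,
):
    S, A = data.n_areas, data.n_ages
    mu = logit(data.pooled_pods()) + jitter * rng.standard_normal(A)
    Phi = 0.1 * jitter * rng.standard_normal((S, n_cols))
    z_rho = jitter * rng.standard_normal()
    z_gam = jitter * rng.standard_normal(n_cols if priors.gamma_mode == "per_age" else 1)
    v_sig = np.log(0.1) + jitter * rng.standard_normal()
    return mu, Phi, z_rho, z_gam, min(v_sig, np.log(priors.C) - 1e-9)



def _elliptical_slice(Phi, Theta, mu, M, sigma, gam_cols, lam, V, dsqrt, Y, N, rng):
    """One elliptical slice move on the whole latent field (prior-preserving)."""
    S, n_cols = Phi.shape
    zmat = rng.standard_normal((S, n_cols))
    nu = sigma * (V @ (zmat / np.sqrt(1.0 - lam[:, None] * gam_cols[None, :]))) / dsqrt[:, None]
    cur_lik = float(_row_loglik(Y, N, mu[None, :] + Theta).sum())
    log_y = cur_lik + np.log(rng.random())
    angle = rng.uniform(0.0, 2.0 * np.pi)
    lo_b, hi_b = angle - 2.0 * np.pi, angle
    for _ in range(50):
        Phi_prop = Phi * np.cos(angle) + nu * np.sin(angle)
        Theta_prop = Phi_prop @ M
        if float(_row_loglik(Y, N, mu[None, :] + Theta_prop).sum()) > log_y:
            return Phi_prop, Theta_prop
        if angle < 0.0:
            lo_b = angle
        else:
            hi_b = angle
        angle = rng.uniform(lo_b, hi_b)
    return Phi, Theta


def _run_chain(data, graph, priors, mcmc, chain_idx):
    rng = np.random.default_rng([int(mcmc.seed), int(chain_idx)])
    S, A = data.n_areas, data.n_ages
    n_cols = A if priors.interaction else 1
    n_gam = n_cols if priors.gamma_mode == "per_age" else 1
    Y, N = data.Y, data.N
    D, W = graph.D, graph.W
    lam = graph.eigenvalues
    classes = _color_classes(W)
    tf = _GammaTransform(graph)

    for _attempt in range(50):
        mu, Phi, z_rho, z_gam, v_sig = _initial_state(data, graph, priors, rng, tf, n_cols)
        rho = float(np.tanh(z_rho)) if priors.interaction else 0.0
        sigma = float(np.exp(v_sig))
        gamma = tf.to_gamma(z_gam)
        state = ParameterState(
            mu=mu,
            Phi=Phi,
            rho=rho,
            sigma=sigma,
            gamma=float(gamma[0]) if n_gam == 1 else gamma,
        )
        try:
            lp0 = log_posterior(state, data, graph, priors)
        except ValueError:
            continue
        if np.isfinite(lp0):
            break
    else:
        raise RuntimeError(
            f"chain {chain_idx}: could not find a finite starting log-posterior "
            "after 50 attempts"
        )

    M = build_M(rho, A) if priors.interaction else np.ones((1, A))
    Theta = Phi @ M
    gam_cols = np.full(n_cols, gamma[0]) if n_gam == 1 else gamma.copy()

    # eigenvectors of D^{-1/2} W D^{-1/2}, shared by all chains' gamma moves
    dsqrt = np.sqrt(D)
    _, V = np.linalg.eigh(W / np.outer(dsqrt, dsqrt))

    # adaptive proposal scales (log scale)
    ls_mu = np.full(A, np.log(0.1))
    ls_rho, ls_rho2 = np.log(0.2), np.log(0.2)
    ls_sig2 = np.log(0.1)
    ls_gam = np.full(n_gam, np.log(0.5))
    ls_gam2 = np.log(0.3)

    n_stored = mcmc.n_stored
    store = {
        "mu": np.empty((n_stored, A)),
        "rho": np.empty(n_stored),
        "sigma": np.empty(n_stored),
        "gamma": np.empty((n_stored, n_gam)),
        "pstar": np.empty((n_stored, S, A)),
    }
    k_store = 0

    for t in range(mcmc.n_iter):
        rate = (t + 10.0) ** -0.6

        # --- Phi rows, one color class at a time -------------------------
        # Each row's full conditional prior given the other rows is Gaussian
        # with mean gamma_a (W Phi)_sa / D_s and variance sigma^2 / D_s,
        # independent across the pairwise non-adjacent rows of a class, so a
        # rejection-free elliptical slice move runs vectorized per class.
        for cls in classes:
            WPhi = W[cls] @ Phi  # neighbour sums; neighbours are other-colored
            m_cond = WPhi * gam_cols[None, :] / D[cls, None]
            sd_cond = sigma / np.sqrt(D[cls])
            resid = Phi[cls] - m_cond
            nu = sd_cond[:, None] * rng.standard_normal(resid.shape)
            Yc, Nc = Y[cls], N[cls]
            cur = _row_loglik(Yc, Nc, mu[None, :] + Theta[cls])
            log_y = cur + np.log(rng.random(len(cls)))
            ang = rng.uniform(0.0, 2.0 * np.pi, len(cls))
            lo_b, hi_b = ang - 2.0 * np.pi, ang.copy()
            Phi_c, Theta_c = Phi[cls].copy(), Theta[cls].copy()
            active = np.ones(len(cls), dtype=bool)
            for _ in range(30):
                idx = np.nonzero(active)[0]
                if idx.size == 0:
                    break
                ca, sa = np.cos(ang[idx])[:, None], np.sin(ang[idx])[:, None]
                prop = m_cond[idx] + resid[idx] * ca + nu[idx] * sa
                th = prop @ M
                ok = _row_loglik(Yc[idx], Nc[idx], mu[None, :] + th) > log_y[idx]
                hit = idx[ok]
                Phi_c[hit] = prop[ok]
                Theta_c[hit] = th[ok]
                active[hit] = False
                miss = idx[~ok]
                neg = ang[miss] < 0.0
                lo_b[miss[neg]] = ang[miss[neg]]
                hi_b[miss[~neg]] = ang[miss[~neg]]
                ang[miss] = rng.uniform(lo_b[miss], hi_b[miss])
            Phi[cls] = Phi_c
            Theta[cls] = Theta_c

        # --- whole-field elliptical slice move -----------------------------
        # A prior-preserving rotation between Phi and a fresh PCAR draw,
        # vetted by the likelihood alone: decorrelates the field globally,
        # which single-site updates cannot do quickly.
        Phi, Theta = _elliptical_slice(
            Phi, Theta, mu, M, sigma, gam_cols, lam, V, dsqrt, Y, N, rng
        )

        # --- age intercepts ----------------------------------------------
        prop_mu = mu + np.exp(ls_mu) * rng.standard_normal(A)
        eta = mu[None, :] + Theta
        eta_new = prop_mu[None, :] + Theta
        dlik_col = (
            Y * (log_expit(eta_new) - log_expit(eta))
            + (N - Y) * (log_expit(-eta_new) - log_expit(-eta))
        ).sum(axis=0)
        acc = np.log(rng.random(A)) < dlik_col
        mu = np.where(acc, prop_mu, mu)
        ls_mu += rate * (acc.astype(float) - 0.44)

        # --- recentering: shift Phi columns, compensate in mu ---------------
        # Likelihood-invariant translation move; the conditional of the shift
        # delta_k under the PCAR prior (flat prior on mu) is Gaussian with
        # precision 1'Q1/sigma^2 and mean -1'Q phi / 1'Q1, Q = D - gamma_k W.
        WPhi_full = W @ Phi
        u = D @ Phi - gam_cols * WPhi_full.sum(axis=0)  # per column: 1'Q phi
        v_prec = D.sum() - gam_cols * W.sum()  # per column: 1'Q1 > 0
        delta = -u / v_prec + (sigma / np.sqrt(v_prec)) * rng.standard_normal(n_cols)
        Phi += delta[None, :]
        mu = mu - delta @ M
        Theta = Phi @ M

        # --- rho, interaction model only: interweaved pair of moves --------
        # (a) ancillary: hold Phi, let Theta = Phi M(rho') follow rho;
        # (b) sufficient: hold Theta, back-transform Phi = Theta M(rho')^{-1},
        #     so the likelihood is invariant and only the PCAR prior votes.
        if priors.interaction:
            cur_lik = float(_row_loglik(Y, N, mu[None, :] + Theta).sum())
            for _ in range(8):
                # (a) ancillary half-step
                z = np.arctanh(rho)
                z_new = z + np.exp(ls_rho) * rng.standard_normal()
                rho_new = float(np.tanh(z_new))
                M_new = build_M(rho_new, A)
                Theta_new = Phi @ M_new
                new_lik = float(_row_loglik(Y, N, mu[None, :] + Theta_new).sum())
                djac = np.log1p(-rho_new**2) - np.log1p(-rho**2)
                if np.log(rng.random()) < new_lik - cur_lik + djac:
                    rho, M, Theta, cur_lik = rho_new, M_new, Theta_new, new_lik
                    ls_rho += rate * (1.0 - 0.44)
                else:
                    ls_rho += rate * (0.0 - 0.44)

                # (b) sufficient half-step (likelihood-free)
                z = np.arctanh(rho)
                z_new = z + np.exp(ls_rho2) * rng.standard_normal()
                rho_new = float(np.tanh(z_new))
                M_new = build_M(rho_new, A)
                Phi_new = solve_triangular(M_new.T, Theta.T, lower=True).T
                qD_n = (D[:, None] * Phi_new**2).sum(axis=0)
                qW_n = (Phi_new * (W @ Phi_new)).sum(axis=0)
                qD_o = (D[:, None] * Phi**2).sum(axis=0)
                qW_o = (Phi * (W @ Phi)).sum(axis=0)
                dprior = -0.5 * float(
                    ((qD_n - gam_cols * qW_n) - (qD_o - gam_cols * qW_o)).sum()
                ) / sigma**2
                # |det M|^{-S} from the Theta->Phi change of variables,
                # det M = (1 - rho^2)^{(A-1)/2}
                dlogdetM = 0.5 * S * (A - 1) * (np.log1p(-rho**2) - np.log1p(-rho_new**2))
                djac = np.log1p(-rho_new**2) - np.log1p(-rho**2)
                if np.log(rng.random()) < dprior + dlogdetM + djac:
                    rho, M, Phi = rho_new, M_new, Phi_new
                    ls_rho2 += rate * (1.0 - 0.44)
                else:
                    ls_rho2 += rate * (0.0 - 0.44)

        # --- quadratic forms reused by sigma and gamma moves ---------------
        qD = (D[:, None] * Phi**2).sum(axis=0)  # per column: phi' D phi
        qW = (Phi * (W @ Phi)).sum(axis=0)  # per column: phi' W phi

        # --- sigma^2: exact truncated inverse-gamma Gibbs -------------------
        # p(sigma) ∝ sigma^{-K*S} exp(-q/(2 sigma^2)) on (0, C]; in sigma^2
        # this is InvGamma((K*S - 1)/2, q/2) truncated at C^2.
        q_tot = float((qD - gam_cols * qW).sum())
        shape = 0.5 * (n_cols * S - 1)
        if shape > 0 and q_tot > 0:
            for _ in range(100):
                s2 = 0.5 * q_tot / rng.gamma(shape)
                if s2 <= priors.C**2:
                    sigma = float(np.sqrt(s2))
                    break

        # --- sigma, non-centered: rescale the whole field with sigma --------
        # Holding the whitened field Phi/sigma fixed, a change of sigma
        # rescales Theta and is vetted by the likelihood alone.
        cur_lik = float(_row_loglik(Y, N, mu[None, :] + Theta).sum())
        v = np.log(sigma)
        v_new = v + np.exp(ls_sig2) * rng.standard_normal()
        sig_new = float(np.exp(v_new))
        if sig_new <= priors.C:
            r = sig_new / sigma
            new_lik = float(_row_loglik(Y, N, mu[None, :] + r * Theta).sum())
            if np.log(rng.random()) < new_lik - cur_lik + (v_new - v):
                sigma = sig_new
                Phi *= r
                Theta *= r
                cur_lik = new_lik
                ls_sig2 += rate * (1.0 - 0.44)
            else:
                ls_sig2 += rate * (0.0 - 0.44)
        else:
            ls_sig2 += rate * (0.0 - 0.44)
        qD = (D[:, None] * Phi**2).sum(axis=0)
        qW = (Phi * (W @ Phi)).sum(axis=0)

        # --- gamma (scaled-logit random walk) -------------------------------
        for _ in range(2):
            z_gam = tf.from_gamma(gamma)
            z_new = z_gam + np.exp(ls_gam) * rng.standard_normal(n_gam)
            gam_new = tf.to_gamma(z_new)
            if n_gam == 1:
                dlogdet = 0.5 * n_cols * np.log1p(-gam_new[0] * lam).sum() - (
                    0.5 * n_cols * np.log1p(-gamma[0] * lam).sum()
                )
                dquad = (gam_new[0] - gamma[0]) * float(qW.sum()) * 0.5 / sigma**2
                djac = float(tf.log_jacobian(z_new[0]) - tf.log_jacobian(z_gam[0]))
                acc1 = np.log(rng.random()) < dlogdet + dquad + djac
                if acc1:
                    gamma = gam_new
                    gam_cols[:] = gamma[0]
                ls_gam += rate * (float(acc1) - 0.44)
            else:
                dlogdet = 0.5 * (
                    np.log1p(-np.outer(gam_new, lam)).sum(axis=1)
                    - np.log1p(-np.outer(gamma, lam)).sum(axis=1)
                )
                dquad = (gam_new - gamma) * qW * 0.5 / sigma**2
                djac = tf.log_jacobian(z_new) - tf.log_jacobian(z_gam)
                acc = np.log(rng.random(n_gam)) < dlogdet + dquad + djac
                gamma = np.where(acc, gam_new, gamma)
                gam_cols = gamma.copy()
                ls_gam += rate * (acc.astype(float) - 0.44)

        # --- gamma, non-centered (shared mode): respectralize the field -----
        # Holding the whitened coordinates fixed, a new gamma re-colors the
        # field through the cached eigenbasis; the PCAR prior is invariant and
        # the likelihood decides.
        if n_gam == 1:
            z0 = float(tf.from_gamma(gamma)[0])
            z_new = z0 + np.exp(ls_gam2) * rng.standard_normal()
            g_new = float(tf.to_gamma(z_new))
            scale = np.sqrt((1.0 - gamma[0] * lam) / (1.0 - g_new * lam))
            U = V.T @ (dsqrt[:, None] * Phi)
            Phi_new = (V @ (scale[:, None] * U)) / dsqrt[:, None]
            Theta_new = Phi_new @ M
            new_lik = float(_row_loglik(Y, N, mu[None, :] + Theta_new).sum())
            djac = float(tf.log_jacobian(z_new) - tf.log_jacobian(z0))
            if np.log(rng.random()) < new_lik - cur_lik + djac:
                gamma = np.array([g_new])
                gam_cols[:] = g_new
                Phi, Theta = Phi_new, Theta_new
                ls_gam2 += rate * (1.0 - 0.44)
            else:
                ls_gam2 += rate * (0.0 - 0.44)

        # --- storage -------------------------------------------------------
        if t >= mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
            store["mu"][k_store] = mu
            store["rho"][k_store] = rho
            store["sigma"][k_store] = sigma
            store["gamma"][k_store] = gamma
            store["pstar"][k_store] = linear_predictor(mu, Theta)
            k_store += 1

    assert k_store == n_stored
    return store


# ---------------------------------------------------------------------------
# diagnostics


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) structure")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    return arr


def rhat(chains) -> float:
    """Classic Brooks-Gelman-Rubin potential scale reduction factor.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B = n * variance of the chain means (both with denominator n-1).
    """
    arr = _as_chain_matrix(chains)
    n = arr.shape[1]
    within = arr.var(axis=1, ddof=1)
    if np.any(within == 0):
        raise ValueError("constant trace in at least one chain")
    W = within.mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def ess(chains) -> float:
    """Effective sample size via the initial-positive-sequence rule.

    Total draws divided by ``1 + 2 * sum of autocorrelations``; the lag sum
    is truncated at the first negative paired (even+odd) sum and the result
    is capped at the total draw count.  Autocorrelations are chain-averaged
    autocovariances normalized by the chain-averaged variance.
    """
    arr = _as_chain_matrix(chains)
    m, n = arr.shape
    centered = arr - arr.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    acov_mean = acov.mean(axis=0)
    if acov_mean[0] == 0:
        raise ValueError("constant trace")
    rho_t = acov_mean / acov_mean[0]
    tau = -1.0
    prev_pair = np.inf
    for k in range(0, n // 2):
        pair = rho_t[2 * k] + (rho_t[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if pair < 0:
            break
        # Geyer's initial monotone refinement: the true paired sums of a
        # reversible chain are non-increasing, so cap noise excursions.
        pair = min(pair, prev_pair)
        prev_pair = pair
        tau += 2.0 * pair
    tau = max(tau, 1.0 / (m * n))
    return float(min(m * n, m * n / tau))


def dic(draws: PosteriorDraws, data: MortalityTable) -> tuple[float, float, float, float]:
    """Deviance information criterion from stored P* draws.

    Returns ``(DIC, mean_deviance, p_D, plugin_deviance)`` where deviance is
    -2 times the full binomial log-likelihood and the plug-in deviance is
    evaluated at the posterior mean of P* (probability scale).  Works for any
    number of stored draws (a single draw gives p_D = 0).
    """
    ps = draws.pstar_flat()
    devs = np.array([-2.0 * binomial_log_likelihood(data.Y, data.N, p) for p in ps])
    dbar = float(devs.mean())
    dhat = -2.0 * binomial_log_likelihood(data.Y, data.N, ps.mean(axis=0))
    p_d = dbar - dhat
    return dbar + p_d, dbar, p_d, dhat


def diagnose(
    draws: PosteriorDraws,
    data: MortalityTable,
    rhat_threshold: float = 1.1,
    ess_threshold: float = 100.0,
) -> Diagnostics:
    """R-hat and ESS for every stored scalar plus the DIC decomposition."""
    rh, es = {}, {}
    for name, trace in draws.scalar_traces().items():
        rh[name] = rhat(trace)
        es[name] = ess(trace)
    dic_val, dbar, p_d, dhat = dic(draws, data)
    return Diagnostics(
        rhat=rh,
        ess=es,
        dic=dic_val,
        mean_deviance=dbar,
        plugin_deviance=dhat,
        p_d=p_d,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
    )
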