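"""The age-space generative model for small-area probabilities of death.

Observed deaths are binomial,

    Y_sa ~ Binomial(N_sa, P*_sa),    logit(P*_sa) = mu_a + theta_sa,

with the S x A matrix of age-space effects built as Theta = Phi @ M.  The
columns of Phi are independent proper CAR (PCAR) spatial fields over the
areas, and M is the upper-triangular Cholesky factor of the AR(1)
correlation matrix Sigma_ij = rho^|i-j|, so contiguous age groups share
similar spatial patterns while the PCAR shares information between
neighbouring areas.  In the separable variant a single spatial-correlation
parameter gamma is shared by all columns of Phi; the inseparable variant
gives each column its own gamma_a.  A simpler no-interaction variant drops
the age dimension of the random effect: logit(P*_sa) = mu_a + theta_s with a
single PCAR field theta (implemented as Phi with one column mixed by a row of
ones).

Priors: flat (improper) on each mu_a, uniform on [-1, 1] for rho, uniform on
[0, C] for sigma, and uniform on the eigenvalue-bounded open support for each
gamma.  All are constant inside their supports, so the log-posterior is the
binomial log-likelihood plus the PCAR log-densities of the columns of Phi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit, gammaln, log_expit

from .graph import SpatialGraph, pcar_log_density

__all__ = [
    "MortalityTable",
    "ParameterState",
    "PriorConfig",
    "build_M",
    "theta_from",
    "linear_predictor",
    "binomial_log_likelihood",
    "log_posterior",
]

_P_FLOOR = np.finfo(float).tiny
_P_CEIL = 1.0 - np.finfo(float).epsneg


@dataclass(frozen=True)
class MortalityTable:
    """Deaths and populations on an (areas x age groups) grid.

    ``age_lowers`` are the interval lower bounds in years, strictly
    increasing; the last interval is open above.  ``T`` is the length of the
    study period in years (PoDs refer to the whole period).
    """

    area_ids: tuple
    age_lowers: tuple
    Y: np.ndarray
    N: np.ndarray
    T: float = 1.0

    def __post_init__(self):
        Y = np.asarray(self.Y)
        N = np.asarray(self.N)
        S, A = len(self.area_ids), len(self.age_lowers)
        if Y.shape != (S, A) or N.shape != (S, A):
            raise ValueError(f"Y and N must both have shape ({S}, {A})")
        if np.any(Y < 0) or np.any(N < 0):
            raise ValueError("deaths and populations must be nonnegative")
        if np.any(Y > N):
            bad = np.argwhere(Y > N)[0]
            raise ValueError(
                f"deaths exceed population for area {self.area_ids[bad[0]]!r}, "
                f"age_lower {self.age_lowers[bad[1]]}"
            )
        lowers = np.asarray(self.age_lowers, dtype=float)
        if np.any(np.diff(lowers) <= 0):
            raise ValueError("age interval lower bounds must be strictly increasing")
        if self.T < 1:
            raise ValueError(f"period length T must be >= 1 year, got {self.T}")
        object.__setattr__(self, "Y", np.ascontiguousarray(Y, dtype=float))
        object.__setattr__(self, "N", np.ascontiguousarray(N, dtype=float))
        object.__setattr__(self, "area_ids", tuple(self.area_ids))
        object.__setattr__(self, "age_lowers", tuple(float(x) for x in lowers))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_ages(self) -> int:
        return len(self.age_lowers)

    def pooled_pods(self, shrink: float = 0.5) -> np.ndarray:
        """Per-age PoDs pooled over all areas, lightly regularized.

        ``(sum_s Y_sa + shrink) / (sum_s N_sa + 2*shrink)`` — used for sampler
        initialization, always strictly inside (0, 1).
        """
        return (self.Y.sum(axis=0) + shrink) / (self.N.sum(axis=0) + 2 * shrink)


@dataclass(frozen=True)
class PriorConfig:
    """Prior and model-variant configuration.

    ``C`` bounds the uniform prior of the spatial standard deviation sigma
    (logit scale; effects beyond +-10 are epidemiologically vacuous, hence the
    default).  ``gamma_mode`` selects a shared gamma (separable model) or one
    gamma per age group; ``interaction`` switches between the full age-space
    random effect and the additive mu_a + theta_s variant.
    """

    C: float = 10.0
    gamma_mode: Literal["shared", "per_age"] = "shared"
    interaction: bool = True

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma_mode not in ("shared", "per_age"):
            raise ValueError(f"unknown gamma_mode {self.gamma_mode!r}")
        if not self.interaction and self.gamma_mode == "per_age":
            raise ValueError("per_age gamma requires the interaction model")


@dataclass
class ParameterState:
    """One point in parameter space.

    ``Phi`` has shape (S, A) for the interaction model and (S, 1) for the
    no-interaction model.  ``gamma`` is a scalar for a shared spatial
    correlation or an A-vector for the inseparable variant.  ``rho`` is the
    age-autoregression parameter, unused (kept at 0) without interaction.
    """

    mu: np.ndarray
    Phi: np.ndarray
    rho: float
    sigma: float
    gamma: float | np.ndarray

    def gamma_vector(self, n_cols: int) -> np.ndarray:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            return np.full(n_cols, float(g))
        if g.shape != (n_cols,):
            raise ValueError(f"gamma must be scalar or length {n_cols}, got shape {g.shape}")
        return g


def build_M(rho: float, A: int) -> np.ndarray:
    """Upper-triangular Cholesky factor of the AR(1) correlation matrix.

    Row 1 is (1, rho, rho^2, ...); rows i > 1 have entries
    ``rho^(j-i) * sqrt(1 - rho^2)`` on and above the diagonal.  Satisfies
    ``M.T @ M == Sigma`` with Sigma_ij = rho^|i-j|.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly in (-1, 1), got {rho}")
    if A < 1:
        raise ValueError("need at least one age group")
    j = np.arange(A)
    M = np.zeros((A, A))
    M[0] = rho**j
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, A):
        M[i, i:] = scale * rho ** (j[i:] - i)
    return M


def theta_from(Phi: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Age-space effects Theta = Phi @ M (column j mixes the latent fields)."""
    Phi = np.asarray(Phi, dtype=float)
    M = np.asarray(M, dtype=float)
    if Phi.ndim != 2 or M.ndim != 2 or Phi.shape[1] != M.shape[0]:
        raise ValueError(f"non-conformable shapes {Phi.shape} and {M.shape}")
    return Phi @ M


def linear_predictor(mu: np.ndarray, Theta: np.ndarray) -> np.ndarray:
    """Smoothed PoDs P*_sa = inverse-logit(mu_a + theta_sa), strictly in (0, 1).

    The inverse logit saturates in floating point; results are clipped to the
    open unit interval so downstream log() calls stay finite.
    """
    mu = np.asarray(mu, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(Theta))):
        raise ValueError("linear predictor inputs must be finite")
    return np.clip(expit(mu[np.newaxis, :] + Theta), _P_FLOOR, _P_CEIL)


def binomial_log_likelihood(Y: np.ndarray, N: np.ndarray, Pstar: np.ndarray) -> float:
    """Sum of binomial log-pmfs over all cells, combinatorial constant included.

    Cells with N = 0 contribute exactly 0.
    """
    Y = np.asarray(Y, dtype=float)
    N = np.asarray(N, dtype=float)
    P = np.asarray(Pstar, dtype=float)
    if np.any(Y > N):
        raise ValueError("deaths exceed population in some cell")
    if np.any((P <= 0) | (P >= 1)):
        raise ValueError("Pstar must lie strictly in (0, 1)")
    terms = (
        gammaln(N + 1)
        - gammaln(Y + 1)
        - gammaln(N - Y + 1)
        + Y * np.log(P)
        + (N - Y) * np.log1p(-P)
    )
    return float(np.where(N > 0, terms, 0.0).sum())


def bernoulli_style_log_likelihood(Y, N, eta) -> float:
    """Binomial log-likelihood from the linear predictor, constants dropped.

    ``Y*log_expit(eta) + (N-Y)*log_expit(-eta)`` is finite for any float eta,
    which the MCMC kernel relies on.  Not part of the public surface.
    """
    return float((Y * log_expit(eta) + (N - Y) * log_expit(-eta)).sum())


def log_posterior(
    state: ParameterState,
    data: MortalityTable,
    graph: SpatialGraph,
    priors: PriorConfig,
) -> float:
    """Joint log-posterior (up to the flat priors' constant) at ``state``.

    Binomial log-likelihood at P* = invlogit(mu + Phi@M) plus one PCAR
    log-density per column of Phi.  Flat priors contribute zero inside their
    supports; parameters outside any support raise ``ValueError`` rather than
    returning -inf.
    """
    A = data.n_ages
    mu = np.asarray(state.mu, dtype=float)
    Phi = np.asarray(state.Phi, dtype=float)
    if mu.shape != (A,):
        raise ValueError(f"mu must have shape ({A},), got {mu.shape}")
    n_cols = A if priors.interaction else 1
    if Phi.shape != (graph.n_areas, n_cols):
        raise ValueError(f"Phi must have shape ({graph.n_areas}, {n_cols}), got {Phi.shape}")
    if not -1.0 < state.rho < 1.0:
        raise ValueError(f"rho={state.rho} outside (-1, 1)")
    if not 0.0 < state.sigma <= priors.C:
        raise ValueError(f"sigma={state.sigma} outside (0, {priors.C}]")
    gam = state.gamma_vector(n_cols)
    if priors.gamma_mode == "shared" and np.asarray(state.gamma).ndim != 0:
        raise ValueError("shared gamma_mode requires a scalar gamma")
    for g in gam:
        if not graph.contains_gamma(float(g)):
            raise ValueError(f"gamma={g} outside the PCAR support {graph.gamma_support}")

    M = build_M(state.rho, A) if priors.interaction else np.ones((1, A))
    Pstar = linear_predictor(mu, theta_from(Phi, M))
    ll = binomial_log_likelihood(data.Y, data.N, Pstar)
    lp = sum(
        pcar_log_density(Phi[:, a], float(gam[a]), state.sigma**2, graph)
        for a in range(n_cols)
    )
    return ll + lp
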