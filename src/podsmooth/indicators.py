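"""Epidemiological indicators derived from raw or smoothed probabilities of death.

Probabilities of death (PoDs) here are *conditional*: the probability of
dying within an age interval given survival to its start, over a study
period of T years.  From a full age vector of PoDs one obtains

* age-specific rates  R_a = P_a / T  (person-year approximation);
* directly standardized rates  ASR = sum_a W_a R_a  with reference weights
  W_a = 1e5 * pob_a / sum(pob) — deaths per 100,000 reference population;
* indirectly standardized mortality ratios  SMR = 100 * observed / expected;
* marginal death probabilities  D_a = prod_{i<a}(1-P_i) * P_a  (last group:
  the survivors, who die there with certainty), summing to one;
* mean ages at death per interval (midpoint rule, a shorter first-interval
  fraction for infant intervals, exponential tail beyond the last lower
  bound with mean T / P_A);
* life expectancy at birth  LE = sum_a age_a * D_a, equivalently the nested
  product form over conditional PoDs.

When applied per MCMC draw the indicators inherit the smoothing of the
fitted PoDs; summaries (mean, median, credible intervals) are quantiles of
per-draw indicator values, never indicators of quantile PoDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .model import MortalityTable

__all__ = [
    "ReferencePopulation",
    "AgeAtDeathRule",
    "raw_pods",
    "rates_from_pods",
    "asr",
    "smr",
    "marginal_death_probs",
    "mean_ages_at_death",
    "life_expectancy",
    "decompose_theta",
    "exceedance_prob",
    "indicator_table",
]

ASR_SCALE = 1e5


@dataclass(frozen=True)
class ReferencePopulation:
    """Reference population counts per age group for direct standardization."""

    pob: np.ndarray

    def __post_init__(self):
        pob = np.asarray(self.pob, dtype=float)
        if np.any(pob < 0) or pob.sum() <= 0:
            raise ValueError("reference population must be nonnegative with positive total")
        object.__setattr__(self, "pob", pob)

    @property
    def weights(self) -> np.ndarray:
        """Standard weights W_a = 1e5 * pob_a / sum(pob); sum to 1e5."""
        return ASR_SCALE * self.pob / self.pob.sum()


@dataclass(frozen=True)
class AgeAtDeathRule:
    """Conventions for the mean age at death within each interval.

    ``first_interval_fraction`` is the fraction of the first interval lived
    by those dying in it; perinatal mortality concentrates infant deaths
    early, so for infant first intervals ([0,1) or [0,5)) the default is 0.1.
    For wider merged first intervals (e.g. [0,40)) that argument does not
    apply and the midpoint 0.5 is used unless a fraction is given explicitly.
    All other closed intervals use their midpoint; the open last interval
    gets an exponential tail with mean T / P_A past its lower bound.
    """

    first_interval_fraction: float | None = None
    other_fraction: float = 0.5

    def __post_init__(self):
        for f in (self.first_interval_fraction, self.other_fraction):
            if f is not None and not 0.0 < f < 1.0:
                raise ValueError(f"interval fractions must lie in (0, 1), got {f}")

    def fractions(self, age_lowers: Sequence[float]) -> np.ndarray:
        """Per-interval survived fraction for the A-1 closed intervals."""
        lowers = np.asarray(age_lowers, dtype=float)
        fr = np.full(len(lowers) - 1, self.other_fraction)
        if self.first_interval_fraction is not None:
            fr[0] = self.first_interval_fraction
        elif lowers[0] == 0.0 and len(lowers) > 1 and lowers[1] <= 5.0:
            fr[0] = 0.1
        return fr


def raw_pods(data: MortalityTable) -> np.ndarray:
    """Raw conditional PoDs Y/N; cells with N = 0 are NaN (undefined), never 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(data.N > 0, data.Y / np.where(data.N > 0, data.N, 1.0), np.nan)
    return P


def rates_from_pods(P: np.ndarray, T: float) -> np.ndarray:
    """Age-specific rates P/T; undefined (NaN) PoDs propagate."""
    if T < 1:
        raise ValueError(f"period length T must be >= 1, got {T}")
    return np.asarray(P, dtype=float) / T


def asr(rates: np.ndarray, ref: ReferencePopulation) -> float | np.ndarray:
    """Directly age-standardized rate sum_a W_a * R_a per 100,000 per year.

    ``rates`` may be a single A-vector or any (..., A) stack (e.g. draws x
    areas x ages).  Undefined rates are an error: smoothed PoDs should be
    used where raw cells are empty.
    """
    r = np.asarray(rates, dtype=float)
    w = ref.weights
    if r.shape[-1] != w.shape[0]:
        raise ValueError(f"rates last axis {r.shape[-1]} != {w.shape[0]} age groups")
    if np.any(np.isnan(r)):
        raise ValueError(
            "undefined age-specific rates (N=0 cells); use smoothed PoDs instead"
        )
    out = r @ w
    return float(out) if out.ndim == 0 else out


def smr(data: MortalityTable, reference_rates: np.ndarray) -> np.ndarray:
    """Standardized mortality ratio, 100 * observed / expected, per area.

    ``reference_rates`` are per-person per-period death probabilities on the
    table's age grouping.  Areas with zero expected deaths get NaN.
    """
    ref = np.asarray(reference_rates, dtype=float)
    if ref.shape != (data.n_ages,):
        raise ValueError(f"reference_rates must have shape ({data.n_ages},)")
    observed = data.Y.sum(axis=1)
    expected = data.N @ ref
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(expected > 0, 100.0 * observed / np.where(expected > 0, expected, 1.0), np.nan)


def _split_pods(p: np.ndarray, n_groups: int | None) -> np.ndarray:
    """Conditional PoDs of the A-1 closed groups from a full or trimmed vector."""
    p = np.asarray(p, dtype=float)
    if n_groups is None:
        n_groups = p.shape[-1]
    if p.shape[-1] == n_groups:
        return p[..., :-1]
    if p.shape[-1] == n_groups - 1:
        return p
    raise ValueError(f"expected {n_groups} or {n_groups - 1} PoDs, got {p.shape[-1]}")


def marginal_death_probs(P: np.ndarray, n_groups: int | None = None) -> np.ndarray:
    """Marginal (unconditional) death probabilities D from conditional PoDs.

    ``D_a = prod_{i<a}(1 - P_i) * P_a`` for the closed groups; the last,
    open group collects all survivors (death there is certain conditional on
    reaching it), so the vector sums to one exactly.  ``P`` may carry a
    conditional PoD for the last group (a full A-vector); it is ignored.
    """
    head = _split_pods(P, n_groups)
    if np.any((head < 0) | (head > 1)):
        raise ValueError("conditional PoDs must lie in [0, 1]")
    surv = np.cumprod(1.0 - head, axis=-1)
    prev = np.concatenate(
        [np.ones(head.shape[:-1] + (1,)), surv[..., :-1]], axis=-1
    )
    return np.concatenate([prev * head, surv[..., -1:]], axis=-1)


def mean_ages_at_death(
    age_lowers: Sequence[float],
    rule: AgeAtDeathRule,
    P_last: float | np.ndarray,
    T: float,
) -> np.ndarray:
    """Mean age at death per interval under the life-table conventions.

    Closed intervals: lower bound plus the rule's fraction of the width.
    Open last interval: lower bound plus T / P_A (exponential tail whose
    mean is the inverse of the group's death rate); P_A = 0 gives +inf,
    which flags an infinite life expectancy downstream.
    """
    lowers = np.asarray(age_lowers, dtype=float)
    A = len(lowers)
    widths = np.diff(lowers)
    fr = rule.fractions(lowers)
    closed = lowers[:-1] + fr * widths
    P_last = np.asarray(P_last, dtype=float)
    with np.errstate(divide="ignore"):
        tail = lowers[-1] + np.where(P_last > 0, T / np.where(P_last > 0, P_last, 1.0), np.inf)
    out = np.broadcast_to(closed, P_last.shape + (A - 1,)).copy()
    return np.concatenate([out, tail[..., np.newaxis]], axis=-1)


def life_expectancy(P: np.ndarray, age: np.ndarray) -> float | np.ndarray:
    """Life expectancy at birth: expected age at death, ``age @ D``.

    Identical to the nested product form
    ``sum_{a<A} age_a * prod_{i<a}(1-P_i) * P_a + age_A * prod_{i<A}(1-P_i)``.
    An infinite age_A yields +inf whenever anyone survives to the last group.
    """
    age = np.asarray(age, dtype=float)
    D = marginal_death_probs(P, n_groups=age.shape[-1])
    with np.errstate(invalid="ignore"):
        le = np.where(
            np.isinf(age[..., -1]) & (D[..., -1] == 0.0),
            (age[..., :-1] * D[..., :-1]).sum(axis=-1),
            (age * D).sum(axis=-1),
        )
    return float(le) if np.ndim(le) == 0 else le


def decompose_theta(Theta: np.ndarray):
    """Split the age-space effect matrix into main effects and interaction.

    Returns ``(grand_mean, age_effect, spatial_effect, interaction)`` where
    the age effect is the centred column means, the spatial effect the
    centred row means, and the interaction the doubly centred remainder;
    the four pieces reconstruct Theta exactly.
    """
    Theta = np.asarray(Theta, dtype=float)
    if not np.all(np.isfinite(Theta)):
        raise ValueError("Theta must be finite")
    m = Theta.mean()
    age = Theta.mean(axis=0) - m
    spatial = Theta.mean(axis=1) - m
    interaction = Theta - m - age[np.newaxis, :] - spatial[:, np.newaxis]
    return float(m), age, spatial, interaction


def exceedance_prob(draws_i: np.ndarray, draws_j: np.ndarray) -> float:
    """Posterior probability that unit i's indicator exceeds unit j's.

    Fraction of jointly drawn iterations with draws_i > draws_j; exact ties
    count one half.
    """
    a = np.asarray(draws_i, dtype=float)
    b = np.asarray(draws_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched draw counts: {a.shape} vs {b.shape}")
    return float(np.mean((a > b) + 0.5 * (a == b)))


# ---------------------------------------------------------------------------
# posterior indicator tables


def _summary(values: np.ndarray) -> dict[str, float]:
    finite = np.isfinite(values)
    if finite.all():
        return {
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "q025": float(np.quantile(values, 0.025)),
            "q975": float(np.quantile(values, 0.975)),
            "flag_infinite": False,
        }
    return {
        "mean": float("nan") if not finite.any() else float(values[finite].mean()),
        "median": float("nan"),
        "q025": float("nan"),
        "q975": float("nan"),
        "flag_infinite": True,
    }


def indicator_table(
    draws: PosteriorDraws,
    data: MortalityTable,
    ref: ReferencePopulation | None = None,
    rule: AgeAtDeathRule | None = None,
    smr_reference_rates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-area posterior summaries of the smoothed indicators.

    Computes, per stored draw and area, the smoothed ASR (when a reference
    population is given) and the smoothed life expectancy (the open-ended
    tail uses each draw's own last-group PoD), then summarizes across draws
    with mean, median and a central 95% credible interval.  The SMR, a
    deterministic function of the observed data, is appended when reference
    rates are supplied.  Long format: one row per (area, indicator).
    """
    rule = rule or AgeAtDeathRule()
    ps = draws.pstar_flat()  # (draws, S, A)
    T = data.T
    rows: list[dict] = []

    per_draw: dict[str, np.ndarray] = {}
    if ref is not None:
        per_draw["sASR"] = asr(rates_from_pods(ps, T), ref)  # (draws, S)
    age = mean_ages_at_death(data.age_lowers, rule, ps[..., -1], T)
    per_draw["sLE"] = life_expectancy(ps, age)

    for a_idx, lo in enumerate(data.age_lowers):
        per_draw[f"sPoD[{lo:g}]"] = ps[:, :, a_idx]

    for s, aid in enumerate(data.area_ids):
        for name, vals in per_draw.items():
            rows.append({"area_id": aid, "indicator": name, **_summary(vals[:, s])})

    if smr_reference_rates is not None:
        smr_vals = smr(data, smr_reference_rates)
        for s, aid in enumerate(data.area_ids):
            v = smr_vals[s]
            rows.append(
                {
                    "area_id": aid,
                    "indicator": "SMR",
                    "mean": v,
                    "median": v,
                    "q025": v,
                    "q975": v,
                    "flag_infinite": bool(np.isnan(v)),
                }
            )
    return pd.DataFrame(rows, columns=["area_id", "indicator", "mean", "median", "q025", "q975", "flag_infinite"])
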