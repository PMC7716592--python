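# Methods

## Model

`podsmooth` fits conditional probabilities of death (PoDs): the probability
of dying within age interval `a` during a study period of `T` years, given
survival to the interval's start, for each small area `s`. Deaths are
binomial rather than Poisson because the at-risk denominators of single
(area, age) cells are small — a binomial cell can never produce more deaths
than people, which matters exactly in the sparse regime the package targets.

The logit of the PoD decomposes into an age intercept and an age–space
random effect, `logit(P*_sa) = mu_a + theta_sa`, with `Theta = Phi M`.
The construction separates two concerns:

* **space** — each column of `Phi` is a proper CAR field,
  `N(0, sigma^2 (D - gamma W)^{-1})`, on the binary contiguity graph
  (degree matrix `D`, adjacency `W`). The PCAR is proper for every `gamma`
  strictly inside `(1/lambda_min, 1/lambda_max)`, where the lambdas are the
  extreme eigenvalues of `D^{-1/2} W D^{-1/2}`; for a connected graph the
  upper endpoint is 1 and the interval contains 0.
* **age** — `M` is the upper-triangular Cholesky factor of the AR(1)
  correlation matrix `rho^|i-j|`, so the columns of `Theta` are linear
  combinations of the independent spatial fields with exactly that
  correlation across age groups. `rho = 0` gives independent age patterns;
  `rho -> 1` forces one shared pattern.

The model is *separable* when a single `gamma` is shared by all columns and
inseparable with per-column `gamma_a` (`gamma_mode="per_age"`). A
no-interaction reference (`mu_a + theta_s`, one field broadcast over ages)
is implemented as the same machinery with a single latent column mixed by a
row of ones, and is the natural DIC comparator when one doubts that age
groups need distinct spatial patterns.

Priors are deliberately weak: improper flat on each `mu_a` (the posterior is
proper whenever every age group has at least one death pooled across areas —
see Limitations), uniform `[-1, 1]` on `rho`, uniform `[0, C]` on `sigma`
with `C = 10` by default (a logit-scale standard deviation above 10 is
epidemiologically vacuous), and uniform on the open eigenvalue-bounded
support for each `gamma`, approached no closer than a margin of `1e-6` by
the sampler.

## Sampling

No general-purpose MCMC engine is used; the sampler is written for this
posterior. One sweep combines:

1. **Latent field** — per-area row updates of `Phi` via elliptical slice
   sampling, vectorized over the color classes of a greedy graph coloring.
   Within a class, areas are pairwise non-adjacent, so given the rest of the
   field each row's conditional prior is independent Gaussian
   (mean `gamma_a (W Phi)_sa / D_s`, variance `sigma^2 / D_s`) and each
   row's likelihood involves only its own data: the rejection-free slice
   loop runs for a whole class at once. A second, global elliptical slice
   move rotates the entire field against a fresh PCAR draw.
2. **Recentering** — the flat prior on `mu_a` makes the pair (`mu`, column
   means of `Phi`) a slow translation direction. A Gibbs move samples the
   shift of each `Phi` column exactly (the conditional is Gaussian because
   the likelihood is invariant when `mu` absorbs the compensating
   `-delta M_k.`) and removes that pathology.
3. **Age intercepts** — simultaneous scalar random-walk updates (columns
   are conditionally independent), with Robbins–Monro adaptation to a 0.44
   acceptance rate.
4. **rho** — interweaved pairs of moves on `atanh(rho)`: an *ancillary*
   step holding `Phi` (likelihood decides) and a *sufficient* step holding
   `Theta` and back-solving `Phi = Theta M^{-1}` (prior and the
   `|det M|^{-S}` Jacobian decide, likelihood invariant). Both conditionals
   are narrow relative to the marginal, so the pair is repeated several
   times per sweep.
5. **sigma** — exact Gibbs for `sigma^2` from its truncated inverse-gamma
   full conditional, followed by a non-centered rescale of the whole field
   vetted by the likelihood.
6. **gamma** — random-walk on a scaled logit of the open support, plus (in
   the shared-gamma case) a non-centered "respectralization" that holds the
   whitened field fixed through the cached eigenbasis of
   `D^{-1/2} W D^{-1/2}` while `gamma` moves.

All proposal scales adapt with a diminishing Robbins–Monro rate, so
ergodicity is preserved. Every random number flows from the single
configuration seed through `numpy` seed sequences `[seed, chain_index]`;
identical inputs give bit-identical draws. Chains start overdispersed
(pooled-logit intercepts plus jitter of scale 0.5) and initialization is
retried if the starting log-posterior is not finite.

The log-determinant of the PCAR precision is evaluated from the precomputed
eigenvalues (`log det(D - gamma W) = sum log D_s + sum log(1 - gamma
lambda_i)`), making every `gamma` and density evaluation O(S + edges) after
one symmetric eigendecomposition.

## Diagnostics and model comparison

R-hat is the classic (non-split) Brooks–Gelman–Rubin factor,
`sqrt(((n-1)/n W + B/n)/W)`, matching the convention of the WinBUGS-era
workflow this model class comes from; the usual bar is R-hat < 1.1 and
effective sample size > 100 for every stored scalar (each `mu_a`, `rho`,
`sigma`, each `gamma`, and all S×A smoothed PoDs). ESS divides total draws
by `1 + 2 sum rho_t` with the autocorrelation sum truncated at the first
negative even+odd pair (Geyer initial-positive rule) and the pair sums
capped to be non-increasing (initial-monotone refinement); the estimate is
capped at the total draw count.

DIC is `mean(D) + pD` with `D = -2 log L` (binomial, constants included)
and `pD = mean(D) - D(posterior mean of P*)`. The plug-in is taken on the
probability scale — the stochastic parents of the data — which is the
closest well-defined analogue of the BUGS convention; DIC values are
therefore comparable between the interaction and no-interaction variants
fitted here, but exact equality with other software's DIC is not promised,
only the ordering behaviour.

## Indicators

* Rates: `R_sa = P_sa / T` (person-years approximated by population times
  period length); with `T = 1`, rates equal PoDs.
* ASR: `sum_a W_a R_sa` with `W_a = 1e5 * pob_a / sum(pob)`; the scale
  1e5 (deaths per 100,000 reference population) is the documented default
  and configurable.
* SMR: `100 * observed / expected`, expected from reference age-specific
  probabilities; zero expected deaths yields an undefined (NaN) value.
* Marginal death probabilities: `D_a = prod_{i<a}(1-P_i) P_a`, last group
  takes all survivors; sums to one identically.
* Mean age at death: closed intervals use the lower bound plus a fraction
  of the width — 0.5 everywhere except an infant first interval ([0,1) or
  [0,5)), which defaults to 0.1 because perinatal deaths concentrate early.
  When the first interval is a wide merge such as [0,40), the perinatal
  argument does not apply and the midpoint is used unless the user sets the
  fraction explicitly. The open last interval adds an exponential tail of
  mean `T / P_A` to its lower bound; `P_A = 0` gives +inf, which flags an
  infinite life expectancy rather than raising.
* Life expectancy: `LE = sum_a age_a D_a`, algebraically identical to the
  nested-product form over conditional PoDs and to a classical abridged
  life table under the same age-at-death conventions (the tests verify the
  triple agreement to 1e-9 years).
* Posterior summaries of sASR and sLE are computed **per draw** and then
  summarized (mean, median, 2.5/97.5% quantiles); computing indicators of
  summarized PoDs would be wrong under these nonlinear maps. The smoothed
  LE uses each draw's own last-group PoD in the tail, so the raw-data
  infinite-LE pathology (areas with no last-group deaths) disappears after
  smoothing while raw LE faithfully reproduces it.

## Synthetic data

Real small-area mortality registries cannot be redistributed, so the
generator draws from the model itself on rook-contiguity lattices. Default
conditions mimic the sparse registry regime: per-area totals log-uniform
over a configurable range (1e2 to 1e5 by default, narrowed to put the
median near 750 for the recovery design, matching small-municipality
populations), a geometrically declining age pyramid (ratio 0.85), age
intercepts rising logit-linearly from about 1e-4 to 0.15, and binomial
deaths — which makes the majority of (area, age) cells empty, as in real
municipal tables. Ground truth (parameters and the true `P*`) is retained
for recovery and coverage experiments.

What the generator does **not** emulate: irregular real cartographies
(adjacency is a lattice), covariates, temporal drift, overdispersion beyond
the model, and data-quality artifacts (late registration, miscoded ages).
Passing recovery tests therefore demonstrates correctness of the
implementation under the model's own assumptions, not robustness to model
misspecification.

## Problem sizes used in checks

The recovery experiment runs one 10×10 lattice with 6 age groups and
chains of 5000 iterations (burn-in 1000, thinning 10, 3 chains — 1200
stored draws); the DIC comparison uses ten 6×6/4-age datasets per regime
with 2×2500 chains. These sizes keep the full check suite at desk scale
while leaving the qualitative conclusions (parameter recovery, convergence
at the usual thresholds, DIC ordering, smoothing-variance reduction)
clearly resolved.

## Known limitations

* With an all-zero age group (no deaths pooled across areas) the flat
  intercept prior makes the posterior improper in that `mu_a`; the intended
  use — as in the published applications of this model class — merges young
  age groups until every group has deaths. The sampler does not guard
  against this; the intercept of an empty group will drift toward -inf.
* Per-age variances `sigma_a^2`, covariates, zero-inflation and Poisson
  likelihoods are out of scope.
* Isolated areas (no neighbours) are rejected: the PCAR formulation is
  undefined for them and no island convention is invented.
* The inseparable (per-age gamma) variant lacks the non-centered gamma
  move and mixes more slowly; it is intended for moderate problems.
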