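# podsmooth

Age–space smoothing of small-area probabilities of death, and the
epidemiological indicators it unlocks: smoothed age-standardized rates
(sASR), smoothed life expectancy (sLE) and standardized mortality ratios
(SMR).

## The problem

Most mortality indicators depend strongly on the age composition of the
population, so comparing raw rates across small areas (municipalities,
census tracts) confounds age structure with real risk differences.
Age-standardized rates and life expectancies fix the confounding but need a
*reliable* age-specific death probability for every (area, age group) cell —
and in small-area tables most cells contain zero deaths. `podsmooth`
estimates those probabilities with a Bayesian hierarchical model that
borrows strength between neighbouring areas *and* contiguous age groups at
the same time, then derives the downstream indicators per MCMC draw so that
each one comes with credible intervals.

## The model

For areas `s = 1..S` and age groups `a = 1..A`, with deaths `Y_sa` out of
population `N_sa`:

    Y_sa ~ Binomial(N_sa, P*_sa)
    logit(P*_sa) = mu_a + theta_sa
    Theta = Phi M

* each column of the S×A matrix `Phi` is an independent proper CAR (PCAR)
  spatial field over the adjacency graph:
  `Phi_.a ~ N(0, sigma^2 (D - gamma_a W)^{-1})`;
* `M` is the upper-triangular Cholesky factor of the AR(1) correlation
  matrix `Sigma_ij = rho^|i-j|`, so `M'M = Sigma` and contiguous age groups
  share correlated spatial patterns;
* priors: flat on `mu_a`, uniform on `[-1, 1]` for `rho`, uniform `[0, C]`
  for `sigma`, and uniform on the eigenvalue-bounded support
  `(1/lambda_min, 1/lambda_max)` of `D^{-1/2} W D^{-1/2}` for `gamma`.

The separable variant shares one `gamma` across all columns; an inseparable
variant gives each column its own `gamma_a`. A no-interaction reference
model (`logit(P*_sa) = mu_a + theta_s`, one shared spatial field) is
included for DIC comparison.

From the smoothed `P*` the package computes rates `R* = P*/T`, directly
standardized rates `sASR_s = sum_a W_a R*_sa` with reference weights summing
to 100,000, marginal death probabilities, mean ages at death (midpoint rule,
a shorter infant first-interval fraction, exponential open-ended tail with
mean `T / P*_sA`), and life expectancy at birth `LE_s = sum_a age_a D_sa`.

## Worked example

```python
import numpy as np
import podsmooth as ps

graph = ps.make_lattice(10, 10)                       # rook-contiguity grid
truth = ps.simulate_dataset(                          # registry-like sparse data
    graph, A=6, rho=0.7, sigma=0.5, gamma=0.9,
    populations=(56.0, 10000.0), seed=42,
)
print((truth.table.Y == 0).mean())                    # 0.548  (sparse cells)

draws = ps.run_mcmc(
    truth.table, graph, ps.PriorConfig(),
    ps.McmcConfig(n_chains=3, n_iter=5000, burn_in=1000, thin=10, seed=7),
)
diag = ps.diagnose(draws, truth.table)
print(round(diag.max_rhat, 3), round(diag.min_ess))   # 1.021 166
lo, hi = np.quantile(draws.rho, [0.025, 0.975])
print(round(draws.rho.mean(), 3), (round(lo, 2), round(hi, 2)))
                                                      # 0.778 (0.47, 0.97)
```

The posterior mean of the age-autoregression parameter (0.778) recovers the
generating value 0.7 inside its 95% credible interval; all R-hat values are
below 1.1 and every stored parameter has more than 100 effective draws, the
usual convergence bar for this model class. Indicators come from
`ps.indicator_table(draws, truth.table, ref=...)`, which evaluates sASR and
sLE per draw and summarizes them with means, medians and 95% intervals.

The same pipeline is available from a shell:

```bash
podsmooth simulate --nrows 10 --ncols 10 --age-groups 6 --seed 1 --out-dir data/
podsmooth fit --counts data/counts.csv --edges data/edges.csv \
    --chains 3 --iterations 5000 --burn-in 1000 --thin 10 --seed 2 --out-dir fit/
podsmooth diagnose --draws-dir fit/ --counts data/counts.csv
podsmooth indicators --draws-dir fit/ --counts data/counts.csv \
    --reference-population ref.csv --out indicators.csv
```

Every run writes a `manifest.json` (input hashes, configuration, seed) so
results can be reproduced bit-identically.

## Layout

| module | contents |
| --- | --- |
| `podsmooth.graph` | adjacency parsing (edge list, GAL), gamma support, PCAR log-density |
| `podsmooth.model` | M-matrix, linear predictor, binomial likelihood, joint log-posterior |
| `podsmooth.mcmc` | adaptive Metropolis-within-Gibbs sampler, R-hat, ESS, DIC |
| `podsmooth.indicators` | raw/smoothed PoDs, rates, ASR, SMR, life expectancy, decomposition |
| `podsmooth.simulate` | lattice geographies, generative simulation, recovery experiments |
| `podsmooth.io` / `podsmooth.cli` | delimited-text formats, run configs, manifests, CLI |
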