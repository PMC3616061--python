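# shearwater-census

A Bayesian census pipeline for burrow-nesting seabird colony systems,
built around the flesh-footed shearwater (*Puffinus carneipes*) population
of Lord Howe Island. It is aimed at quantitative ecologists who need to
estimate the size and trend of a colony system from partial,
non-contemporaneous field data — belt-transect burrow counts, small
samples of chick and occupancy checks, literature summaries from earlier
censuses — while propagating every source of uncertainty through to the
final population statements.

## Models

**Burrow abundance.** Counts per 40 m² belt-transect section in colony *i*
are overdispersed counts,

```
B_ij ~ Poisson(a_ij · λ_i · ε_ij),   ε_ij ~ Gamma(α, α)   (unit mean)
```

equivalently negative binomial with mean `a_ij·λ_i` and shape α
(uniform(0.4, 2.5) prior on the shape parameters; vague Gamma(0.01, 0.01)
prior on each density λ_i). The burrow total of a colony with area A_i is
the observed count plus a posterior-predictive draw for the unsurveyed
remainder, so the variance of the total shrinks to zero as survey coverage
approaches one (a finite-population correction); a fully counted colony is
an exact census with zero variance. The island total B = Σ_i B_i is summed
draw-wise.

**Reproduction.** Productivity θ_i (chick per burrow) and occupancy τ_i
(pair per burrow) are binomial rates with Beta priors; published mean ± SE
estimates from earlier work enter as Normal likelihood terms. Chick and
pair totals are simulated binomially per posterior draw,
`N_i ~ Binomial(B_i, θ_i)`, `Pop_i ~ Binomial(B_i, τ_i)`, so count and
rate uncertainty propagate jointly. Seasons with productivity checks but
no occupancy checks are imputed through a constant cross-colony
relationship `logit(τ) = a + b·logit(θ) + δ_season + e` with Student-t
residuals.

**Road mortality.** Carcasses persist with daily probability 1 − r, with r
estimated from a marked cohort via `c2/c1 = (1−r)^(t2−t1)`. With constant
daily kills m, the count at season day T satisfies
`M' = m·(1−(1−r)^T)/r`, which is inverted per posterior draw for the
season total `M = m·T`. A Poisson GLM of transect band counts on distance
from the road (log-area offset) extrapolates the surveyed strips to the
whole roadside. The survival cost is expressed through the life-expectancy
estimator `LE = −1/ln(φ)`.

**Trend.** Current posteriors are compared draw-wise with historical
censuses published as mean ± SE, giving percent change, its credible
interval and the posterior probability of decline.

Inference is by an in-package adaptive Metropolis-within-Gibbs sampler
(proposal scales tuned during burn-in only), with split-chain Gelman–Rubin
Rhat and autocorrelation-based effective sample sizes; conjugate
sub-posteriors are sampled exactly.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
island generated by the package (six colonies with the published areas and
transect layouts, ~6% survey coverage):

```sh
python analysis/01_simulate_data.py --seed 1
python analysis/02_census_burrows.py --seed 1
```

```
island truth: 26636 burrows; daily road kills m=0.75, disappearance r=0.0052
colony  burrows           95% CI   truth
LMG          58      12-163           55
CP        11589    9740-13720      11311
...
island total 26316 (PSD 1418, 95% CI 23764-29211); truth 26636
worst Rhat 1.006
```

Each colony row is the posterior burrow total against the simulated truth;
the island 95% credible interval covers the true 26,636 burrows, and the
fully counted colony (HB) comes back exact (94, zero variance). The later
drivers continue the chain — `03` reproduction (`total pairs 16188
(14028-18472)`), `04` road mortality (`r = 0.0052/day`, season mortality
`151 (67-302)` over 180 days, life expectancy `12 y at phi=0.92 vs 11.4 y
at 0.916`), `05` trend (`p(decline)` per historical census), and `06` a
simulation-based calibration of interval coverage.

The same stages are available as a CLI:
`shearwater-census simulate|census|roadkill|trend|all --seed N --out-dir DIR [--fast]`.

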