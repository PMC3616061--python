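# Methods

## The estimation problem

A colony system of a burrow-nesting seabird is censused by belt transects:
straight strips divided into 40 m² sections in which every apparent burrow
is counted. Coverage is sparse (roughly 6% of colony area), chick and
occupancy checks are small samples from a subset of colonies and seasons,
and earlier island-wide censuses survive only as published mean ± SE
summaries. The pipeline estimates burrow totals, chick production and
breeding pairs with full uncertainty propagation, corrects a roadside
carcass survey for carcass disappearance, and quantifies the population
trend against the historical summaries.

## Burrow-density model

Section counts are Poisson with a multiplicative Gamma section effect:

    B_ij ~ Poisson(a_ij · λ_i · ε_ij),   ε_ij ~ Gamma(α, β) / (α/β)

The unit-mean rescaling keeps λ_i interpretable as the mean burrow density
of colony i (burrows m⁻²). A consequence worth stating plainly: after
rescaling, ε_ij ~ Gamma(α, α) in distribution, so the rate parameter β has
no likelihood role — it is carried with its uniform(0.4, 2.5) prior for
completeness, and its posterior equals its prior. Overdispersion is
governed by α alone (Var ε = 1/α). For sampling, ε is marginalised
analytically: counts are negative binomial with mean a_ij·λ_i and shape α,
which gives identical posteriors for (λ, α) at a fraction of the
dimensionality.

Priors: λ_i ~ Gamma(0.01, 0.01) (positive support, conjugate-checkable in
the Poisson limit, negligible information at observed scales); α, β ~
uniform(0.4, 2.5). Sections are treated as exchangeable within a colony —
no along-transect autocorrelation. Partial end sections carry their true
area as the Poisson offset.

**Finite-population totals.** The burrow total of colony i is, per
posterior draw,

    B_i = observed count + NB(shape = n_u·α, mean = A_u·λ_i)

where A_u is the unsurveyed area and n_u = A_u/40 its section count (the
negative binomial sum of n_u unit-mean-Gamma-mixed Poisson sections; the
shape adds over independent sections, and fractional n_u is accepted).
This realises the coverage-dependent variance behaviour exactly: the
variance of B_i is non-increasing in surveyed fraction, reaches zero at
full coverage, and a fully counted colony is reported as an exact census
(zero posterior SD). We chose explicit prediction of the unseen remainder
over a variance-deflation factor in the likelihood because it produces the
stated limit behaviour by construction and composes draw-wise with every
downstream quantity.

## Reproduction models

Productivity θ_i and occupancy τ_i are binomial rates with Beta(1, 1)
priors. Pure-binomial posteriors are conjugate and sampled exactly from
the Beta posterior; when published summaries enter (as Normal(mean, se)
likelihood terms on the rate), the one-dimensional posterior is sampled by
MCMC. Colonies with no checks take the draw-wise mean of the sampled
colonies' rates.

Chick and pair totals are simulated binomially per draw —
N_i ~ Binomial(B_i, θ_i), Pop_i ~ Binomial(B_i, τ_i) — rather than formed
as deterministic products, so binomial sampling noise appears in the
totals alongside parameter uncertainty, and the draw-wise bounds
N_i ≤ B_i, Pop_i ≤ B_i hold by construction.

**Occupancy imputation.** Where a season has productivity but no occupancy
data, occupancy is predicted from a constant cross-colony relationship fit
on the logit scale with Student-t residuals:

    logit(τ) = a + b·logit(θ) + δ_season + e,   e ~ t_ν(0, σ)

ν defaults to 3 (heavy tails with finite variance; configurable), the
year effect δ is an additive intercept shift per season (the earliest
season is the reference; applying the effect to the slope as well was
considered and rejected as unidentifiable at three seasons of calibration
data), and predictive draws include the t noise before the inverse logit,
which keeps predictions in [0, 1] without truncation. Priors: N(0, 5²) on
a, b and δ; half-normal(1) on σ. The fit refuses degenerate calibration
sets (fewer than 3 pairs, or all productivities equal).

**Design-based alternative.** The non-hierarchical comparator multiplies
the burrow-total and occupancy point estimates, with the variance of a
product of independent estimates (B²σ_τ² + τ²σ_B² + σ_B²σ_τ²) and normal
2.5–97.5% limits.

**Breeding success** is chicks per egg with the denominator augmented by
chicks found late without a January egg record — a simple stand-in for the
unpublished adjustment procedure used by earlier censuses, flagged as such.

## Road mortality

Daily carcass persistence is geometric: a carcass survives d days with
probability (1 − r)^d, the discrete counterpart of an exponential carcass
lifetime. From a marked cohort (c1 marked, c2 present after Δt days) the
point estimate is r = 1 − (c2/c1)^(1/Δt); the posterior uses the binomial
likelihood c2 ~ Binomial(c1, (1−r)^Δt) with a uniform prior, and remains
proper when c2 = 0 (where the closed form is undefined).

With constant daily kills m, the carcasses present at count day T are

    M' = m · Σ_{t=1..T} (1−r)^(T−t) = m · (1 − (1−r)^T)/r

inverted per draw for m and the season total M = m·T; at r = 0 this
reduces to M = M'. M' itself comes from a Poisson GLM of per-band carcass
counts on distance-band midpoint with a log-area offset (statsmodels IRLS),
extrapolated over the roadside strip geometry with coefficient-covariance
uncertainty; out-of-range bands trigger an extrapolation warning, and
all-zero counts give a flagged boundary fit (capped intercept) rather than
an IRLS failure. M' and r draws are paired independently.

The season length T defaults to 180 days (arrival in early November to
fledging in early May) and is a configuration field; the marked-cohort
interval in the bundled data is 107 days (1 January to 17 April).
Detection within surveyed strips is assumed perfect. Life expectancy uses
LE = −1/ln(φ) for annual survival φ, and road deaths are converted to an
annual survival decrement and an LE reduction against a φ = 0.92 baseline.

## Trend

Historical censuses are modelled as Normal(mean, se) — SEs being what the
prior literature reports — truncated at zero for count metrics. Percent
change is computed draw-wise against the current posterior; the headline
follows the census convention (a decline as a positive percentage, the raw
change interval alongside) with p(decline) the fraction of draws below
zero. Annualization is geometric: (1 + c)^(1/years) − 1.

## MCMC

The sampler is component-wise random-walk Metropolis on unconstrained
scales (log for half-bounded, logit for box-bounded parameters, Jacobians
folded into the target). Proposal scales adapt every 50 iterations toward
44% acceptance during burn-in only, and are frozen afterwards so the
retained chain is Markovian. Chains start from overdispersed points drawn
from per-chain seed streams; a given (seed, config, data) triple is
bit-reproducible. The reference protocol is 100,000 iterations, 50,000
burn-in, 5 chains, thinning 10; the shipped `fast` setting (4,000/2,000/3/1)
and the calibration setting (1,500/750/2/1) were sized for the
low-dimensional targets here, and pilot runs hold split-Rhat below 1.01 on
every monitored node at those settings. Rhat is the split-chain
Gelman–Rubin factor (zero-variance chains return 1 by convention);
effective sample size uses FFT autocorrelations with Geyer's
initial-positive-sequence truncation, capped at the draw count (constant
chains return the draw count). An Rhat above 1.01 is recorded as a manifest
warning, never an exception.

## Synthetic data

The generator emulates exactly the structures the models assume:
Gamma-mixed Poisson section counts tiled over each colony (the true total
is the realised sum over all sections, so calibration compares posteriors
to realised truth, not to the expectation); binomial chick and occupancy
checks with optional logit-scale year effects; a daily carcass process
(Poisson kills, truncated-exponential distance-from-road placement,
geometric persistence, thinning onto surveyed transects) plus a marked
cohort; historical summaries as normal perturbations of a true trajectory.
One integer seed drives a named stream per generator so data families
regenerate independently.

The default scenario mirrors the published system: six colonies with the
published areas and transect layouts, densities 0.015–0.148 burrows m⁻²,
occupancy ≈ 0.6–0.67, productivity ≈ 0.3–0.44, breeding success 0.69,
α = 1.2, m = 0.75 kills day⁻¹, r = 0.0052 day⁻¹, T = 180. What the
generator does **not** emulate: spatial autocorrelation along transects,
imperfect burrow or carcass detection, observer effects, and
between-season demographic stochasticity beyond the year effect — so
passing calibration shows the estimators are self-consistent at realistic
sizes and noise levels, not that real surveys are free of those additional
error sources.

## Validation strategy

The published posterior values (27,323 burrows, 16,267 pairs, 135 road
deaths, the 8.5%/6.8% declines) cannot be reproduced exactly: they depend
on per-section raw counts, earlier-census SEs, road lengths and a season
length that were never published. The pipeline is therefore validated by
(i) exact reproduction of every closed-form quantity that *is* printed
(densities 12.5 and 0.49 carcasses/1000 m², 121 background carcasses, the
12 vs 11.4 year life expectancies, table marginals), (ii) conjugate and
grid oracles for each sampler, and (iii) simulation-based calibration:
50 replicates of simulate→fit→score, requiring pooled 95% CI coverage for
λ, τ, θ, r and the island total in the 90–99% band. Coverage is assessed
pooled across those quantities (450 interval/truth trials) because a
single scalar at 50 replicates has a non-trivial chance of 100% observed
coverage under nominal behaviour.

## Numerical choices and limitations

- Count likelihoods use `xlogy` so zero counts at vanishing means do not
  produce NaNs; boundary rates (e.g. all marked carcasses persisting) fall
  back to well-defined conventions with warnings.
- The smallest colony's published surveyed area is internally inconsistent
  with its published density (16 burrows/560 m² = 0.029 vs printed 0.015,
  which matches 1,120 m²); the bundled table stores the printed values
  verbatim and the loader flags the discrepancy rather than fixing it.
- Independent draw pairing is used when composing posteriors estimated
  separately (GLM coefficients × r); any real dependence between carcass
  deposition and persistence is not modelled.
- The sampler is adequate for the low-dimensional, well-identified targets
  here; it is not a general-purpose PPL and strongly multimodal targets
  will be flagged by Rhat rather than explored.
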