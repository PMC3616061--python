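"""Chick production, burrow occupancy and breeding-pair estimation.

Productivity θ_i (probability a burrow holds a near-fledging chick) and
occupancy τ_i (probability a burrow holds a breeding pair) are binomial
rates with vague Beta priors.  Chick and pair totals are simulated
binomially per posterior draw — N_i ~ Binomial(B_i, θ_i) — so burrow-count
uncertainty and sampling noise both propagate through the model graph
rather than being combined post hoc.

Where occupancy was not measured in a season, it is imputed from the
(assumed constant across colonies) relationship between occupancy and
productivity, fit on the logit scale with Student-t residuals and an
additive year effect.  Published summaries from earlier censuses enter as
Normal(mean, se) evidence on the rates.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm, t as student_t

from .mcmc import Model, Parameter, PosteriorSummary, run_mcmc
from .records import (ChickStation, HistoricalSummary, OccupancyRecord,
                      RunConfig, ValidationError, season_index)

__all__ = [
    "fit_productivity", "estimate_chicks", "fit_occupancy", "impute_occupancy",
    "estimate_pairs", "design_based_pairs", "breeding_success",
    "BreedingSuccess", "OccupancyRelationship",
]


def _n_draws(config: RunConfig) -> int:
    return config.chains * config.draws_per_chain


def fit_productivity(stations: Sequence[ChickStation], config: RunConfig,
                     colonies: Optional[Sequence[str]] = None,
                     seed: int = 0) -> Dict[str, PosteriorSummary]:
    """Per-colony productivity posteriors θ_i from station chick checks.

    The binomial likelihood with a Beta prior is conjugate, so draws are
    taken exactly from the Beta posterior.  Colonies listed in ``colonies``
    without any stations receive the draw-wise mean of the sampled colonies'
    θ (the stated pooling rule for unsampled colonies).
    """
    a0, b0 = config.occupancy_prior
    n = _n_draws(config)
    rng = np.random.default_rng(seed)
    checked: Dict[str, int] = {}
    found: Dict[str, int] = {}
    for s in stations:
        checked[s.colony_id] = checked.get(s.colony_id, 0) + s.burrows_checked
        found[s.colony_id] = found.get(s.colony_id, 0) + s.chicks_found
    if not checked:
        raise ValueError("no chick stations supplied")
    out: Dict[str, PosteriorSummary] = {}
    sampled = []
    for cid in sorted(checked):
        draws = rng.beta(a0 + found[cid], b0 + checked[cid] - found[cid], size=n)
        out[cid] = PosteriorSummary.from_draws(f"theta[{cid}]", draws)
        sampled.append(draws)
    pooled = np.mean(sampled, axis=0)
    for cid in colonies or []:
        if cid not in out:
            out[cid] = PosteriorSummary.from_draws(f"theta[{cid}]", pooled.copy())
    return out


def _binomial_totals(burrow_totals: Dict[str, PosteriorSummary],
                     rates: Dict[str, PosteriorSummary],
                     prefix: str, total_name: str,
                     seed: int) -> Dict[str, PosteriorSummary]:
    lengths = {len(s.draws) for s in burrow_totals.values()}
    lengths |= {len(s.draws) for s in rates.values()}
    if len(lengths) != 1:
        raise ValueError(f"mismatched draw counts: {sorted(lengths)}")
    rng = np.random.default_rng(seed)
    out: Dict[str, PosteriorSummary] = {}
    per_colony = []
    for cid in burrow_totals:
        if cid not in rates:
            raise ValueError(f"no rate posterior for colony {cid!r}")
        b = np.round(burrow_totals[cid].draws).astype(np.int64)
        p = np.clip(rates[cid].draws, 0.0, 1.0)
        draws = rng.binomial(b, p)
        per_colony.append(draws)
        out[cid] = PosteriorSummary.from_draws(f"{prefix}[{cid}]", draws.astype(float))
    out["total"] = PosteriorSummary.from_draws(
        total_name, np.sum(per_colony, axis=0).astype(float))
    return out


def estimate_chicks(burrow_totals: Dict[str, PosteriorSummary],
                    theta: Dict[str, PosteriorSummary],
                    seed: int = 0) -> Dict[str, PosteriorSummary]:
    """Draw-wise N_i ~ Binomial(B_i, θ_i) per colony plus the island total."""
    return _binomial_totals(burrow_totals, theta, "N", "N_total", seed)


def estimate_pairs(burrow_totals: Dict[str, PosteriorSummary],
                   tau: Dict[str, PosteriorSummary],
                   seed: int = 0) -> Dict[str, PosteriorSummary]:
    """Draw-wise Pop_i ~ Binomial(B_i, τ_i) per colony plus the island total."""
    return _binomial_totals(burrow_totals, tau, "Pop", "Pop_total", seed)


def fit_occupancy(records: Sequence[OccupancyRecord], config: RunConfig,
                  priors: Sequence[HistoricalSummary] = (),
                  seed: int = 0) -> Dict[str, PosteriorSummary]:
    """Per-colony occupancy posteriors τ_i from burrow checks plus literature.

    With only binomial data the Beta posterior is sampled exactly; published
    Normal(mean, se) occupancy summaries add non-conjugate likelihood terms,
    in which case the one-dimensional posterior is sampled by MCMC.
    """
    a0, b0 = config.occupancy_prior
    n = _n_draws(config)
    checked: Dict[str, int] = {}
    occupied: Dict[str, int] = {}
    for r in records:
        checked[r.colony_id] = checked.get(r.colony_id, 0) + r.burrows_checked
        occupied[r.colony_id] = occupied.get(r.colony_id, 0) + r.burrows_occupied
    lit: Dict[str, list] = {}
    for h in priors:
        if h.metric != "occupancy":
            continue
        if not (0.0 <= h.mean <= 1.0):
            raise ValidationError(f"literature occupancy mean {h.mean} outside [0,1]")
        lit.setdefault(h.colony_id, []).append((h.mean, h.se))

    out: Dict[str, PosteriorSummary] = {}
    rng = np.random.default_rng(seed)
    for cid in sorted(set(checked) | set(lit)):
        k = occupied.get(cid, 0)
        m = checked.get(cid, 0)
        terms = lit.get(cid, [])
        if not terms:
            draws = rng.beta(a0 + k, b0 + m - k, size=n)
        else:
            def log_density(x, k=k, m=m, terms=terms):
                tau = x[0]
                lp = (a0 - 1) * math.log(tau) + (b0 - 1) * math.log(1 - tau)
                if m:
                    lp += k * math.log(tau) + (m - k) * math.log(1 - tau)
                for mean, se in terms:
                    lp += norm.logpdf(tau, mean, max(se, 1e-9))
                return lp
            init = (k + terms[0][0] * 10 + 1) / (m + 12)
            model = Model([Parameter("tau", init=min(max(init, 0.02), 0.98),
                                     lower=0.0, upper=1.0)], log_density)
            res = run_mcmc(model, config, seed=int(
                np.random.SeedSequence(
                    [seed, zlib.crc32(cid.encode())]).generate_state(1)[0] % (2**31)))
            draws = res.draws("tau")
        out[cid] = PosteriorSummary.from_draws(f"tau[{cid}]", draws)
    return out


@dataclass
class OccupancyRelationship:
    """Posterior of the logit-scale occupancy-on-productivity regression."""

    intercept: PosteriorSummary
    slope: PosteriorSummary
    year_effects: Dict[str, PosteriorSummary]   # season label -> additive effect
    sigma: PosteriorSummary
    nu: float
    seasons: Tuple[str, ...]
    predictions: Dict[tuple, PosteriorSummary]  # (colony, season) -> tau draws


def impute_occupancy(pairs: Sequence[tuple], targets: Sequence[tuple],
                     config: RunConfig, seed: int = 0) -> OccupancyRelationship:
    """Impute occupancy for colony-seasons where only productivity is known.

    ``pairs`` are calibration tuples ``(occupancy, productivity, colony,
    season)`` on the rate scale; ``targets`` are ``(colony, season,
    productivity)``.  Fits logit(occ) = a + b·logit(prod) + δ_season + e,
    e ~ Student-t(ν, 0, σ), with the earliest season as reference (δ = 0),
    and returns the predictive τ for each target (Student-t predictive noise
    included, inverse-logit keeps τ in [0, 1]).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 calibration (occupancy, productivity) pairs")
    prods = np.array([p[1] for p in pairs], dtype=float)
    occs = np.array([p[0] for p in pairs], dtype=float)
    if np.ptp(prods) < 1e-12:
        raise ValueError("all calibration productivities identical: slope unidentifiable")
    eps = 1e-4
    y = logit(np.clip(occs, eps, 1 - eps))
    x = logit(np.clip(prods, eps, 1 - eps))
    seasons = tuple(sorted({str(p[3]) for p in pairs}, key=season_index))
    season_of = np.array([seasons.index(str(p[3])) for p in pairs])
    nu = config.student_t_df

    params = [Parameter("intercept", init=0.0, init_spread=0.5),
              Parameter("slope", init=1.0, init_spread=0.5)]
    for s in seasons[1:]:
        params.append(Parameter(f"year[{s}]", init=0.0, init_spread=0.5))
    params.append(Parameter("log_sigma", init=-1.5, init_spread=0.5))

    def log_density(v: np.ndarray) -> float:
        a, b = v[0], v[1]
        deltas = np.concatenate([[0.0], v[2:2 + len(seasons) - 1]])
        sigma = math.exp(v[-1])
        mu = a + b * x + deltas[season_of]
        lp = float(np.sum(student_t.logpdf((y - mu) / sigma, df=nu) - math.log(sigma)))
        lp += -0.5 * (a ** 2 + b ** 2) / 25.0          # N(0, 5) priors
        lp += -0.5 * float(np.sum(deltas[1:] ** 2)) / 25.0
        lp += -0.5 * sigma ** 2 + v[-1]                # HalfNormal(1) on σ, log-Jacobian
        return lp

    res = run_mcmc(Model(params, log_density), config, seed=seed)
    a = res.draws("intercept")
    b = res.draws("slope")
    deltas = {seasons[0]: np.zeros_like(a)}
    for s in seasons[1:]:
        deltas[s] = res.draws(f"year[{s}]")
    sigma = np.exp(res.draws("log_sigma"))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    predictions = {}
    for colony, season, prod in targets:
        season = str(season)
        delta = deltas.get(season)
        if delta is None:
            delta = np.zeros_like(a)   # unseen season: no year-effect information
        eta = (a + b * math.log(prod / (1 - prod))
               + delta + sigma * rng.standard_t(nu, size=len(a)))
        predictions[(colony, season)] = PosteriorSummary.from_draws(
            f"tau[{colony},{season}]", expit(eta))

    def _summ(name):
        return res[name]

    return OccupancyRelationship(
        intercept=_summ("intercept"), slope=_summ("slope"),
        year_effects={s: _summ(f"year[{s}]") for s in seasons[1:]},
        sigma=PosteriorSummary.from_draws("sigma", sigma),
        nu=nu, seasons=seasons, predictions=predictions)


def design_based_pairs(burrow_mean: float, burrow_sd: float,
                       occ_mean: float, occ_sd: float) -> Tuple[float, float, float]:
    """Design-based pair estimate: product of means with propagated variance.

    Variance of a product of independent estimates
    (B²σ_τ² + τ²σ_B² + σ_B²σ_τ²) with normal 2.5–97.5% limits.
    """
    if burrow_sd < 0 or occ_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    est = burrow_mean * occ_mean
    var = (burrow_mean ** 2 * occ_sd ** 2 + occ_mean ** 2 * burrow_sd ** 2
           + burrow_sd ** 2 * occ_sd ** 2)
    half = 1.959963984540054 * math.sqrt(var)
    return est, est - half, est + half


@dataclass
class BreedingSuccess:
    rate: float
    posterior: PosteriorSummary


def breeding_success(january_eggs: int, april_chicks: int,
                     late_found_chicks: int = 0,
                     n_draws: int = 20_000, seed: int = 0) -> BreedingSuccess:
    """Breeding success (chicks per egg) with a late-found-chick adjustment.

    Chicks found in April without a January egg record augment the
    denominator (an approximation of the unpublished adjustment used by
    earlier censuses).  Uncertainty is the Beta(1, 1)-binomial posterior.
    """
    if min(january_eggs, april_chicks, late_found_chicks) < 0:
        raise ValueError("counts must be non-negative")
    denom = january_eggs + late_found_chicks
    if denom == 0:
        raise ValueError("no eggs recorded: breeding success undefined")
    if april_chicks > denom:
        raise ValueError("more chicks than adjusted egg count")
    rate = april_chicks / denom
    rng = np.random.default_rng(seed)
    draws = rng.beta(1 + april_chicks, 1 + denom - april_chicks, size=n_draws)
    return BreedingSuccess(rate=rate,
                           posterior=PosteriorSummary.from_draws("success", draws))
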