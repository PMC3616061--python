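"""Road-mortality analysis: carcass densities, distance-decay GLM,
persistence-corrected season mortality and the life-expectancy calculus.

Carcasses beside roads are counted once, late in the season; earlier kills
may already have disappeared (scavenging, burial, decay).  Persistence is
geometric with daily disappearance probability r, estimated from a marked
cohort re-checked after Δt days.  With constant daily kills m, the count
at day T satisfies M' = m·Σ_{t=1..T}(1−r)^{T−t} = m(1−(1−r)^T)/r, which is
inverted for m and hence the season total M = m·T.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mcmc import Model, Parameter, PosteriorSummary, run_mcmc
from .records import CarcassTransect, MarkedCarcassStudy, RunConfig

__all__ = [
    "carcass_density", "fit_carcass_glm", "predict_roadside_carcasses",
    "disappearance_rate", "total_road_mortality", "background_mortality",
    "life_expectancy", "mortality_as_survival_delta",
    "expected_snapshot", "invert_snapshot", "CarcassGlmFit", "DisappearanceRate",
    "SurvivalDelta",
]


def carcass_density(transects: Sequence[CarcassTransect]) -> Tuple[float, float]:
    """Pooled carcass density per 1000 m² with its Poisson standard error."""
    total_area = sum(t.area_m2 for t in transects)
    if total_area <= 0:
        raise ValueError("zero total surveyed area")
    total = sum(t.carcass_count for t in transects)
    density = total / total_area * 1000.0
    se = math.sqrt(total) / total_area * 1000.0
    return density, se


@dataclass
class CarcassGlmFit:
    """Poisson GLM of band counts on distance with a log-area offset."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    cov: np.ndarray
    deviance: float
    distance_range: Tuple[float, float]
    boundary: bool = False   # all-zero counts: intercept capped, fit degenerate

    def predict_density(self, distance_m) -> np.ndarray:
        """Expected carcasses per m² at the given distances from the road."""
        return np.exp(self.intercept + self.slope * np.asarray(distance_m, float))


_BOUNDARY_INTERCEPT = -30.0


def fit_carcass_glm(band_counts: pd.DataFrame) -> CarcassGlmFit:
    """Fit the distance-decay Poisson regression (IRLS, log-area offset).

    ``band_counts`` needs columns ``distance_mid_m``, ``area_m2`` and
    ``count`` (one row per transect × distance band).  All-zero counts give
    a flagged boundary fit with the intercept capped rather than an error.
    """
    required = {"distance_mid_m", "area_m2", "count"}
    missing = required - set(band_counts.columns)
    if missing:
        raise ValueError(f"band table missing columns {sorted(missing)}")
    if band_counts["distance_mid_m"].nunique() < 2:
        raise ValueError("need counts at >= 2 distinct distances")
    d = band_counts["distance_mid_m"].to_numpy(float)
    if band_counts["count"].sum() == 0:
        return CarcassGlmFit(intercept=_BOUNDARY_INTERCEPT, slope=0.0,
                             intercept_se=np.inf, slope_se=np.inf,
                             cov=np.full((2, 2), np.inf), deviance=0.0,
                             distance_range=(d.min(), d.max()), boundary=True)
    X = sm.add_constant(d)
    model = sm.GLM(band_counts["count"].to_numpy(float), X,
                   family=sm.families.Poisson(),
                   offset=np.log(band_counts["area_m2"].to_numpy(float)))
    try:
        fit = model.fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise RuntimeError(f"Poisson GLM did not converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("Poisson GLM did not converge after 100 IRLS iterations")
    return CarcassGlmFit(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                         intercept_se=float(fit.bse[0]), slope_se=float(fit.bse[1]),
                         cov=np.asarray(fit.cov_params()), deviance=float(fit.deviance),
                         distance_range=(float(d.min()), float(d.max())))


def predict_roadside_carcasses(glm_fit: CarcassGlmFit, road_geometry: pd.DataFrame,
                               n_draws: int = 4000, seed: int = 0) -> PosteriorSummary:
    """Predict M', carcasses present beside all roads, from the fitted GLM.

    ``road_geometry`` needs columns ``distance_mid_m`` and ``area_m2`` (one
    row per road × band).  Uncertainty propagates the coefficient covariance
    through normal draws.  Bands outside the fitted distance range trigger
    an extrapolation warning.
    """
    required = {"distance_mid_m", "area_m2"}
    missing = required - set(road_geometry.columns)
    if missing:
        raise ValueError(f"geometry table missing columns {sorted(missing)}")
    if (road_geometry["area_m2"] < 0).any():
        raise ValueError("negative band area")
    d = road_geometry["distance_mid_m"].to_numpy(float)
    a = road_geometry["area_m2"].to_numpy(float)
    lo, hi = glm_fit.distance_range
    if ((d < lo) | (d > hi)).any():
        _warnings.warn("road geometry extends outside the fitted distance range; "
                       "predictions there are extrapolations", stacklevel=2)
    if glm_fit.boundary:
        return PosteriorSummary.point_mass("M_prime", 0.0, n_draws)
    rng = np.random.default_rng(seed)
    coefs = rng.multivariate_normal([glm_fit.intercept, glm_fit.slope],
                                    glm_fit.cov, size=n_draws)
    log_dens = coefs[:, [0]] + np.outer(coefs[:, 1], d)
    totals = np.exp(log_dens) @ a
    return PosteriorSummary.from_draws("M_prime", totals)


@dataclass
class DisappearanceRate:
    """Daily carcass disappearance probability r."""

    point: Optional[float]          # 1 − (c2/c1)^(1/Δt); None when c2 = 0
    posterior: PosteriorSummary     # Binomial(c1, (1−r)^Δt) likelihood, U(0,1) prior
    warnings: list = field(default_factory=list)


def disappearance_rate(study: MarkedCarcassStudy, config: Optional[RunConfig] = None,
                       seed: int = 0) -> DisappearanceRate:
    """Estimate r from a marked cohort: c1 marked, c2 persisting after Δt days.

    A marked carcass persists Δt days with probability (1−r)^Δt (geometric
    daily persistence, the discrete counterpart of an exponential carcass
    lifetime), giving the closed-form point estimate and, with a uniform
    prior on r, a proper binomial posterior even when c2 = 0.
    """
    dt = study.dt
    warn = []
    if study.c2 == 0:
        point = None
        warn.append("no marked carcasses persisted: closed-form point estimate "
                    "undefined, posterior still proper")
    else:
        point = 1.0 - (study.c2 / study.c1) ** (1.0 / dt)
    cfg = config if config is not None else RunConfig.fast()

    def log_density(x: np.ndarray) -> float:
        r = x[0]
        s = dt * math.log1p(-r)                 # log persistence probability
        return study.c2 * s + (study.c1 - study.c2) * math.log1p(-math.exp(s))

    init = point if point is not None else 0.02
    model = Model([Parameter("r", init=min(max(init, 1e-4), 0.5),
                             lower=0.0, upper=1.0)], log_density)
    res = run_mcmc(model, cfg, seed=seed)
    return DisappearanceRate(point=point, posterior=res["r"], warnings=warn)


def expected_snapshot(m: float, r: float, T: int) -> float:
    """Expected carcasses present at day T under constant daily kills m."""
    if T < 1:
        raise ValueError("need T >= 1")
    if r == 0.0:
        return m * T
    return m * (1.0 - (1.0 - r) ** T) / r


def invert_snapshot(m_prime: float, r: float, T: int) -> float:
    """Solve M' = m(1−(1−r)^T)/r for the constant daily kill rate m."""
    if T < 1:
        raise ValueError("need T >= 1")
    if r == 0.0:
        return m_prime / T
    return m_prime * r / (1.0 - (1.0 - r) ** T)


def total_road_mortality(m_prime: PosteriorSummary, r: PosteriorSummary,
                         T: int, seed: int = 0) -> PosteriorSummary:
    """Season road mortality M: invert the persistence sum per draw, M = m·T.

    M' and r draws are paired independently (resampled to a common length).
    At r = 0 the inversion reduces to M = M' exactly; r = 1 with M' > 0 and
    T > 1 warns, since only last-day kills remain countable.
    """
    if T < 1:
        raise ValueError("need T >= 1")
    rng = np.random.default_rng(seed)
    n = len(m_prime.draws)
    r_draws = r.draws if len(r.draws) == n else rng.choice(r.draws, size=n)
    if np.any((r_draws >= 1.0 - 1e-12) & (m_prime.draws > 0)) and T > 1:
        _warnings.warn("r = 1 with M' > 0: only last-day kills are observable",
                       stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        geom = np.where(r_draws > 0,
                        (1.0 - (1.0 - r_draws) ** T) / np.where(r_draws > 0, r_draws, 1.0),
                        float(T))
    m_daily = m_prime.draws / geom
    return PosteriorSummary.from_draws("M", m_daily * T)


def background_mortality(background_density_per_1000m2: float,
                         colony_area_m2: float) -> float:
    """Expected colony-wide carcass count from away-from-road density."""
    if background_density_per_1000m2 < 0 or colony_area_m2 < 0:
        raise ValueError("density and area must be >= 0")
    return background_density_per_1000m2 * colony_area_m2 / 1000.0


def life_expectancy(phi: float) -> float:
    """Mean life expectancy in years for annual survival φ: LE = −1/ln(φ)."""
    if not 0.0 < phi < 1.0:
        raise ValueError("annual survival must lie strictly between 0 and 1")
    return -1.0 / math.log(phi)


@dataclass
class SurvivalDelta:
    mortality_fraction: float
    phi_baseline: float
    phi_reduced: float
    le_baseline_years: float
    le_reduced_years: float
    le_reduction_pct: float


def mortality_as_survival_delta(road_deaths: float, adult_population: float,
                                phi_baseline: float = 0.92) -> SurvivalDelta:
    """Express road deaths as an annual adult mortality and a life-expectancy cost."""
    if adult_population <= 0:
        raise ValueError("adult population must be positive")
    if road_deaths > adult_population:
        raise ValueError("more road deaths than adults")
    frac = road_deaths / adult_population
    phi_new = phi_baseline - frac
    le0 = life_expectancy(phi_baseline)
    le1 = life_expectancy(phi_new)
    return SurvivalDelta(mortality_fraction=frac, phi_baseline=phi_baseline,
                         phi_reduced=phi_new, le_baseline_years=le0,
                         le_reduced_years=le1,
                         le_reduction_pct=(1.0 - le1 / le0) * 100.0)
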