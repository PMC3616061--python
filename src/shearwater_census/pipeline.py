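"""Stage orchestration: census → reproduction → road-kill → trend.

Each stage takes a validated input bundle (see :mod:`shearwater_census.io`),
runs the model modules, writes the result tables and a JSON run manifest
(seed, config echo, per-node Rhat/ESS, input digests), and returns the
in-memory summaries.  The command-line interface in :mod:`cli` is a thin
wrapper over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .density import colony_burrow_total, fit_density, island_total
from .io import write_manifest, write_results
from .mcmc import PosteriorSummary
from .records import Colony, HistoricalSummary, RunConfig
from .reproduction import estimate_chicks, estimate_pairs, fit_occupancy, fit_productivity
from .roadkill import (background_mortality, carcass_density, disappearance_rate,
                       fit_carcass_glm, predict_roadside_carcasses,
                       total_road_mortality)
from .trend import TrendResult, percent_change

__all__ = ["CensusResult", "run_census", "run_roadkill", "run_trend"]


def _derive_seed(seed: int, offset: int) -> int:
    return int(np.random.SeedSequence([seed, offset]).generate_state(1)[0] % (2 ** 31))


@dataclass
class CensusResult:
    burrow_totals: Dict[str, PosteriorSummary]
    island: PosteriorSummary
    theta: Dict[str, PosteriorSummary]
    chicks: Dict[str, PosteriorSummary]
    tau: Dict[str, PosteriorSummary]
    pairs: Dict[str, PosteriorSummary]
    density_fit: object
    diagnostics: dict
    warnings: list


def _survey_margins(bundle: dict) -> Dict[str, tuple]:
    margins: Dict[str, tuple] = {}
    for s in bundle["sections"]:
        count, area = margins.get(s.colony_id, (0, 0.0))
        margins[s.colony_id] = (count + s.burrow_count, area + s.area_m2)
    return margins


def run_census(bundle: dict, config: RunConfig, seed: Optional[int] = None,
               out_dir=None, input_paths: Optional[dict] = None) -> CensusResult:
    """Burrow, chick and pair estimation over a full input bundle.

    ``bundle`` holds validated record collections keyed as in
    :func:`shearwater_census.io.read_bundle` (colonies, sections, stations,
    occupancy, optionally historical).  Fully counted colonies contribute a
    single census "section" covering their whole area and get zero-variance
    totals.
    """
    if seed is None:
        seed = config.seed
    colonies: List[Colony] = bundle["colonies"]
    margins = _survey_margins(bundle)

    fit = fit_density(bundle["sections"], colonies, config,
                      seed=_derive_seed(seed, 1))
    totals: Dict[str, PosteriorSummary] = {}
    for colony in colonies:
        count, area = margins.get(colony.colony_id, (0, 0.0))
        totals[colony.colony_id] = colony_burrow_total(
            fit, colony, count, area, seed=_derive_seed(seed, 2))
    island = island_total(list(totals.values()))

    colony_ids = [c.colony_id for c in colonies]
    theta = fit_productivity(bundle["stations"], config, colonies=colony_ids,
                             seed=_derive_seed(seed, 3))
    chicks = estimate_chicks(totals, theta, seed=_derive_seed(seed, 4))

    historical = bundle.get("historical", [])
    tau = fit_occupancy(bundle["occupancy"], config, priors=historical,
                        seed=_derive_seed(seed, 5))
    # colonies without occupancy evidence take the pooled mean of the others
    if tau:
        pooled = np.mean([s.draws for s in tau.values()], axis=0)
        for cid in colony_ids:
            if cid not in tau:
                tau[cid] = PosteriorSummary.from_draws(f"tau[{cid}]", pooled.copy())
    pairs = estimate_pairs(totals, tau, seed=_derive_seed(seed, 6))

    diagnostics = {name: {"rhat": s.rhat, "ess": s.ess}
                   for name, s in fit.result.summaries.items()}
    result = CensusResult(burrow_totals=totals, island=island, theta=theta,
                          chicks=chicks, tau=tau, pairs=pairs, density_fit=fit,
                          diagnostics=diagnostics, warnings=list(fit.result.warnings))
    if out_dir is not None:
        out_dir = Path(out_dir)
        families = {
            "burrows": list(totals.values()) + [island],
            "chicks": [chicks[k] for k in chicks],
            "pairs": [pairs[k] for k in pairs],
            "densities": [fit.summary(cid) for cid in fit.colony_ids],
        }
        write_results(families, out_dir)
        write_manifest(out_dir / "manifest.json", seed=seed, config=config,
                       diagnostics=diagnostics, inputs=input_paths or {},
                       warnings=result.warnings, version=__version__)
    return result


def run_roadkill(transects, marked, config: RunConfig,
                 band_counts: Optional[pd.DataFrame] = None,
                 road_geometry: Optional[pd.DataFrame] = None,
                 colony_area_m2: float = 247_300.0,
                 seed: Optional[int] = None, out_dir=None,
                 input_paths: Optional[dict] = None) -> dict:
    """Carcass densities, disappearance rate and season road mortality.

    Without a band table/geometry, M' is estimated by scaling the pooled
    roadside density to the roadside strip area with Poisson uncertainty;
    with them, via the distance-decay GLM prediction.
    """
    if seed is None:
        seed = config.seed
    roadside = [t for t in transects if not t.is_background]
    background = [t for t in transects if t.is_background]
    road_density, road_se = carcass_density(roadside)
    bg_density, bg_se = (carcass_density(background) if background else (0.0, 0.0))

    rate = disappearance_rate(marked, config, seed=_derive_seed(seed, 11))

    n_draws = config.chains * config.draws_per_chain
    if band_counts is not None and road_geometry is not None:
        glm = fit_carcass_glm(band_counts)
        m_prime = predict_roadside_carcasses(glm, road_geometry,
                                             n_draws=n_draws,
                                             seed=_derive_seed(seed, 12))
        glm_row = {"glm_intercept": glm.intercept, "glm_slope": glm.slope,
                   "glm_deviance": glm.deviance}
    else:
        total_road_area = sum(t.area_m2 for t in roadside)
        rng = np.random.default_rng(_derive_seed(seed, 12))
        count = sum(t.carcass_count for t in roadside)
        m_prime = PosteriorSummary.from_draws(
            "M_prime", rng.gamma(count + 0.5, 1.0, size=n_draws))
        glm_row = {}

    mortality = total_road_mortality(m_prime, rate.posterior,
                                     config.season_length_days,
                                     seed=_derive_seed(seed, 13))
    background_expected = background_mortality(bg_density, colony_area_m2)

    report = {
        "road_density_per_1000m2": road_density,
        "road_density_se": road_se,
        "background_density_per_1000m2": bg_density,
        "background_density_se": bg_se,
        "density_ratio": road_density / bg_density if bg_density else np.inf,
        "disappearance_rate_point": rate.point,
        "disappearance_rate": rate.posterior,
        "m_prime": m_prime,
        "season_mortality": mortality,
        "background_carcasses": background_expected,
        **glm_row,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for key, value in report.items():
            if isinstance(value, PosteriorSummary):
                rows.append({"quantity": key, **{k: v for k, v in value.to_row().items()
                                                 if k != "name"}})
            elif value is not None:
                rows.append({"quantity": key, "mean": value})
        pd.DataFrame(rows).to_csv(out_dir / "roadkill.csv", index=False,
                                  float_format="%.6g")
        write_manifest(out_dir / "manifest_roadkill.json", seed=seed, config=config,
                       diagnostics={"r": {"rhat": rate.posterior.rhat,
                                          "ess": rate.posterior.ess}},
                       inputs=input_paths or {}, warnings=rate.warnings,
                       version=__version__)
    return report


def run_trend(current: Dict[str, PosteriorSummary],
              historical: List[HistoricalSummary], to_season: str = "2008/9",
              seed: int = 0, out_dir=None) -> List[TrendResult]:
    """Percent change and probability of decline for every matchable metric.

    ``current`` maps metric names (e.g. ``burrow_total``) to posteriors;
    historical records without a matching current posterior are skipped with
    a warning row rather than an error.
    """
    results: List[TrendResult] = []
    skipped: List[str] = []
    for i, h in enumerate(historical):
        cur = current.get(h.metric)
        if cur is None:
            skipped.append(f"{h.metric} ({h.colony_id}/{h.season})")
            continue
        results.append(percent_change(cur, h, to_season=to_season,
                                      seed=_derive_seed(seed, 20 + i)))
    if skipped:
        import warnings as _w
        _w.warn(f"no current posterior for historical metric(s): {skipped}",
                stacklevel=2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([t.to_row() for t in results]).to_csv(
            out_dir / "trend.csv", index=False, float_format="%.6g")
    return results
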