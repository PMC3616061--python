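"""Synthetic field data with the statistical structure the models assume.

The generator emulates every input the pipeline consumes: overdispersed
belt-transect burrow counts (Poisson with a unit-mean Gamma section effect),
binomial chick checks and burrow-occupancy checks, a daily roadside carcass
deposition process thinned by geometric disappearance, and historical
censuses as mean ± SE summaries.  Ground truth is recorded alongside so
parameter-recovery and coverage tests can compare posteriors to the values
that generated the data.

One integer seed drives a named stream per generator (survey, reproduction,
carcass, historical), so each data family can be regenerated independently.
The default scenario mirrors the Lord Howe Island colony system: six
colonies with the published areas and transect layouts, densities and rates
of the published magnitude, so synthetic outputs are magnitude-comparable
to the published results without claiming to reproduce them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .records import (CarcassTransect, ChickStation, Colony, HistoricalSummary,
                      MarkedCarcassStudy, OccupancyRecord, TransectSection)

__all__ = ["GroundTruth", "SyntheticSurvey", "SyntheticCarcassData",
           "generate_colony_survey", "generate_reproduction",
           "generate_carcass_process", "generate_historical"]

_STREAMS = {"survey": 1, "reproduction": 2, "carcass": 3, "historical": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class GroundTruth:
    """True parameter values behind a synthetic dataset."""

    colonies: List[Colony]
    lam: Dict[str, float]              # burrow density, burrows m⁻²
    alpha: float                       # Gamma overdispersion shape (unit-mean)
    tau: Dict[str, float]              # occupancy
    theta: Dict[str, float]            # productivity
    success: float                     # breeding success, chicks per egg
    m_daily: float                     # road kills per day
    r: float                           # daily carcass disappearance probability
    T: int                             # season length, days
    transects_per_colony: Dict[str, int] = field(default_factory=dict)
    historical_totals: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.lam, self.tau, self.theta):
            for v in d.values():
                if v < 0:
                    raise ValueError("rates and densities must be >= 0")
        for v in list(self.tau.values()) + list(self.theta.values()) + [self.success]:
            if not 0 <= v <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.r <= 1:
            raise ValueError("disappearance probability must lie in [0, 1]")

    @classmethod
    def lordhowe_like(cls) -> "GroundTruth":
        """Six colonies with published areas/layouts and published-magnitude rates."""
        colonies = [
            Colony("LMG", "Little Muttonbird Ground", 4_100, False),
            Colony("CP", "Clear Place", 77_300, False),
            Colony("MB", "Middle Beach", 58_800, False),
            Colony("NB", "Ned's Beach", 28_900, False),
            Colony("SP", "Steven's Point", 74_100, False),
            Colony("HB", "Hunter Bay", 4_100, True),
        ]
        return cls(
            colonies=colonies,
            lam={"LMG": 0.015, "CP": 0.148, "MB": 0.131, "NB": 0.125,
                 "SP": 0.061, "HB": 0.022},
            alpha=1.2,
            tau={"LMG": 0.62, "CP": 0.67, "MB": 0.65, "NB": 0.60,
                 "SP": 0.63, "HB": 0.62},
            theta={"LMG": 0.35, "CP": 0.44, "MB": 0.38, "NB": 0.30,
                   "SP": 0.36, "HB": 0.35},
            success=0.69, m_daily=0.75, r=0.0052, T=180,
            transects_per_colony={"LMG": 2, "CP": 4, "MB": 4, "NB": 1, "SP": 5},
            historical_totals={"1978/9": 36_900.0, "2002/3": 29_860.0},
        )

    @property
    def colony_ids(self) -> List[str]:
        return [c.colony_id for c in self.colonies]


@dataclass
class SyntheticSurvey:
    sections: List[TransectSection]
    true_totals: Dict[str, int]        # actual burrows per colony (all sections)
    observed_counts: Dict[str, int]    # burrows in the surveyed sections
    surveyed_area_m2: Dict[str, float]


def generate_colony_survey(truth: GroundTruth, coverage: float = 0.06,
                           seed: int = 0,
                           section_area_m2: float = 40.0) -> SyntheticSurvey:
    """Simulate belt-transect section counts plus the true burrow totals.

    Every colony is tiled into 40 m² sections, each given a count
    Poisson(area × λ × ε) with ε ~ Gamma(α, α) (unit mean); the surveyed
    subset covers ``coverage`` of the sections, spread over the colony's
    transects.  The true total is the sum over *all* sections, so recovery
    tests compare the posterior total to the realised truth.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    rng = _rng(seed, "survey")
    sections: List[TransectSection] = []
    true_totals: Dict[str, int] = {}
    observed: Dict[str, int] = {}
    surveyed_area: Dict[str, float] = {}
    for colony in truth.colonies:
        cid = colony.colony_id
        lam = truth.lam[cid]
        n_total = max(int(round(colony.area_m2 / section_area_m2)), 1)
        eps = rng.gamma(truth.alpha, 1.0 / truth.alpha, size=n_total)
        counts = rng.poisson(section_area_m2 * lam * eps)
        true_totals[cid] = int(counts.sum())
        if colony.fully_counted:
            observed[cid] = int(counts.sum())
            surveyed_area[cid] = colony.area_m2
            continue
        n_surv = max(int(round(coverage * n_total)), 1)
        surv = counts[:n_surv]   # sections are exchangeable; take a block
        n_transects = truth.transects_per_colony.get(cid, 1)
        per_transect = int(np.ceil(n_surv / n_transects))
        for idx, count in enumerate(surv):
            t = idx // per_transect + 1
            sections.append(TransectSection(
                colony_id=cid, transect_id=f"{cid}-T{t}",
                section_index=idx % per_transect,
                area_m2=section_area_m2, burrow_count=int(count)))
        observed[cid] = int(surv.sum())
        surveyed_area[cid] = n_surv * section_area_m2
    return SyntheticSurvey(sections=sections, true_totals=true_totals,
                           observed_counts=observed,
                           surveyed_area_m2=surveyed_area)


def generate_reproduction(truth: GroundTruth, n_stations: int = 18,
                          burrows_per_station: int = 5,
                          n_occupancy_checks: int = 100, seed: int = 0,
                          seasons: Sequence[str] = ("2008/9",),
                          year_effects: Optional[Dict[str, float]] = None,
                          ) -> Tuple[List[ChickStation], List[OccupancyRecord]]:
    """Simulate chick-check stations and burrow-occupancy checks.

    ``year_effects`` shift each season's occupancy on the logit scale
    (reference 0), emulating between-season variation for the imputation
    regression.
    """
    if min(n_stations, burrows_per_station, n_occupancy_checks) < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng(seed, "reproduction")
    year_effects = year_effects or {}
    stations: List[ChickStation] = []
    occupancy: List[OccupancyRecord] = []
    for colony in truth.colonies:
        cid = colony.colony_id
        for k in range(n_stations):
            stations.append(ChickStation(
                colony_id=cid, transect_id=f"{cid}-T{k % 3 + 1}",
                station_id=f"{cid}-S{k + 1}",
                burrows_checked=burrows_per_station,
                chicks_found=int(rng.binomial(burrows_per_station,
                                              truth.theta[cid]))))
        for season in seasons:
            tau = float(expit(logit(truth.tau[cid])
                              + year_effects.get(str(season), 0.0)))
            occupancy.append(OccupancyRecord(
                colony_id=cid, season=str(season),
                burrows_checked=n_occupancy_checks,
                burrows_occupied=int(rng.binomial(n_occupancy_checks, tau))))
    return stations, occupancy


@dataclass
class SyntheticCarcassData:
    transects: List[CarcassTransect]   # surveyed roadside + background strips
    band_counts: pd.DataFrame          # tidy per-transect × band table for the GLM
    marked: MarkedCarcassStudy
    true_snapshot: int                 # carcasses actually present at day T
    true_total_kills: int              # all kills over the season


def generate_carcass_process(truth: GroundTruth, seed: int = 0,
                             n_road_transects: int = 40,
                             road_area_m2: float = 8_000.0,
                             transect_length_m: float = 10.0,
                             transect_width_m: float = 2.0,
                             decay_per_m: float = 0.3,
                             background_area_m2: float = 4_116.0,
                             background_rate_per_m2: float = 0.0005,
                             n_marked: int = 7,
                             marked_interval_days: int = 107,
                             ) -> SyntheticCarcassData:
    """Simulate the roadside carcass process and a marked persistence cohort.

    Kills arrive Poisson(m) per day over T days, land at a road-perpendicular
    distance with an exponential decay profile, and persist each further day
    with probability 1−r.  The day-T snapshot is thinned onto the surveyed
    transects (a fraction of the roadside strip) and binned into 2 m distance
    bands.  A cohort of ``n_marked`` carcasses is followed for
    ``marked_interval_days`` days.
    """
    if truth.T < 1:
        raise ValueError("need season length T >= 1")
    rng = _rng(seed, "carcass")
    T, r, m = truth.T, truth.r, truth.m_daily
    kills_per_day = rng.poisson(m, size=T)
    total_kills = int(kills_per_day.sum())
    # survive from kill day t (1-based) to the count at day T: (1-r)^(T-t)
    days = np.repeat(np.arange(1, T + 1), kills_per_day)
    alive = rng.uniform(size=total_kills) < (1.0 - r) ** (T - days)
    n_alive = int(alive.sum())

    # place survivors along the road-perpendicular axis, truncated-exponential
    u = rng.uniform(size=n_alive)
    cdf_max = 1.0 - math.exp(-decay_per_m * transect_length_m)
    dist = -np.log(1.0 - u * cdf_max) / decay_per_m

    surveyed_area = n_road_transects * transect_length_m * transect_width_m
    frac = min(surveyed_area / road_area_m2, 1.0)
    on_transect = rng.uniform(size=n_alive) < frac
    which = rng.integers(0, n_road_transects, size=n_alive)

    band_edges = np.arange(0.0, transect_length_m + 1e-9, 2.0)
    rows = []
    transects: List[CarcassTransect] = []
    for t_idx in range(n_road_transects):
        sel = dist[on_transect & (which == t_idx)]
        bands = []
        for lo, hi in zip(band_edges[:-1], band_edges[1:]):
            c = int(np.sum((sel >= lo) & (sel < hi)))
            bands.append((float(lo), float(hi), c))
            rows.append({"transect_id": f"R{t_idx + 1}",
                         "distance_mid_m": (lo + hi) / 2.0,
                         "area_m2": (hi - lo) * transect_width_m, "count": c})
        transects.append(CarcassTransect(
            transect_id=f"R{t_idx + 1}", road_id="road",
            area_m2=transect_length_m * transect_width_m,
            carcass_count=int(len(sel)),
            distance_band_counts=tuple(bands)))
    transects.append(CarcassTransect(
        transect_id="BG", road_id="background", area_m2=background_area_m2,
        carcass_count=int(rng.poisson(background_rate_per_m2 * background_area_m2))))

    c2 = int(rng.binomial(n_marked, (1.0 - r) ** marked_interval_days))
    marked = MarkedCarcassStudy(c1=n_marked, c2=c2, t1=0, t2=marked_interval_days)
    return SyntheticCarcassData(transects=transects,
                                band_counts=pd.DataFrame(rows),
                                marked=marked, true_snapshot=n_alive,
                                true_total_kills=total_kills)


def generate_historical(truth: GroundTruth, se_level: float = 2_500.0,
                        seed: int = 0,
                        rates: Optional[Dict[str, Tuple[str, float, float]]] = None,
                        ) -> List[HistoricalSummary]:
    """Summarize the true historical trajectory as noisy mean ± SE records.

    ``rates`` optionally adds rate metrics as
    {colony_id: (metric, true_rate, se)}; generated rate means are clipped
    to [0, 1].
    """
    if se_level < 0:
        raise ValueError("se must be >= 0")
    rng = _rng(seed, "historical")
    out: List[HistoricalSummary] = []
    for season, total in truth.historical_totals.items():
        mean = float(max(rng.normal(total, se_level), 0.0)) if se_level else float(total)
        out.append(HistoricalSummary(colony_id="ALL", season=season,
                                     metric="burrow_total", mean=mean,
                                     se=se_level))
    for cid, (metric, rate, se) in (rates or {}).items():
        mean = float(np.clip(rng.normal(rate, se), 0.0, 1.0)) if se else float(rate)
        out.append(HistoricalSummary(colony_id=cid, season="2002/3",
                                     metric=metric, mean=mean, se=se))
    return out
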