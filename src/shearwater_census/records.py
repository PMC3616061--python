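"""Domain records for the colony census pipeline.

Each record mirrors one kind of field observation: colony geometry,
belt-transect burrow counts, chick checks at stations, burrow occupancy
checks, summarized historical census estimates, road carcass transects and
the marked-carcass persistence experiment.  Records validate their own
invariants at construction time so that file readers can point at the
offending row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "ValidationError",
    "Colony",
    "TransectSection",
    "ChickStation",
    "OccupancyRecord",
    "HistoricalSummary",
    "CarcassTransect",
    "MarkedCarcassStudy",
    "RunConfig",
    "season_index",
]

RATE_METRICS = {"occupancy", "productivity", "breeding_success"}
METRICS = RATE_METRICS | {"burrow_density", "burrow_total"}


class ValidationError(ValueError):
    """A record violated one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def season_index(season: str) -> int:
    """Numeric index of a breeding season labelled by year of laying.

    ``"2008/9"`` → 2008; a bare year string is accepted too.
    """
    head = str(season).split("/")[0]
    try:
        return int(head)
    except ValueError as exc:
        raise ValidationError(f"unparseable season label {season!r}") from exc


@dataclass(frozen=True)
class Colony:
    colony_id: str
    name: str
    area_m2: float
    fully_counted: bool = False

    def __post_init__(self) -> None:
        _require(self.area_m2 > 0, f"colony {self.colony_id}: area_m2 must be > 0")


@dataclass(frozen=True)
class TransectSection:
    colony_id: str
    transect_id: str
    section_index: int
    area_m2: float
    burrow_count: int

    def __post_init__(self) -> None:
        _require(self.burrow_count >= 0,
                 f"section {self.transect_id}/{self.section_index}: negative burrow_count")
        _require(self.area_m2 > 0,
                 f"section {self.transect_id}/{self.section_index}: area_m2 must be > 0")


@dataclass(frozen=True)
class ChickStation:
    colony_id: str
    transect_id: str
    station_id: str
    burrows_checked: int
    chicks_found: int

    def __post_init__(self) -> None:
        _require(self.burrows_checked > 0,
                 f"station {self.station_id}: burrows_checked must be positive")
        _require(0 <= self.chicks_found <= self.burrows_checked,
                 f"station {self.station_id}: chicks_found outside [0, burrows_checked]")


@dataclass(frozen=True)
class OccupancyRecord:
    colony_id: str
    season: str
    burrows_checked: int
    burrows_occupied: int

    def __post_init__(self) -> None:
        _require(self.burrows_checked > 0,
                 f"occupancy {self.colony_id}/{self.season}: burrows_checked must be positive")
        _require(0 <= self.burrows_occupied <= self.burrows_checked,
                 f"occupancy {self.colony_id}/{self.season}: occupied outside [0, checked]")

    @property
    def season_index(self) -> int:
        return season_index(self.season)


@dataclass(frozen=True)
class HistoricalSummary:
    """A published mean ± SE for one colony/metric/season.

    These summarize censuses whose raw data are unavailable; they enter the
    models as Normal(mean, se) evidence.
    """

    colony_id: str
    season: str
    metric: str
    mean: float
    se: float

    def __post_init__(self) -> None:
        _require(self.metric in METRICS,
                 f"historical {self.colony_id}/{self.season}: unknown metric {self.metric!r}")
        _require(self.se >= 0,
                 f"historical {self.colony_id}/{self.season}: se must be >= 0")
        if self.metric in RATE_METRICS:
            _require(0.0 <= self.mean <= 1.0,
                     f"historical {self.colony_id}/{self.season}: rate metric outside [0, 1]")


@dataclass(frozen=True)
class CarcassTransect:
    transect_id: str
    road_id: str  # a road label, or "background" for away-from-road strips
    area_m2: float
    carcass_count: int
    # optional per-band breakdown: [(band_lo_m, band_hi_m, count), ...]
    distance_band_counts: Optional[tuple] = None

    def __post_init__(self) -> None:
        _require(self.carcass_count >= 0,
                 f"carcass transect {self.transect_id}: negative carcass_count")
        _require(self.area_m2 > 0,
                 f"carcass transect {self.transect_id}: area_m2 must be > 0")
        if self.distance_band_counts is not None:
            total = sum(int(c) for (_, _, c) in self.distance_band_counts)
            _require(total == self.carcass_count,
                     f"carcass transect {self.transect_id}: band counts sum to {total}, "
                     f"not carcass_count {self.carcass_count}")

    @property
    def is_background(self) -> bool:
        return self.road_id == "background"


@dataclass(frozen=True)
class MarkedCarcassStudy:
    """c1 carcasses marked on day t1, c2 still present on day t2."""

    c1: int
    c2: int
    t1: int
    t2: int

    def __post_init__(self) -> None:
        _require(0 <= self.c2 <= self.c1, "marked carcasses: need 0 <= c2 <= c1")
        _require(self.t2 > self.t1, "marked carcasses: need t2 > t1")

    @property
    def dt(self) -> int:
        return self.t2 - self.t1


@dataclass
class RunConfig:
    """MCMC, prior and survey-geometry settings for one pipeline run.

    Defaults mirror the census protocol (100,000 iterations, 50,000 burn-in,
    five chains, thinning 10); ``fast()`` gives scaled-down settings for
    tests and exploratory runs.
    """

    iterations: int = 100_000
    burn_in: int = 50_000
    chains: int = 5
    thinning: int = 10
    seed: int = 0
    # priors
    shape_prior_bounds: tuple = (0.4, 2.5)   # uniform bounds on Gamma shape params
    density_prior: tuple = (0.01, 0.01)      # vague Gamma(shape, rate) on burrow density
    occupancy_prior: tuple = (1.0, 1.0)      # Beta prior on occupancy/productivity rates
    student_t_df: float = 3.0                # residual df of occupancy~productivity fit
    # survey geometry / season
    season_length_days: int = 180
    roadside_buffer_m: float = 10.0
    section_area_m2: float = 40.0

    def __post_init__(self) -> None:
        _require(self.iterations > self.burn_in >= 0, "need iterations > burn_in >= 0")
        _require(self.chains >= 2, "need >= 2 chains")
        _require(self.thinning >= 1, "need thinning >= 1")
        _require(self.season_length_days >= 1, "need season length >= 1 day")

    @classmethod
    def fast(cls, seed: int = 0) -> "RunConfig":
        """Test-scale settings: 4,000 iterations, 2,000 burn-in, 3 chains."""
        return cls(iterations=4_000, burn_in=2_000, chains=3, thinning=1, seed=seed)

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    def to_dict(self) -> dict:
        return asdict(self)
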