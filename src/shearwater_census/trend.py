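"""Population-trend inference against summarized historical censuses.

Only two island-wide censuses predate this pipeline, published as mean ± SE;
the current posterior is compared draw-wise with Normal(mean, se) draws for
the historical estimate (truncated at zero for count metrics).  Results are
reported in the census convention: a decline as a positive headline
percentage, with the raw (new−old)/old change interval alongside, plus the
posterior probability of decline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import truncnorm

from .mcmc import PosteriorSummary
from .records import RATE_METRICS, HistoricalSummary

__all__ = ["TrendResult", "percent_change", "annualized_rate"]


@dataclass
class TrendResult:
    metric: str
    from_season: str
    to_season: str
    change_mean: float          # (new − old)/old × 100
    change_ci: Tuple[float, float]
    decline_mean: float         # −change: positive numbers are declines
    decline_ci: Tuple[float, float]
    p_decline: float

    def to_row(self) -> dict:
        return {"metric": self.metric, "from_season": self.from_season,
                "to_season": self.to_season, "change_pct": self.change_mean,
                "change_2.5%": self.change_ci[0], "change_97.5%": self.change_ci[1],
                "decline_pct": self.decline_mean,
                "decline_2.5%": self.decline_ci[0], "decline_97.5%": self.decline_ci[1],
                "p_decline": self.p_decline}


def percent_change(current: PosteriorSummary, historical: HistoricalSummary,
                   to_season: str = "", seed: int = 0) -> TrendResult:
    """Draw-wise percent change of a current posterior vs a published estimate."""
    if historical.mean <= 0:
        raise ValueError("historical mean must be positive to express a percent change")
    rng = np.random.default_rng(seed)
    n = len(current.draws)
    if historical.se == 0:
        hist = np.full(n, historical.mean)
    elif historical.metric in RATE_METRICS:
        hist = rng.normal(historical.mean, historical.se, size=n)
    else:
        # count metrics cannot go negative
        a = (0.0 - historical.mean) / historical.se
        hist = truncnorm.rvs(a, np.inf, loc=historical.mean,
                             scale=historical.se, size=n, random_state=rng)
        hist = np.maximum(hist, 1e-9)
    change = (current.draws - hist) / hist * 100.0
    lo, hi = np.quantile(change, [0.025, 0.975])
    return TrendResult(
        metric=historical.metric, from_season=historical.season,
        to_season=to_season or current.name,
        change_mean=float(change.mean()), change_ci=(float(lo), float(hi)),
        decline_mean=float(-change.mean()),
        decline_ci=(float(-hi), float(-lo)),
        p_decline=float(np.mean(change < 0.0)))


def annualized_rate(total_change_fraction: float, years: float) -> float:
    """Geometric per-annum rate of a total change: (1+c)^(1/years) − 1."""
    if total_change_fraction <= -1.0:
        raise ValueError("total change fraction must exceed -1")
    if years < 1:
        raise ValueError("need years >= 1")
    return (1.0 + total_change_fraction) ** (1.0 / years) - 1.0
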