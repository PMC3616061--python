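"""A small MCMC layer: adaptive Metropolis-within-Gibbs plus diagnostics.

The model families in this pipeline (Gamma-Poisson burrow counts, binomial
rates with normal literature evidence, a Student-t regression, a binomial
persistence likelihood) are all low-dimensional with cheap log-densities, so
a component-wise random-walk sampler with proposal scales adapted during
burn-in (and frozen afterwards, keeping the post-burn-in chain Markovian)
is entirely adequate.  Parameters declare box constraints; sampling happens
on an unconstrained scale (log / logit / identity) with the Jacobian folded
into the target density.

Determinism contract: a given (seed, config, model) triple yields
bit-identical draws.  Chains start from overdispersed points derived from
independent seed streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .records import RunConfig

__all__ = [
    "Parameter",
    "Model",
    "PosteriorSummary",
    "MCMCResult",
    "run_mcmc",
    "rhat",
    "effective_sample_size",
    "InitializationError",
]

_ADAPT_INTERVAL = 50
_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk updates
RHAT_WARN_THRESHOLD = 1.01


class InitializationError(RuntimeError):
    """No finite starting log-density could be found for some chain."""


@dataclass(frozen=True)
class Parameter:
    """One scalar model parameter with box constraints.

    ``init`` is the centre of the overdispersed starting distribution and
    ``init_spread`` its half-width (on the unconstrained scale).
    """

    name: str
    init: float
    lower: float = -np.inf
    upper: float = np.inf
    init_spread: float = 1.0

    def to_unconstrained(self, x: float) -> float:
        lo, hi = self.lower, self.upper
        if np.isfinite(lo) and np.isfinite(hi):
            p = (x - lo) / (hi - lo)
            p = min(max(p, 1e-12), 1 - 1e-12)
            return math.log(p / (1 - p))
        if np.isfinite(lo):
            return math.log(max(x - lo, 1e-300))
        if np.isfinite(hi):
            return math.log(max(hi - x, 1e-300))
        return x

    def to_constrained(self, z: float) -> float:
        lo, hi = self.lower, self.upper
        if np.isfinite(lo) and np.isfinite(hi):
            return lo + (hi - lo) / (1.0 + math.exp(-z))
        if np.isfinite(lo):
            return lo + math.exp(z)
        if np.isfinite(hi):
            return hi - math.exp(z)
        return z

    def log_jacobian(self, z: float) -> float:
        """log |dx/dz| of the unconstraining transform."""
        lo, hi = self.lower, self.upper
        if np.isfinite(lo) and np.isfinite(hi):
            return math.log(hi - lo) - z - 2.0 * math.log1p(math.exp(-z))
        if np.isfinite(lo) or np.isfinite(hi):
            return z
        return 0.0


@dataclass
class Model:
    """A log-density over declared scalar parameters.

    ``log_density`` receives the constrained parameter vector (in declaration
    order) and returns the unnormalised log posterior.
    """

    parameters: Sequence[Parameter]
    log_density: Callable[[np.ndarray], float]

    @property
    def names(self) -> list:
        return [p.name for p in self.parameters]


@dataclass
class PosteriorSummary:
    """Draws plus mean, posterior SD, central 95% CI and diagnostics."""

    name: str
    draws: np.ndarray
    mean: float
    psd: float
    ci95: tuple
    rhat: Optional[float] = None
    ess: Optional[float] = None

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray,
                   rhat_value: Optional[float] = None,
                   ess_value: Optional[float] = None) -> "PosteriorSummary":
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        return cls(name=name, draws=draws, mean=float(draws.mean()),
                   psd=float(draws.std(ddof=0)), ci95=(float(lo), float(hi)),
                   rhat=rhat_value, ess=ess_value)

    @classmethod
    def from_chains(cls, name: str, chains: np.ndarray) -> "PosteriorSummary":
        chains = np.asarray(chains, dtype=float)
        s = cls.from_draws(name, chains.reshape(-1))
        s.rhat = rhat(chains)
        s.ess = effective_sample_size(chains)
        return s

    @classmethod
    def point_mass(cls, name: str, value: float, n_draws: int) -> "PosteriorSummary":
        draws = np.full(n_draws, float(value))
        return cls(name=name, draws=draws, mean=float(value), psd=0.0,
                   ci95=(float(value), float(value)), rhat=1.0, ess=float(n_draws))

    def covers(self, value: float) -> bool:
        return self.ci95[0] <= value <= self.ci95[1]

    def to_row(self) -> dict:
        return {"name": self.name, "mean": self.mean, "psd": self.psd,
                "ci_2.5%": self.ci95[0], "ci_97.5%": self.ci95[1],
                "rhat": self.rhat, "ess": self.ess}


@dataclass
class MCMCResult:
    """Per-parameter summaries plus the raw chain array (chains × draws × dim)."""

    summaries: dict
    chains: np.ndarray
    names: list
    warnings: list = field(default_factory=list)

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]

    def draws(self, name: str) -> np.ndarray:
        """Pooled post-burn-in draws for one parameter."""
        return self.chains[:, :, self.names.index(name)].reshape(-1)

    def diagnostics(self) -> dict:
        return {n: {"rhat": s.rhat, "ess": s.ess} for n, s in self.summaries.items()}


def run_mcmc(model: Model, config: RunConfig, seed: Optional[int] = None) -> MCMCResult:
    """Sample the model with adaptive Metropolis-within-Gibbs.

    Proposal scales adapt toward 44% acceptance during burn-in only.  Raises
    :class:`InitializationError` if no finite starting density is found for a
    chain after retries; an Rhat above 1.01 is recorded as a warning on the
    result, never an exception.
    """
    if seed is None:
        seed = config.seed
    params = list(model.parameters)
    dim = len(params)
    n_keep = config.draws_per_chain
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.chains)

    kept = np.empty((config.chains, n_keep, dim))
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        z = _init_chain(model, params, rng)
        kept[c] = _run_chain(model, params, z, rng, config, n_keep)

    names = model.names
    summaries = {}
    warnings = []
    for j, name in enumerate(names):
        s = PosteriorSummary.from_chains(name, kept[:, :, j])
        summaries[name] = s
        if s.rhat is not None and s.rhat > RHAT_WARN_THRESHOLD:
            warnings.append(f"{name}: Rhat {s.rhat:.3f} exceeds {RHAT_WARN_THRESHOLD}")
    return MCMCResult(summaries=summaries, chains=kept, names=names, warnings=warnings)


def _init_chain(model: Model, params: list, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        z = np.array([p.to_unconstrained(p.init) + p.init_spread * rng.uniform(-1, 1)
                      for p in params])
        if np.isfinite(_log_target(model, params, z)):
            return z
    raise InitializationError(
        "no finite log-density found at 100 overdispersed starting points")


def _log_target(model: Model, params: list, z: np.ndarray) -> float:
    x = np.array([p.to_constrained(zi) for p, zi in zip(params, z)])
    lp = model.log_density(x)
    if not np.isfinite(lp):
        return -np.inf
    return lp + sum(p.log_jacobian(zi) for p, zi in zip(params, z))


def _run_chain(model: Model, params: list, z: np.ndarray,
               rng: np.random.Generator, config: RunConfig,
               n_keep: int) -> np.ndarray:
    dim = len(params)
    scales = np.ones(dim)
    accepts = np.zeros(dim)
    lp = _log_target(model, params, z)
    out = np.empty((n_keep, dim))
    kept = 0
    for it in range(config.iterations):
        in_burn = it < config.burn_in
        for j in range(dim):
            z_prop = z.copy()
            z_prop[j] += scales[j] * rng.standard_normal()
            lp_prop = _log_target(model, params, z_prop)
            if math.log(rng.uniform()) < lp_prop - lp:
                z, lp = z_prop, lp_prop
                accepts[j] += 1
        if in_burn and (it + 1) % _ADAPT_INTERVAL == 0:
            rates = accepts / _ADAPT_INTERVAL
            scales *= np.exp(np.clip(rates - _TARGET_ACCEPT, -0.5, 0.5))
            accepts[:] = 0.0
        if not in_burn and (it - config.burn_in) % config.thinning == 0 and kept < n_keep:
            out[kept] = [p.to_constrained(zi) for p, zi in zip(params, z)]
            kept += 1
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics


def _as_chain_matrix(chains) -> np.ndarray:
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D (chains × draws) array")
    if a.shape[0] < 2 or a.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    return a


def rhat(chains) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    Each chain is split in half, doubling the chain count, then the classic
    PSRF sqrt(((n-1)/n · W + B/n) / W) is computed.  Zero total variance
    (all chains constant and equal) returns 1 by convention.
    """
    a = _as_chain_matrix(chains)
    n = a.shape[1] // 2
    halves = np.concatenate([a[:, :n], a[:, n: 2 * n]], axis=0)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 0.0 and b <= 0.0:
        return 1.0
    if w <= 0.0:
        return np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains) -> float:
    """Autocorrelation-based effective sample size, capped at the draw count.

    Uses FFT autocorrelations averaged across chains with Geyer's initial
    positive-sequence truncation.  Constant chains return the total draw
    count by convention.
    """
    a = _as_chain_matrix(chains)
    m, n = a.shape
    total = m * n
    if np.allclose(a.var(), 0.0):
        return float(total)
    acf = np.mean([_autocorr(chain) for chain in a], axis=0)
    # Geyer: sum consecutive-lag pairs while positive
    rho_sum = 0.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair < 0.0:
            break
        rho_sum += pair
        t += 2
    ess = total / (1.0 + 2.0 * rho_sum)
    return float(min(ess, total))


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]
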