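"""Constant-rate birth-death model of a sequential speciation chain.

A single focal lineage is tracked through a tectonic era of length ``T``
Myr.  Events arrive as a Poisson process of total rate ``lambda + mu``
(rates per lineage per Myr): each event is a speciation with probability
``lambda / (lambda + mu)`` — the chain steps to the new species and
continues — or an extinction, which truncates the chain.  The quantity of
interest is how many new species the chain generates before extinction or
the end of the era: with rates at or below 1 per lineage per Myr and eras of
500-1000 Myr this is at most a few hundred, which is why a late start of the
evolutionary clock (late onset of plate tectonics) matters.

This is deliberately a *chain*, not a branching birth-death tree: the model
asks how long a sequential ladder of anagenetic/cladogenetic steps toward a
technological species can grow, not how many lineages coexist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "BirthDeathParams",
    "ChainResult",
    "ChainQuantiles",
    "expected_chain_length",
    "simulate_chain",
    "chain_length_quantiles",
]


@dataclass(frozen=True)
class BirthDeathParams:
    """Per-lineage speciation/extinction rates (per Myr) and a time horizon (Myr)."""

    speciation_rate: float
    extinction_rate: float
    horizon: float

    def __post_init__(self) -> None:
        if self.speciation_rate < 0:
            raise ValueError(f"speciation_rate must be >= 0, got {self.speciation_rate}")
        if self.extinction_rate < 0:
            raise ValueError(f"extinction_rate must be >= 0, got {self.extinction_rate}")
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        if max(self.speciation_rate, self.extinction_rate) > 1.0:
            warnings.warn(
                "speciation/extinction rates above 1 per lineage per Myr are "
                "rare outside crisis intervals",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ChainResult:
    """Outcome of one simulated chain."""

    n_speciations: int
    chain_extinct: bool
    extinction_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_speciations < 0:
            raise ValueError("n_speciations must be non-negative")


def expected_chain_length(params: BirthDeathParams, tol: float = 1e-12) -> float:
    """Expected number of sequential speciation events within the horizon.

    The chain survives k or more steps iff the first k events are all
    speciations (probability p^k with p = lambda/(lambda+mu)) and the k-th
    event falls inside the horizon (a Gamma(k, rate lambda+mu) tail), so

        E[N] = sum_{k>=1} p^k * P(Gamma(k, lambda+mu) <= T),

    evaluated by truncated summation: terms are added in blocks until the
    next term drops below ``tol`` past the bulk of the event-count
    distribution.  For mu = 0 this reduces to the Poisson mean lambda*T.
    """
    lam, mu, horizon = params.speciation_rate, params.extinction_rate, params.horizon
    total = lam + mu
    if lam == 0:
        return 0.0
    p = lam / total
    # Sum in vectorized blocks; the Gamma tail dies out a few sds past
    # total*horizon, and p^k decays geometrically when mu > 0.
    mean_events = total * horizon
    block = max(64, int(mean_events + 10 * np.sqrt(mean_events)))
    result = 0.0
    k0 = 1
    while True:
        k = np.arange(k0, k0 + block)
        terms = p**k * stats.gamma.cdf(horizon, a=k, scale=1.0 / total)
        result += float(terms.sum())
        if terms[-1] < tol and k[-1] > mean_events:
            return result
        k0 += block


def _draw_chain(params: BirthDeathParams, rng: np.random.Generator) -> ChainResult:
    lam, mu, horizon = params.speciation_rate, params.extinction_rate, params.horizon
    total = lam + mu
    if total == 0:
        return ChainResult(0, False)
    p_speciate = lam / total
    n_speciations = 0
    t = 0.0
    # Draw waiting times in chunks sized so that one chunk almost always
    # suffices: the chain ends at the horizon (~total*horizon events) or at
    # extinction (geometric, mean total/mu events), whichever is smaller.
    expected = total * horizon
    if mu > 0:
        expected = min(expected, 20.0 * total / mu)
    chunk = max(64, int(expected + 10 * np.sqrt(expected)))
    while True:
        waits = rng.exponential(1.0 / total, size=chunk)
        is_extinction = rng.random(chunk) >= p_speciate
        times = t + np.cumsum(waits)
        ext_idx = np.flatnonzero(is_extinction)
        first_ext = int(ext_idx[0]) if ext_idx.size else chunk
        # Events strictly before `beyond` fall inside the horizon.
        beyond = int(np.searchsorted(times, horizon, side="right"))
        if first_ext < beyond:
            # Extinction inside the horizon; all earlier events were speciations.
            return ChainResult(
                n_speciations + first_ext, True, float(times[first_ext])
            )
        if beyond < chunk:
            return ChainResult(n_speciations + beyond, False)
        n_speciations += chunk
        t = float(times[-1])


def simulate_chain(params: BirthDeathParams, seed) -> ChainResult:
    """One event-driven realization of the sequential chain.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  The chain
    stops at the horizon or at the first extinction event, whichever comes
    first; reproducible for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_chain(params, rng)


@dataclass(frozen=True)
class ChainQuantiles:
    """Replicate summary of chain lengths."""

    median: float
    q05: float
    q95: float
    mean: float
    extinct_fraction: float
    n_reps: int
    seed: int


def chain_length_quantiles(
    params: BirthDeathParams, n_reps: int, seed: int
) -> ChainQuantiles:
    """Quantiles of the speciation count over independent chain replicates."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps)
    extinct = 0
    for i in range(n_reps):
        result = _draw_chain(params, rng)
        counts[i] = result.n_speciations
        extinct += result.chain_extinct
    return ChainQuantiles(
        median=float(np.median(counts)),
        q05=float(np.quantile(counts, 0.05)),
        q95=float(np.quantile(counts, 0.95)),
        mean=float(np.mean(counts)),
        extinct_fraction=extinct / n_reps,
        n_reps=n_reps,
        seed=seed,
    )
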