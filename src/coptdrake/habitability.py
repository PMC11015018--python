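"""Estimators for the two rare-Earth habitability fractions and their product.

``f_oc`` is the fraction of habitable exoplanets carrying *both* significant
continents and oceans — i.e. whose surface-water inventory falls inside the
narrow radius-dependent permitted window.  ``f_pt`` is the fraction of those
that additionally sustain plate tectonics for at least 0.5 Gyr.  Their
product replaces the classic intelligent-life factor f_i in the Drake
equation; because f_pt is known only as an upper bound, every downstream
count inherits upper-bound status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

from .water_budget import permitted_window, PlanetSpec

__all__ = [
    "VariabilityRange",
    "HabitabilityFractions",
    "FocPopulationEstimate",
    "FptEstimate",
    "DELIVERED_WATER_PCT",
    "OCEAN_WORLD_PCT",
    "WINDOW_WIDTH_RANGE_PCT",
    "foc_ratio_bounds",
    "foc_from_population",
    "fpt_estimate",
    "fi_product",
]

#: Total water mass fraction (percent) deliverable by water-rich planetesimals,
#: spanning 0-90 % impact volatile loss and 5-10 % planetesimal water content.
DELIVERED_WATER_PCT = (0.008, 3.8)

#: Water mass fraction (percent) of ocean worlds such as Europa and Callisto.
OCEAN_WORLD_PCT = (6.0, 55.0)

#: Permitted-window widths (percent) across planet radii 2.35 down to 0.5
#: Earth radii: 0.020 %/R evaluated at the two ends of the radius range.
WINDOW_WIDTH_RANGE_PCT = (0.009, 0.04)


@dataclass(frozen=True)
class VariabilityRange:
    """Expected spread of delivered planetary water mass fractions (percent)."""

    var_low: float
    var_high: float

    def __post_init__(self) -> None:
        if not (0 < self.var_low < self.var_high):
            raise ValueError(
                f"require 0 < var_low < var_high, got ({self.var_low}, {self.var_high})"
            )


#: Default variability: planetesimal-delivery maximum up to ocean-world maximum.
DEFAULT_VARIABILITY = VariabilityRange(DELIVERED_WATER_PCT[1], OCEAN_WORLD_PCT[1])


@dataclass(frozen=True)
class HabitabilityFractions:
    """Bundle of f_oc bounds, the f_pt upper bound, and the f_i product."""

    foc_low: float
    foc_high: float
    fpt_upper: float
    fi_low: float = field(init=False)
    fi_high: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("foc_low", "foc_high", "fpt_upper"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.foc_low > self.foc_high:
            raise ValueError("foc_low must not exceed foc_high")
        lo, hi = fi_product((self.foc_low, self.foc_high), self.fpt_upper)
        object.__setattr__(self, "fi_low", lo)
        object.__setattr__(self, "fi_high", hi)


def foc_ratio_bounds(
    width_low: float,
    width_high: float,
    variability: VariabilityRange = DEFAULT_VARIABILITY,
) -> Tuple[float, float]:
    """Bound f_oc as the ratio of window width to water-delivery variability.

    If delivered water is uniformly distributed over a variability range, the
    probability of landing inside a permitted window of width ``w`` is
    ``w / variability``.  Cross-pairing the narrowest window with the widest
    variability (and vice versa) brackets f_oc:

        lower = width_low / var_high,   upper = width_high / var_low.

    With the default widths (0.009, 0.04) and variability (3.8, 55) this gives
    the headline bracket (0.00016, 0.011).
    """
    if not (0 < width_low <= width_high):
        raise ValueError(f"require 0 < width_low <= width_high, got ({width_low}, {width_high})")
    if width_high > variability.var_low:
        raise ValueError(
            "window width exceeds the variability lower end; the uniform-ratio "
            "bound assumes the window is narrower than the variability range"
        )
    return width_low / variability.var_high, width_high / variability.var_low


@dataclass(frozen=True)
class FocPopulationEstimate:
    """Empirical f_oc from a planet population, with binomial standard error."""

    value: float
    std_error: float
    n_inside: int
    n_total: int


def foc_from_population(
    population, freeboard_mode: str = "conservative"
) -> FocPopulationEstimate:
    """Fraction of a planet population inside its radius-dependent window.

    ``population`` is any object exposing ``radius`` and ``water_fraction``
    array attributes (e.g. :class:`~coptdrake.population.PlanetPopulation`),
    radii in Earth radii and water fractions in percent.  Window membership is
    a closed interval; the standard error is the binomial sqrt(p(1-p)/n).
    """
    radius = np.asarray(population.radius, dtype=float)
    water = np.asarray(population.water_fraction, dtype=float)
    n = radius.size
    if n == 0:
        raise ValueError("population is empty")
    if np.any(radius <= 0):
        raise ValueError("all radii must be positive")
    if np.any(water < 0):
        raise ValueError("all water fractions must be non-negative")
    # All windows share the same Earth-anchored bounds scaled by 1/R, so
    # membership is vectorized as fmin(1) <= f*R <= fmax(1).
    ref = permitted_window(PlanetSpec(1.0), freeboard_mode)
    scaled = water * radius
    inside = int(np.count_nonzero((scaled >= ref.fmin) & (scaled <= ref.fmax)))
    p = inside / n
    return FocPopulationEstimate(
        value=p,
        std_error=math.sqrt(p * (1 - p) / n),
        n_inside=inside,
        n_total=n,
    )


#: Fraction of observed stellar compositions likely to yield planets capable of
#: density-driven (plate) tectonics.
STELLAR_COMPOSITION_FRACTION = 0.33

#: Fraction of terrestrial planets large enough for vigorous mantle convection
#: (small Mars/Mercury-class planets, ~50 % of accretion-model outcomes, are
#: excluded).
LARGE_ENOUGH_FRACTION = 0.5


@dataclass(frozen=True)
class FptEstimate:
    """Upper bound on f_pt as a product of independent reduction factors."""

    value: float
    factors: Tuple[float, ...]
    is_upper_bound: bool = True


def fpt_estimate(
    stellar_fraction: float = STELLAR_COMPOSITION_FRACTION,
    large_enough_fraction: float = LARGE_ENOUGH_FRACTION,
    extra_factors: Iterable[float] = (),
) -> FptEstimate:
    """Upper bound on the long-lived plate-tectonics fraction f_pt.

    The default factors are the stellar-composition cut (0.33) and the
    planet-size cut (0.5), giving 0.165 (displayed as 0.17).  Additional
    multiplicative reduction factors (super-Earth exclusion, mantle thermal
    history, ...) may be appended; each must lie in [0, 1].  The result is an
    upper bound: unquantified reductions only push f_pt lower.
    """
    factors = (stellar_fraction, large_enough_fraction, *extra_factors)
    for f in factors:
        if not 0 <= f <= 1:
            raise ValueError(f"every f_pt factor must lie in [0, 1], got {f}")
    return FptEstimate(value=math.prod(factors), factors=factors)


def fi_product(
    foc_bounds: Sequence[float], fpt: float
) -> Tuple[float, float]:
    """Elementwise product f_i = f_oc * f_pt for a (low, high) f_oc bracket.

    Because f_pt is an upper bound, both returned values are upper bounds.
    """
    low, high = foc_bounds
    for name, v in (("foc low", low), ("foc high", high), ("fpt", fpt)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if low > high:
        raise ValueError("foc bounds must satisfy low <= high")
    return low * fpt, high * fpt
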