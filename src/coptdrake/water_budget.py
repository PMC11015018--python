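"""Isostatic surface-water budget: the radius-dependent permitted water window.

Terrestrial planets can host continents, oceans and plate tectonics
simultaneously only if their surface water inventory falls inside a narrow
"Goldilocks" window.  The lower bound keeps mid-ocean ridges submarine (so
oceanic crust hydrates and one-sided subduction stays stable); the upper
bound stops the oceans from flooding essentially all dry land.  Because
isostatically compensated topography is nearly independent of planet size,
the window expressed as a *mass fraction* of surface water scales inversely
with planetary radius.

Units: water inventories are percent of planet mass throughout ("percent
mass fraction"); ocean-equivalents use Earth's surface ocean, defined
intrinsically as 0.0224 % of one Earth mass, as the unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "EARTH_OCEAN_MASS_FRACTION_PCT",
    "CONSERVATIVE_FMIN_PCT",
    "CONSERVATIVE_FMAX_PCT",
    "KORENAGA_FMAX_PCT",
    "FREEBOARD_MODES",
    "PlanetSpec",
    "WaterWindow",
    "planet_mass",
    "fraction_to_oceans",
    "permitted_window",
    "window_width",
]

logger = logging.getLogger(__name__)

#: Earth's surface-water mass fraction in percent; defines 1 Earth ocean.
EARTH_OCEAN_MASS_FRACTION_PCT = 0.0224

#: Earth-radius window bounds (percent mass fraction).  The lower bound keeps
#: mid-ocean ridges submarine; the conservative upper bound preserves
#: significant (>5-10 % of surface) land masses.
CONSERVATIVE_FMIN_PCT = 0.007
CONSERVATIVE_FMAX_PCT = 0.027

#: Alternative upper bound from continental-freeboard modelling that allows a
#: water world at two to three Earth oceans before land vanishes entirely.
KORENAGA_FMAX_PCT = 0.067

FREEBOARD_MODES = ("conservative", "korenaga")


def planet_mass(radius_rel: float, density_rel: float = 1.0) -> float:
    """Planet mass in Earth masses from relative radius and bulk density.

    Parameters
    ----------
    radius_rel : float
        Radius in Earth radii, > 0.
    density_rel : float
        Bulk density in Earth densities, > 0 (default 1).
    """
    if radius_rel <= 0:
        raise ValueError(f"radius_rel must be positive, got {radius_rel}")
    if density_rel <= 0:
        raise ValueError(f"density_rel must be positive, got {density_rel}")
    return density_rel * radius_rel**3


@dataclass(frozen=True)
class PlanetSpec:
    """A planet's size relative to Earth.

    ``mass_rel`` is derived from the cube law ``density_rel * radius_rel**3``
    and must not be supplied.
    """

    radius_rel: float
    density_rel: float = 1.0
    mass_rel: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mass_rel", planet_mass(self.radius_rel, self.density_rel)
        )


#: Convenience reference planet.
EARTH = PlanetSpec(1.0)


@dataclass(frozen=True)
class WaterWindow:
    """Permitted surface-water window for one planet.

    ``fmin``/``fmax`` are percent mass fractions, ``oceans_min``/``oceans_max``
    the same bounds converted to Earth-ocean units.
    """

    fmin: float
    fmax: float
    oceans_min: float
    oceans_max: float
    mode: str = "conservative"

    def __post_init__(self) -> None:
        # fmin == fmax (a degenerate, zero-width window) is tolerated so that
        # width computations on edge cases are well defined.
        if not (0 < self.fmin <= self.fmax):
            raise ValueError(f"require 0 < fmin <= fmax, got ({self.fmin}, {self.fmax})")
        if not (0 < self.oceans_min <= self.oceans_max):
            raise ValueError(
                f"require 0 < oceans_min <= oceans_max, "
                f"got ({self.oceans_min}, {self.oceans_max})"
            )

    def contains(self, fraction_pct: float) -> bool:
        """Closed-interval membership test for a water mass fraction."""
        return self.fmin <= fraction_pct <= self.fmax


def fraction_to_oceans(fraction_pct: float, planet: PlanetSpec = EARTH) -> float:
    """Convert a percent water mass fraction into Earth-ocean units.

    One Earth ocean is defined as 0.0224 % of one Earth mass, so the
    conversion is the dimensionless ratio
    ``(fraction_pct / 0.0224) * planet.mass_rel`` — no kg-scale constants.
    """
    if fraction_pct < 0:
        raise ValueError(f"fraction_pct must be non-negative, got {fraction_pct}")
    return (fraction_pct / EARTH_OCEAN_MASS_FRACTION_PCT) * planet.mass_rel


def permitted_window(
    planet: PlanetSpec, freeboard_mode: str = "conservative"
) -> WaterWindow:
    """Radius-dependent permitted water window for a planet.

    The Earth-radius bounds (0.007-0.027 % conservative, upper bound 0.067 %
    in ``korenaga`` mode) scale in inverse proportion to planetary radius.
    Note that for a Mars-size planet (0.5 Earth radii) the exact scaling gives
    0.014-0.054 %, slightly below the loosely rounded 0.015-0.055 % sometimes
    quoted; the scaling law, not the rounded instance, is the model.
    """
    if freeboard_mode not in FREEBOARD_MODES:
        raise ValueError(
            f"unknown freeboard_mode {freeboard_mode!r}; expected one of {FREEBOARD_MODES}"
        )
    fmax_earth = (
        CONSERVATIVE_FMAX_PCT if freeboard_mode == "conservative" else KORENAGA_FMAX_PCT
    )
    fmin = CONSERVATIVE_FMIN_PCT / planet.radius_rel
    fmax = fmax_earth / planet.radius_rel
    logger.debug(
        "permitted window for R=%g (%s): %.6g-%.6g %%",
        planet.radius_rel,
        freeboard_mode,
        fmin,
        fmax,
    )
    return WaterWindow(
        fmin=fmin,
        fmax=fmax,
        oceans_min=fraction_to_oceans(fmin, planet),
        oceans_max=fraction_to_oceans(fmax, planet),
        mode=freeboard_mode,
    )


def window_width(window: WaterWindow) -> float:
    """Width of the permitted window in percent mass fraction."""
    return window.fmax - window.fmin
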