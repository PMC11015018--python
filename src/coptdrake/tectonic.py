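"""Timescales of the single-lid to plate-tectonics transition.

Two independent clocks bracket how long a planet needs to convert a single
stagnant/squishy lid into a global plate mosaic: (1) kinematics — a global
network of convergent margins must lengthen from a single subduction
initiation point at observed trench-lengthening rates; (2) stratigraphy —
the Neoproterozoic carbon-isotope excursions and Snowball glaciations mark
the onset and the end of the surface-system disruption that accompanied the
transition on Earth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "GLOBAL_TRENCH_LENGTH_KM",
    "TRENCH_RATE_RANGE_KM_PER_MYR",
    "MosaicGrowthParams",
    "EventBracket",
    "C_ISOTOPE_BRACKET",
    "GLACIATION_BRACKET",
    "assembly_time",
    "assembly_time_range",
    "bracket_duration",
]

#: Present-day total length of convergent plate margins (km).
GLOBAL_TRENCH_LENGTH_KM = 55_000.0

#: Trench-lengthening rates (km/Myr) observed and modelled for Cretaceous and
#: younger subduction-initiation episodes.
TRENCH_RATE_RANGE_KM_PER_MYR = (100.0, 600.0)


@dataclass(frozen=True)
class MosaicGrowthParams:
    """Linear plate-mosaic growth: target margin length and rate range."""

    target_length: float = GLOBAL_TRENCH_LENGTH_KM
    rate_low: float = TRENCH_RATE_RANGE_KM_PER_MYR[0]
    rate_high: float = TRENCH_RATE_RANGE_KM_PER_MYR[1]

    def __post_init__(self) -> None:
        if self.target_length < 0:
            raise ValueError("target_length must be non-negative")
        if not (0 < self.rate_low <= self.rate_high):
            raise ValueError(
                f"require 0 < rate_low <= rate_high, got ({self.rate_low}, {self.rate_high})"
            )


@dataclass(frozen=True)
class EventBracket:
    """Two geological event ages (Ma before present) bracketing a transition."""

    first_event_age: float
    last_event_age: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.first_event_age <= self.last_event_age:
            raise ValueError(
                "first_event_age must exceed last_event_age (ages decrease "
                f"toward present), got ({self.first_event_age}, {self.last_event_age})"
            )


#: Oldest (Bitter Springs, 811 Ma) to youngest (Shuram, ~570 Ma) Neoproterozoic
#: carbon-isotope excursions.
C_ISOTOPE_BRACKET = EventBracket(811.0, 570.0, "C-isotope excursions")

#: First (Sturtian, ~720 Ma) to last (Gaskiers, ~580 Ma) Snowball glaciations.
GLACIATION_BRACKET = EventBracket(720.0, 580.0, "Snowball glaciations")


def assembly_time(target_length: float, rate: float) -> float:
    """Myr to grow ``target_length`` km of convergent margin at ``rate`` km/Myr.

    Growth is modelled as linear lengthening from a point source at a
    constant rate, so the time is the simple quotient length/rate.
    """
    if target_length < 0:
        raise ValueError("target_length must be non-negative")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return target_length / rate


def assembly_time_range(params: MosaicGrowthParams) -> Tuple[float, float]:
    """(shortest, longest) assembly time; the fastest rate gives the shortest."""
    return (
        assembly_time(params.target_length, params.rate_high),
        assembly_time(params.target_length, params.rate_low),
    )


def bracket_duration(bracket: EventBracket) -> float:
    """Duration in Myr between the bracketing event ages."""
    return bracket.first_event_age - bracket.last_event_age
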