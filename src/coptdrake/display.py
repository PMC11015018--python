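"""Display rounding conventions used in reports.

Published habitability estimates mix rounding conventions — one significant
figure for fractions near 0.003, two for probability brackets, whole numbers
for ocean counts and timescales.  Science code keeps full precision; this
module centralizes the half-away-from-zero display rounding so reports can
show raw and rounded values side by side.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP

__all__ = ["ROUNDING_CONVENTIONS", "round_like_paper"]

ROUNDING_CONVENTIONS = ("sig1", "sig2", "dec1", "dec2", "int")


def _round_half_away(value: float, exponent: int) -> float:
    """Round to 10**exponent, halves away from zero."""
    quantum = Decimal(1).scaleb(exponent)
    d = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(d)


def round_like_paper(value: float, convention: str) -> float:
    """Round ``value`` for display under a named convention.

    ``sig1``/``sig2`` round to one/two significant figures, ``dec1``/``dec2``
    to one/two decimal places, ``int`` to the nearest integer — all with
    halves rounded away from zero (0.165 -> 0.17 under ``dec2``).
    """
    if convention not in ROUNDING_CONVENTIONS:
        raise ValueError(
            f"unknown rounding convention {convention!r}; "
            f"expected one of {ROUNDING_CONVENTIONS}"
        )
    if convention == "int":
        return _round_half_away(value, 0)
    if convention.startswith("dec"):
        return _round_half_away(value, -int(convention[3]))
    # significant figures
    if value == 0:
        return 0.0
    sig = int(convention[3])
    magnitude = math.floor(math.log10(abs(value)))
    return _round_half_away(value, magnitude - (sig - 1))
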