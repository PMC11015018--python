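"""Classic, modified and COPT forms of the Drake equation.

The Drake equation estimates the expected number of active communicative
civilizations (ACCs) in the galaxy as the product

    N = R* . f_p . n_e . f_l . f_i . f_c . L

with R* the star-formation rate (stars/yr), f_p the fraction of stars with
planets, n_e habitable planets per system, f_l the fraction developing life,
f_i the fraction of those evolving civilizations, f_c the fraction becoming
ACCs, and L the broadcast lifetime in years.  The modified (ACC) form splits
f_i = f_oc . f_pt; the COPT form drops the civilization factors and counts
planets with long-term coexisting Continents, Oceans and Plate Tectonics
over the characteristic coexistence time L_COPT = 5e8 yr.

Each term is a :class:`Term` — a point, an interval, or an interval with a
named sampling distribution — so the same parameter set supports point,
interval-arithmetic, and seeded Monte Carlo evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "Term",
    "DrakeParams",
    "DrakeResult",
    "DRAKE_1961_ACC_RANGE",
    "L_COPT_YEARS",
    "drake_1961",
    "modified_acc_params",
    "copt_params",
    "evaluate_point",
    "evaluate_interval",
    "scale_acc_range",
    "evaluate_monte_carlo",
]

#: The 1961 consensus ACC range acknowledged by Drake (taken as given).
DRAKE_1961_ACC_RANGE = (200.0, 5.0e7)

#: Characteristic time (yr) of continent-ocean-plate-tectonics coexistence on
#: Earth needed for accelerated development of advanced life.
L_COPT_YEARS = 5.0e8

_DISTRIBUTIONS = ("point", "uniform", "loguniform")

#: Span ratio above which an interval term defaults to log-uniform sampling.
_LOG_SPAN_RATIO = 100.0


@dataclass(frozen=True)
class Term:
    """One Drake-equation factor: an interval [low, high] with a sampler.

    ``distribution`` is one of ``point`` (degenerate), ``uniform`` or
    ``loguniform``.  When left unset, terms spanning more than two decades
    default to log-uniform (the standard non-informative choice for
    order-of-magnitude parameters) and narrower terms to uniform.
    ``upper_bound`` marks factors known only as upper limits (f_pt); the flag
    propagates into every derived count.
    """

    low: float
    high: float
    distribution: Optional[str] = None
    upper_bound: bool = False

    def __post_init__(self) -> None:
        if self.low < 0:
            raise ValueError(f"term lower end must be non-negative, got {self.low}")
        if self.low > self.high:
            raise ValueError(f"term requires low <= high, got ({self.low}, {self.high})")
        if self.distribution is not None and self.distribution not in _DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; expected one of {_DISTRIBUTIONS}"
            )
        if self.distribution == "loguniform" and self.low <= 0:
            raise ValueError("loguniform terms require a strictly positive lower end")

    @classmethod
    def point(cls, value: float, upper_bound: bool = False) -> "Term":
        return cls(value, value, "point", upper_bound)

    @classmethod
    def interval(
        cls,
        low: float,
        high: float,
        distribution: Optional[str] = None,
        upper_bound: bool = False,
    ) -> "Term":
        return cls(low, high, distribution, upper_bound)

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    def resolved_distribution(self) -> str:
        """The sampling distribution, applying the span-based default."""
        if self.is_point:
            return "point"
        if self.distribution is not None:
            return self.distribution
        if self.low > 0 and self.high / self.low > _LOG_SPAN_RATIO:
            return "loguniform"
        return "uniform"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        dist = self.resolved_distribution()
        if dist == "point":
            return np.full(n, self.low)
        if dist == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        # loguniform
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=n))


#: Canonical term order for the two equation modes.
_ACC_TERMS = ("r_star", "f_p", "n_e", "f_l", "f_i", "f_c", "lifetime")
_COPT_TERMS = ("r_star", "f_p", "n_e", "f_l", "f_oc", "f_pt", "lifetime")


@dataclass(frozen=True)
class DrakeParams:
    """Full parameter set for one Drake-equation evaluation.

    The civilization factor is supplied either directly as ``f_i`` (ACC mode
    with a monolithic intelligence fraction) or split as ``f_oc``/``f_pt``.
    When split, ACC mode uses their product in place of f_i and COPT mode
    keeps them as separate factors and drops f_c (``f_c`` then defaults to 1).
    """

    r_star: Term
    f_p: Term
    n_e: Term
    f_l: Term
    f_c: Term
    lifetime: Term
    f_i: Optional[Term] = None
    f_oc: Optional[Term] = None
    f_pt: Optional[Term] = None
    mode: str = "ACC"

    def __post_init__(self) -> None:
        if self.mode not in ("ACC", "COPT"):
            raise ValueError(f"mode must be 'ACC' or 'COPT', got {self.mode!r}")
        split = self.f_oc is not None or self.f_pt is not None
        if split and (self.f_oc is None or self.f_pt is None):
            raise ValueError("f_oc and f_pt must be supplied together")
        if self.f_i is not None and split:
            raise ValueError("supply either f_i or the (f_oc, f_pt) pair, not both")
        if self.f_i is None and not split:
            raise ValueError("a civilization factor (f_i or f_oc/f_pt) is required")
        if self.mode == "COPT" and not split:
            raise ValueError("COPT mode requires the (f_oc, f_pt) pair")

    def terms(self) -> Dict[str, Term]:
        """Ordered factor dictionary for the configured mode."""
        if self.mode == "COPT":
            return {
                "r_star": self.r_star,
                "f_p": self.f_p,
                "n_e": self.n_e,
                "f_l": self.f_l,
                "f_oc": self.f_oc,
                "f_pt": self.f_pt,
                "lifetime": self.lifetime,
            }
        out: Dict[str, Term] = {
            "r_star": self.r_star,
            "f_p": self.f_p,
            "n_e": self.n_e,
            "f_l": self.f_l,
        }
        if self.f_i is not None:
            out["f_i"] = self.f_i
        else:
            out["f_oc"] = self.f_oc
            out["f_pt"] = self.f_pt
        out["f_c"] = self.f_c
        out["lifetime"] = self.lifetime
        return out

    @property
    def any_upper_bound(self) -> bool:
        return any(t.upper_bound for t in self.terms().values())


def drake_1961(f_i: Tuple[float, float] = (1.0, 1.0)) -> DrakeParams:
    """The 1961 'educated guess' parameter ranges."""
    return DrakeParams(
        r_star=Term.point(1.0),
        f_p=Term.interval(0.2, 0.5),
        n_e=Term.interval(1.0, 5.0),
        f_l=Term.point(1.0),
        f_i=Term.interval(*f_i),
        f_c=Term.interval(0.1, 0.2),
        lifetime=Term.interval(1.0e3, 1.0e8),
        mode="ACC",
    )


def modified_acc_params(
    foc_bounds: Tuple[float, float] = (0.00016, 0.011),
    fpt: float = 0.17,
) -> DrakeParams:
    """1961 ranges with the civilization factor split into f_oc * f_pt."""
    base = drake_1961()
    return replace(
        base,
        f_i=None,
        f_oc=Term.interval(*foc_bounds, upper_bound=True),
        f_pt=Term.point(fpt, upper_bound=True),
    )


def copt_params(
    foc_bounds: Tuple[float, float] = (0.00016, 0.011),
    fpt: float = 0.17,
    lifetime: float = L_COPT_YEARS,
) -> DrakeParams:
    """Remote-sensing COPT-planet count: no civilization terms, L = L_COPT."""
    return DrakeParams(
        r_star=Term.point(1.0),
        f_p=Term.interval(0.2, 0.5),
        n_e=Term.interval(1.0, 5.0),
        f_l=Term.point(1.0),
        f_c=Term.point(1.0),
        f_oc=Term.interval(*foc_bounds, upper_bound=True),
        f_pt=Term.point(fpt, upper_bound=True),
        lifetime=Term.point(lifetime),
        mode="COPT",
    )


@dataclass(frozen=True)
class DrakeResult:
    """Summary of one evaluation; interval or Monte Carlo fields may be unset."""

    mode: str
    is_upper_bound: bool
    low: Optional[float] = None
    high: Optional[float] = None
    point: Optional[float] = None
    mean: Optional[float] = None
    median: Optional[float] = None
    q025: Optional[float] = None
    q975: Optional[float] = None
    sample_min: Optional[float] = None
    sample_max: Optional[float] = None
    p_at_least_one: Optional[float] = None
    n_samples: Optional[int] = None
    seed: Optional[int] = None


def evaluate_point(params: DrakeParams) -> float:
    """Product of all factors; every term must be a point value."""
    prod = 1.0
    for name, term in params.terms().items():
        if not term.is_point:
            raise ValueError(f"term {name!r} is not a point value")
        prod *= term.low
    return prod


def evaluate_interval(params: DrakeParams) -> Tuple[float, float]:
    """Interval-arithmetic bounds: products of lows and of highs.

    Valid because every factor is non-negative, so the product is monotone
    non-decreasing in each term.
    """
    lows = highs = 1.0
    for term in params.terms().values():
        lows *= term.low
        highs *= term.high
    return lows, highs


def scale_acc_range(
    base: Tuple[float, float], fi_bounds: Tuple[float, float]
) -> Tuple[float, float]:
    """Rescale a published ACC range by replacement f_i bounds.

    The 1961 range implicitly used f_i = 1; substituting the continent/ocean
    and plate-tectonics product scales each end multiplicatively.  Both
    returned values are upper bounds whenever the f_i bounds are.
    """
    if min(*base, *fi_bounds) < 0:
        raise ValueError("all inputs must be non-negative")
    return base[0] * fi_bounds[0], base[1] * fi_bounds[1]


def evaluate_monte_carlo(
    params: DrakeParams, n_samples: int, seed: int
) -> DrakeResult:
    """Seeded Monte Carlo propagation of the term distributions.

    Each term is sampled independently from its resolved distribution; the
    summary reports mean, median, central 95 % quantiles, sample extrema and
    the fraction of draws with N >= 1.  Reproducible for a given seed.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    samples = np.ones(n_samples)
    for term in params.terms().values():
        samples *= term.sample(n_samples, rng)
    return DrakeResult(
        mode=params.mode,
        is_upper_bound=params.any_upper_bound,
        mean=float(np.mean(samples)),
        median=float(np.median(samples)),
        q025=float(np.quantile(samples, 0.025)),
        q975=float(np.quantile(samples, 0.975)),
        sample_min=float(np.min(samples)),
        sample_max=float(np.max(samples)),
        p_at_least_one=float(np.mean(samples >= 1.0)),
        n_samples=n_samples,
        seed=seed,
    )
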