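# Methods

This note documents the models behind `coptdrake`, the choices made where
the design was genuinely open, and what the test suite does and does not
demonstrate.

## Surface-water budget (`water_budget`)

**Model.** Planetary topography is assumed isostatically compensated, which
makes elevation contrasts between continent-like and ocean-basin-like crust
nearly independent of planet size. The permitted surface-water window is
therefore anchored at the Earth-radius bounds — 0.007 % of planet mass
(ridges stay submarine, oceanic crust hydrates, one-sided subduction remains
stable) to 0.027 % (significant land survives flooding) — and both bounds
scale as 1/R with planetary radius. An alternative `korenaga` mode widens
the upper bound to 0.067 % (two to three Earth oceans), the freeboard-model
limit at which a water world finally submerges all land.

**Units.** One Earth ocean is *defined* as 0.0224 % of one Earth mass, so
every conversion between mass fractions and ocean counts is a ratio of two
dimensionless numbers; no kilogram-scale constants enter the core. Ocean
equivalents consequently scale exactly as R² at fixed density (fraction
∝ 1/R times mass ∝ R³).

**Numerical choices.** Functions return full-precision values; the
published-style display rounding lives in a separate utility (below). The
cube-law mass is accepted for any positive density even though the anchor
cases assume Earth density. Window membership is a closed interval: planets
sitting exactly on a bound count as inside (ties have measure zero for the
continuous generators used here). For a 0.5-Earth-radius planet the exact
scaling gives 0.014–0.054 %, which differs in the last digit from the
loosely rounded 0.015–0.055 % sometimes quoted for Mars-size planets; the
scaling law is treated as the model and the instance as a rounding artifact.

## Habitability fractions (`habitability`)

**f_oc ratio bound.** Delivered water is modelled as uniformly distributed
over its variability range, so the probability of landing inside a permitted
window of width w is w divided by the variability span. Cross-pairing the
narrowest window (0.009 %, at 2.35 Earth radii) with the widest variability
(55 %, ocean worlds) and the widest window (0.04 %, at 0.5 Earth radii) with
the narrowest (3.8 %, planetesimal delivery) brackets
f_oc ∈ (0.00016, 0.011). The uniform assumption is the only distributional
reading that reproduces both endpoints of that bracket from the printed
ranges; it is a modelling convention, not an inference.

**f_pt.** A product of independent reduction factors, each in [0, 1]:
stellar compositions capable of density-driven tectonics (0.33) and
planets large enough for vigorous convection (0.5), giving 0.165
(displayed 0.17). The estimate is one-sided — further cuts (super-Earth
exclusion, mantle thermal history) are real but unquantified — so the value
is flagged as an upper bound and the flag propagates into every product
that uses it. Downstream intervals treat the f_pt lower end as 0.

**Empirical f_oc.** `foc_from_population` counts population members inside
their radius-dependent window (vectorised as f·R against the Earth-anchored
bounds, valid because both bounds scale as 1/R) and reports the binomial
standard error √(p(1−p)/n).

## Drake engine (`drake`)

Terms are intervals with a named sampling distribution. Defaults: terms
spanning more than two decades (L, the f_i-type factors) sample
log-uniformly — the standard non-informative choice for order-of-magnitude
parameters — and narrower terms (f_p, f_c) uniformly; both are overridable.
Interval evaluation multiplies lower and upper ends separately, which is
exact because all factors are non-negative. Monte Carlo evaluation draws all
terms independently with one seeded generator and reports mean, median,
2.5/97.5 % quantiles, extrema and P(N ≥ 1); samples are contained in the
interval bounds by construction, which the tests assert as an oracle.

The historical 1961 ACC range 200–50,000,000 is taken as given (the product
of the published minima is actually 20, not 200) and rescaled by replacement
f_i bounds rather than re-derived. The published reduction chain applies
one-significant-figure rounding to f_i *before* rescaling (3×10⁻⁵ and
2×10⁻³ give 0.006 and 100,000), so reports do the same and record the raw
bounds alongside. The further L-reduced ACC range and the published COPT
count range do not follow from any printed factor combination; both are
available only as parameterised scenarios and are never asserted.

## Tectonic clock (`tectonic`)

Plate-mosaic assembly is linear lengthening from a single subduction
initiation point at a constant trench-lengthening rate, so the time is the
quotient of target margin length (55,000 km, the modern global total) by
rate (100–600 km/Myr): 92–550 Myr. No logistic or branching "infection"
dynamics are modelled — the arithmetic the estimate rests on is a simple
quotient, and dressing it up would suggest precision that is not there.
Event-bracketed durations subtract ages (Ma before present): the
carbon-isotope excursion bracket (811 − 570 = 241 Myr) and the Snowball
glaciation bracket (720 − 580 = 140 Myr).

## Speciation chain (`speciation`)

**Model.** A single focal lineage in a constant-rate birth–death setting:
events arrive as a Poisson process at rate λ+μ (per Myr); each event is a
speciation with probability λ/(λ+μ), stepping the chain forward, or an
extinction, which truncates it; the chain also stops at the horizon T.
This is deliberately a *chain*, not a branching tree: the question is how
long a sequential ladder of species-to-species transitions toward a
technological species can grow, and only under this reading do rates ≤ 1
per lineage per Myr over 500–1000 Myr yield the expected "at most a few
hundred" steps (a full birth–death tree would give exponentially many
coexisting lineages). Re-seeding the chain from sister lineages after
extinction is out of scope.

**Computation.** The expected count is the truncated series
E[N] = Σ_k p^k · P(Gamma(k, λ+μ) ≤ T), summed in vectorised blocks until
terms fall below 10⁻¹² past the bulk of the event-count distribution; for
μ = 0 it reduces to the Poisson mean λT. The tests cross-check it against
the independent closed form λ(1−e^(−μT))/μ (speciations accrue at rate λ
while the lineage survives an exponential lifetime) and against Monte Carlo
simulation. The simulator draws waiting times in chunks sized to the
expected event count — min((λ+μ)T, 20(λ+μ)/μ) plus ten standard deviations
— so one chunk almost always suffices even for near-infinite horizons.

## Synthetic population (`population`)

**What it emulates.** The statistical footprint of planet-formation Monte
Carlo output for terrestrial planets around M dwarfs: radii log-uniform on
0.5–2.35 Earth radii (a scale parameter with only its bounds specified) and
surface water fractions 0–56 % drawn from a three-component mixture — dry
planets (point mass at 0, weight 0.70), planetesimal-delivered water
(uniform 0.008–3.8 %, weight 0.19) and ocean worlds (log-uniform 6–55 %,
weight 0.11). The weights are a calibration: they place the analytic
in-window probability at ≈ 9.3×10⁻⁴, inside the 0.0006–0.0022 decade
reported when published formation-model output is filtered through the same
window. That is a choice to make the default pipeline resemble the external
result, not a prediction of it.

**What it does not emulate.** Any physics of migration, snowline chemistry
or impact devolatilization; radius–water correlations; measurement error.
Passing recovery tests therefore show the estimator chain is self-consistent
on populations with the assumed statistical structure, not that real
exoplanet demographics follow that structure.

**Analytic companion.** `in_window_mass` integrates each component's closed
form CDF over the radius-dependent window and averages over the radius
density by adaptive quadrature (`scipy.integrate.quad`, tolerance 10⁻¹⁰).
Generator and companion are compared at n = 10⁶ within three binomial
standard errors in the tests.

## Scenario runner, display rounding (`scenario`, `display`, `cli`)

Scenarios are YAML files naming stages and per-stage parameters; stages run
in dependency order (population → foc → fpt → drake/copt; tectonic and
speciation independent), every stochastic stage requires a seed, and the
same scenario + seed produce byte-identical CSV/JSON (fixed column order,
6-significant-digit formatting, display values in a separate column).
Display rounding (`round_like_paper`) supports one/two significant figures,
one/two decimals and nearest integer, always rounding halves away from zero
(0.165 → 0.17), since banker's rounding would not reproduce the published
presentation. Raw values always accompany rounded ones.

## Problem sizes and limitations

Default test and acceptance sizes — 10⁵ Monte Carlo Drake samples, 10⁶
synthetic planets, 10⁴ pure-birth replicates, 2×10³ chain replicates — were
chosen so that three-standard-error recovery bands are decisively narrower
than the effects under test while the whole suite stays interactive.

Known limitations: the water window ignores lithospheric flexure and
mantle-water partitioning (which would narrow it on super-Earths); f_pt is
an upper bound with no distributional content; the speciation chain ignores
ecological covariates; and the synthetic population is a statistical
stand-in, so external-data agreement is a range check, not an equality test.
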