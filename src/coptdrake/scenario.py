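"""Scenario runner: reproducible multi-stage analysis runs from config files.

A scenario is a YAML document naming the stages to run (``water``, ``foc``,
``fpt``, ``drake``, ``copt``, ``tectonic``, ``speciation``, ``population``)
with one parameter block per stage plus an optional seed.  Stages execute in
dependency order (population feeds foc; foc and fpt feed drake/copt;
tectonic and speciation are independent) and every reported rounded value is
accompanied by the raw value it was rounded from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import __version__
from .display import round_like_paper
from . import drake as drake_mod
from . import habitability as hab
from . import population as pop_mod
from . import speciation as spec_mod
from . import tectonic as tect_mod
from .water_budget import PlanetSpec, permitted_window, window_width

__all__ = [
    "STAGES",
    "Scenario",
    "RunReport",
    "load_scenario",
    "bundled_scenario_names",
    "run_scenario",
]

logger = logging.getLogger(__name__)

STAGES = ("population", "water", "foc", "fpt", "drake", "copt", "tectonic", "speciation")

#: Stages whose results depend on pseudo-random draws, hence need a seed.
_STOCHASTIC_STAGES = {"population", "speciation"}

_EXECUTION_ORDER = ("population", "water", "foc", "fpt", "drake", "copt", "tectonic", "speciation")


@dataclass(frozen=True)
class Scenario:
    """Validated scenario: name, selected stages, per-stage parameter blocks."""

    name: str
    stages: tuple
    params: Dict[str, Dict[str, Any]] = dc_field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("scenario selects no stages")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
        needs_seed = _STOCHASTIC_STAGES.intersection(self.stages)
        if "drake" in self.stages and self.params.get("drake", {}).get("monte_carlo"):
            needs_seed.add("drake")
        if "copt" in self.stages and self.params.get("copt", {}).get("monte_carlo"):
            needs_seed.add("copt")
        if needs_seed and self.seed is None:
            raise ValueError(
                f"stages {sorted(needs_seed)} are stochastic; the scenario needs a seed"
            )


def load_scenario(source, seed_override: Optional[int] = None) -> Scenario:
    """Load a scenario from a YAML path or a bundled scenario name."""
    path = Path(str(source))
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("coptdrake").joinpath(f"scenarios/{source}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(
                f"no scenario file {source!r} and no bundled scenario of that name "
                f"(bundled: {bundled_scenario_names()})"
            )
        text = ref.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "stages" not in raw:
        raise ValueError("scenario file must be a mapping with a 'stages' list")
    seed = seed_override if seed_override is not None else raw.get("seed")
    stages = tuple(raw["stages"])
    params = {k: v for k, v in raw.items() if k in STAGES and isinstance(v, dict)}
    return Scenario(
        name=raw.get("name", getattr(path, "stem", str(source))),
        stages=stages,
        params=params,
        seed=seed,
    )


def bundled_scenario_names() -> List[str]:
    root = resources.files("coptdrake").joinpath("scenarios")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


@dataclass
class RunReport:
    """Results of one scenario run, raw and display values side by side."""

    scenario: str
    version: str
    seed: Optional[int]
    stages: Dict[str, Dict[str, Dict[str, Any]]] = dc_field(default_factory=dict)

    def record(
        self,
        stage: str,
        key: str,
        value,
        convention: Optional[str] = None,
        upper_bound: bool = False,
        **extra,
    ) -> None:
        entry: Dict[str, Any] = {"value": value}
        if convention is not None:
            entry["display"] = round_like_paper(value, convention)
            entry["convention"] = convention
        if upper_bound:
            entry["upper_bound"] = True
        entry.update(extra)
        self.stages.setdefault(stage, {})[key] = entry

    def to_json(self, path) -> None:
        payload = {
            "scenario": self.scenario,
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_csv(self, path) -> None:
        lines = ["scenario,stage,key,value,display,upper_bound"]
        for stage in sorted(self.stages):
            for key in sorted(self.stages[stage]):
                e = self.stages[stage][key]
                value = e["value"]
                val_str = f"{value:.6g}" if isinstance(value, (int, float)) else str(value)
                disp = e.get("display", "")
                disp_str = f"{disp:.6g}" if isinstance(disp, float) else str(disp)
                ub = "1" if e.get("upper_bound") else "0"
                lines.append(f"{self.scenario},{stage},{key},{val_str},{disp_str},{ub}")
        Path(path).write_text("\n".join(lines) + "\n")


def _stage_water(report: RunReport, block: Dict[str, Any]) -> None:
    radii = block.get("radii", [0.5, 1.0, 2.35])
    mode = block.get("freeboard_mode", "conservative")
    for r in radii:
        w = permitted_window(PlanetSpec(float(r)), mode)
        tag = f"R{r:g}"
        report.record("water", f"{tag}_fmin_pct", w.fmin, "sig1")
        report.record("water", f"{tag}_fmax_pct", w.fmax, "sig2")
        report.record("water", f"{tag}_oceans_min", w.oceans_min)
        report.record("water", f"{tag}_oceans_max", w.oceans_max)
        report.record("water", f"{tag}_width_pct", window_width(w))


def _stage_population(report: RunReport, block: Dict[str, Any], seed: int, ctx: Dict) -> None:
    n = int(block.get("n", 100_000))
    config = pop_mod.default_config(n=n, seed=seed)
    population = pop_mod.generate(config)
    ctx["population"] = population
    ctx["population_config"] = config
    mode = block.get("freeboard_mode", "conservative")
    est = hab.foc_from_population(population, mode)
    analytic = pop_mod.in_window_mass(config, mode)
    report.record("population", "n", n)
    report.record("population", "foc_empirical", est.value, std_error=est.std_error)
    report.record("population", "foc_analytic", analytic)
    report.record("population", "provenance", population.provenance)


def _stage_foc(report: RunReport, block: Dict[str, Any], ctx: Dict) -> None:
    width_low = float(block.get("width_low", hab.WINDOW_WIDTH_RANGE_PCT[0]))
    width_high = float(block.get("width_high", hab.WINDOW_WIDTH_RANGE_PCT[1]))
    var = hab.VariabilityRange(
        float(block.get("var_low", hab.DEFAULT_VARIABILITY.var_low)),
        float(block.get("var_high", hab.DEFAULT_VARIABILITY.var_high)),
    )
    low, high = hab.foc_ratio_bounds(width_low, width_high, var)
    ctx["foc_bounds"] = (low, high)
    report.record("foc", "foc_low", low, "sig2")
    report.record("foc", "foc_high", high, "sig2")


def _stage_fpt(report: RunReport, block: Dict[str, Any], ctx: Dict) -> None:
    est = hab.fpt_estimate(
        float(block.get("stellar_fraction", hab.STELLAR_COMPOSITION_FRACTION)),
        float(block.get("large_enough_fraction", hab.LARGE_ENOUGH_FRACTION)),
        tuple(block.get("extra_factors", ())),
    )
    ctx["fpt"] = est.value
    report.record("fpt", "fpt_upper", est.value, "dec2", upper_bound=True)


def _civ_bounds(block: Dict[str, Any], ctx: Dict):
    foc = tuple(block.get("foc_bounds", ctx.get("foc_bounds", (0.00016, 0.011))))
    fpt = float(block.get("fpt", ctx.get("fpt", 0.17)))
    return foc, fpt


def _stage_drake(report: RunReport, block: Dict[str, Any], seed: Optional[int], ctx: Dict) -> None:
    foc, fpt = _civ_bounds(block, ctx)
    fi = hab.fi_product(foc, fpt)
    report.record("drake", "fi_low", fi[0], "sig1", upper_bound=True)
    report.record("drake", "fi_high", fi[1], "sig1", upper_bound=True)

    base = tuple(block.get("base_range", drake_mod.DRAKE_1961_ACC_RANGE))
    # The published chain scales the historical ACC range by the *displayed*
    # (one-significant-figure) f_i bounds, so reports do the same; the raw
    # bounds are recorded alongside.
    fi_display = (round_like_paper(fi[0], "sig1"), round_like_paper(fi[1], "sig1"))
    scaled = drake_mod.scale_acc_range(base, fi_display)
    report.record("drake", "acc_base_low", base[0])
    report.record("drake", "acc_base_high", base[1])
    report.record("drake", "acc_scaled_low", scaled[0], "sig1", upper_bound=True)
    report.record("drake", "acc_scaled_high", scaled[1], "sig1", upper_bound=True)
    if scaled[0] < 1.0:
        report.record(
            "drake",
            "p_at_least_one_acc_lower_pct",
            100.0 * scaled[0],
            "sig1",
            upper_bound=True,
            caveat="lower-limit probability; strongly dependent on remaining parameter uncertainties",
        )

    params = drake_mod.modified_acc_params(foc, fpt)
    lo, hi = drake_mod.evaluate_interval(params)
    report.record("drake", "interval_low", lo, upper_bound=True)
    report.record("drake", "interval_high", hi, upper_bound=True)
    mc = block.get("monte_carlo")
    if mc:
        n_samples = int(mc.get("n_samples", 100_000)) if isinstance(mc, dict) else 100_000
        result = drake_mod.evaluate_monte_carlo(params, n_samples, seed)
        for k in ("mean", "median", "q025", "q975", "p_at_least_one"):
            report.record("drake", f"mc_{k}", getattr(result, k), upper_bound=True)
        report.record("drake", "mc_n_samples", n_samples)
        report.record("drake", "mc_seed", seed)


def _stage_copt(report: RunReport, block: Dict[str, Any], seed: Optional[int], ctx: Dict) -> None:
    foc, fpt = _civ_bounds(block, ctx)
    lifetime = float(block.get("lifetime", drake_mod.L_COPT_YEARS))
    params = drake_mod.copt_params(foc, fpt, lifetime)
    lo, hi = drake_mod.evaluate_interval(params)
    report.record("copt", "lifetime_years", lifetime)
    report.record("copt", "interval_low", lo, upper_bound=True)
    report.record("copt", "interval_high", hi, upper_bound=True)
    mc = block.get("monte_carlo")
    if mc:
        n_samples = int(mc.get("n_samples", 100_000)) if isinstance(mc, dict) else 100_000
        result = drake_mod.evaluate_monte_carlo(params, n_samples, seed)
        for k in ("mean", "median", "q025", "q975", "p_at_least_one"):
            report.record("copt", f"mc_{k}", getattr(result, k), upper_bound=True)
        report.record("copt", "mc_n_samples", n_samples)
        report.record("copt", "mc_seed", seed)


def _stage_tectonic(report: RunReport, block: Dict[str, Any]) -> None:
    params = tect_mod.MosaicGrowthParams(
        float(block.get("target_length", tect_mod.GLOBAL_TRENCH_LENGTH_KM)),
        float(block.get("rate_low", tect_mod.TRENCH_RATE_RANGE_KM_PER_MYR[0])),
        float(block.get("rate_high", tect_mod.TRENCH_RATE_RANGE_KM_PER_MYR[1])),
    )
    fast, slow = tect_mod.assembly_time_range(params)
    report.record("tectonic", "assembly_time_min_myr", fast, "int")
    report.record("tectonic", "assembly_time_max_myr", slow, "int")
    report.record(
        "tectonic",
        "c_isotope_transition_myr",
        tect_mod.bracket_duration(tect_mod.C_ISOTOPE_BRACKET),
        "int",
    )
    report.record(
        "tectonic",
        "glaciation_transition_myr",
        tect_mod.bracket_duration(tect_mod.GLACIATION_BRACKET),
        "int",
    )


def _stage_speciation(report: RunReport, block: Dict[str, Any], seed: int) -> None:
    params = spec_mod.BirthDeathParams(
        float(block.get("speciation_rate", 0.5)),
        float(block.get("extinction_rate", 0.0)),
        float(block.get("horizon", 1000.0)),
    )
    expected = spec_mod.expected_chain_length(params)
    report.record("speciation", "expected_chain_length", expected)
    n_reps = int(block.get("n_reps", 2000))
    q = spec_mod.chain_length_quantiles(params, n_reps, seed)
    report.record("speciation", "median", q.median)
    report.record("speciation", "q05", q.q05)
    report.record("speciation", "q95", q.q95)
    report.record("speciation", "mean", q.mean)
    report.record("speciation", "extinct_fraction", q.extinct_fraction)
    report.record("speciation", "n_reps", n_reps)
    report.record("speciation", "seed", seed)


def run_scenario(scenario: Scenario, out_dir=None) -> RunReport:
    """Execute a scenario's stages in dependency order.

    When ``out_dir`` is given, writes ``<name>.json`` and ``<name>.csv``
    there (and the generated population table, if any).  Identical scenario +
    seed give byte-identical outputs.
    """
    report = RunReport(scenario=scenario.name, version=__version__, seed=scenario.seed)
    ctx: Dict[str, Any] = {}
    for stage in _EXECUTION_ORDER:
        if stage not in scenario.stages:
            continue
        block = scenario.params.get(stage, {})
        logger.info("running stage %s of scenario %s", stage, scenario.name)
        if stage == "water":
            _stage_water(report, block)
        elif stage == "population":
            _stage_population(report, block, scenario.seed, ctx)
        elif stage == "foc":
            _stage_foc(report, block, ctx)
        elif stage == "fpt":
            _stage_fpt(report, block, ctx)
        elif stage == "drake":
            _stage_drake(report, block, scenario.seed, ctx)
        elif stage == "copt":
            _stage_copt(report, block, scenario.seed, ctx)
        elif stage == "tectonic":
            _stage_tectonic(report, block)
        elif stage == "speciation":
            _stage_speciation(report, block, scenario.seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"{scenario.name}.json")
        report.to_csv(out / f"{scenario.name}.csv")
        if "population" in ctx:
            pop_mod.write_population(ctx["population"], out / f"{scenario.name}_population.tsv")
    return report
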