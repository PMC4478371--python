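"""Scenario input schema: definition, validation, reading and writing.

A scenario file (YAML or JSON) carries an explicit ``schema_version`` tag,
the economic parameterization of each treatment strategy and the OS/PFS
survival curves per strategy.  Curves may be given inline (``months`` /
``survival`` arrays), as a reference to a two-column CSV file, or as an
exponential shorthand calibrated by median survival (used by the bundled
fixture, whose curves are illustrative stand-ins rather than trial data).

The full schema is documented in ``docs/scenario_schema.md``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

from ceamodel.survival_model import SurvivalCurve

SCHEMA_VERSION = 1

GRADE_BANDS = ("g12", "g34")
FAMILIES = ("beta", "gamma", "fixed")
AE_COST_BASES = ("alive", "stable_only")


class ScenarioValidationError(ValueError):
    """Schema violation, reported with the dotted path of the offending field."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


def _fail(path: str, message: str) -> None:
    raise ScenarioValidationError(path, message)


@dataclass(frozen=True)
class DistributionSpec:
    """A base-case value with its sensitivity range and sampling family.

    ``low <= base <= high`` always; beta specs live in [0, 1], gamma specs
    are nonnegative, and ``fixed`` marks a parameter excluded from
    probabilistic sampling (``low = base = high`` is permitted).
    """

    base: float
    low: float
    high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, path: str = "distribution") -> None:
        if self.family not in FAMILIES:
            _fail(f"{path}.family", f"unknown family {self.family!r}; expected one of {FAMILIES}")
        for name in ("base", "low", "high"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                _fail(f"{path}.{name}", f"must be a finite number, got {v!r}")
        if not (self.low <= self.base <= self.high):
            _fail(path, f"requires low <= base <= high, got ({self.low}, {self.base}, {self.high})")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            _fail(path, f"beta family requires range within [0, 1], got [{self.low}, {self.high}]")
        if self.family == "gamma" and self.low < 0.0:
            _fail(path, f"gamma family requires low >= 0, got {self.low}")

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.base == self.high

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls(base=value, low=value, high=value, family="fixed")


@dataclass(frozen=True)
class AdverseEventSpec:
    """One adverse-event row: per-cycle on-drug probability and monthly
    management cost, optionally with a dedicated AE-state utility weight."""

    name: str
    grade_band: str
    monthly_probability: DistributionSpec
    management_cost: DistributionSpec
    ae_state_utility: float | None = None

    def validate(self, path: str = "adverse_event") -> None:
        if not self.name:
            _fail(f"{path}.name", "must be non-empty")
        if self.grade_band not in GRADE_BANDS:
            _fail(f"{path}.grade_band", f"must be one of {GRADE_BANDS}, got {self.grade_band!r}")
        self.monthly_probability.validate(f"{path}.monthly_probability")
        self.management_cost.validate(f"{path}.management_cost")
        if not (0.0 <= self.monthly_probability.base <= 1.0):
            _fail(f"{path}.monthly_probability.base", "probability must lie in [0, 1]")
        if self.management_cost.base < 0:
            _fail(f"{path}.management_cost.base", "cost must be >= 0")
        if self.ae_state_utility is not None and not (0.0 <= self.ae_state_utility <= 1.0):
            _fail(f"{path}.ae_state_utility", "utility must lie in [0, 1]")


@dataclass(frozen=True)
class StrategySpec:
    """Full economic parameterization of one treatment arm."""

    name: str
    monthly_drug_cost: DistributionSpec
    utility_stable: DistributionSpec
    utility_progression: DistributionSpec
    adverse_events: tuple[AdverseEventSpec, ...] = ()
    #: USD added per unit of progression-state occupancy per cycle; models
    #: comparator-arm crossover onto the experimental drug (0 = none).
    crossover_monthly_cost: float = 0.0

    def validate(self, path: str = "strategy") -> None:
        if not self.name:
            _fail(f"{path}.name", "must be non-empty")
        self.monthly_drug_cost.validate(f"{path}.monthly_drug_cost")
        if self.monthly_drug_cost.base < 0:
            _fail(f"{path}.monthly_drug_cost.base", "cost must be >= 0")
        for util_name in ("utility_stable", "utility_progression"):
            spec = getattr(self, util_name)
            spec.validate(f"{path}.{util_name}")
            if not (0.0 <= spec.base <= 1.0):
                _fail(f"{path}.{util_name}.base", "utility must lie in [0, 1]")
        if self.crossover_monthly_cost < 0:
            _fail(f"{path}.crossover_monthly_cost", "cost must be >= 0")
        for i, ae in enumerate(self.adverse_events):
            ae.validate(f"{path}.adverse_events[{i}]")


@dataclass(frozen=True)
class Settings:
    """Model conventions that are fixed per scenario."""

    anchor_month: int = 8
    half_cycle: bool = False
    #: Which occupancy carries AE management costs: all alive states
    #: (literal reading of the costing rule) or the stable state only.
    ae_cost_basis: str = "alive"

    def validate(self, path: str = "settings") -> None:
        if self.anchor_month < 1:
            _fail(f"{path}.anchor_month", "must be >= 1")
        if self.ae_cost_basis not in AE_COST_BASES:
            _fail(f"{path}.ae_cost_basis", f"must be one of {AE_COST_BASES}")


@dataclass
class Scenario:
    """A complete runnable analysis: strategies, curves and conventions."""

    strategies: list[StrategySpec]
    survival: dict[str, dict[str, SurvivalCurve]]
    wtp_default: float = 100_000.0
    cycle_length_months: int = 1
    max_cycles: int = 600
    discount_rate_annual: float = 0.0
    settings: Settings = field(default_factory=Settings)

    def validate(self) -> None:
        if not self.strategies:
            _fail("strategies", "at least one strategy required")
        names = [s.name for s in self.strategies]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            _fail("strategies", f"duplicate strategy names: {sorted(dupes)}")
        for i, s in enumerate(self.strategies):
            s.validate(f"strategies[{i}]")
        if self.wtp_default <= 0:
            _fail("wtp_default", "must be > 0")
        if self.cycle_length_months < 1:
            _fail("cycle_length_months", "must be >= 1")
        if self.max_cycles < 1:
            _fail("max_cycles", "must be >= 1")
        if self.discount_rate_annual < 0:
            _fail("discount_rate_annual", "must be >= 0")
        self.settings.validate()
        for name in names:
            if name not in self.survival:
                _fail(f"survival.{name}", "missing survival curves for strategy")
            for endpoint in ("os", "pfs"):
                if endpoint not in self.survival[name]:
                    _fail(f"survival.{name}.{endpoint}", "missing curve")

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _require_mapping(node: Any, path: str) -> Mapping[str, Any]:
    if not isinstance(node, Mapping):
        _fail(path, f"expected a mapping, got {type(node).__name__}")
    return node


def _check_keys(node: Mapping[str, Any], allowed: Iterable[str], path: str) -> None:
    unknown = set(node) - set(allowed)
    if unknown:
        _fail(path, f"unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def _number(node: Mapping[str, Any], key: str, path: str, default: float | None = None) -> float:
    if key not in node:
        if default is not None:
            return default
        _fail(f"{path}.{key}", "required field missing")
    v = node[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        _fail(f"{path}.{key}", f"expected a number, got {v!r}")
    return float(v)


def _parse_distribution(node: Any, path: str) -> DistributionSpec:
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        return DistributionSpec.fixed(float(node))
    node = _require_mapping(node, path)
    _check_keys(node, ("base", "low", "high", "family"), path)
    base = _number(node, "base", path)
    try:
        return DistributionSpec(
            base=base,
            low=_number(node, "low", path, default=base),
            high=_number(node, "high", path, default=base),
            family=str(node.get("family", "fixed")),
        )
    except ScenarioValidationError as err:
        raise ScenarioValidationError(path, str(err)) from None


def _parse_adverse_event(node: Any, path: str) -> AdverseEventSpec:
    node = _require_mapping(node, path)
    _check_keys(
        node,
        ("name", "grade_band", "monthly_probability", "management_cost", "ae_state_utility"),
        path,
    )
    for key in ("name", "grade_band", "monthly_probability", "management_cost"):
        if key not in node:
            _fail(f"{path}.{key}", "required field missing")
    ae = AdverseEventSpec(
        name=str(node["name"]),
        grade_band=str(node["grade_band"]),
        monthly_probability=_parse_distribution(node["monthly_probability"], f"{path}.monthly_probability"),
        management_cost=_parse_distribution(node["management_cost"], f"{path}.management_cost"),
        ae_state_utility=(
            None if node.get("ae_state_utility") is None else float(node["ae_state_utility"])
        ),
    )
    ae.validate(path)
    return ae


def _parse_strategy(node: Any, path: str) -> StrategySpec:
    node = _require_mapping(node, path)
    _check_keys(
        node,
        (
            "name",
            "monthly_drug_cost",
            "utility_stable",
            "utility_progression",
            "adverse_events",
            "crossover_monthly_cost",
        ),
        path,
    )
    for key in ("name", "monthly_drug_cost", "utility_stable", "utility_progression"):
        if key not in node:
            _fail(f"{path}.{key}", "required field missing")
    aes = node.get("adverse_events", []) or []
    if not isinstance(aes, Sequence) or isinstance(aes, str):
        _fail(f"{path}.adverse_events", "expected a list")
    strategy = StrategySpec(
        name=str(node["name"]),
        monthly_drug_cost=_parse_distribution(node["monthly_drug_cost"], f"{path}.monthly_drug_cost"),
        utility_stable=_parse_distribution(node["utility_stable"], f"{path}.utility_stable"),
        utility_progression=_parse_distribution(
            node["utility_progression"], f"{path}.utility_progression"
        ),
        adverse_events=tuple(
            _parse_adverse_event(ae, f"{path}.adverse_events[{i}]") for i, ae in enumerate(aes)
        ),
        crossover_monthly_cost=_number(node, "crossover_monthly_cost", path, default=0.0),
    )
    strategy.validate(path)
    return strategy


def read_curve_csv(path: Path, anchor_month: int = 8, label: str = "") -> SurvivalCurve:
    """Read a curve from a CSV with columns ``month,survival``."""
    if not path.exists():
        raise FileNotFoundError(f"survival curve file not found: {path}")
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["month", "survival"]:
        raise ScenarioValidationError(str(path), "curve CSV must have columns month,survival")
    return SurvivalCurve(
        months=df.iloc[:, 0].to_numpy(dtype=int),
        survival=df.iloc[:, 1].to_numpy(dtype=float),
        anchor_month=anchor_month,
        label=label or path.stem,
    )


def write_curve_csv(curve: SurvivalCurve, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("month,survival\n")
        for m, s in zip(curve.months, curve.survival):
            fh.write(f"{int(m)},{float(s)!r}\n")


def _parse_curve(node: Any, path: str, base_dir: Path, default_anchor: int) -> SurvivalCurve:
    node = _require_mapping(node, path)
    if "months" in node:
        _check_keys(node, ("months", "survival", "anchor_month"), path)
        if "survival" not in node:
            _fail(f"{path}.survival", "required alongside 'months'")
        try:
            return SurvivalCurve(
                months=np.asarray(node["months"]),
                survival=np.asarray(node["survival"], dtype=float),
                anchor_month=int(node.get("anchor_month", default_anchor)),
                label=path,
            )
        except ValueError as err:
            raise ScenarioValidationError(path, str(err)) from None
    if "csv" in node:
        _check_keys(node, ("csv", "anchor_month"), path)
        return read_curve_csv(
            base_dir / str(node["csv"]),
            anchor_month=int(node.get("anchor_month", default_anchor)),
            label=path,
        )
    if "exponential" in node:
        _check_keys(node, ("exponential",), path)
        exp = _require_mapping(node["exponential"], f"{path}.exponential")
        _check_keys(exp, ("median_months", "follow_up_months"), f"{path}.exponential")
        return SurvivalCurve.from_exponential_median(
            median_months=_number(exp, "median_months", f"{path}.exponential"),
            follow_up_months=int(exp.get("follow_up_months", default_anchor)),
            label=path,
        )
    _fail(path, f"curve must use one of the forms months/csv/exponential, got keys {sorted(node)}")
    raise AssertionError  # unreachable


TOP_LEVEL_KEYS = (
    "schema_version",
    "strategies",
    "survival",
    "wtp_default",
    "cycle_length_months",
    "max_cycles",
    "discount_rate_annual",
    "settings",
)


def parse_scenario(doc: Mapping[str, Any], base_dir: Path | None = None) -> Scenario:
    """Build and validate a :class:`Scenario` from a parsed document."""
    base_dir = base_dir or Path.cwd()
    doc = _require_mapping(doc, "")
    _check_keys(doc, TOP_LEVEL_KEYS, "scenario")
    if "schema_version" not in doc:
        _fail("schema_version", "required field missing")
    if doc["schema_version"] != SCHEMA_VERSION:
        _fail("schema_version", f"unsupported version {doc['schema_version']!r}; expected {SCHEMA_VERSION}")

    settings_node = _require_mapping(doc.get("settings", {}) or {}, "settings")
    _check_keys(settings_node, ("anchor_month", "half_cycle", "ae_cost_basis"), "settings")
    settings = Settings(
        anchor_month=int(settings_node.get("anchor_month", 8)),
        half_cycle=bool(settings_node.get("half_cycle", False)),
        ae_cost_basis=str(settings_node.get("ae_cost_basis", "alive")),
    )

    strategies_node = doc.get("strategies")
    if not isinstance(strategies_node, Sequence) or isinstance(strategies_node, str):
        _fail("strategies", "expected a list of strategies")
    strategies = [
        _parse_strategy(s, f"strategies[{i}]") for i, s in enumerate(strategies_node)
    ]

    survival_node = _require_mapping(doc.get("survival", {}), "survival")
    survival: dict[str, dict[str, SurvivalCurve]] = {}
    for strat_name, endpoints in survival_node.items():
        endpoints = _require_mapping(endpoints, f"survival.{strat_name}")
        _check_keys(endpoints, ("os", "pfs"), f"survival.{strat_name}")
        survival[str(strat_name)] = {
            ep: _parse_curve(
                endpoints[ep], f"survival.{strat_name}.{ep}", base_dir, settings.anchor_month
            )
            for ep in ("os", "pfs")
            if ep in endpoints
        }

    scenario = Scenario(
        strategies=strategies,
        survival=survival,
        wtp_default=_number(doc, "wtp_default", "scenario", default=100_000.0),
        cycle_length_months=int(doc.get("cycle_length_months", 1)),
        max_cycles=int(doc.get("max_cycles", 600)),
        discount_rate_annual=_number(doc, "discount_rate_annual", "scenario", default=0.0),
        settings=settings,
    )
    scenario.validate()
    return scenario


def load_scenario(path: str | Path) -> Scenario:
    """Load and fully validate a scenario from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scenario file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return parse_scenario(doc, base_dir=path.parent)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _dump_distribution(spec: DistributionSpec) -> dict[str, Any]:
    return {"base": spec.base, "low": spec.low, "high": spec.high, "family": spec.family}


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Plain-dict form of a scenario (curves dumped inline)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "wtp_default": scenario.wtp_default,
        "cycle_length_months": scenario.cycle_length_months,
        "max_cycles": scenario.max_cycles,
        "discount_rate_annual": scenario.discount_rate_annual,
        "settings": {
            "anchor_month": scenario.settings.anchor_month,
            "half_cycle": scenario.settings.half_cycle,
            "ae_cost_basis": scenario.settings.ae_cost_basis,
        },
        "strategies": [
            {
                "name": s.name,
                "monthly_drug_cost": _dump_distribution(s.monthly_drug_cost),
                "utility_stable": _dump_distribution(s.utility_stable),
                "utility_progression": _dump_distribution(s.utility_progression),
                "crossover_monthly_cost": s.crossover_monthly_cost,
                "adverse_events": [
                    {
                        "name": ae.name,
                        "grade_band": ae.grade_band,
                        "monthly_probability": _dump_distribution(ae.monthly_probability),
                        "management_cost": _dump_distribution(ae.management_cost),
                        "ae_state_utility": ae.ae_state_utility,
                    }
                    for ae in s.adverse_events
                ],
            }
            for s in scenario.strategies
        ],
        "survival": {
            name: {
                ep: {
                    "months": [int(m) for m in curve.months],
                    "survival": [float(v) for v in curve.survival],
                    "anchor_month": curve.anchor_month,
                }
                for ep, curve in endpoints.items()
            }
            for name, endpoints in scenario.survival.items()
        },
    }


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario back to YAML (or JSON by extension); round-trips
    numerically exactly through :func:`load_scenario`."""
    path = Path(path)
    doc = scenario_to_dict(scenario)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# results CSV
# ---------------------------------------------------------------------------

FRONTIER_COLUMNS = ("name", "total_cost", "total_qaly", "inc_cost", "inc_qaly", "icer", "status")
RESULT_COLUMNS = ("name", "total_cost", "total_qaly")


def _fmt_cost(v: float | None) -> str:
    return "" if v is None else f"{v:.2f}"


def _fmt_qaly(v: float | None) -> str:
    return "" if v is None else f"{v:.4f}"


def write_results(result: Any, path: str | Path) -> None:
    """Write a result object to CSV with a documented, deterministic layout.

    Accepted inputs (dispatched structurally to avoid import cycles):

    * a single ``CEAResult`` or a list of them → ``name,total_cost,total_qaly``
      rows sorted by total cost ascending;
    * a frontier table (list of ``FrontierEntry``) → the seven-column layout
      ``name,total_cost,total_qaly,inc_cost,inc_qaly,icer,status`` sorted by
      total cost ascending;
    * a ``CEACCurve`` → ``wtp`` column plus one proportion column per strategy.

    Costs are written with 2 decimals, QALYs and proportions with 4.
    """
    path = Path(path)
    rows: list[str] = []
    if hasattr(result, "wtp_grid"):  # CEACCurve
        names = list(result.strategy_names)
        rows.append(",".join(["wtp"] + names))
        for i, wtp in enumerate(result.wtp_grid):
            rows.append(
                ",".join([_fmt_cost(float(wtp))] + [
                    f"{float(result.proportions[name][i]):.4f}" for name in names
                ])
            )
    else:
        items = [result] if not isinstance(result, (list, tuple)) else list(result)
        if items and hasattr(items[0], "status"):  # frontier entries
            rows.append(",".join(FRONTIER_COLUMNS))
            for e in sorted(items, key=lambda e: (e.total_cost, e.name)):
                icer_txt = "" if e.icer is None else f"{e.icer:.2f}"
                rows.append(
                    ",".join(
                        [
                            e.name,
                            _fmt_cost(e.total_cost),
                            _fmt_qaly(e.total_qaly),
                            _fmt_cost(e.inc_cost),
                            _fmt_qaly(e.inc_qaly),
                            icer_txt,
                            e.status,
                        ]
                    )
                )
        else:
            rows.append(",".join(RESULT_COLUMNS))
            for r in sorted(items, key=lambda r: (r.total_cost, r.strategy)):
                rows.append(f"{r.strategy},{_fmt_cost(r.total_cost)},{_fmt_qaly(r.total_qaly)}")
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(rows) + "\n")
    except OSError as err:
        raise OSError(f"cannot write results to {path}: {err}") from err


def bundled_scenario_path() -> Path:
    """Path to the packaged base-case scenario fixture."""
    return Path(resources.files("ceamodel").joinpath("data/table1_melanoma.yaml"))
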