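"""Deterministic and probabilistic sensitivity analysis.

Distribution fitting
    Base / low / high triples are fitted by method of moments with the
    range read as a 95% interval: ``sd = (high - low) / (2 * 1.96)``.
    Probabilities use beta, costs gamma, ``fixed`` a point mass.  A beta
    whose printed range is the uninformative full [0, 1] interval (or whose
    implied variance is infeasible) falls back to an effective-sample-size
    parameterization ``alpha = base * ess, beta = (1 - base) * ess``
    centred on the base value (default ``ess = 20``, configurable).

Seeding
    One master seed; each parameter derives an independent substream from
    the SHA-256 of its parameter path, so results do not depend on the
    order in which parameters are declared.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ceamodel.cohort_engine import Exposure, run_scenario, scenario_exposures
from ceamodel.inputs_io import DistributionSpec, Scenario, ScenarioValidationError

logger = logging.getLogger(__name__)

Z_95 = 1.96
DEFAULT_ESS = 20.0
DEFAULT_WTP_GRID = np.arange(0.0, 300_000.0 + 1, 5_000.0)


@dataclass(frozen=True)
class FittedDistribution:
    """A sampleable distribution matched to a base/low/high spec.

    ``a``/``b`` are (alpha, beta) for the beta family, (shape, scale) for
    gamma, and (value, 0) for a point mass.  The fitted mean always equals
    ``source.base``.
    """

    family: str  # "beta" | "gamma" | "point"
    a: float
    b: float
    source: DistributionSpec

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return self.a

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(shape=self.a, scale=self.b, size=size)
        return np.full(size, self.a)

    @property
    def is_degenerate(self) -> bool:
        return self.family == "point"


def fit_distribution(spec: DistributionSpec, ess: float = DEFAULT_ESS) -> FittedDistribution:
    """Fit a sampleable distribution to a base/low/high spec (see module doc)."""
    base = spec.base
    if spec.family == "fixed" or spec.is_degenerate:
        return FittedDistribution("point", base, 0.0, spec)
    sd = (spec.high - spec.low) / (2.0 * Z_95)
    if spec.family == "gamma":
        if base <= 0 or sd <= 0:
            return FittedDistribution("point", base, 0.0, spec)
        var = sd * sd
        return FittedDistribution("gamma", base * base / var, var / base, spec)
    # beta
    if base <= 0.0 or base >= 1.0:
        return FittedDistribution("point", base, 0.0, spec)
    uninformative = spec.low <= 0.0 and spec.high >= 1.0
    var = sd * sd
    if not uninformative and var < base * (1.0 - base):
        nu = base * (1.0 - base) / var - 1.0
        return FittedDistribution("beta", base * nu, (1.0 - base) * nu, spec)
    if not uninformative:
        logger.warning(
            "beta range (%g, %g, %g) implies infeasible variance; "
            "falling back to effective sample size %g",
            spec.low,
            spec.base,
            spec.high,
            ess,
        )
    return FittedDistribution("beta", base * ess, (1.0 - base) * ess, spec)


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------


def parameter_paths(scenario: Scenario) -> dict[str, DistributionSpec]:
    """All sampleable parameters, keyed by dotted path.

    Paths: ``<strategy>.monthly_drug_cost``, ``<strategy>.utility_stable``,
    ``<strategy>.utility_progression`` and per adverse event
    ``<strategy>.adverse_events.<name>.<grade>.monthly_probability`` /
    ``.management_cost``.
    """
    out: dict[str, DistributionSpec] = {}
    for s in scenario.strategies:
        out[f"{s.name}.monthly_drug_cost"] = s.monthly_drug_cost
        out[f"{s.name}.utility_stable"] = s.utility_stable
        out[f"{s.name}.utility_progression"] = s.utility_progression
        for ae in s.adverse_events:
            stem = f"{s.name}.adverse_events.{ae.name}.{ae.grade_band}"
            out[f"{stem}.monthly_probability"] = ae.monthly_probability
            out[f"{stem}.management_cost"] = ae.management_cost
    return out


def _scalar_paths(scenario: Scenario) -> set[str]:
    paths = set(parameter_paths(scenario))
    paths.update(f"{s.name}.crossover_monthly_cost" for s in scenario.strategies)
    return paths


def parameter_rng(master_seed: int, path: str) -> np.random.Generator:
    """Independent, order-robust random stream for one parameter."""
    digest = hashlib.sha256(path.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed)] + words))


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DSAResult:
    """Grid sweep of one parameter with per-strategy totals and the ICER of
    the parameter's strategy versus the comparator."""

    parameter: str
    strategy: str
    comparator: str
    wtp: float
    table: pd.DataFrame
    #: Parameter value at which the ICER crosses ``wtp`` (linear
    #: interpolation between grid points; exact for affine relations), or
    #: ``None`` if the sweep never crosses.
    crossing: float | None


def one_way_dsa(
    scenario: Scenario,
    parameter: str,
    grid: Sequence[float],
    comparator: str | None = None,
    wtp: float | None = None,
) -> DSAResult:
    """Re-run the model across a grid of values for one scalar parameter.

    The parameter's owning strategy (first path component) is compared
    against ``comparator`` (default: the cheapest other strategy at base
    case).  All other inputs stay at base values.
    """
    if parameter not in _scalar_paths(scenario):
        raise ScenarioValidationError(parameter, "unknown parameter path")
    if len(grid) < 1:
        raise ValueError("grid must contain at least one value")
    strategy = parameter.split(".", 1)[0]
    if wtp is None:
        wtp = scenario.wtp_default
    if comparator is None:
        base = {r.strategy: r for r in run_scenario(scenario, keep_trace=False)}
        others = [n for n in scenario.strategy_names if n != strategy]
        comparator = min(others, key=lambda n: base[n].total_cost)

    records = []
    icers = []
    for value in grid:
        results = run_scenario(scenario, overrides={parameter: float(value)}, keep_trace=False)
        by_name = {r.strategy: r for r in results}
        s, c = by_name[strategy], by_name[comparator]
        d_qaly = s.total_qaly - c.total_qaly
        icer_v = (s.total_cost - c.total_cost) / d_qaly if d_qaly != 0 else np.nan
        icers.append(icer_v)
        rec: dict[str, float] = {"value": float(value)}
        for r in results:
            rec[f"{r.strategy}_cost"] = r.total_cost
            rec[f"{r.strategy}_qaly"] = r.total_qaly
        rec["icer"] = icer_v
        records.append(rec)

    crossing = None
    icers_arr = np.asarray(icers, dtype=float)
    grid_arr = np.asarray(grid, dtype=float)
    diff = icers_arr - wtp
    for k in range(len(grid_arr) - 1):
        d0, d1 = diff[k], diff[k + 1]
        if np.isnan(d0) or np.isnan(d1):
            continue
        if d0 == 0.0:
            crossing = float(grid_arr[k])
            break
        if d0 * d1 < 0:
            crossing = float(grid_arr[k] - d0 * (grid_arr[k + 1] - grid_arr[k]) / (d1 - d0))
            break
    else:
        if len(grid_arr) and diff[-1] == 0.0:
            crossing = float(grid_arr[-1])

    return DSAResult(
        parameter=parameter,
        strategy=strategy,
        comparator=comparator,
        wtp=float(wtp),
        table=pd.DataFrame.from_records(records),
        crossing=crossing,
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSASample:
    """One Monte-Carlo iteration: drawn parameters and resulting totals."""

    iteration: int
    draws: dict[str, float]
    totals: dict[str, tuple[float, float]]  # name -> (cost, qaly)


@dataclass
class CEACCurve:
    """Cost-effectiveness acceptability curve on a WTP grid."""

    wtp_grid: np.ndarray
    proportions: dict[str, np.ndarray]

    @property
    def strategy_names(self) -> list[str]:
        return list(self.proportions)

    def at(self, wtp: float) -> dict[str, float]:
        """Proportions at the nearest grid point (see :func:`ceac_report`)."""
        return ceac_report(self, wtp)


def draw_parameters(
    scenario: Scenario,
    n_iterations: int,
    seed: int,
    ess: float = DEFAULT_ESS,
) -> dict[str, np.ndarray]:
    """Draw every non-fixed parameter; ``n_iterations`` values per path."""
    draws: dict[str, np.ndarray] = {}
    for path, spec in sorted(parameter_paths(scenario).items()):
        fitted = fit_distribution(spec, ess=ess)
        draws[path] = fitted.draw(parameter_rng(seed, path), n_iterations)
    return draws


def _psa_totals(
    scenario: Scenario,
    draws: Mapping[str, np.ndarray],
    exposures: Mapping[str, Exposure],
    n: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorized per-strategy (cost, qaly) arrays across iterations."""
    totals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in scenario.strategies:
        drug = draws[f"{s.name}.monthly_drug_cost"]
        u_s = draws[f"{s.name}.utility_stable"]
        u_p = draws[f"{s.name}.utility_progression"]
        ae_cost = np.zeros(n)
        for ae in s.adverse_events:
            stem = f"{s.name}.adverse_events.{ae.name}.{ae.grade_band}"
            ae_cost += draws[f"{stem}.monthly_probability"] * draws[f"{stem}.management_cost"]
        exp = exposures[s.name]
        cost = drug * exp.alive + ae_cost * exp.ae_basis + s.crossover_monthly_cost * exp.progressed
        qaly = (u_s * exp.stable + u_p * exp.progressed) * exp.cycle_length_months / 12.0
        totals[s.name] = (cost, qaly)
    return totals


def run_psa(
    scenario: Scenario,
    n_iterations: int,
    seed: int,
    wtp_grid: Sequence[float] | None = None,
    ess: float = DEFAULT_ESS,
    keep_samples: bool = True,
) -> tuple[list[PSASample], CEACCurve]:
    """Monte-Carlo PSA: independent parameter draws, cohort totals per
    strategy per iteration, and the acceptability curve by arg-max net
    monetary benefit at each WTP grid point.

    Fully reproducible given ``(seed, n_iterations, scenario)``; parameter
    declaration order does not matter.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size < 1:
        raise ValueError("wtp_grid must be non-empty")

    exposures = scenario_exposures(scenario)
    draws = draw_parameters(scenario, n_iterations, seed, ess=ess)
    totals = _psa_totals(scenario, draws, exposures, n_iterations)

    # Column order sorted by base-case cost so that np.argmax resolves NMB
    # ties toward the cheaper strategy.
    base = {r.strategy: r for r in run_scenario(scenario, keep_trace=False)}
    names = sorted(scenario.strategy_names, key=lambda n: (base[n].total_cost, scenario.strategy_names.index(n)))
    cost_mat = np.column_stack([totals[n][0] for n in names])
    qaly_mat = np.column_stack([totals[n][1] for n in names])

    proportions = {name: np.zeros(grid.size) for name in scenario.strategy_names}
    for gi, wtp in enumerate(grid):
        winners = np.argmax(wtp * qaly_mat - cost_mat, axis=1)
        counts = np.bincount(winners, minlength=len(names))
        for ci, name in enumerate(names):
            proportions[name][gi] = counts[ci] / n_iterations
    curve = CEACCurve(wtp_grid=grid, proportions={n: proportions[n] for n in scenario.strategy_names})

    samples: list[PSASample] = []
    if keep_samples:
        paths = list(draws)
        for i in range(n_iterations):
            samples.append(
                PSASample(
                    iteration=i,
                    draws={p: float(draws[p][i]) for p in paths},
                    totals={
                        name: (float(totals[name][0][i]), float(totals[name][1][i]))
                        for name in scenario.strategy_names
                    },
                )
            )
    return samples, curve


def ceac_report(curve: CEACCurve, wtp: float) -> dict[str, float]:
    """Per-strategy proportions at the grid point nearest to ``wtp``."""
    grid = curve.wtp_grid
    if wtp < grid.min() or wtp > grid.max():
        raise ValueError(f"wtp {wtp} outside CEAC grid range [{grid.min()}, {grid.max()}]")
    idx = int(np.argmin(np.abs(grid - wtp)))
    return {name: float(p[idx]) for name, p in curve.proportions.items()}
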