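"""Cost and QALY accumulation over a cohort occupancy trace.

Accounting conventions (documented so independent oracles can match):

* costs and QALYs accrue for cycles ``t = 0 .. T-1`` using start-of-cycle
  occupancy (optionally trapezoidal across the cycle with ``half_cycle``);
* drug cost accrues on all alive occupancy; adverse-event management cost
  accrues on alive occupancy by default (``stable_only`` basis available);
* the crossover cost accrues on progressed occupancy only;
* QALY increment per cycle is utility-weighted occupancy times
  ``cycle_length_months / 12``;
* discounting, off by default, applies ``(1 + r)^(-t * cycle_length / 12)``.

Totals are affine in every unit cost and utility, which the sensitivity
layer exploits via :class:`Exposure`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ceamodel.inputs_io import Scenario, Settings, StrategySpec, ScenarioValidationError
from ceamodel.survival_model import (
    DEAD_ABSORPTION_TOL,
    OccupancyRow,
    extrapolate,
    occupancy_from_survival,
)


@dataclass
class CohortTrace:
    """Per-cycle occupancy with cost/QALY increments and running totals."""

    rows: list[OccupancyRow]
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray

    @property
    def cumulative_cost(self) -> np.ndarray:
        return np.cumsum(self.cycle_cost)

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.cumsum(self.cycle_qaly)


@dataclass
class CEAResult:
    """Lifetime totals for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    trace: CohortTrace | None = None


@dataclass(frozen=True)
class Exposure:
    """Discounted occupancy-time sums (in cycles) over the accrual window.

    Totals decompose as::

        cost = drug_cost * alive + ae_cost * ae_basis + crossover * progressed
        qaly = (u_stable * stable + u_prog * progressed) * cycle_length / 12
    """

    alive: float
    stable: float
    progressed: float
    ae_basis: float
    cycle_length_months: int


def expected_ae_cost_per_cycle(
    strategy: StrategySpec,
    overrides: Mapping[str, float] | None = None,
) -> float:
    """Probability-weighted adverse-event management cost per on-drug cycle.

    ``overrides`` may replace individual probabilities/costs by parameter
    path (as produced by :func:`ceamodel.sensitivity.parameter_paths`).
    """
    overrides = overrides or {}
    total = 0.0
    for ae in strategy.adverse_events:
        stem = f"{strategy.name}.adverse_events.{ae.name}.{ae.grade_band}"
        p = overrides.get(f"{stem}.monthly_probability", ae.monthly_probability.base)
        c = overrides.get(f"{stem}.management_cost", ae.management_cost.base)
        total += p * c
    if total < 0:
        raise ValueError("expected AE cost must be >= 0")
    return total


def composite_state_utility(
    base_utility: float,
    ae_probs: Sequence[float],
    ae_state_utilities: Sequence[float],
) -> float:
    """Expected utility of a health state as a mixture over AE sub-states.

    ``(1 - sum(p_i)) * u_base + sum(p_i * u_i)``; the published composite
    utilities were built this way upstream, so the base case uses them
    directly and this helper serves custom AE-state utilities.
    """
    if len(ae_probs) != len(ae_state_utilities):
        raise ValueError("ae_probs and ae_state_utilities must have equal length")
    p_total = float(sum(ae_probs))
    if p_total > 1.0 + 1e-12:
        raise ScenarioValidationError(
            "ae_probs", f"AE state probabilities sum to {p_total:.6g} > 1"
        )
    if any(p < 0 for p in ae_probs):
        raise ScenarioValidationError("ae_probs", "probabilities must be >= 0")
    u = (1.0 - p_total) * base_utility + sum(
        p * ui for p, ui in zip(ae_probs, ae_state_utilities)
    )
    return min(max(u, 0.0), 1.0)


def _occupancy_arrays(occupancy: Sequence[OccupancyRow]) -> tuple[np.ndarray, np.ndarray]:
    stable = np.array([r.stable for r in occupancy])
    progressed = np.array([r.progressed for r in occupancy])
    return stable, progressed


def compute_exposure(
    occupancy: Sequence[OccupancyRow],
    *,
    cycle_length_months: int = 1,
    discount_rate_annual: float = 0.0,
    half_cycle: bool = False,
    ae_cost_basis: str = "alive",
) -> Exposure:
    """Reduce an occupancy trace to the discounted exposure sums."""
    stable, progressed = _occupancy_arrays(occupancy)
    n_cycles = len(occupancy) - 1 if len(occupancy) > 1 else 1
    if half_cycle and len(occupancy) > 1:
        stable_acc = (stable[:-1] + stable[1:]) / 2.0
        prog_acc = (progressed[:-1] + progressed[1:]) / 2.0
    else:
        stable_acc = stable[:n_cycles]
        prog_acc = progressed[:n_cycles]
    t = np.arange(len(stable_acc))
    disc = (1.0 + discount_rate_annual) ** (-(t * cycle_length_months) / 12.0)
    alive_acc = stable_acc + prog_acc
    e_alive = float(np.sum(disc * alive_acc))
    e_stable = float(np.sum(disc * stable_acc))
    e_prog = float(np.sum(disc * prog_acc))
    e_basis = e_stable if ae_cost_basis == "stable_only" else e_alive
    return Exposure(
        alive=e_alive,
        stable=e_stable,
        progressed=e_prog,
        ae_basis=e_basis,
        cycle_length_months=cycle_length_months,
    )


def totals_from_exposure(
    exposure: Exposure,
    *,
    drug_cost: float,
    ae_cost: float,
    crossover_cost: float,
    u_stable: float,
    u_progression: float,
) -> tuple[float, float]:
    """(total cost, total QALY) from an exposure and unit values."""
    cost = (
        drug_cost * exposure.alive
        + ae_cost * exposure.ae_basis
        + crossover_cost * exposure.progressed
    )
    qaly = (
        (u_stable * exposure.stable + u_progression * exposure.progressed)
        * exposure.cycle_length_months
        / 12.0
    )
    return cost, qaly


def run_cohort(
    strategy: StrategySpec,
    occupancy: Sequence[OccupancyRow],
    *,
    cycle_length_months: int = 1,
    discount_rate_annual: float = 0.0,
    half_cycle: bool = False,
    ae_cost_basis: str = "alive",
    overrides: Mapping[str, float] | None = None,
    keep_trace: bool = True,
) -> CEAResult:
    """Accumulate lifetime cost and QALYs for one strategy over a trace.

    ``overrides`` maps parameter paths (see the sensitivity module) to
    replacement values, used by DSA and PSA without mutating the spec.
    """
    if len(occupancy) < 1:
        raise ValueError("occupancy trace is empty")
    overrides = overrides or {}
    drug_cost = overrides.get(f"{strategy.name}.monthly_drug_cost", strategy.monthly_drug_cost.base)
    u_stable = overrides.get(f"{strategy.name}.utility_stable", strategy.utility_stable.base)
    u_prog = overrides.get(
        f"{strategy.name}.utility_progression", strategy.utility_progression.base
    )
    crossover = overrides.get(
        f"{strategy.name}.crossover_monthly_cost", strategy.crossover_monthly_cost
    )
    ae_cost = expected_ae_cost_per_cycle(strategy, overrides)

    stable, progressed = _occupancy_arrays(occupancy)
    n_cycles = len(occupancy) - 1 if len(occupancy) > 1 else 1
    if half_cycle and len(occupancy) > 1:
        stable_acc = (stable[:-1] + stable[1:]) / 2.0
        prog_acc = (progressed[:-1] + progressed[1:]) / 2.0
    else:
        stable_acc = stable[:n_cycles]
        prog_acc = progressed[:n_cycles]
    t = np.arange(len(stable_acc))
    disc = (1.0 + discount_rate_annual) ** (-(t * cycle_length_months) / 12.0)
    alive_acc = stable_acc + prog_acc
    basis_acc = stable_acc if ae_cost_basis == "stable_only" else alive_acc

    cycle_cost = disc * (drug_cost * alive_acc + ae_cost * basis_acc + crossover * prog_acc)
    cycle_qaly = disc * (u_stable * stable_acc + u_prog * prog_acc) * cycle_length_months / 12.0

    # Totals go through the same exposure decomposition the PSA fast path
    # uses, so a degenerate (all-fixed) PSA reproduces them bitwise.
    exposure = Exposure(
        alive=float(np.sum(disc * alive_acc)),
        stable=float(np.sum(disc * stable_acc)),
        progressed=float(np.sum(disc * prog_acc)),
        ae_basis=float(np.sum(disc * basis_acc)),
        cycle_length_months=cycle_length_months,
    )
    total_cost, total_qaly = totals_from_exposure(
        exposure,
        drug_cost=drug_cost,
        ae_cost=ae_cost,
        crossover_cost=crossover,
        u_stable=u_stable,
        u_progression=u_prog,
    )
    trace = (
        CohortTrace(rows=list(occupancy), cycle_cost=cycle_cost, cycle_qaly=cycle_qaly)
        if keep_trace
        else None
    )
    return CEAResult(
        strategy=strategy.name,
        total_cost=total_cost,
        total_qaly=total_qaly,
        trace=trace,
    )


def strategy_occupancy(scenario: Scenario, name: str) -> list[OccupancyRow]:
    """Extrapolated occupancy trace for one strategy of a scenario.

    The horizon is ``max_cycles``, shortened to the cycle at which the
    cohort is (numerically) fully absorbed into the dead state.
    """
    curves = scenario.survival[name]
    anchor = scenario.settings.anchor_month
    os_x = extrapolate(curves["os"], scenario.max_cycles, anchor_month=anchor)
    pfs_x = extrapolate(curves["pfs"], scenario.max_cycles, anchor_month=anchor)
    rows = occupancy_from_survival(os_x, pfs_x, scenario.max_cycles)
    for t, row in enumerate(rows):
        if row.dead >= 1.0 - DEAD_ABSORPTION_TOL:
            return rows[: t + 1]
    return rows


def run_scenario(
    scenario: Scenario,
    overrides: Mapping[str, float] | None = None,
    keep_trace: bool = True,
) -> list[CEAResult]:
    """Run every strategy of a scenario; results in declaration order."""
    results = []
    for strat in scenario.strategies:
        occupancy = strategy_occupancy(scenario, strat.name)
        results.append(
            run_cohort(
                strat,
                occupancy,
                cycle_length_months=scenario.cycle_length_months,
                discount_rate_annual=scenario.discount_rate_annual,
                half_cycle=scenario.settings.half_cycle,
                ae_cost_basis=scenario.settings.ae_cost_basis,
                overrides=overrides,
                keep_trace=keep_trace,
            )
        )
    return results


def scenario_exposures(scenario: Scenario) -> dict[str, Exposure]:
    """Per-strategy exposure sums; the fast path for PSA and pricing."""
    return {
        strat.name: compute_exposure(
            strategy_occupancy(scenario, strat.name),
            cycle_length_months=scenario.cycle_length_months,
            discount_rate_annual=scenario.discount_rate_annual,
            half_cycle=scenario.settings.half_cycle,
            ae_cost_basis=scenario.settings.ae_cost_basis,
        )
        for strat in scenario.strategies
    }
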