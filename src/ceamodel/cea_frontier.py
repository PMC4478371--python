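"""Efficiency frontier: dominance, ICERs, net monetary benefit, thresholds.

Strategies are compared from least to most expensive.  A strategy is
strictly dominated if another costs no more and yields no fewer QALYs
(at least one strictly); extended dominance then removes strategies
iteratively until frontier ICERs are strictly increasing.  Net monetary
benefit is the standard ``wtp * qaly - cost`` form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from ceamodel.cohort_engine import (
    CEAResult,
    compute_exposure,
    run_cohort,
    run_scenario,
    strategy_occupancy,
)
from ceamodel.inputs_io import Scenario

STATUS_FRONTIER = "frontier"
STATUS_DOMINATED = "dominated"
STATUS_EXTENDED = "extended_dominated"


class UndefinedICERError(ValueError):
    """Equal effectiveness: the ICER is undefined; report dominance by cost."""


class UndefinedThresholdError(ValueError):
    """No drug exposure: total cost does not depend on the monthly price."""


@dataclass
class FrontierEntry:
    name: str
    total_cost: float
    total_qaly: float
    status: str
    comparator: str | None = None
    inc_cost: float | None = None
    inc_qaly: float | None = None
    icer: float | None = None

    @property
    def icer_rounded(self) -> int | None:
        """ICER to the nearest dollar (presentation form)."""
        return None if self.icer is None else int(round_half_away(self.icer, 0))


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (table-presentation rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost-effectiveness ratio of a versus b, USD per QALY."""
    if qaly_a == qaly_b:
        raise UndefinedICERError(
            "equal QALYs: ICER undefined; compare by cost (dominance)"
        )
    return (cost_a - cost_b) / (qaly_a - qaly_b)


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


def required_incremental_qaly(inc_cost: float, wtp: float) -> float:
    """Incremental effectiveness needed for an ICER to equal the threshold."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return inc_cost / wtp


def break_even_total_cost(comparator_cost: float, inc_qaly: float, wtp: float) -> float:
    """Total lifetime cost at which the ICER versus the comparator equals wtp."""
    if inc_qaly <= 0:
        raise ValueError("inc_qaly must be > 0")
    return comparator_cost + wtp * inc_qaly


def _strictly_dominates(a: CEAResult, b: CEAResult) -> bool:
    return (
        a.total_cost <= b.total_cost
        and a.total_qaly >= b.total_qaly
        and (a.total_cost < b.total_cost or a.total_qaly > b.total_qaly)
    )


def build_frontier(results: Sequence[CEAResult]) -> list[FrontierEntry]:
    """Classify strategies and compute frontier ICERs.

    Returns one entry per input strategy, ordered by total cost ascending
    (ties by input order).  Exact (cost, QALY) ties are resolved
    deterministically: the later-listed strategy is flagged dominated.
    """
    if len(results) < 1:
        raise ValueError("at least one strategy required")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {sorted(n for n in names if names.count(n) > 1)}")

    order = sorted(range(len(results)), key=lambda i: (results[i].total_cost, i))
    dominated: set[int] = set()
    for i in range(len(results)):
        for j in range(len(results)):
            if i == j or j in dominated:
                continue
            a, b = results[j], results[i]
            if a.total_cost == b.total_cost and a.total_qaly == b.total_qaly:
                if j < i:  # later-listed loses the tie
                    dominated.add(i)
            elif _strictly_dominates(a, b):
                dominated.add(i)

    # Extended dominance: remove members until frontier ICERs increase.
    frontier = [i for i in order if i not in dominated]
    extended: set[int] = set()
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            lo, mid, hi = (results[i] for i in (frontier[k - 1], frontier[k], frontier[k + 1]))
            icer_mid = icer(mid.total_cost, mid.total_qaly, lo.total_cost, lo.total_qaly)
            icer_hi = icer(hi.total_cost, hi.total_qaly, mid.total_cost, mid.total_qaly)
            if icer_mid >= icer_hi:
                extended.add(frontier[k])
                frontier.pop(k)
                changed = True
                break

    entries: dict[int, FrontierEntry] = {}
    prev: CEAResult | None = None
    for i in frontier:
        r = results[i]
        entry = FrontierEntry(
            name=r.strategy, total_cost=r.total_cost, total_qaly=r.total_qaly, status=STATUS_FRONTIER
        )
        if prev is not None:
            entry.comparator = prev.strategy
            entry.inc_cost = r.total_cost - prev.total_cost
            entry.inc_qaly = r.total_qaly - prev.total_qaly
            entry.icer = icer(r.total_cost, r.total_qaly, prev.total_cost, prev.total_qaly)
        entries[i] = entry
        prev = r
    for i in order:
        if i in entries:
            continue
        r = results[i]
        entries[i] = FrontierEntry(
            name=r.strategy,
            total_cost=r.total_cost,
            total_qaly=r.total_qaly,
            status=STATUS_EXTENDED if i in extended else STATUS_DOMINATED,
        )
    return [entries[i] for i in order]


def pairwise_comparison(a: CEAResult, b: CEAResult) -> FrontierEntry:
    """Head-to-head incremental table row: the costlier of the pair versus
    the cheaper, regardless of dominance elsewhere."""
    cheap, dear = sorted((a, b), key=lambda r: r.total_cost)
    entry = FrontierEntry(
        name=dear.strategy,
        total_cost=dear.total_cost,
        total_qaly=dear.total_qaly,
        status=STATUS_FRONTIER,
        comparator=cheap.strategy,
        inc_cost=dear.total_cost - cheap.total_cost,
        inc_qaly=dear.total_qaly - cheap.total_qaly,
    )
    if entry.inc_qaly != 0:
        entry.icer = entry.inc_cost / entry.inc_qaly
    return entry


def optimal_strategy(results: Sequence[CEAResult], wtp: float) -> CEAResult:
    """Strategy with the highest net monetary benefit at the threshold.

    Ties resolve to the more effective strategy, then the cheaper, then
    input order — so the optimum is never a dominated strategy.
    """
    best = results[0]
    best_nmb = nmb(best.total_cost, best.total_qaly, wtp)
    for r in results[1:]:
        v = nmb(r.total_cost, r.total_qaly, wtp)
        if v > best_nmb or (
            v == best_nmb
            and (-r.total_qaly, r.total_cost) < (-best.total_qaly, best.total_cost)
        ):
            best, best_nmb = r, v
    return best


def threshold_monthly_price(
    scenario: Scenario,
    strategy: str,
    comparator: str,
    wtp: float | None = None,
) -> float:
    """Monthly drug price at which the strategy's ICER versus the comparator
    equals the willingness-to-pay threshold.

    Total cost is affine in the monthly price:
    ``total_cost(p) = fixed + p * exposure``, with ``exposure`` the
    discounted sum of alive occupancy over the accrual window, so the
    threshold solves exactly.
    """
    if wtp is None:
        wtp = scenario.wtp_default
    strat = scenario.strategy(strategy)
    comp_res = _run_one(scenario, comparator)
    occupancy = strategy_occupancy(scenario, strategy)
    exposure = compute_exposure(
        occupancy,
        cycle_length_months=scenario.cycle_length_months,
        discount_rate_annual=scenario.discount_rate_annual,
        half_cycle=scenario.settings.half_cycle,
        ae_cost_basis=scenario.settings.ae_cost_basis,
    )
    if exposure.alive <= 0:
        raise UndefinedThresholdError(
            f"strategy {strategy!r} has zero alive exposure; price has no effect"
        )
    if math.isinf(wtp):
        return math.inf
    zero_price = run_cohort(
        strat,
        occupancy,
        cycle_length_months=scenario.cycle_length_months,
        discount_rate_annual=scenario.discount_rate_annual,
        half_cycle=scenario.settings.half_cycle,
        ae_cost_basis=scenario.settings.ae_cost_basis,
        overrides={f"{strategy}.monthly_drug_cost": 0.0},
        keep_trace=False,
    )
    # Same relation as break_even_total_cost but valid for any QALY gap sign:
    # at the threshold price the ICER versus the comparator equals wtp.
    target_cost = comp_res.total_cost + wtp * (zero_price.total_qaly - comp_res.total_qaly)
    return (target_cost - zero_price.total_cost) / exposure.alive


def _run_one(scenario: Scenario, name: str) -> CEAResult:
    for res in run_scenario(scenario, keep_trace=False):
        if res.strategy == name:
            return res
    raise KeyError(f"no strategy named {name!r}")
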