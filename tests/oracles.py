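"""Independent brute-force oracles used to cross-check the package.

These deliberately use plain scalar Python loops and definitional
enumeration; they share no code with the implementation paths they check.
"""

from __future__ import annotations

import math
from typing import Sequence


def cohort_totals_oracle(
    occupancy,
    *,
    drug_cost: float,
    ae_cost: float,
    crossover_cost: float,
    u_stable: float,
    u_progression: float,
    cycle_length_months: float = 1,
    discount_rate_annual: float = 0.0,
    half_cycle: bool = False,
    ae_cost_basis: str = "alive",
) -> tuple[float, float]:
    """Spreadsheet-style cycle-by-cycle accumulation of cost and QALYs.

    Accrual over cycles t = 0..T-1 with start-of-cycle occupancy
    (trapezoidal across the cycle if half_cycle).
    """
    n_cycles = len(occupancy) - 1 if len(occupancy) > 1 else 1
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(n_cycles):
        if half_cycle and len(occupancy) > 1:
            stable = (occupancy[t].stable + occupancy[t + 1].stable) / 2.0
            prog = (occupancy[t].progressed + occupancy[t + 1].progressed) / 2.0
        else:
            stable = occupancy[t].stable
            prog = occupancy[t].progressed
        alive = stable + prog
        basis = stable if ae_cost_basis == "stable_only" else alive
        disc = (1.0 + discount_rate_annual) ** (-(t * cycle_length_months) / 12.0)
        total_cost += disc * (
            drug_cost * alive + ae_cost * basis + crossover_cost * prog
        )
        total_qaly += disc * (
            (u_stable * stable + u_progression * prog) * cycle_length_months / 12.0
        )
    return total_cost, total_qaly


def expected_ae_cost_oracle(pairs: Sequence[tuple[float, float]]) -> float:
    """Hand-sum of probability x cost pairs."""
    return math.fsum(p * c for p, c in pairs)


def strictly_dominated_oracle(points: Sequence[tuple[float, float]]) -> set[int]:
    """Indices of strategies strictly dominated by some other (cost, qaly)
    point, with exact ties resolved against the later index."""
    out = set()
    for i, (ci, qi) in enumerate(points):
        for j, (cj, qj) in enumerate(points):
            if i == j:
                continue
            if cj == ci and qj == qi:
                if j < i:
                    out.add(i)
            elif cj <= ci and qj >= qi:
                out.add(i)
    return out


def frontier_oracle(points: Sequence[tuple[float, float]]) -> set[int]:
    """Indices of strategies that win the NMB argmax for some WTP >= 0.

    Textbook definition of the efficiency frontier: a strategy belongs to
    it iff it is optimal for some willingness-to-pay.  The NMB winner is
    piecewise constant in lambda with breakpoints only at pairwise ICERs,
    so probing one lambda inside every breakpoint interval (plus 0 and a
    point beyond the largest) enumerates all winners exactly.  Ties go to
    the more effective strategy, then the cheaper, then the lower index.
    """
    costs = [c for c, _ in points]
    qalys = [q for _, q in points]
    breakpoints = sorted(
        {
            (costs[i] - costs[j]) / (qalys[i] - qalys[j])
            for i in range(len(points))
            for j in range(i)
            if qalys[i] != qalys[j]
        }
    )
    breakpoints = [b for b in breakpoints if b >= 0]
    probes = [0.0] + breakpoints
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        probes.append((lo + hi) / 2.0)
    probes.append((breakpoints[-1] + 1.0) * 2.0 if breakpoints else 1.0)
    winners = set()
    for lam in probes:
        best, best_nmb = None, -math.inf
        for i in range(len(points)):
            v = lam * qalys[i] - costs[i]
            if best is None or v > best_nmb or (
                v == best_nmb
                and (-qalys[i], costs[i], i) < (-qalys[best], costs[best], best)
            ):
                best, best_nmb = i, v
        winners.add(best)
    return winners
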