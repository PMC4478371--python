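"""Survival curves, constant-hazard tail extrapolation and state occupancy.

State occupancy is derived in partitioned-survival style directly from the
overall-survival (OS) and progression-free-survival (PFS) curves:

    stable(t)     = PFS(t)
    progressed(t) = OS(t) - PFS(t)
    dead(t)       = 1 - OS(t)

Beyond the observed follow-up, curves are extended with a constant hazard
estimated from the survival probability at an anchor month (the DEALE
approximation), so the tail is a declining exponential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: PFS > OS by at most this much is treated as floating-point noise and
#: silently clipped.
CLIP_SILENT_TOL = 1e-9
#: PFS > OS by more than the silent tolerance but at most this much is
#: clipped with a warning (digitized curves are noisy); beyond it the
#: inputs are considered corrupted.
CLIP_WARN_TOL = 0.05

#: Default lifetime horizon: 600 monthly cycles (50 years).
DEFAULT_HORIZON_CYCLES = 600
#: Horizon may terminate early once the dead fraction reaches 1 - this.
DEAD_ABSORPTION_TOL = 1e-6


class CurveError(ValueError):
    """Raised for invalid survival-curve data or incompatible curve pairs."""


class InfiniteHazardError(CurveError):
    """Raised when S(anchor) = 0, which implies an infinite hazard."""


@dataclass
class SurvivalCurve:
    """Monthly survival probabilities for one endpoint (OS or PFS) of one arm.

    Parameters
    ----------
    months
        Integer month grid starting at 0 with unit step.
    survival
        Survival probabilities ``S(t)`` on that grid; ``S(0) = 1``,
        nonincreasing, all values in [0, 1].
    anchor_month
        Month at which the extrapolation hazard is estimated (default 8,
        the last month of observed follow-up).
    hazard
        Constant monthly hazard of the extrapolated tail; ``None`` until
        :func:`deale_hazard` / :func:`extrapolate` has been applied.
    label
        Free-text identifier used in log messages.
    """

    months: np.ndarray
    survival: np.ndarray
    anchor_month: int = 8
    hazard: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.months.ndim != 1 or self.survival.ndim != 1:
            raise CurveError(f"{self._name}: months and survival must be 1-D")
        if self.months.size != self.survival.size:
            raise CurveError(f"{self._name}: months and survival lengths differ")
        if self.months.size == 0:
            raise CurveError(f"{self._name}: empty curve")
        if self.months[0] != 0:
            raise CurveError(f"{self._name}: month grid must start at 0")
        if not np.all(np.diff(self.months) == 1):
            raise CurveError(f"{self._name}: month grid must have unit step")
        if abs(self.survival[0] - 1.0) > 1e-12:
            raise CurveError(f"{self._name}: S(0) must be 1, got {self.survival[0]!r}")
        if np.any(self.survival < -1e-15) or np.any(self.survival > 1.0 + 1e-15):
            raise CurveError(f"{self._name}: survival probabilities outside [0, 1]")
        self.survival = np.clip(self.survival, 0.0, 1.0)
        if np.any(np.diff(self.survival) > 1e-12):
            raise CurveError(f"{self._name}: survival must be nonincreasing")
        if self.hazard is not None and self.hazard < 0:
            raise CurveError(f"{self._name}: hazard must be >= 0")

    @property
    def _name(self) -> str:
        return self.label or "survival curve"

    def __len__(self) -> int:
        return int(self.months.size)

    @property
    def last_month(self) -> int:
        return int(self.months[-1])

    def at(self, month: int) -> float:
        """S(month) for a month on the grid."""
        if not 0 <= month <= self.last_month:
            raise CurveError(f"{self._name}: month {month} outside grid 0..{self.last_month}")
        return float(self.survival[month])

    @classmethod
    def from_exponential_median(
        cls,
        median_months: float,
        follow_up_months: int = 8,
        label: str = "",
    ) -> "SurvivalCurve":
        """Exponential curve with the given median, on months 0..follow_up."""
        if median_months <= 0:
            raise CurveError("median_months must be > 0")
        if follow_up_months < 1:
            raise CurveError("follow_up_months must be >= 1")
        h = math.log(2.0) / median_months
        months = np.arange(follow_up_months + 1)
        return cls(
            months=months,
            survival=np.exp(-h * months),
            anchor_month=follow_up_months,
            label=label,
        )


@dataclass(frozen=True)
class OccupancyRow:
    """Cohort occupancy of the three health states at the start of a cycle."""

    cycle: int
    stable: float
    progressed: float
    dead: float

    @property
    def alive(self) -> float:
        return self.stable + self.progressed


def deale_hazard(curve: SurvivalCurve, anchor_month: int | None = None) -> float:
    """Constant monthly hazard from the survival probability at the anchor.

    ``hazard = -ln(S(anchor)) / anchor``; with no deaths by the anchor the
    hazard is 0.
    """
    anchor = curve.anchor_month if anchor_month is None else int(anchor_month)
    if anchor < 1 or anchor > curve.last_month:
        raise CurveError(
            f"{curve._name}: anchor month {anchor} outside observed range 1..{curve.last_month}"
        )
    s_anchor = curve.at(anchor)
    if s_anchor <= 0.0:
        raise InfiniteHazardError(
            f"{curve._name}: S({anchor}) = 0 implies an infinite hazard; "
            "choose an earlier anchor month"
        )
    return -math.log(s_anchor) / anchor


def extrapolate(
    curve: SurvivalCurve,
    horizon_cycles: int,
    anchor_month: int | None = None,
) -> SurvivalCurve:
    """Extend a curve to ``horizon_cycles`` months with a constant-hazard tail.

    The observed segment up to the anchor is kept verbatim; beyond it,
    ``S(t) = S(anchor) * exp(-hazard * (t - anchor))``.
    """
    anchor = curve.anchor_month if anchor_month is None else int(anchor_month)
    if horizon_cycles < curve.last_month:
        raise CurveError(
            f"{curve._name}: horizon {horizon_cycles} shorter than observed "
            f"segment ({curve.last_month} months)"
        )
    hazard = curve.hazard if curve.hazard is not None else deale_hazard(curve, anchor)
    months = np.arange(horizon_cycles + 1)
    survival = np.empty(horizon_cycles + 1)
    survival[: anchor + 1] = curve.survival[: anchor + 1]
    tail = months[anchor:] - anchor
    survival[anchor:] = curve.at(anchor) * np.exp(-hazard * tail)
    # Observed values past the anchor are replaced by the model tail, which
    # is the extrapolation contract: the anchor defines the hazard.
    return SurvivalCurve(
        months=months,
        survival=np.minimum.accumulate(survival),
        anchor_month=anchor,
        hazard=hazard,
        label=curve.label,
    )


def average_curves(a: SurvivalCurve, b: SurvivalCurve) -> SurvivalCurve:
    """Pointwise arithmetic mean of two curves on the same month grid.

    Used to pool two comparator arms into a single strategy curve.
    """
    if not np.array_equal(a.months, b.months):
        raise CurveError("cannot average curves on different month grids")
    label = a.label or b.label
    return SurvivalCurve(
        months=a.months.copy(),
        survival=(a.survival + b.survival) / 2.0,
        anchor_month=a.anchor_month,
        label=f"mean({label})" if label else "",
    )


def occupancy_from_survival(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    horizon_cycles: int | None = None,
) -> list[OccupancyRow]:
    """Partition OS/PFS curves into per-cycle three-state occupancy rows.

    Both curves must already cover the horizon on the same grid.  Small
    PFS > OS violations are clipped (see module tolerances); larger ones
    indicate inconsistent inputs and raise.
    """
    if not np.array_equal(os_curve.months, pfs_curve.months):
        raise CurveError("OS and PFS curves must share the same month grid")
    if horizon_cycles is None:
        horizon_cycles = os_curve.last_month
    if horizon_cycles > os_curve.last_month:
        raise CurveError(
            f"horizon {horizon_cycles} exceeds curve length {os_curve.last_month}; "
            "extrapolate first"
        )
    os_s = os_curve.survival[: horizon_cycles + 1]
    pfs_s = pfs_curve.survival[: horizon_cycles + 1]
    excess = pfs_s - os_s
    worst = float(excess.max(initial=0.0))
    if worst > CLIP_WARN_TOL:
        raise CurveError(
            f"PFS exceeds OS by {worst:.4g} (> {CLIP_WARN_TOL}): inconsistent curves"
        )
    if worst > CLIP_SILENT_TOL:
        logger.warning(
            "PFS exceeds OS by up to %.3g at %d month(s); clipping PFS to OS",
            worst,
            int((excess > CLIP_SILENT_TOL).sum()),
        )
    stable = np.minimum(pfs_s, os_s)
    rows = []
    for t in range(horizon_cycles + 1):
        s = float(stable[t])
        p = float(os_s[t] - stable[t])
        rows.append(OccupancyRow(cycle=t, stable=s, progressed=p, dead=1.0 - s - p))
    return rows


def transition_probabilities(rows: Sequence[OccupancyRow]) -> np.ndarray:
    """Diagnostic: per-cycle conditional transition probabilities.

    Returns an array of shape ``(len(rows) - 1, 3)`` with columns
    ``(p_stable_to_progressed, p_stable_to_dead, p_progressed_to_dead)``
    under the convention that deaths are drawn proportionally from both
    alive states (the partition itself does not identify state-specific
    mortality; this is the standard proportional allocation).  Provided so
    the occupancy trace can be cross-checked against an explicit
    transition-matrix simulation.
    """
    out = np.zeros((len(rows) - 1, 3))
    for t in range(len(rows) - 1):
        cur, nxt = rows[t], rows[t + 1]
        p_die = (nxt.dead - cur.dead) / cur.alive if cur.alive > 0 else 0.0
        p_die = min(max(p_die, 0.0), 1.0)
        stable_survivors = cur.stable * (1.0 - p_die)
        if stable_survivors > 0:
            q_prog = 1.0 - nxt.stable / stable_survivors
            q_prog = min(max(q_prog, 0.0), 1.0)
        else:
            q_prog = 0.0
        out[t] = ((1.0 - p_die) * q_prog, p_die, p_die)
    return out


def replay_transitions(
    rows: Sequence[OccupancyRow], probs: np.ndarray
) -> list[OccupancyRow]:
    """Diagnostic: re-run the cohort through the derived transition matrix.

    Consistency contract: the replayed trace reproduces the input trace.
    """
    replay = [rows[0]]
    for t in range(len(rows) - 1):
        p_sp, p_sd, p_die = probs[t]
        cur = replay[-1]
        stable = cur.stable * (1.0 - p_sp - p_sd)
        progressed = cur.progressed * (1.0 - p_die) + cur.stable * p_sp
        replay.append(
            OccupancyRow(
                cycle=t + 1,
                stable=stable,
                progressed=progressed,
                dead=1.0 - stable - progressed,
            )
        )
    return replay


def effective_horizon(rows: Sequence[OccupancyRow]) -> int:
    """Number of leading cycles to accrue: stop once the cohort is absorbed."""
    for t, row in enumerate(rows):
        if row.dead >= 1.0 - DEAD_ABSORPTION_TOL:
            return t
    return len(rows)
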