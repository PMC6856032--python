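"""Cohort propagation: occupancy traces and discounted cost/QALY accrual.

Deterministic cohort simulation: each stratum's occupancy vector is pushed
through its transition matrix for ``n_cycles`` one-year cycles; rewards are
accrued on cycle-start occupancy (so cycle 0 earns the first year's reward
undiscounted) and discounted at ``1/(1+rate)**cycle``.  No half-cycle
correction is applied by default; pass ``half_cycle_correction=True`` to
accrue on the mean of cycle-start and cycle-end occupancy instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ValidationError
from .pathways import HealthState, StateReward, Stratum

__all__ = [
    "NumericalIntegrityError",
    "CohortTrace",
    "discount_factor",
    "run_cohort",
    "strategy_totals",
]

_OCCUPANCY_TOL = 1e-6


class NumericalIntegrityError(RuntimeError):
    """Cohort mass drifted away from 1 during propagation."""


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value weight of a reward accrued at the start of ``cycle``."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if cycle < 0:
        raise ValidationError(f"cycle must be >= 0, got {cycle}")
    return float((1.0 + rate) ** (-cycle))


@dataclass(frozen=True)
class CohortTrace:
    """Aggregated run output.

    occupancy:
        (n_cycles + 1, n_states) cohort fractions at the start of each
        cycle, weight-averaged over strata (row sums are 1, dead included).
    cost_per_cycle, qaly_per_cycle:
        discounted per-cycle accruals (length n_cycles); one-off costs are
        charged at state entry in the cycle of arrival.
    cost_per_cycle_undiscounted, qaly_per_cycle_undiscounted:
        the same before discounting.
    """

    states: tuple
    occupancy: np.ndarray
    cost_per_cycle: np.ndarray
    qaly_per_cycle: np.ndarray
    cost_per_cycle_undiscounted: np.ndarray
    qaly_per_cycle_undiscounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_per_cycle.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_per_cycle.sum())

    @property
    def cumulative_cost(self) -> np.ndarray:
        return np.cumsum(self.cost_per_cycle)

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.cumsum(self.qaly_per_cycle)

    def to_dataframe(self) -> pd.DataFrame:
        names = [s.value if isinstance(s, HealthState) else str(s) for s in self.states]
        n = len(self.cost_per_cycle)
        df = pd.DataFrame(self.occupancy[:n], columns=names)
        df.insert(0, "cycle", np.arange(n))
        df["cost_discounted"] = self.cost_per_cycle
        df["qaly_discounted"] = self.qaly_per_cycle
        df["cost_undiscounted"] = self.cost_per_cycle_undiscounted
        df["qaly_undiscounted"] = self.qaly_per_cycle_undiscounted
        return df


def run_cohort(
    strata: list[Stratum],
    rewards: dict,
    n_cycles: int,
    rate: float,
    half_cycle_correction: bool = False,
) -> CohortTrace:
    """Propagate every stratum and accumulate weighted, discounted rewards.

    ``rewards`` maps each state in the strata's (shared) state tuple to a
    :class:`StateReward`.  One-off costs attach to state entry: the initial
    occupancy at cycle 0, and inflow from *other* states thereafter.  The
    stratum's ``cycle0_cost`` (test administration) is charged once,
    undiscounted, at cycle 0.
    """
    if n_cycles < 1:
        raise ValidationError(f"n_cycles must be >= 1, got {n_cycles}")
    if not strata:
        raise ValidationError("no strata to run")
    states = strata[0].matrix.states
    n_states = len(states)
    cost_vec = np.array([rewards[s].annual_cost for s in states])
    util_vec = np.array([rewards[s].annual_utility for s in states])
    oneoff_vec = np.array([rewards[s].one_off_cost for s in states])
    has_oneoff = bool(np.any(oneoff_vec > 0))

    occupancy = np.zeros((n_cycles + 1, n_states))
    cost_u = np.zeros(n_cycles)
    qaly_u = np.zeros(n_cycles)
    oneoff_u = np.zeros(n_cycles)

    for st in strata:
        if st.matrix.states != states:
            raise ValidationError("all strata must share one state ordering")
        m = st.matrix.matrix
        m_offdiag = m - np.diag(np.diag(m))
        occ = np.zeros(n_states)
        occ[st.matrix.index(st.initial_state)] = 1.0
        w = st.weight
        oneoff_u[0] += w * st.cycle0_cost
        if has_oneoff:
            oneoff_u[0] += w * float(occ @ oneoff_vec)
        for t in range(n_cycles):
            occupancy[t] += w * occ
            occ_next = occ @ m
            drift = abs(occ_next.sum() - 1.0)
            if drift > _OCCUPANCY_TOL:
                raise NumericalIntegrityError(
                    f"{st.label}: occupancy sum drifted by {drift:.3g} at cycle {t + 1}"
                )
            eff = 0.5 * (occ + occ_next) if half_cycle_correction else occ
            cost_u[t] += w * float(eff @ cost_vec)
            qaly_u[t] += w * float(eff @ util_vec)
            if has_oneoff and t + 1 < n_cycles:
                entrants = occ @ m_offdiag
                oneoff_u[t + 1] += w * float(entrants @ oneoff_vec)
            occ = occ_next
        occupancy[n_cycles] += w * occ

    df = np.array([discount_factor(rate, t) for t in range(n_cycles)])
    return CohortTrace(
        states=states,
        occupancy=occupancy,
        cost_per_cycle=(cost_u + oneoff_u) * df,
        qaly_per_cycle=qaly_u * df,
        cost_per_cycle_undiscounted=cost_u + oneoff_u,
        qaly_per_cycle_undiscounted=qaly_u,
    )


def strategy_totals(trace: CohortTrace) -> tuple[float, float]:
    """Final cumulative discounted (cost, QALY) of a completed trace."""
    return trace.total_cost, trace.total_qaly
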