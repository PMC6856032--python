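"""Health-state space, treatment-pathway transition matrices, and rewards.

Eleven mutually exclusive states describe where a patient is in the
second-line treatment sequence: stable or relapsed on a conventional
antipsychotic (AP), on clozapine (CLZ), or on a post-clozapine AP; off
medication through non-adherence; switching off clozapine after intolerable
adverse events; an initial-assessment entry state; and death (absorbing).

Each strategy (TAU: try AP2 first, clozapine on failure; SMA: a predictive
test routes predicted non-responders straight to clozapine) is expanded into
weighted strata — one per (subgroup x test class) combination — each with
its own time-homogeneous transition matrix.  The pathway position is encoded
in the state, so deterministic treatment sequences (e.g. one relapse year on
a failed drug, then switch) need no cycle-dependent matrices.  Adverse
events are folded into state rewards as expected-value adjustments rather
than explicit states; mortality and non-adherence are stochastic decorations
applied to every matrix.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterSet, ValidationError
from .stratifier import classify_cohort, split_false_negatives

__all__ = [
    "DrugClass",
    "HealthState",
    "STATES",
    "TransitionMatrix",
    "StateReward",
    "Stratum",
    "TAU",
    "SMA",
    "STRATEGIES",
    "build_strategy",
    "build_rewards",
    "apply_nonadherence",
    "apply_adverse_events",
    "apply_mortality",
    "export_matrices",
]

logger = logging.getLogger(__name__)

TAU = "TAU"
SMA = "SMA"
STRATEGIES = (TAU, SMA)


class DrugClass(enum.Enum):
    AP = "conventional_antipsychotic"
    CLZ = "clozapine"
    NONE = "no_antipsychotic"


class HealthState(enum.Enum):
    """The default 11-state enumeration."""

    STABLE_AP = "stable_on_AP"
    RELAPSE_AP = "relapse_on_AP"
    STABLE_CLZ = "stable_on_CLZ"
    RELAPSE_CLZ = "relapse_on_CLZ"
    STABLE_NONADHERENT = "stable_nonadherent"
    RELAPSE_NONADHERENT = "relapse_nonadherent"
    STABLE_POSTCLZ_AP = "stable_on_postCLZ_AP"
    RELAPSE_POSTCLZ_AP = "relapse_on_postCLZ_AP"
    CLZ_SWITCHING = "clz_intolerant_switching"
    INITIAL = "initial_assessment"
    DEAD = "dead"

    @property
    def drug_class(self) -> DrugClass:
        if self in (HealthState.STABLE_CLZ, HealthState.RELAPSE_CLZ):
            return DrugClass.CLZ
        if self in (
            HealthState.STABLE_AP,
            HealthState.RELAPSE_AP,
            HealthState.STABLE_POSTCLZ_AP,
            HealthState.RELAPSE_POSTCLZ_AP,
        ):
            return DrugClass.AP
        return DrugClass.NONE

    @property
    def on_clozapine(self) -> bool:
        return self.drug_class is DrugClass.CLZ

    @property
    def in_relapse(self) -> bool:
        return self in (
            HealthState.RELAPSE_AP,
            HealthState.RELAPSE_CLZ,
            HealthState.RELAPSE_NONADHERENT,
            HealthState.RELAPSE_POSTCLZ_AP,
            HealthState.CLZ_SWITCHING,
            HealthState.INITIAL,
        )

    @property
    def alive(self) -> bool:
        return self is not HealthState.DEAD


STATES: tuple[HealthState, ...] = tuple(HealthState)


# --------------------------------------------------------------------------
# transition matrices


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic per-cycle transition probabilities over ``states``.

    The engine accepts any state tuple, not only the default 11-state space;
    absorbing states (``alive`` False, or any state named "dead") must have
    an identity row.
    """

    states: tuple
    matrix: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.states)
        if m.shape != (n, n):
            raise ValidationError(f"{self.label}: matrix shape {m.shape} != ({n}, {n})")
        self.validate()

    def validate(self) -> None:
        m = self.matrix
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValidationError(f"{self.label}: entries outside [0, 1]")
        rowsums = m.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValidationError(
                f"{self.label}: row for {self.states[bad]} sums to {rowsums[bad]!r}"
            )
        for i, s in enumerate(self.states):
            if isinstance(s, HealthState) and not s.alive:
                row = np.zeros(len(self.states))
                row[i] = 1.0
                if not np.allclose(self.matrix[i], row, atol=1e-12):
                    raise ValidationError(f"{self.label}: dead row is not absorbing")

    def index(self, state) -> int:
        return self.states.index(state)

    def with_matrix(self, m: np.ndarray) -> "TransitionMatrix":
        return TransitionMatrix(states=self.states, matrix=m, label=self.label)

    def to_frame(self) -> pd.DataFrame:
        names = [s.value if isinstance(s, HealthState) else str(s) for s in self.states]
        return pd.DataFrame(self.matrix, index=names, columns=names)


def deterministic_matrix(
    moves: dict, states: tuple = STATES, label: str = ""
) -> TransitionMatrix:
    """Matrix where every state self-loops except the given ``from -> to`` moves."""
    n = len(states)
    m = np.eye(n)
    for src, dst in moves.items():
        i, j = states.index(src), states.index(dst)
        m[i, i] = 0.0
        m[i, j] = 1.0
    return TransitionMatrix(states=states, matrix=m, label=label)


def add_branch(tm: TransitionMatrix, src, dst, prob: float) -> TransitionMatrix:
    """Divert probability ``prob`` of the ``src`` row into ``dst``,
    scaling the existing destinations by ``1 - prob``."""
    if not 0.0 <= prob <= 1.0:
        raise ValidationError(f"branch probability must lie in [0, 1], got {prob}")
    m = tm.matrix.copy()
    i, j = tm.index(src), tm.index(dst)
    m[i] = m[i] * (1.0 - prob)
    m[i, j] += prob
    return tm.with_matrix(m)


def apply_nonadherence(
    tm: TransitionMatrix, p: ParameterSet, home: HealthState
) -> TransitionMatrix:
    """Add the non-adherence cycle around a responder's stable state.

    ``home`` (a stable on-drug state) leaks into ``stable_nonadherent`` with
    the drug-class annual non-adherence probability; untreated patients stay
    without medication until a relapse (``relapse_nonadherent``), after
    which they return to the same drug.  Clozapine carries a lower default
    non-adherence probability than conventional antipsychotics.
    """
    key = "clz" if home.drug_class is DrugClass.CLZ else "ap"
    p_na = p.nonadherence_probs[key]
    if p_na == 0.0:
        return tm
    out = add_branch(tm, home, HealthState.STABLE_NONADHERENT, p_na)
    m = out.matrix.copy()
    i_sna = out.index(HealthState.STABLE_NONADHERENT)
    i_rna = out.index(HealthState.RELAPSE_NONADHERENT)
    i_home = out.index(home)
    m[i_sna] = 0.0
    m[i_sna, i_sna] = 1.0 - p.p_relapse_if_nonadherent
    m[i_sna, i_rna] = p.p_relapse_if_nonadherent
    m[i_rna] = 0.0
    m[i_rna, i_home] = 1.0
    result = out.with_matrix(m)
    result.validate()  # construction error if rows no longer stochastic
    return result


def apply_clz_intolerance(
    tm: TransitionMatrix, p: ParameterSet, dest: HealthState
) -> TransitionMatrix:
    """Annual risk of intolerable clozapine adverse events: stable-on-CLZ
    patients divert to the switching state, then (next cycle) to ``dest`` —
    a post-clozapine conventional AP state whose flavour depends on whether
    the patient would respond to it."""
    if p.p_clz_intolerance == 0.0:
        return tm
    out = add_branch(tm, HealthState.STABLE_CLZ, HealthState.CLZ_SWITCHING, p.p_clz_intolerance)
    m = out.matrix.copy()
    i_sw = out.index(HealthState.CLZ_SWITCHING)
    m[i_sw] = 0.0
    m[i_sw, out.index(dest)] = 1.0
    return out.with_matrix(m)


def apply_mortality(tm: TransitionMatrix, p: ParameterSet) -> TransitionMatrix:
    """Give every living state a transition to dead.

    Background annual death probability, scaled by the clozapine multiplier
    (< 1) for on-clozapine states, with optional per-state overrides;
    surviving flows are rescaled so rows stay stochastic.  The dead row
    remains identity.
    """
    m = tm.matrix.copy()
    try:
        i_dead = tm.index(HealthState.DEAD)
    except ValueError:
        raise ValidationError(f"{tm.label}: no dead state to apply mortality to")
    for i, s in enumerate(tm.states):
        if s is HealthState.DEAD:
            continue
        q = p.mortality.by_state.get(s.value if isinstance(s, HealthState) else str(s))
        if q is None:
            q = p.mortality.p_death
            if isinstance(s, HealthState) and s.on_clozapine:
                q *= p.mortality.clz_multiplier
        if not 0.0 <= q <= 1.0:
            raise ValidationError(f"death probability for {s} outside [0, 1]: {q}")
        m[i] = m[i] * (1.0 - q)
        m[i, i_dead] += q
    return tm.with_matrix(m)


# --------------------------------------------------------------------------
# state rewards


@dataclass(frozen=True)
class StateReward:
    """Annual cost (GBP/yr), annual utility (QALY/yr), and a one-off cost
    charged on entry into the state."""

    annual_cost: float
    annual_utility: float
    one_off_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.annual_cost < 0 or self.one_off_cost < 0:
            raise ValidationError("state costs must be >= 0")
        if not 0.0 <= self.annual_utility <= 1.0:
            raise ValidationError(
                f"state utility must lie in [0, 1], got {self.annual_utility}"
            )


def apply_adverse_events(
    reward: StateReward, state: HealthState, p: ParameterSet
) -> StateReward:
    """Fold expected adverse-event burden into a state's rewards.

    Utility falls by sum(P(AE) * decrement) and cost rises by
    sum(P(AE) * AE cost) over the AEs of the state's drug class
    (neutropenia applies to clozapine only); clozapine states additionally
    pay the annual blood-monitoring cost.  Dead and drug-free states are
    untouched.
    """
    drug = state.drug_class
    if drug is DrugClass.NONE or not state.alive:
        return reward
    key = "clz" if drug is DrugClass.CLZ else "ap"
    probs = p.adverse_event_probs.get(key, {})
    d_util = sum(pr * p.ae_utility_decrements.get(ev, 0.0) for ev, pr in probs.items())
    d_cost = sum(pr * p.ae_costs.get(ev, 0.0) for ev, pr in probs.items())
    if drug is DrugClass.CLZ:
        d_cost += p.clz_monitoring_cost
    utility = reward.annual_utility - d_util
    if utility < 0.0:
        logger.warning(
            "adverse-event decrements drive utility below 0 for %s; clamping", state
        )
        utility = 0.0
    return _dc_replace(reward, annual_cost=reward.annual_cost + d_cost, annual_utility=utility)


def build_rewards(p: ParameterSet) -> dict:
    """Per-state rewards: stable states earn the remission cost/utility,
    relapse-type states (including switching and assessment) the active-
    psychosis cost and relapse utility, dead nothing; then adverse-event
    adjustment per drug class."""
    rewards: dict = {}
    for s in STATES:
        if not s.alive:
            rewards[s] = StateReward(0.0, 0.0)
            continue
        if s.in_relapse:
            base = StateReward(p.cost_relapse_year, p.utility_relapse)
        else:
            base = StateReward(p.cost_remission_year, p.utility_stable)
        rewards[s] = apply_adverse_events(base, s, p)
    return rewards


# --------------------------------------------------------------------------
# strategy construction


@dataclass(frozen=True)
class Stratum:
    """One homogeneous slice of the cohort under a strategy: its weight,
    transition matrix, starting state, and any cycle-0 one-off cost (the
    test administration charge under SMA)."""

    label: str
    strategy: str
    test_class: str | None
    weight: float
    matrix: TransitionMatrix
    initial_state: HealthState
    cycle0_cost: float = 0.0


def _ap2_responder_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # responds to the second-line AP immediately and stays on it
    tm = deterministic_matrix({}, label=label)
    return apply_nonadherence(tm, p, HealthState.STABLE_AP)


def _clz_responder_tau_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # one failed year on AP2, then clozapine response; intolerance exits to
    # a post-clozapine AP that will not work for this subgroup
    tm = deterministic_matrix(
        {HealthState.RELAPSE_AP: HealthState.STABLE_CLZ}, label=label
    )
    tm = apply_clz_intolerance(tm, p, HealthState.RELAPSE_POSTCLZ_AP)
    return apply_nonadherence(tm, p, HealthState.STABLE_CLZ)


def _clz_responder_sma_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # clozapine from cycle 0 — the strategy's core benefit
    tm = deterministic_matrix({}, label=label)
    tm = apply_clz_intolerance(tm, p, HealthState.RELAPSE_POSTCLZ_AP)
    return apply_nonadherence(tm, p, HealthState.STABLE_CLZ)


def _nonresponder_tau_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # fails every line: AP relapse -> clozapine relapse -> post-CLZ AP relapse
    return deterministic_matrix(
        {
            HealthState.RELAPSE_AP: HealthState.RELAPSE_CLZ,
            HealthState.RELAPSE_CLZ: HealthState.RELAPSE_POSTCLZ_AP,
        },
        label=label,
    )


def _nonresponder_sma_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    return deterministic_matrix(
        {HealthState.RELAPSE_CLZ: HealthState.RELAPSE_POSTCLZ_AP}, label=label
    )


def _fn_on_clz_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # AP2 responder who also responds to clozapine: stays on it; if
    # intolerant, switches and responds to the post-clozapine AP
    tm = deterministic_matrix({}, label=label)
    tm = apply_clz_intolerance(tm, p, HealthState.STABLE_POSTCLZ_AP)
    return apply_nonadherence(tm, p, HealthState.STABLE_CLZ)


def _fn_rerouted_matrix(p: ParameterSet, label: str) -> TransitionMatrix:
    # AP2 responder who fails clozapine: one relapse year on it, then
    # responds to a second-line conventional AP
    tm = deterministic_matrix(
        {HealthState.RELAPSE_CLZ: HealthState.STABLE_POSTCLZ_AP}, label=label
    )
    return apply_nonadherence(tm, p, HealthState.STABLE_POSTCLZ_AP)


def build_strategy(strategy: str, p: ParameterSet) -> list[Stratum]:
    """Expand a strategy into weighted strata with decorated matrices.

    TAU strata are the three response subgroups at their prevalences.  SMA
    strata are the four classification cells; false negatives split further
    by clozapine response, and the negative/positive non-AP2 cells split
    into clozapine responders vs non-responders at their relative
    prevalence.  Zero-weight strata are dropped; weights sum to 1.
    Mortality is applied to every matrix last.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    mix = p.mix
    entries: list[tuple[str, str | None, float, TransitionMatrix, HealthState]] = []
    if strategy == TAU:
        entries = [
            ("ap2_responder", None, mix.p_ap2,
             _ap2_responder_matrix(p, "TAU/ap2_responder"), HealthState.STABLE_AP),
            ("clz_responder", None, mix.p_clz,
             _clz_responder_tau_matrix(p, "TAU/clz_responder"), HealthState.RELAPSE_AP),
            ("nonresponder", None, mix.p_nonresp,
             _nonresponder_tau_matrix(p, "TAU/nonresponder"), HealthState.RELAPSE_AP),
        ]
    else:
        fr = classify_cohort(p.stratifier, mix.p_ap2)
        fn_clz, fn_rr = split_false_negatives(fr.fn, p.p_fn_clz_response)
        non_ap2 = mix.p_clz + mix.p_nonresp
        q_clz = mix.p_clz / non_ap2 if non_ap2 > 0 else 0.0
        entries = [
            ("tp_ap2_responder", "tp", fr.tp,
             _ap2_responder_matrix(p, "SMA/tp_ap2_responder"), HealthState.STABLE_AP),
            ("fn_clz_response", "fn", fn_clz,
             _fn_on_clz_matrix(p, "SMA/fn_clz_response"), HealthState.STABLE_CLZ),
            ("fn_rerouted", "fn", fn_rr,
             _fn_rerouted_matrix(p, "SMA/fn_rerouted"), HealthState.RELAPSE_CLZ),
            ("tn_clz_responder", "tn", fr.tn * q_clz,
             _clz_responder_sma_matrix(p, "SMA/tn_clz_responder"), HealthState.STABLE_CLZ),
            ("tn_nonresponder", "tn", fr.tn * (1.0 - q_clz),
             _nonresponder_sma_matrix(p, "SMA/tn_nonresponder"), HealthState.RELAPSE_CLZ),
            ("fp_clz_responder", "fp", fr.fp * q_clz,
             _clz_responder_tau_matrix(p, "SMA/fp_clz_responder"), HealthState.RELAPSE_AP),
            ("fp_nonresponder", "fp", fr.fp * (1.0 - q_clz),
             _nonresponder_tau_matrix(p, "SMA/fp_nonresponder"), HealthState.RELAPSE_AP),
        ]
    strata = []
    for name, test_class, weight, tm, init in entries:
        if weight <= 0.0:
            continue
        strata.append(
            Stratum(
                label=name,
                strategy=strategy,
                test_class=test_class,
                weight=weight,
                matrix=apply_mortality(tm, p),
                initial_state=init,
                cycle0_cost=p.cost_test if strategy == SMA else 0.0,
            )
        )
    total = sum(s.weight for s in strata)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{strategy}: stratum weights sum to {total!r}")
    return strata


def export_matrices(strata: list[Stratum], out_dir: str | Path) -> list[Path]:
    """Write one CSV per stratum matrix (states as header row/column)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in strata:
        path = out / f"matrix_{s.strategy}_{s.label}.csv"
        s.matrix.to_frame().to_csv(path)
        paths.append(path)
    return paths
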