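"""Ready-made parameter sets and toy models with closed-form answers.

``make_base_case`` is the study's default scenario: a 60%/60% test, the
16.67/62.50/20.83% responder mix, and the documented stand-in defaults for
the detailed pathway parameters (adverse events, adherence, mortality,
monitoring) that the printed evidence does not provide — each such value is
flagged "assumption, not source-reported" in :data:`stratcea.params.PROVENANCE`.
The other fixtures are engineered edge cases for testing the engine and the
comparison logic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .markov import run_cohort
from .params import (
    DEFAULTS,
    PROVENANCE,
    ParameterSet,
    ValidationError,
    load_parameters,
)
from .pathways import HealthState, StateReward, Stratum, TransitionMatrix

__all__ = [
    "make_base_case",
    "make_perfect_test",
    "make_null_benefit",
    "make_toy_closed_form",
    "ToyModel",
    "perturb",
    "catalog",
    "ONE_WAY_RANGES",
]

#: deterministic sweep ranges of the documented one-way analyses; the test's
#: sensitivity/specificity (0-1) are explored jointly by the two-way
#: threshold analysis rather than one at a time
ONE_WAY_RANGES: dict[str, tuple[float, float]] = {
    "mix.p_clz": (0.0, 0.7915),
    "p_fn_clz_response": (0.0, 1.0),
    "cost_test": (100.0, 1000.0),
    "cost_remission_year": (10000.0, 39141.0),
    "utility_relapse": (0.1900, 0.6040),
    "utility_stable": (0.8650, 0.9190),
    "discount_rate": (0.0, 0.050),
    "n_cycles": (10, 100),
}


def make_base_case() -> ParameterSet:
    """The default scenario (every documented point value and PSA spec)."""
    return load_parameters(copy.deepcopy(DEFAULTS))


def make_perfect_test() -> ParameterSet:
    """Base case with a perfectly accurate stratifier (no misclassification)."""
    return make_base_case().replace(
        **{"stratifier.sensitivity": 1.0, "stratifier.specificity": 1.0}
    )


def make_null_benefit() -> ParameterSet:
    """Base case with no clozapine responders: the stratifier has no
    beneficiary, so the test cost is pure loss and SMA can never be
    preferred."""
    from .cea import set_parameter  # local import to avoid a cycle

    return set_parameter(make_base_case(), "mix.p_clz", 0.0)


@dataclass(frozen=True)
class ToyModel:
    """A degenerate one-living-state cohort and its geometric-series totals."""

    strata: list
    rewards: dict
    n_cycles: int
    rate: float
    expected_cost: float
    expected_qaly: float

    def run(self, **kw):
        return run_cohort(self.strata, self.rewards, self.n_cycles, self.rate, **kw)


def make_toy_closed_form(
    utility: float, cost: float, rate: float, n_cycles: int
) -> ToyModel:
    """One immortal state earning fixed rewards: totals are
    ``reward * sum_{t=0}^{T-1} (1+rate)^-t`` exactly."""
    states = (HealthState.STABLE_AP, HealthState.DEAD)
    matrix = TransitionMatrix(states=states, matrix=np.eye(2), label="toy")
    stratum = Stratum(
        label="toy",
        strategy="TAU",
        test_class=None,
        weight=1.0,
        matrix=matrix,
        initial_state=HealthState.STABLE_AP,
    )
    rewards = {
        HealthState.STABLE_AP: StateReward(cost, utility),
        HealthState.DEAD: StateReward(0.0, 0.0),
    }
    annuity = sum((1.0 + rate) ** (-t) for t in range(n_cycles))
    return ToyModel(
        strata=[stratum],
        rewards=rewards,
        n_cycles=n_cycles,
        rate=rate,
        expected_cost=cost * annuity,
        expected_qaly=utility * annuity,
    )


_JITTER_FIELDS_PROB = (
    "p_fn_clz_response",
    "p_relapse_if_nonadherent",
    "p_clz_intolerance",
    "nonadherence_probs.ap",
    "nonadherence_probs.clz",
    "mortality.p_death",
    "utility_relapse",
    "utility_stable",
)
_JITTER_FIELDS_COST = (
    "cost_test",
    "cost_relapse_year",
    "cost_remission_year",
    "clz_monitoring_cost",
)


def perturb(p: ParameterSet, seed: int, scale: float) -> ParameterSet:
    """Seed-reproducible jitter of the non-fixed parameters, for fuzzing.

    Probabilities and utilities move multiplicatively within (0, 1); costs
    multiplicatively within [0, inf); the subgroup mix is re-drawn near its
    point value and renormalized.  ``scale = 0`` returns the set unchanged;
    any output passes validation.
    """
    if scale < 0:
        raise ValidationError(f"perturb scale must be >= 0, got {scale}")
    if scale == 0:
        return p
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    cfg = p.to_dict()
    for name in _JITTER_FIELDS_PROB:
        value = _get(cfg, name)
        jittered = value * (1.0 + scale * rng.uniform(-1, 1))
        updates[name] = float(np.clip(jittered, 0.0, 1.0))
    for name in _JITTER_FIELDS_COST:
        value = _get(cfg, name)
        updates[name] = float(max(value * (1.0 + scale * rng.uniform(-1, 1)), 0.0))
    mix = np.array([p.mix.p_ap2, p.mix.p_clz, p.mix.p_nonresp])
    mix = np.clip(mix * (1.0 + scale * rng.uniform(-1, 1, size=3)), 1e-9, None)
    mix = mix / mix.sum()
    out = p.replace(**updates)
    return out.replace(
        mix={"p_ap2": float(mix[0]), "p_clz": float(mix[1]), "p_nonresp": float(mix[2])}
    )


def _get(cfg: dict, path: str):
    node = cfg
    for k in path.split("."):
        node = node[k]
    return node


def catalog() -> dict:
    """Named fixture factories with provenance notes."""
    return {
        "base_case": {
            "factory": make_base_case,
            "note": "documented default scenario; per-parameter provenance in "
                    "stratcea.params.PROVENANCE",
        },
        "perfect_test": {
            "factory": make_perfect_test,
            "note": "sensitivity = specificity = 1; no misclassification",
        },
        "null_benefit": {
            "factory": make_null_benefit,
            "note": "no clozapine responders; the test cannot pay for itself",
        },
        "toy_closed_form": {
            "factory": lambda: make_toy_closed_form(0.8650, 15086.0, 0.035, 80),
            "note": "one-living-state model with geometric-series totals",
        },
    }


def provenance() -> dict:
    """Parameter-path -> provenance flag for the base case."""
    return dict(PROVENANCE)
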