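"""Strategy comparison and sensitivity analysis.

Deterministic comparison reports incremental cost and QALYs of SMA over TAU
and a dominance/ICER verdict.  One-way sweeps re-run both strategies over a
parameter grid; the two-way threshold finds the minimal test specificity at
which SMA is preferred (by net monetary benefit) for a given sensitivity.
Probabilistic sensitivity analysis re-draws every distributed parameter
jointly and the cost-effectiveness acceptability curve reports, per
willingness-to-pay value, the fraction of draws in which each strategy has
the highest net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import CohortTrace, run_cohort, strategy_totals
from .params import ParameterSet, ValidationError, sample_parameters
from .pathways import SMA, TAU, build_rewards, build_strategy

__all__ = [
    "VERDICT_SMA_DOMINANT",
    "VERDICT_TAU_DOMINANT",
    "VERDICT_ICER",
    "VERDICT_TIE",
    "NEVER_PREFERRED",
    "CEAResult",
    "PSAResult",
    "CEAC",
    "net_monetary_benefit",
    "compare_strategies",
    "run_strategy",
    "evaluate",
    "set_parameter",
    "one_way_sa",
    "two_way_threshold",
    "run_psa",
    "build_ceac",
    "tornado",
]

logger = logging.getLogger(__name__)

VERDICT_SMA_DOMINANT = "SMA dominant"
VERDICT_TAU_DOMINANT = "TAU dominant"
VERDICT_ICER = "ICER"
VERDICT_TIE = "tie"

#: sentinel returned by :func:`two_way_threshold` when no specificity in
#: [0, 1] makes SMA preferred
NEVER_PREFERRED = 2.0


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp * qaly - cost; at wtp = 0 ranking by NMB is cost-minimization."""
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * qaly - cost


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of SMA versus TAU (incrementals are SMA - TAU)."""

    tau_cost: float
    tau_qaly: float
    sma_cost: float
    sma_qaly: float
    incremental_cost: float
    incremental_qaly: float
    verdict: str
    icer: float | None = None

    def to_dict(self) -> dict:
        return {
            "tau_cost": self.tau_cost,
            "tau_qaly": self.tau_qaly,
            "sma_cost": self.sma_cost,
            "sma_qaly": self.sma_qaly,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "verdict": self.verdict,
            "icer": self.icer,
        }


def compare_strategies(
    tau: tuple[float, float], sma: tuple[float, float]
) -> CEAResult:
    """Dominance/ICER verdict from per-strategy (cost, QALY) totals.

    A strategy dominates when it costs no more and yields no fewer QALYs,
    strictly better on at least one axis; otherwise the ICER
    (delta cost / delta QALY) is reported.
    """
    tau_c, tau_q = float(tau[0]), float(tau[1])
    sma_c, sma_q = float(sma[0]), float(sma[1])
    for v in (tau_c, tau_q, sma_c, sma_q):
        if not np.isfinite(v):
            raise ValidationError("strategy totals must be finite")
    dc, dq = sma_c - tau_c, sma_q - tau_q
    icer: float | None = None
    if dc == 0.0 and dq == 0.0:
        verdict = VERDICT_TIE
    elif dc <= 0.0 and dq >= 0.0:
        verdict = VERDICT_SMA_DOMINANT
    elif dc >= 0.0 and dq <= 0.0:
        verdict = VERDICT_TAU_DOMINANT
    else:
        verdict = VERDICT_ICER
        icer = dc / dq
    return CEAResult(
        tau_cost=tau_c,
        tau_qaly=tau_q,
        sma_cost=sma_c,
        sma_qaly=sma_q,
        incremental_cost=dc,
        incremental_qaly=dq,
        verdict=verdict,
        icer=icer,
    )


def run_strategy(
    strategy: str, p: ParameterSet, half_cycle_correction: bool = False
) -> CohortTrace:
    """Build and run one strategy at the given parameters."""
    strata = build_strategy(strategy, p)
    rewards = build_rewards(p)
    return run_cohort(
        strata, rewards, p.n_cycles, p.discount_rate,
        half_cycle_correction=half_cycle_correction,
    )


def evaluate(p: ParameterSet, half_cycle_correction: bool = False) -> CEAResult:
    """Run both strategies at the point estimates and compare them."""
    tau = strategy_totals(run_strategy(TAU, p, half_cycle_correction))
    sma = strategy_totals(run_strategy(SMA, p, half_cycle_correction))
    return compare_strategies(tau, sma)


# --------------------------------------------------------------------------
# deterministic sensitivity analysis

_MIX_COMPONENTS = ("p_ap2", "p_clz", "p_nonresp")


def set_parameter(p: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with one dotted-path parameter set to ``value``.

    Subgroup-mix components (``mix.p_ap2`` etc.) rebalance the other two
    components proportionally so the mix stays on the simplex (equal split
    when the other components are both zero); the Dirichlet counts are
    rescaled to stay consistent with the new point estimate.
    """
    if name.startswith("mix."):
        comp = name.split(".", 1)[1]
        if comp not in _MIX_COMPONENTS:
            raise ValidationError(f"unknown mix component {comp!r}")
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        mix = {c: getattr(p.mix, c) for c in _MIX_COMPONENTS}
        old = mix[comp]
        rest = 1.0 - old
        new_mix = {}
        for c in _MIX_COMPONENTS:
            if c == comp:
                new_mix[c] = value
            elif rest > 0:
                new_mix[c] = mix[c] * (1.0 - value) / rest
            else:
                new_mix[c] = (1.0 - value) / (len(_MIX_COMPONENTS) - 1)
        out = p.replace(mix=new_mix)
        spec = p.distributions.get("mix")
        if spec is not None and spec.kind == "dirichlet_counts":
            total = sum(spec.counts)
            # counts order (clz, ap2, nonresp)
            new_counts = [
                max(total * new_mix["p_clz"], 1e-9),
                max(total * new_mix["p_ap2"], 1e-9),
                max(total * new_mix["p_nonresp"], 1e-9),
            ]
            out = out.replace(**{"distributions.mix.counts": new_counts})
        return out
    cfg = p.to_dict()
    try:
        node = cfg
        for key in name.split("."):
            node = node[key]
    except (KeyError, TypeError):
        raise ValidationError(
            f"unknown parameter {name!r}; valid top-level names: {sorted(cfg)}"
        ) from None
    return p.replace(**{name: value})


def one_way_sa(
    p: ParameterSet,
    param_name: str,
    value_range: tuple[float, float],
    n_points: int = 11,
    half_cycle_correction: bool = False,
) -> pd.DataFrame:
    """Deterministic sweep of one parameter, all else at base case.

    Returns one row per grid value with both strategies' totals,
    incrementals, and verdict.  A zero-width range yields a single row.
    Range endpoints outside the parameter's validity bounds raise
    :class:`ValidationError` before anything is run.
    """
    lo, hi = float(value_range[0]), float(value_range[1])
    if hi < lo:
        raise ValidationError(f"range for {param_name} has hi < lo")
    # endpoint construction doubles as bounds validation
    for endpoint in (lo, hi):
        set_parameter(p, param_name, endpoint)
    values = np.linspace(lo, hi, 1 if hi == lo else max(2, int(n_points)))
    rows = []
    for v in values:
        res = evaluate(set_parameter(p, param_name, float(v)), half_cycle_correction)
        rows.append({"parameter": param_name, "value": float(v), **res.to_dict()})
    return pd.DataFrame(rows)


def _incremental_nmb(p: ParameterSet, wtp: float, tau_totals=None) -> float:
    if tau_totals is None:
        tau_totals = strategy_totals(run_strategy(TAU, p))
    sma_totals = strategy_totals(run_strategy(SMA, p))
    return net_monetary_benefit(*sma_totals, wtp) - net_monetary_benefit(*tau_totals, wtp)


def two_way_threshold(
    p: ParameterSet,
    sensitivity: float,
    wtp: float = 20000.0,
    tol: float = 1e-3,
) -> float:
    """Minimal specificity making SMA at least as good as TAU (by NMB).

    For the given test sensitivity, bisects the incremental NMB of SMA over
    specificity in [0, 1] to within ``tol``.  Returns 0.0 if SMA is
    preferred even at zero specificity, and the sentinel
    :data:`NEVER_PREFERRED` (> 1) if no specificity suffices.  TAU does not
    depend on the test, so it is evaluated once.  Monotonicity of the
    incremental NMB in specificity is checked on a coarse grid; if it fails,
    the function falls back to a fine grid scan, logs every sign crossing,
    and returns the smallest.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValidationError(f"sensitivity must lie in [0, 1], got {sensitivity}")
    base = p.replace(**{"stratifier.sensitivity": sensitivity})
    tau_totals = strategy_totals(run_strategy(TAU, base))

    def f(spec: float) -> float:
        q = base.replace(**{"stratifier.specificity": spec})
        return _incremental_nmb(q, wtp, tau_totals)

    coarse = np.linspace(0.0, 1.0, 11)
    fc = np.array([f(s) for s in coarse])
    if fc[0] >= 0.0:
        return 0.0
    if fc[-1] < 0.0:
        return NEVER_PREFERRED
    if np.any(np.diff(fc) < -1e-9):  # non-monotone: exhaustive scan
        grid = np.linspace(0.0, 1.0, 1001)
        fg = np.array([f(s) for s in grid])
        crossings = grid[1:][(fg[:-1] < 0) & (fg[1:] >= 0)]
        logger.warning(
            "incremental NMB non-monotone in specificity; crossings at %s", crossings
        )
        return float(crossings[0])
    lo, hi = 0.0, 1.0
    i = int(np.searchsorted(fc >= 0.0, True))
    lo, hi = float(coarse[i - 1]), float(coarse[i])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return hi


def tornado(
    p: ParameterSet,
    ranges: dict[str, tuple[float, float]],
    wtp: float = 20000.0,
) -> pd.DataFrame:
    """Incremental NMB of SMA at each parameter's low/high bound.

    One row per parameter with the swept bounds and the resulting
    incremental NMB — the data behind a tornado diagram.
    """
    base_nmb = _incremental_nmb(p, wtp)
    rows = []
    for name, (lo, hi) in ranges.items():
        nmb_lo = _incremental_nmb(set_parameter(p, name, lo), wtp)
        nmb_hi = _incremental_nmb(set_parameter(p, name, hi), wtp)
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "incremental_nmb_low": nmb_lo,
                "incremental_nmb_high": nmb_hi,
                "incremental_nmb_base": base_nmb,
                "swing": abs(nmb_hi - nmb_lo),
            }
        )
    return pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration (cost, QALY) pairs for both strategies."""

    iterations: int
    seed: int
    tau_cost: np.ndarray
    tau_qaly: np.ndarray
    sma_cost: np.ndarray
    sma_qaly: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        n = self.iterations
        return pd.DataFrame(
            {
                "iteration": np.concatenate([np.arange(n), np.arange(n)]),
                "strategy": [TAU] * n + [SMA] * n,
                "cost": np.concatenate([self.tau_cost, self.sma_cost]),
                "qaly": np.concatenate([self.tau_qaly, self.sma_qaly]),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, seed: int = -1) -> "PSAResult":
        tau = df[df["strategy"] == TAU].sort_values("iteration")
        sma = df[df["strategy"] == SMA].sort_values("iteration")
        if len(tau) != len(sma) or len(tau) == 0:
            raise ValidationError("PSA table must hold both strategies per iteration")
        return cls(
            iterations=len(tau),
            seed=seed,
            tau_cost=tau["cost"].to_numpy(),
            tau_qaly=tau["qaly"].to_numpy(),
            sma_cost=sma["cost"].to_numpy(),
            sma_qaly=sma["qaly"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "PSAResult":
        return cls.from_dataframe(pd.read_csv(path), seed=seed)


def run_psa(p: ParameterSet, n_iterations: int, seed: int) -> PSAResult:
    """Joint-uncertainty analysis: sample all distributed parameters, run
    both strategies, repeat.

    Per-iteration substreams are spawned deterministically from the single
    ``seed``, so results are bitwise reproducible.  Any iteration whose
    sampled set fails validation or whose cohort loses mass aborts with the
    iteration index.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_iterations)
    tau_c = np.empty(n_iterations)
    tau_q = np.empty(n_iterations)
    sma_c = np.empty(n_iterations)
    sma_q = np.empty(n_iterations)
    for i, s in enumerate(child_seeds):
        try:
            draw = sample_parameters(p, int(s))
            tau_c[i], tau_q[i] = strategy_totals(run_strategy(TAU, draw))
            sma_c[i], sma_q[i] = strategy_totals(run_strategy(SMA, draw))
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
    return PSAResult(
        iterations=n_iterations,
        seed=seed,
        tau_cost=tau_c,
        tau_qaly=tau_q,
        sma_cost=sma_c,
        sma_qaly=sma_q,
    )


@dataclass(frozen=True)
class CEAC:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    p_tau: np.ndarray
    p_sma: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "p_TAU": self.p_tau, "p_SMA": self.p_sma}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def default_wtp_grid() -> np.ndarray:
    """GBP 0 to 50,000 per QALY in GBP 500 steps."""
    return np.arange(0.0, 50000.0 + 1, 500.0)


def build_ceac(psa: PSAResult, wtp_grid=None) -> CEAC:
    """Probability each strategy has the strictly greatest net monetary
    benefit at each willingness-to-pay value; exact ties split equally."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValidationError("willingness-to-pay grid is empty")
    nmb_tau = wtp[:, None] * psa.tau_qaly[None, :] - psa.tau_cost[None, :]
    nmb_sma = wtp[:, None] * psa.sma_qaly[None, :] - psa.sma_cost[None, :]
    sma_wins = (nmb_sma > nmb_tau).mean(axis=1)
    ties = (nmb_sma == nmb_tau).mean(axis=1)
    p_sma = sma_wins + 0.5 * ties
    return CEAC(wtp_grid=wtp, p_tau=1.0 - p_sma, p_sma=p_sma)
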