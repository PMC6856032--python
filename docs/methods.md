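# Methods

## Model structure

The model is a deterministic cohort Markov model over eleven mutually
exclusive health states, advanced in one-year cycles. A state encodes both
clinical status (stable remission vs active psychosis/relapse) and the
patient's position in the treatment sequence (on a conventional
antipsychotic, on clozapine, on a post-clozapine conventional
antipsychotic, non-adherent and untreated, switching off clozapine after
intolerable adverse events, or dead). Because the position is in the state,
deterministic sequences — "one failed year on the second-line drug, then
switch to clozapine" — are expressed with time-homogeneous transition
matrices; no cycle-dependent matrices are needed.

Each strategy is expanded into weighted *strata*, one per combination of
response subgroup and test result, each with its own matrix and starting
state:

| stratum | start | pathway |
|---|---|---|
| AP2 responder on AP (TAU; SMA true positive) | stable on AP | stays, subject to non-adherence |
| clozapine responder (TAU; SMA false positive) | relapse on AP | 1 relapse year, then stable on clozapine |
| non-responder (TAU; SMA false positive) | relapse on AP | relapse on AP → on clozapine → on post-clozapine AP, indefinitely |
| SMA true negative, clozapine responder | stable on clozapine | the strategy's benefit: clozapine one cycle earlier |
| SMA true negative, non-responder | relapse on clozapine | → relapse on post-clozapine AP |
| SMA false negative, responds to clozapine (71.16%) | stable on clozapine | stays on clozapine |
| SMA false negative, fails clozapine (28.84%) | relapse on clozapine | 1 lost year, then responds on a post-clozapine AP |

Negative/positive non-AP2 cells are split into clozapine responders vs
non-responders at their relative prevalence. Non-responders have no
recovery route once all three lines are exhausted.

Three stochastic decorations are applied to every matrix, in order:
clozapine intolerance (stable-on-clozapine → switching state → a
post-clozapine antipsychotic whose flavour depends on whether the patient
would respond to it), non-adherence (stable → untreated-stable → untreated
relapse → return to the same drug; clozapine gets a lower probability than
conventional drugs), and mortality (every living state → dead, with the
on-clozapine death probability scaled by a multiplier below 1; rows are
rescaled to stay stochastic, and the dead row stays identity).

Rewards: stable states earn the annual remission cost and the stable
utility; relapse-type states (including the switching and assessment
states) earn the active-psychosis cost and the relapse utility. Adverse
events are folded in as expected-value adjustments per drug class — utility
minus Σ P(AE)·decrement, cost plus Σ P(AE)·cost — rather than as explicit
states, keeping the state count fixed; neutropenia risk and the annual
blood-monitoring cost apply to clozapine states only. Rewards accrue on
cycle-start occupancy, so cycle 0 earns a full undiscounted year; the
discount factor is 1/(1+r)^t. No half-cycle correction is applied by
default (a switchable `half_cycle_correction` flag implements the
mean-of-endpoints variant). The `initial_assessment` state is part of the
enumeration for custom pathways but unoccupied in the default strategies:
making every stratum spend cycle 0 being assessed would delay both arms by
a year and obscure the one-cycle-earlier mechanism, so the test
administration fee is instead charged as a per-stratum one-off cost at
cycle 0 of every SMA stratum. General one-off costs on state entry are
supported by the engine (charged on inflow, at the entry cycle's discount
factor).

## Parameters

Point values and sweep ranges for the documented parameters: test
sensitivity and specificity 0.60 each (fixed by assumption, explored 0–1 in
the two-way analysis); subgroup mix 16.67 / 62.50 / 20.83% (AP2 responder / clozapine responder /
non-responder) with a joint Dirichlet(21.0, 5.6, 7.0) prior — concentrations
ordered (clozapine responder, AP2 responder, non-responder) — whose
normalized values reproduce those means; P(false negative responds to clozapine) 0.7116; test cost £500
(£100–1,000); annual active-psychosis cost £39,141; annual remission cost
£15,086 (£10,000–39,141); relapse utility 0.4790 (SD 0.0330); stable
utility 0.8650 (SD 0.0210); discount rate 3.5%/yr (0–5%); 80 cycles
(10–100). Costs are 2017 GBP; no inflation logic exists in the engine.

The detailed pathway parameters are not published; the package ships
documented stand-ins, each flagged `"assumption, not source-reported"` in
`stratcea.params.PROVENANCE`: adverse-event probabilities (conventional:
weight gain 0.15, acute EPS 0.10, diabetes 0.04; clozapine: weight gain
0.45, acute EPS 0.02, diabetes 0.12, neutropenia 0.01), utility decrements
(0.04/0.07/0.06/0.10) and annual AE costs (£200/£300/£1,500/£3,000),
clozapine monitoring £400/yr, annual non-adherence 0.08 (conventional) vs
0.05 (clozapine), P(relapse if non-adherent) 0.70, clozapine intolerance
0.04/yr, background mortality 0.02/yr with a clozapine multiplier of 0.95.
Two qualitative constraints anchored these choices: clozapine must carry a
higher adherence rate, more weight gain/diabetes, less acute EPS, and a
monitoring burden than conventional drugs; and an AP2 responder misrouted
onto clozapine must end up *near-neutral with a small net loss* — without
the second constraint the model degenerates (clozapine becomes best for
everyone and the specificity thresholds collapse to zero, contradicting the
threshold structure the analysis is built to exhibit). The mortality
multiplier is deliberately mild because most of clozapine's observed
survival advantage is mediated by treatment response, which the state
structure already captures. All stand-ins are single constants in
`params.DEFAULTS`, trivially replaced if the source values are obtained.

## Sampling and sensitivity analysis

PSA distributions are fitted by the method of moments: Beta shapes from
`ν = m(1−m)/s² − 1`, `α = mν`, `β = (1−m)ν` (feasible iff `s² < m(1−m)`);
Gamma `shape = m²/s²`, `scale = s²/m`. The subgroup mix is drawn jointly
from its Dirichlet so it stays on the simplex. The test's operating
characteristics, the discount rate and the cycle count are fixed and never
sampled. Draw order is deterministic (mix first, then sorted names) and
per-iteration seeds are spawned from one `SeedSequence`, making PSA output
bitwise reproducible for a given seed.

One-way sweeps re-run both strategies over a parameter grid; sweeping a mix
component rebalances the other two proportionally (the only well-defined
reading of a one-way range on a simplex component) and rescales the
Dirichlet counts to match. The two-way threshold bisects the incremental
NMB of SMA over specificity to 1e-3, evaluating TAU once (it does not
depend on the test); monotonicity is checked on a coarse grid with an
exhaustive-scan fallback that reports all crossings. CEAC optimality is
maximal NMB with exact ties split equally; the default WTP grid is
£0–50,000 in £500 steps.

## Numerical choices

Occupancy is propagated by vector–matrix products; a mass drift above 1e-6
raises an integrity error (row sums are validated to 1e-9 at construction).
Degenerate inputs are handled explicitly: zero-weight strata are dropped,
zero-width one-way ranges return the single base-case row, a mix component
of 1 leaves nothing to rebalance and splits the remainder equally, and the
threshold search returns 0 when SMA is preferred at zero specificity and a
sentinel of 2 when no specificity suffices.

## What the defaults do and do not show

The shipped base case reproduces every documented point value exactly and
the documented qualitative results: SMA dominates TAU (here −£4,062, +0.085
QALYs), dominance survives the documented one-way ranges except where it
structurally cannot (see limitations), the minimal cost-effective
specificity falls as sensitivity rises (18.1% at sensitivity 0 vs 11.3% at
0.5, at £20,000/QALY), and the PSA favours SMA at all WTP values.
Absolute totals, exact thresholds and exact CEAC probabilities depend on
the stand-in defaults and should not be read as estimates for any real
health system. Problem sizes used in the shipped analyses — 80-cycle
horizon, 5,000 PSA iterations in the reproduction script, 1,001-point
threshold scans — are the package's own defaults and are configurable.

## Known limitations

- Cohort-level only; no microsimulation, dose titration, or more than
  three treatment lines.
- One relapse cost for all drug lines; societal costs excluded.
- Clozapine intolerance allows a single switch; conventional-antipsychotic
  intolerance is not modelled, a simplification that works against the
  stratified strategy.
- In the false-negative-on-clozapine stratum, only the clozapine stable
  state carries the non-adherence loop: the shared non-adherent state pair
  can encode one return drug per matrix, so patients who later switch to a
  post-clozapine antipsychotic after intolerance (≤ 4%/yr of a stratum that
  is itself ~4.7% of the cohort) do not get a second loop.
- Dominance of the stratified strategy cannot survive two extremes of the
  documented one-way ranges, under any cost assignment: with no clozapine
  responders in the population the test has no beneficiary (SMA is then TAU
  plus the test cost plus misrouting), and with the remission cost equal to
  the relapse cost early clozapine saves nothing to offset the test and
  monitoring costs (SMA still gains QALYs and remains preferred at
  £20,000/QALY, but is no longer strictly dominant).
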