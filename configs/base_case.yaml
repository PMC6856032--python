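# Base-case parameter set: a 60%/60% predictive test on a cohort of
# schizophrenia patients who failed a first-line antipsychotic.
# Values flagged "assumption, not source-reported" in stratcea.params.PROVENANCE are
# documented stand-ins for the detailed appendix parameters; edit freely.
adverse_event_probs:
  ap:
    acute_eps: 0.1
    diabetes: 0.04
    weight_gain: 0.15
  clz:
    acute_eps: 0.02
    diabetes: 0.12
    neutropenia: 0.01
    weight_gain: 0.45
ae_costs:
  acute_eps: 300.0
  diabetes: 1500.0
  neutropenia: 3000.0
  weight_gain: 200.0
ae_utility_decrements:
  acute_eps: 0.07
  diabetes: 0.06
  neutropenia: 0.1
  weight_gain: 0.04
clz_monitoring_cost: 400.0
cost_relapse_year: 39141.0
cost_remission_year: 15086.0
cost_test: 500.0
discount_rate: 0.035
distributions:
  adverse_event_probs.ap.acute_eps:
    kind: beta_mean_sd
    mean: 0.1
    sd: 0.05
  adverse_event_probs.ap.diabetes:
    kind: beta_mean_sd
    mean: 0.04
    sd: 0.02
  adverse_event_probs.ap.weight_gain:
    kind: beta_mean_sd
    mean: 0.15
    sd: 0.075
  adverse_event_probs.clz.acute_eps:
    kind: beta_mean_sd
    mean: 0.02
    sd: 0.01
  adverse_event_probs.clz.diabetes:
    kind: beta_mean_sd
    mean: 0.12
    sd: 0.06
  adverse_event_probs.clz.neutropenia:
    kind: beta_mean_sd
    mean: 0.01
    sd: 0.005
  adverse_event_probs.clz.weight_gain:
    kind: beta_mean_sd
    mean: 0.45
    sd: 0.225
  ae_costs.acute_eps:
    kind: gamma_mean_sd
    mean: 300.0
    sd: 150.0
  ae_costs.diabetes:
    kind: gamma_mean_sd
    mean: 1500.0
    sd: 750.0
  ae_costs.neutropenia:
    kind: gamma_mean_sd
    mean: 3000.0
    sd: 1500.0
  ae_costs.weight_gain:
    kind: gamma_mean_sd
    mean: 200.0
    sd: 100.0
  ae_utility_decrements.acute_eps:
    kind: beta_mean_sd
    mean: 0.07
    sd: 0.035
  ae_utility_decrements.diabetes:
    kind: beta_mean_sd
    mean: 0.06
    sd: 0.03
  ae_utility_decrements.neutropenia:
    kind: beta_mean_sd
    mean: 0.1
    sd: 0.05
  ae_utility_decrements.weight_gain:
    kind: beta_mean_sd
    mean: 0.04
    sd: 0.02
  clz_monitoring_cost:
    kind: gamma_mean_sd
    mean: 400.0
    sd: 200.0
  cost_relapse_year:
    kind: gamma_mean_sd
    mean: 39141.0
    sd: 19570.5
  cost_remission_year:
    kind: gamma_mean_sd
    mean: 15086.0
    sd: 7543.0
  cost_test:
    kind: gamma_mean_sd
    mean: 500.0
    sd: 250.0
  discount_rate:
    kind: fixed
  mix:
    counts:
    - 21.0
    - 5.6
    - 7.0
    kind: dirichlet_counts
  mortality.clz_multiplier:
    kind: beta_mean_sd
    mean: 0.95
    sd: 0.025
  mortality.p_death:
    kind: beta_mean_sd
    mean: 0.02
    sd: 0.01
  n_cycles:
    kind: fixed
  nonadherence_probs.ap:
    kind: beta_mean_sd
    mean: 0.08
    sd: 0.04
  nonadherence_probs.clz:
    kind: beta_mean_sd
    mean: 0.05
    sd: 0.025
  p_clz_intolerance:
    kind: beta_mean_sd
    mean: 0.04
    sd: 0.02
  p_fn_clz_response:
    kind: beta_mean_sd
    mean: 0.7116
    sd: 0.3558
  p_relapse_if_nonadherent:
    kind: beta_mean_sd
    mean: 0.7
    sd: 0.35
  stratifier.sensitivity:
    kind: fixed
  stratifier.specificity:
    kind: fixed
  utility_relapse:
    kind: beta_mean_sd
    mean: 0.479
    sd: 0.033
  utility_stable:
    kind: beta_mean_sd
    mean: 0.865
    sd: 0.021
mix:
  p_ap2: 0.1667
  p_clz: 0.625
  p_nonresp: 0.2083
mortality:
  by_state: {}
  clz_multiplier: 0.95
  p_death: 0.02
n_cycles: 80
nonadherence_probs:
  ap: 0.08
  clz: 0.05
p_clz_intolerance: 0.04
p_fn_clz_response: 0.7116
p_relapse_if_nonadherent: 0.7
stratifier:
  sensitivity: 0.6
  specificity: 0.6
utility_relapse: 0.479
utility_stable: 0.865
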