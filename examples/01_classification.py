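"""How an imperfect predictive test splits the cohort.

A stratifier with 60% sensitivity and 60% specificity is applied to a
population in which 16.67% of patients would respond to a second-line
conventional antipsychotic (AP2 responders).  The four cells say who is
routed where: test-positives try the conventional drug first, test-negatives
go straight to clozapine.
"""

import stratcea as sc

p = sc.make_base_case()
fr = sc.classify_cohort(p.stratifier, p.mix.p_ap2)

print(f"true positives   {fr.tp:7.2%}  (AP2 responders, correctly sent to AP2)")
print(f"false positives  {fr.fp:7.2%}  (non-responders to AP2, sent to AP2 anyway)")
print(f"true negatives   {fr.tn:7.2%}  (non-AP2-responders, sent straight to clozapine)")
print(f"false negatives  {fr.fn:7.2%}  (AP2 responders, sent to clozapine unnecessarily)")
print(f"test positive    {fr.p_positive:7.2%}   test negative  {fr.p_negative:7.2%}")

on_clz, rerouted = sc.split_false_negatives(fr.fn, p.p_fn_clz_response)
print(
    f"\nOf the false negatives, {p.p_fn_clz_response:.2%} respond to clozapine and "
    f"stay on it ({on_clz:.2%} of the cohort);\nthe remaining {rerouted:.2%} fail "
    "clozapine, lose a year, and are then rerouted to an AP2 they respond to."
)
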