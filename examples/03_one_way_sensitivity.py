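"""One-way sensitivity analysis: sweep one parameter, hold the rest.

Sweeps the price of the predictive test over its plausible £100-£1,000
range.  Because the test is administered once per patient at entry, the
incremental cost of the stratified strategy moves £1 for £1 with the price;
the verdict column shows whether dominance survives.
"""

import stratcea as sc

p = sc.make_base_case()
table = sc.one_way_sa(p, "cost_test", (100.0, 1000.0), n_points=10)
cols = ["value", "incremental_cost", "incremental_qaly", "verdict"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
print(
    "\nEach row is a full re-run of both strategies with the test priced at\n"
    "'value'; the QALY gain never changes (the test's accuracy is fixed), so\n"
    "only the cost column moves."
)
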