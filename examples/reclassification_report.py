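"""Cross-edition reclassification on the deterministic 546-patient cohort.

Builds the fixture cohort, classifies it under both editions and prints
the transition matrix, the reclassified/worsened fractions, and the
reasoned report (which molecular feature drove each transition).
"""

from eln_aml import (
    ambiguity_census,
    build_reclassification_fixture,
    build_transition_table,
    classify_cohort,
    percent,
    worsened_fraction,
)

cohort = build_reclassification_fixture()
a17 = classify_cohort(cohort, 2017)
a22 = classify_cohort(cohort, 2022)
t = build_transition_table(a17, a22, cohort)

print("Transition matrix (rows: 2017 ELN, columns: 2022 ELN):")
print(t.counts.to_string())
print(f"\nreclassified: {t.n_reclassified}/{t.n} = {percent(t.n_reclassified, t.n)}%")
print(f"moved to a worse prognosis group: {worsened_fraction(t)}%")
n_amb, pct_amb = ambiguity_census(a22)
print(f"matched >1 category under 2022 rules: {n_amb} ({pct_amb}%)\n")
print("Reasoned transitions (count, %, molecular feature, 2017 -> 2022):")
for frm, to, label, c, pct in t.reasons:
    print(f"  {c:3d} ({pct:4.1f}%)  {label:60s} {frm} -> {to}")
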