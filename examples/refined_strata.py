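"""The proposed post-2022 refinements on the fixture cohort.

Applies the very-adverse stratum (inv(3), mutated TP53, CK+TP53) and the
MDS-gene-burden reallocation (a single mutated MDS-related gene with no
other adverse lesion moves down to intermediate) and prints how the
546-patient partition shifts.
"""

from collections import Counter

from eln_aml import (
    build_reclassification_fixture,
    classify_cohort,
    refine_cohort,
)

cohort = build_reclassification_fixture()
a22 = classify_cohort(cohort, 2022)
refined = refine_cohort(cohort, a22, very_adverse=True, mds_burden=True)

base = Counter(a.resolved for a in a22)
after = Counter(r.refined_category for r in refined)
print("2022 partition:         ", dict(base))
print("after both refinements: ", dict(after))

va = [r for r in refined if r.very_adverse]
print(f"\nvery-adverse stratum: {len(va)} patients")
print("  sub-cases:", Counter(l for r in va for l in r.very_adverse_lesions))

moved = [r for a, r in zip(a22, refined)
         if a.resolved == "adverse" and r.refined_category == "intermediate"]
print(f"single-MDS-gene patients reallocated to intermediate: {len(moved)}")
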