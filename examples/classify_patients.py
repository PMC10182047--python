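"""Classify individual AML patient profiles under both ELN editions.

Builds three small profiles whose risk assignment changed between the
2017 and 2022 revisions and prints the matched lesions, the resolved
category and the ambiguity flag for each.
"""

from eln_aml import MutationCall, PatientProfile, classify_patient, parse_karyotype


def patient(pid, muts, kar):
    return PatientProfile(
        patient_id=pid, age_years=58, sex="female", intensive=True,
        mutations=tuple(muts), karyotype=parse_karyotype(kar),
        os_months=0.0, death=False,
    )


cases = [
    # NPM1 with a low-allelic-ratio FLT3-ITD: favorable in 2017, but the
    # 2022 revision ignores the ratio and files every FLT3-ITD as intermediate
    patient("npm1-itd-low",
            [MutationCall("NPM1", 0.42),
             MutationCall("FLT3", 0.30, itd_allelic_ratio=0.3)],
            "46,XX"),
    # a lone SRSF2 mutation: one of the nine myelodysplasia-related genes
    # promoted to adverse-defining in 2022
    patient("srsf2-only", [MutationCall("SRSF2", 0.35)], "46,XY"),
    # monosomy 7 with FLT3-ITD: matches two 2022 categories; the adverse
    # cytogenetic lesion wins under the default precedence policy
    patient("minus7-itd",
            [MutationCall("FLT3", 0.30, itd_allelic_ratio=0.8)],
            "45,XY,-7"),
]

for p in cases:
    print(f"== {p.patient_id}")
    for edition in (2017, 2022):
        a = classify_patient(p, edition)
        matched = {c: v for c, v in a.matched.items() if v}
        flag = " (ambiguous)" if a.ambiguous else ""
        print(f"  ELN {edition}: {a.resolved}{flag}   matched={matched}")
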