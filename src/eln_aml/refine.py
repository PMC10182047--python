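"""Proposed refinements of the 2022 risk partition.

Two data-driven proposals layered on top of the 2022 engine output:

* a *very adverse* stratum inside the adverse category — inv(3)/t(3;3),
  mutated TP53, or complex karyotype with TP53 — whose members share a
  dismal prognosis;
* reallocation of adverse-risk patients whose only adverse-defining lesion
  is a single mutated myelodysplasia-related gene down to intermediate
  (patients with two or more such genes behave like the rest of the
  adverse group and stay put).

Disabling both refinements reproduces the base 2022 partition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortTable, PatientProfile, count_mds_genes, filter_reportable_variants
from .cytogenetics import derive_findings
from .rules import ADVERSE, INTERMEDIATE, RiskAssignment

__all__ = [
    "VERY_ADVERSE",
    "RefinedAssignment",
    "flag_very_adverse",
    "refine_by_mds_burden",
    "refine_assignment",
    "refine_cohort",
]

VERY_ADVERSE = "very-adverse"


@dataclass
class RefinedAssignment:
    base: RiskAssignment
    very_adverse: bool
    mds_burden: int
    refined_category: str
    #: labelled sub-case of the very-adverse stratum, for re-analysis
    very_adverse_lesions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.very_adverse and self.base.resolved != ADVERSE:
            raise ValueError("very-adverse stratum lies inside 2022 adverse")
        if (self.refined_category == VERY_ADVERSE) != self.very_adverse:
            raise ValueError("refined_category inconsistent with very_adverse flag")


def flag_very_adverse(p: PatientProfile, a: RiskAssignment) -> bool:
    """True iff the patient carries inv(3)/t(3;3) or a mutated TP53.

    Complex karyotype plus TP53 is a labelled sub-case, not an extra
    condition: TP53 dominates regardless of karyotype complexity.
    Only resolved 2022-adverse patients qualify.
    """
    if a.edition != 2022:
        raise ValueError("very-adverse refinement applies to 2022 assignments")
    if a.resolved != ADVERSE:
        return False
    lesions = _very_adverse_lesions(p)
    return bool(lesions)


def _very_adverse_lesions(p: PatientProfile) -> tuple[str, ...]:
    tp53 = p.mutated("TP53")
    f = None if isinstance(p.karyotype, str) else derive_findings(p.karyotype)
    out = []
    if f is not None and f.inv3_t3_3:
        out.append("inv(3)")
    if tp53 and f is not None and f.complex_2022:
        out.append("CK+TP53")
    elif tp53:
        out.append("TP53")
    return tuple(out)


def _mds_only_adverse(a: RiskAssignment) -> bool:
    adverse = a.matched.get(ADVERSE, [])
    return bool(adverse) and all(lbl.startswith("MDS-gene:") for lbl in adverse)


def refine_by_mds_burden(
    a: RiskAssignment, burden: int, enabled: bool = True
) -> RefinedAssignment:
    """Reallocate single-MDS-gene adverse patients to intermediate.

    ``burden`` is the distinct mutated MDS-gene count
    (:func:`eln_aml.cohort.count_mds_genes`).  Only patients whose adverse
    match consists exclusively of MDS-gene lesions, with burden exactly 1,
    move; any co-occurring non-MDS adverse lesion pins the patient in the
    adverse group.  The reallocation never moves a patient upward.
    """
    category = a.resolved
    if enabled and category == ADVERSE and burden == 1 and _mds_only_adverse(a):
        category = INTERMEDIATE
    return RefinedAssignment(
        base=a, very_adverse=False, mds_burden=burden, refined_category=category
    )


def refine_assignment(
    p: PatientProfile,
    a: RiskAssignment,
    very_adverse: bool = True,
    mds_burden: bool = True,
) -> RefinedAssignment:
    """Apply both refinements (each individually switchable) to one patient.

    The MDS-burden reallocation runs first; the very-adverse flag is
    evaluated on what remains adverse afterwards.
    """
    burden = count_mds_genes(filter_reportable_variants(p.mutations))
    r = refine_by_mds_burden(a, burden, enabled=mds_burden)
    if very_adverse and r.refined_category == ADVERSE and flag_very_adverse(p, a):
        return RefinedAssignment(
            base=a,
            very_adverse=True,
            mds_burden=burden,
            refined_category=VERY_ADVERSE,
            very_adverse_lesions=_very_adverse_lesions(p),
        )
    return r


def refine_cohort(
    cohort: CohortTable,
    assignments: list[RiskAssignment],
    very_adverse: bool = True,
    mds_burden: bool = True,
) -> list[RefinedAssignment]:
    if len(cohort) != len(assignments):
        raise ValueError("cohort and assignments length mismatch")
    return [
        refine_assignment(p, a, very_adverse, mds_burden)
        for p, a in zip(cohort, assignments)
    ]
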