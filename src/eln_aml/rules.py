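"""ELN 2017 and 2022 genetic risk classification engines.

Each engine works in two stages.  :func:`match_defining_lesions` scans a
patient profile against every category-defining rule of the requested
edition and returns the full map ``category -> [lesion labels]`` — a
patient may legitimately match more than one category (e.g. adverse-risk
cytogenetics together with FLT3-ITD under the 2022 rules).
:func:`resolve` then applies an ordered precedence policy to pick the
final category, records the ambiguity flag, and keeps an audit trail of
every fired rule.  Resolution policies are data (ordered lists of rule
classes), so the published tie-breaks are defaults the caller can
override.

Fallback intermediate rules ("cytogenetics neither favorable nor adverse",
NPM1-wild-type without a defining lesion) fire only when no defining
lesion matched; they do not create ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import (
    MDS_GENES,
    CohortTable,
    PatientProfile,
    filter_reportable_variants,
)
from .cytogenetics import CytogeneticFindings, derive_findings

__all__ = [
    "FAVORABLE",
    "INTERMEDIATE",
    "ADVERSE",
    "CATEGORIES",
    "ITD_RATIO_CUTOFF",
    "RiskAssignment",
    "ResolutionPolicy",
    "DEFAULT_POLICY_2017",
    "DEFAULT_POLICY_2022",
    "UnresolvableError",
    "match_defining_lesions",
    "resolve",
    "assign_subset",
    "classify_patient",
    "classify_cohort",
    "ambiguity_census",
]

FAVORABLE = "favorable"
INTERMEDIATE = "intermediate"
ADVERSE = "adverse"
CATEGORIES = (FAVORABLE, INTERMEDIATE, ADVERSE)

#: FLT3-ITD high/low allelic-ratio cutoff used by the 2017 edition.
ITD_RATIO_CUTOFF = 0.5

#: VAF condition on TP53 (2022 guideline option); off by default.
TP53_VAF_THRESHOLD = 0.10


class UnresolvableError(ValueError):
    """The resolution policy cannot break a category tie."""


# --- lesion labels -----------------------------------------------------------
# Cytogenetic adverse lesions, shared vocabulary across editions.
_CYTO_ADVERSE_2017 = (
    ("t_6_9", "t(6;9)"),
    ("t_v_11q23", "t(v;11q23.3)"),
    ("t_9_22", "t(9;22)"),
    ("inv3_t3_3", "inv(3)/t(3;3)"),
    ("del5_minus5", "-5/del(5q)"),
    ("minus7", "-7"),
    ("minus17_abn17p", "-17/abn(17p)"),
)
_CYTO_ADVERSE_2022_EXTRA = (
    ("t_8_16", "t(8;16)"),
    ("t_3q26_v", "t(3q26.2;v)"),
)

ADVERSE_CYTO_LABELS = frozenset(
    lbl for _, lbl in _CYTO_ADVERSE_2017 + _CYTO_ADVERSE_2022_EXTRA
) | {"complex karyotype", "monosomal karyotype"}

CEBPA_BZIP_LABEL = "CEBPA bZIP"
FLT3_ITD_LABEL = "FLT3-ITD"
T9_11_LABEL = "t(9;11)"
OTHER_LABEL = "other"


def label_class(category: str, label: str) -> str:
    """Rule class of a matched lesion label, used by precedence policies."""
    if category == ADVERSE and label in ADVERSE_CYTO_LABELS:
        return "adverse-cytogenetics"
    if category == ADVERSE:
        return "adverse-molecular"
    if category == FAVORABLE and label == CEBPA_BZIP_LABEL:
        return "favorable-cebpa-bzip"
    if category == INTERMEDIATE and label in {FLT3_ITD_LABEL, T9_11_LABEL}:
        return "intermediate-defining"
    return category


@dataclass(frozen=True)
class ResolutionPolicy:
    """Ordered precedence over rule classes; first present class wins."""

    name: str
    order: tuple[str, ...]

    def resolve(self, matched: dict[str, list[str]]) -> tuple[str, str]:
        """Return (category, winning rule class); raise if no class applies."""
        present = {
            label_class(cat, lbl): cat
            for cat in reversed(CATEGORIES)
            for lbl in matched.get(cat, ())
        }
        for cls in self.order:
            if cls in present:
                return present[cls], cls
        raise UnresolvableError(
            f"policy {self.name!r} cannot order categories "
            f"{sorted(k for k, v in matched.items() if v)}"
        )


#: 2017 default: favorable-defining lesions outrank the intermediate-defining
#: ones, which outrank adverse — reproducing both published 2017 resolutions
#: (NPM1 + high-ratio ITD + RUNX1 -> intermediate; high-ratio ITD + biallelic
#: CEBPA -> favorable).
DEFAULT_POLICY_2017 = ResolutionPolicy(
    "eln2017-default",
    (
        "favorable",
        "intermediate-defining",
        "intermediate",
        "adverse-cytogenetics",
        "adverse-molecular",
        "adverse",
    ),
)

#: 2022 default: adverse cytogenetics dominate; CEBPA bZIP beats FLT3-ITD;
#: FLT3-ITD (and t(9;11)) beat molecular adverse lesions — reproducing the
#: published resolutions (adverse-cyto + ITD -> adverse, bZIP + ITD ->
#: favorable) and the intermediate assignment of NPM1/FLT3-ITD patients
#: carrying a single MDS-gene mutation.
DEFAULT_POLICY_2022 = ResolutionPolicy(
    "eln2022-default",
    (
        "adverse-cytogenetics",
        "favorable-cebpa-bzip",
        "intermediate-defining",
        "adverse-molecular",
        "favorable",
        "intermediate",
    ),
)


@dataclass
class RiskAssignment:
    """Outcome of classifying one patient under one edition."""

    edition: int
    matched: dict[str, list[str]]
    resolved: str
    ambiguous: bool
    subset: str | None = None
    audit: list[str] = field(default_factory=list)
    patient_id: str | None = None

    @property
    def matched_categories(self) -> tuple[str, ...]:
        return tuple(c for c in CATEGORIES if self.matched.get(c))


# ---------------------------------------------------------------------------
# stage 1: defining-lesion matching


def _profile_features(p: PatientProfile) -> dict:
    itd = p.flt3_itd
    cebpa = p.cebpa
    return {
        "npm1": p.mutated("NPM1"),
        "itd": itd is not None,
        "itd_ratio": itd.itd_allelic_ratio if itd is not None else None,
        "cebpa_biallelic": bool(cebpa and cebpa.cebpa_biallelic),
        "cebpa_bzip": bool(cebpa and cebpa.cebpa_bzip_inframe),
        "tp53": p.calls("TP53"),
        "mds_genes": sorted({m.gene for m in p.mutations} & MDS_GENES),
        "runx1": p.mutated("RUNX1"),
        "asxl1": p.mutated("ASXL1"),
    }


def _findings(p: PatientProfile) -> CytogeneticFindings | None:
    if isinstance(p.karyotype, str):  # "unknown"
        return None
    return derive_findings(p.karyotype)


def _tp53_adverse(tp53_calls, vaf_threshold: float | None) -> bool:
    if not tp53_calls:
        return False
    if vaf_threshold is None:
        return True
    return any(c.vaf >= vaf_threshold for c in tp53_calls)


def _match_2017(feat: dict, f: CytogeneticFindings | None, tp53_vaf) -> dict:
    fav: list[str] = []
    inter: list[str] = []
    adv: list[str] = []
    ratio = feat["itd_ratio"]
    itd_low_or_absent = not feat["itd"] or ratio < ITD_RATIO_CUTOFF
    itd_high = feat["itd"] and ratio >= ITD_RATIO_CUTOFF

    if f is not None:
        if f.t_8_21:
            fav.append("t(8;21)")
        if f.inv16_t16_16:
            fav.append("inv(16)/t(16;16)")
    if feat["npm1"] and itd_low_or_absent:
        fav.append("NPM1mut without FLT3-ITD or FLT3-ITDlow")
    if feat["cebpa_biallelic"]:
        fav.append("biallelic CEBPA")

    if feat["npm1"] and itd_high:
        inter.append("NPM1mut with FLT3-ITDhigh")
    if f is not None and f.t_9_11:
        inter.append(T9_11_LABEL)

    if f is not None:
        for flag, lbl in _CYTO_ADVERSE_2017:
            if getattr(f, flag):
                adv.append(lbl)
        if f.complex_2017:
            adv.append("complex karyotype")
        if f.monosomal:
            adv.append("monosomal karyotype")
    if not feat["npm1"] and itd_high:
        adv.append("FLT3-ITDhigh without NPM1")
    # RUNX1/ASXL1 do not count as adverse when a favorable-defining lesion
    # co-occurs (guideline footnote).
    if not fav:
        if feat["runx1"]:
            adv.append("RUNX1")
        if feat["asxl1"]:
            adv.append("ASXL1")
    if _tp53_adverse(feat["tp53"], tp53_vaf):
        adv.append("TP53")

    return {FAVORABLE: fav, INTERMEDIATE: inter, ADVERSE: adv}


def _match_2022(feat: dict, f: CytogeneticFindings | None, tp53_vaf) -> dict:
    fav: list[str] = []
    inter: list[str] = []
    adv: list[str] = []

    if f is not None:
        for flag, lbl in _CYTO_ADVERSE_2017 + _CYTO_ADVERSE_2022_EXTRA:
            if getattr(f, flag):
                adv.append(lbl)
        if f.complex_2022:
            adv.append("complex karyotype")
        if f.monosomal:
            adv.append("monosomal karyotype")
    cyto_adverse = bool(adv)

    if f is not None:
        if f.t_8_21:
            fav.append("t(8;21)")
        if f.inv16_t16_16:
            fav.append("inv(16)/t(16;16)")
    # Adverse chromosomal abnormalities define poor outcome irrespective of
    # NPM1 mutations: the NPM1 favorable rule is withheld in their presence.
    if feat["npm1"] and not feat["itd"] and not cyto_adverse:
        fav.append("NPM1mut without FLT3-ITD")
    if feat["cebpa_bzip"]:
        fav.append(CEBPA_BZIP_LABEL)

    if feat["itd"]:
        inter.append(FLT3_ITD_LABEL)
    if f is not None and f.t_9_11:
        inter.append(T9_11_LABEL)

    # MDS-related genes are not adverse markers when a favorable-defining
    # lesion co-occurs; TP53 always counts.
    if not fav:
        for gene in feat["mds_genes"]:
            adv.append(f"MDS-gene:{gene}")
    if _tp53_adverse(feat["tp53"], tp53_vaf):
        adv.append("TP53")

    return {FAVORABLE: fav, INTERMEDIATE: inter, ADVERSE: adv}


def match_defining_lesions(
    p: PatientProfile,
    edition: int,
    tp53_vaf_threshold: float | None = None,
) -> dict[str, list[str]]:
    """Map ``category -> matched defining-lesion labels`` for one patient.

    ``tp53_vaf_threshold`` optionally enables the 2022 guideline's VAF
    condition on TP53 (e.g. ``0.10``); by default any reportable TP53
    variant counts.
    """
    feat = _profile_features(p)
    f = _findings(p)
    if edition == 2017:
        return _match_2017(feat, f, tp53_vaf_threshold)
    if edition == 2022:
        return _match_2022(feat, f, tp53_vaf_threshold)
    raise ValueError(f"unknown edition {edition!r}")


# ---------------------------------------------------------------------------
# stage 2: precedence resolution


def resolve(
    matched: dict[str, list[str]],
    edition: int,
    policy: ResolutionPolicy | None = None,
) -> RiskAssignment:
    """Pick the final category from the matched-lesion map."""
    if policy is None:
        policy = DEFAULT_POLICY_2017 if edition == 2017 else DEFAULT_POLICY_2022
    audit = [
        f"matched {cat}: {lbl}" for cat in CATEGORIES for lbl in matched.get(cat, ())
    ]
    nonempty = [c for c in CATEGORIES if matched.get(c)]
    if not nonempty:
        matched = {FAVORABLE: [], INTERMEDIATE: [OTHER_LABEL], ADVERSE: []}
        audit.append("no defining lesion: fallback intermediate (other)")
        return RiskAssignment(edition, matched, INTERMEDIATE, False, audit=audit)
    if len(nonempty) == 1:
        audit.append(f"single category: {nonempty[0]}")
        return RiskAssignment(edition, matched, nonempty[0], False, audit=audit)
    resolved, cls = policy.resolve(matched)
    audit.append(
        f"ambiguous {'/'.join(nonempty)}: policy {policy.name} -> "
        f"{resolved} via {cls}"
    )
    return RiskAssignment(edition, matched, resolved, True, audit=audit)


# ---------------------------------------------------------------------------
# genetic-subset labels (2022 outcome tables)

FAVORABLE_SUBSETS = (
    "NPM1mut, FLT3-ITD WT",
    "CEBPA-bZIP",
    "inv(16)",
    "t(8;21)",
)
INTERMEDIATE_SUBSETS = (
    "NPM1mut, FLT3-ITD mut",
    "NPM1 WT, FLT3-ITD mut",
    "t(9;11)",
    "Other abnormalities",
)
ADVERSE_SUBSETS = (
    "inv(3)",
    "(-5, -7, -17)",
    "Complex karyotype and TP53",
    "Mutated TP53",
    "Complex karyotype",
    "MDS-mutated genes",
    "t(v;11q23)",
    "t(6;9)",
    "t(9;22)",
)


def assign_subset(p: PatientProfile, a: RiskAssignment) -> str:
    """First-match genetic-subset label within the resolved 2022 category."""
    if a.edition != 2022:
        raise ValueError("genetic subsets are defined for the 2022 edition")
    feat = _profile_features(p)
    f = _findings(p)
    tp53 = bool(feat["tp53"])
    if a.resolved == FAVORABLE:
        if feat["npm1"] and not feat["itd"]:
            return "NPM1mut, FLT3-ITD WT"
        if feat["cebpa_bzip"]:
            return "CEBPA-bZIP"
        if f is not None and f.inv16_t16_16:
            return "inv(16)"
        if f is not None and f.t_8_21:
            return "t(8;21)"
        return "other"
    if a.resolved == INTERMEDIATE:
        if feat["npm1"] and feat["itd"]:
            return "NPM1mut, FLT3-ITD mut"
        if feat["itd"]:
            return "NPM1 WT, FLT3-ITD mut"
        if f is not None and f.t_9_11:
            return "t(9;11)"
        return "Other abnormalities"
    ck = f is not None and f.complex_2022
    if f is not None and f.inv3_t3_3:
        return "inv(3)"
    if f is not None and (f.del5_minus5 or f.minus7 or f.minus17_abn17p):
        return "(-5, -7, -17)"
    if ck and tp53:
        return "Complex karyotype and TP53"
    if tp53:
        return "Mutated TP53"
    if ck:
        return "Complex karyotype"
    if feat["mds_genes"]:
        return "MDS-mutated genes"
    if f is not None and f.t_v_11q23:
        return "t(v;11q23)"
    if f is not None and f.t_6_9:
        return "t(6;9)"
    if f is not None and f.t_9_22:
        return "t(9;22)"
    return "other"


# ---------------------------------------------------------------------------
# cohort-level driver


def classify_patient(
    p: PatientProfile,
    edition: int,
    policy: ResolutionPolicy | None = None,
    tp53_vaf_threshold: float | None = None,
) -> RiskAssignment:
    """Filter, match, resolve and subset-label a single patient."""
    filtered = filter_reportable_variants(p.mutations)
    if len(filtered) != len(p.mutations):
        from dataclasses import replace

        p = replace(p, mutations=filtered)
    matched = match_defining_lesions(p, edition, tp53_vaf_threshold)
    a = resolve(matched, edition, policy)
    a.patient_id = p.patient_id
    if edition == 2022:
        a.subset = assign_subset(p, a)
    return a


def classify_cohort(
    cohort: CohortTable,
    edition: int,
    policy: ResolutionPolicy | None = None,
    tp53_vaf_threshold: float | None = None,
) -> list[RiskAssignment]:
    """Classify every patient in order; errors carry the patient id."""
    out = []
    for p in cohort:
        try:
            out.append(classify_patient(p, edition, policy, tp53_vaf_threshold))
        except Exception as e:
            raise type(e)(f"patient {p.patient_id}: {e}") from e
    return out


def ambiguity_census(assignments: list[RiskAssignment]) -> tuple[int, float]:
    """(count, percent) of patients matching more than one category."""
    from .compare import percent  # local import to avoid cycle

    n_amb = sum(1 for a in assignments if a.ambiguous)
    return n_amb, percent(n_amb, len(assignments)) if assignments else 0.0
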