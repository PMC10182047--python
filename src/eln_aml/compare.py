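"""Cross-edition reclassification analysis.

Builds the 3x3 transition table between the 2017 and 2022 risk
assignments of one cohort, derives the reasoned reclassification report
(molecular feature behind each transition, phrased as in the published
reclassification table so reports are diffable), computes the worsened /
improved / stable fractions, tests covariate association with the risk
distribution, and exports a Sankey-ready flow file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MDS_GENES, CohortTable, PatientProfile
from .cytogenetics import derive_findings
from .rules import ADVERSE, CATEGORIES, FAVORABLE, INTERMEDIATE, ITD_RATIO_CUTOFF, RiskAssignment

__all__ = [
    "percent",
    "TransitionTable",
    "build_transition_table",
    "worsened_fraction",
    "improved_fraction",
    "stable_fraction",
    "subgroup_distribution",
    "export_sankey",
]

_RANK = {FAVORABLE: 0, INTERMEDIATE: 1, ADVERSE: 2}


def percent(count: int, n: int, decimals: int = 1) -> float:
    """100*count/n rounded half-up to the printed precision."""
    if n == 0:
        raise ZeroDivisionError("empty cohort")
    q = Decimal(10) ** -decimals
    return float(Decimal(100 * count / n).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TransitionTable:
    """2017 x 2022 cross-classification with reasoned transitions."""

    counts: pd.DataFrame  # index: 2017 category, columns: 2022 category
    n: int
    reasons: list[tuple[str, str, str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.n:
            raise ValueError("transition counts do not sum to n")

    @property
    def n_reclassified(self) -> int:
        m = self.counts.to_numpy()
        return int(m.sum() - np.trace(m))

    def marginals(self, edition: int) -> pd.Series:
        if edition == 2017:
            return self.counts.sum(axis=1)
        if edition == 2022:
            return self.counts.sum(axis=0)
        raise ValueError(f"unknown edition {edition}")


# -- reclassification reasons, phrased as in the published report ------------

def _transition_reason(
    p: PatientProfile, a17: RiskAssignment, a22: RiskAssignment
) -> str:
    itd = p.flt3_itd
    ratio = itd.itd_allelic_ratio if itd else None
    cebpa = p.cebpa
    mds = {m.gene for m in p.mutations} & MDS_GENES
    f = None if isinstance(p.karyotype, str) else derive_findings(p.karyotype)
    hyperdiploid = f is not None and f.hyperdiploid_trisomies_only
    frm, to = a17.resolved, a22.resolved

    if frm == FAVORABLE and to == INTERMEDIATE:
        if p.mutated("NPM1") and itd and ratio < ITD_RATIO_CUTOFF:
            return "Mutated NPM1 with low allelic ratio FLT3-ITD"
    if frm == FAVORABLE and to == ADVERSE:
        if cebpa and cebpa.cebpa_biallelic and not cebpa.cebpa_bzip_inframe and mds:
            return "Biallelic mutated CEBPA (not bZIP domain) + mutated MDS genes"
    if frm == INTERMEDIATE and to == FAVORABLE:
        if cebpa and cebpa.cebpa_bzip_inframe:
            return "bZIP in frame mutated CEBPA (only one CEBPA mutation)"
    if frm == INTERMEDIATE and to == ADVERSE:
        if mds and not (mds & {"RUNX1", "ASXL1"}):
            return "Mutated MDS genes (not RUNX1 and ASXL1)"
    if frm == ADVERSE and to == INTERMEDIATE:
        if hyperdiploid and itd and ratio >= ITD_RATIO_CUTOFF:
            return "Hyperdiploid karyotype + high allelic ratio FLT3-ITD"
        if hyperdiploid:
            return "Hyperdiploid karyotype"
        if itd and ratio >= ITD_RATIO_CUTOFF:
            return "High allelic ratio FLT3-ITD"
    return "Other"


def build_transition_table(
    a17: list[RiskAssignment],
    a22: list[RiskAssignment],
    profiles: CohortTable | list[PatientProfile] | None = None,
) -> TransitionTable:
    """Cross-classify per-patient assignments from the two editions.

    Both lists must cover the same patients in the same order (checked via
    the patient ids the classifier stamps on each assignment).  Passing the
    source profiles enables the reasoned transition report.
    """
    if len(a17) != len(a22):
        raise ValueError("assignment lists differ in length")
    for x, y in zip(a17, a22):
        if x.patient_id != y.patient_id:
            raise ValueError(
                f"patient id mismatch between editions: {x.patient_id!r} vs {y.patient_id!r}"
            )
    n = len(a17)
    counts = pd.DataFrame(
        0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int
    )
    for x, y in zip(a17, a22):
        counts.loc[x.resolved, y.resolved] += 1

    reasons: list[tuple[str, str, str, int, float]] = []
    if profiles is not None:
        plist = list(profiles)
        if len(plist) != n:
            raise ValueError("profiles length mismatch")
        tally: dict[tuple[str, str, str], int] = {}
        for p, x, y in zip(plist, a17, a22):
            if x.resolved == y.resolved:
                continue
            key = (x.resolved, y.resolved, _transition_reason(p, x, y))
            tally[key] = tally.get(key, 0) + 1
        reasons = [
            (frm, to, label, c, percent(c, n))
            for (frm, to, label), c in sorted(
                tally.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
    return TransitionTable(counts=counts, n=n, reasons=reasons)


def worsened_fraction(t: TransitionTable) -> float:
    """Percent of patients moved to a worse prognosis group (1 decimal)."""
    m = t.counts
    worse = sum(
        int(m.loc[a, b])
        for a in CATEGORIES
        for b in CATEGORIES
        if _RANK[b] > _RANK[a]
    )
    return percent(worse, t.n)


def improved_fraction(t: TransitionTable) -> float:
    m = t.counts
    better = sum(
        int(m.loc[a, b])
        for a in CATEGORIES
        for b in CATEGORIES
        if _RANK[b] < _RANK[a]
    )
    return percent(better, t.n)


def stable_fraction(t: TransitionTable) -> float:
    return percent(int(np.trace(t.counts.to_numpy())), t.n)


# ---------------------------------------------------------------------------

@dataclass
class SubgroupDistribution:
    by: str
    counts: pd.DataFrame  # strata x categories
    column_percents: pd.DataFrame
    chi2: float
    p: float  # NaN when undefined (empty stratum)


def subgroup_distribution(
    assignments: list[RiskAssignment],
    profiles: CohortTable | list[PatientProfile],
    by: str,
) -> SubgroupDistribution:
    """Risk-category distribution across a binary covariate.

    ``by`` is ``"sex"`` (male/female) or ``"age65"`` (<65 / >=65 years).
    Returns the contingency counts, within-stratum percents, and the
    Pearson chi-square test (no continuity correction).  With an empty
    stratum or category margin, p is reported as NaN.
    """
    plist = list(profiles)
    if len(plist) != len(assignments):
        raise ValueError("profiles and assignments length mismatch")
    if by == "sex":
        strata = ["male", "female"]
        key = lambda p: p.sex
    elif by == "age65":
        strata = ["<65", ">=65"]
        key = lambda p: "<65" if p.age_years < 65 else ">=65"
    else:
        raise ValueError(f"unsupported covariate {by!r}")
    counts = pd.DataFrame(0, index=strata, columns=list(CATEGORIES), dtype=int)
    for p, a in zip(plist, assignments):
        counts.loc[key(p), a.resolved] += 1
    row_tot = counts.sum(axis=1)
    pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100
    m = counts.to_numpy()
    m = m[:, m.sum(axis=0) > 0]  # categories nobody occupies carry no signal
    if m.shape[1] < 2 or (m.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        res = stats.chi2_contingency(m, correction=False)
        chi2, p = float(res.statistic), float(res.pvalue)
    return SubgroupDistribution(by=by, counts=counts, column_percents=pct, chi2=chi2, p=p)


def export_sankey(t: TransitionTable, path: str | Path) -> dict:
    """Write a Sankey flow file (6 nodes, one link per nonzero cell)."""
    if t.n == 0:
        raise ValueError("cannot export an empty transition table")
    nodes = [f"2017 {c}" for c in CATEGORIES] + [f"2022 {c}" for c in CATEGORIES]
    links = [
        {
            "source": nodes.index(f"2017 {a}"),
            "target": nodes.index(f"2022 {b}"),
            "value": int(t.counts.loc[a, b]),
        }
        for a in CATEGORIES
        for b in CATEGORIES
        if t.counts.loc[a, b] > 0
    ]
    payload = {"nodes": [{"name": n} for n in nodes], "links": links, "n": t.n}
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
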