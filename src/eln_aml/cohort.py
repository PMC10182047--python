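"""Patient-level domain types, cohort TSV/CSV I/O and the variant filter.

Schema
------
One row per patient, tab- or comma-separated, with columns

``patient_id  age_years  sex  intensive  midostaurin  karyotype  mutations
os_months  death``

``mutations`` is a semicolon-separated list of tokens
``GENE:vaf:pathogenic:hotspot[:key=value...]`` where vaf may be given as a
fraction (``0.42``) or percentage (``42%``), booleans are ``1``/``0``, and
the optional keys are ``itd_ratio`` (FLT3 only), ``biallelic`` and ``bzip``
(CEBPA only).  ``karyotype`` is a restricted ISCN string (see
:mod:`eln_aml.cytogenetics`) or the literal ``unknown``.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .cytogenetics import Karyotype, KaryotypeError, parse_karyotype

__all__ = [
    "PANEL_GENES",
    "MDS_GENES",
    "MutationCall",
    "PatientProfile",
    "CohortTable",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "filter_reportable_variants",
    "count_mds_genes",
]

#: 32-gene myeloid NGS panel used for risk-relevant mutation calls.
PANEL_GENES = frozenset(
    {
        "ASXL1", "BCOR", "BRAF", "CALR", "CBL", "CEBPA", "CSF3R", "DNMT3A",
        "ETV6", "EZH2", "FLT3", "GATA2", "HRAS", "IDH1", "IDH2", "JAK2",
        "KIT", "KRAS", "MPL", "NPM1", "NRAS", "PTPN11", "RUNX1", "SETBP1",
        "SF3B1", "SRSF2", "STAG2", "TET2", "TP53", "U2AF1", "WT1", "ZRSR2",
    }
)

#: Myelodysplasia-related genes, adverse-defining under the 2022 revision.
MDS_GENES = frozenset(
    {"ASXL1", "BCOR", "EZH2", "RUNX1", "SF3B1", "SRSF2", "STAG2", "U2AF1", "ZRSR2"}
)


class CohortValidationError(ValueError):
    """A row or field violated the cohort schema."""


@dataclass(frozen=True)
class MutationCall:
    """One reported somatic variant.

    A FLT3 internal tandem duplication is represented by a FLT3 call whose
    ``itd_allelic_ratio`` is set (mutant/wild-type allele ratio, >= 0);
    a FLT3 call without it is a non-ITD variant (e.g. TKD).  CEBPA calls
    carry the allelic state and whether the variant is an in-frame change
    in the bZIP domain; both are input annotations, not computed here.
    """

    gene: str
    vaf: float
    pathogenic: bool = True
    hotspot: bool = False
    itd_allelic_ratio: float | None = None
    cebpa_biallelic: bool | None = None
    cebpa_bzip_inframe: bool | None = None

    def __post_init__(self) -> None:
        if self.gene != self.gene.upper() or self.gene not in PANEL_GENES:
            raise CohortValidationError(f"unknown panel gene {self.gene!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise CohortValidationError(f"vaf {self.vaf} outside [0, 1]")
        if self.itd_allelic_ratio is not None:
            if self.gene != "FLT3":
                raise CohortValidationError("itd_allelic_ratio is FLT3-only")
            if self.itd_allelic_ratio < 0:
                raise CohortValidationError("itd_allelic_ratio must be >= 0")
        if (
            self.cebpa_biallelic is not None or self.cebpa_bzip_inframe is not None
        ) and self.gene != "CEBPA":
            raise CohortValidationError("cebpa_* annotations are CEBPA-only")

    @property
    def is_itd(self) -> bool:
        return self.gene == "FLT3" and self.itd_allelic_ratio is not None


@dataclass(frozen=True)
class PatientProfile:
    """One patient's demographic, genetic, treatment and survival record."""

    patient_id: str
    age_years: int
    sex: str
    intensive: bool
    mutations: tuple[MutationCall, ...]
    karyotype: Karyotype | str  # parsed karyotype or the literal "unknown"
    os_months: float
    death: bool
    midostaurin: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise CohortValidationError("pediatric patients (<18 y) are excluded")
        if self.sex not in {"male", "female"}:
            raise CohortValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.os_months < 0:
            raise CohortValidationError("os_months must be >= 0")
        if isinstance(self.karyotype, str) and self.karyotype != "unknown":
            raise CohortValidationError(
                "karyotype must be a Karyotype or the literal 'unknown'"
            )
        if sum(1 for m in self.mutations if m.is_itd) > 1:
            raise CohortValidationError("at most one FLT3-ITD record per patient")
        if sum(1 for m in self.mutations if m.gene == "CEBPA") > 1:
            raise CohortValidationError("at most one CEBPA record per patient")

    def calls(self, gene: str) -> tuple[MutationCall, ...]:
        return tuple(m for m in self.mutations if m.gene == gene)

    def mutated(self, gene: str) -> bool:
        return any(m.gene == gene for m in self.mutations)

    @property
    def flt3_itd(self) -> MutationCall | None:
        for m in self.mutations:
            if m.is_itd:
                return m
        return None

    @property
    def cebpa(self) -> MutationCall | None:
        for m in self.mutations:
            if m.gene == "CEBPA":
                return m
        return None


@dataclass
class CohortTable:
    profiles: list[PatientProfile]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)


# ---------------------------------------------------------------------------
# variant reporting filter

def filter_reportable_variants(
    mutations: Iterable[MutationCall],
) -> tuple[MutationCall, ...]:
    """Apply the consensus variant-reporting rule.

    A variant is reportable if it is pathogenic (or probably damaging) with
    VAF >= 5%, or lies in a known hotspot with VAF in the 1-5% range.
    Idempotent; output is always a subset of the input.
    """
    return tuple(
        m
        for m in mutations
        if (m.pathogenic and m.vaf >= 0.05)
        or (0.01 <= m.vaf < 0.05 and m.hotspot)
    )


def count_mds_genes(mutations: Iterable[MutationCall]) -> int:
    """Number of distinct mutated myelodysplasia-related genes (0..9)."""
    return len({m.gene for m in mutations} & MDS_GENES)


# ---------------------------------------------------------------------------
# serialization

_BOOL = {"1": True, "0": False, "true": True, "false": False}
COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "intensive",
    "midostaurin",
    "karyotype",
    "mutations",
    "os_months",
    "death",
)


def _parse_bool(text: str, what: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise CohortValidationError(f"{what}: expected boolean 0/1, got {text!r}")


def _parse_vaf(text: str) -> float:
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def _parse_mutation_token(token: str) -> MutationCall:
    parts = token.strip().split(":")
    if len(parts) < 4:
        raise CohortValidationError(f"malformed mutation token {token!r}")
    gene, vaf, patho, hot = parts[:4]
    kwargs: dict = {}
    for extra in parts[4:]:
        key, _, value = extra.partition("=")
        if key == "itd_ratio":
            kwargs["itd_allelic_ratio"] = float(value)
        elif key == "biallelic":
            kwargs["cebpa_biallelic"] = _parse_bool(value, "biallelic")
        elif key == "bzip":
            kwargs["cebpa_bzip_inframe"] = _parse_bool(value, "bzip")
        else:
            raise CohortValidationError(f"unknown mutation key {key!r} in {token!r}")
    return MutationCall(
        gene=gene.strip().upper() if gene.strip() in PANEL_GENES else gene.strip(),
        vaf=_parse_vaf(vaf),
        pathogenic=_parse_bool(patho, "pathogenic"),
        hotspot=_parse_bool(hot, "hotspot"),
        **kwargs,
    )


def _format_mutation(m: MutationCall) -> str:
    parts = [m.gene, f"{m.vaf:g}", "1" if m.pathogenic else "0", "1" if m.hotspot else "0"]
    if m.itd_allelic_ratio is not None:
        parts.append(f"itd_ratio={m.itd_allelic_ratio:g}")
    if m.cebpa_biallelic is not None:
        parts.append(f"biallelic={1 if m.cebpa_biallelic else 0}")
    if m.cebpa_bzip_inframe is not None:
        parts.append(f"bzip={1 if m.cebpa_bzip_inframe else 0}")
    return ":".join(parts)


def _row_to_profile(row: dict[str, str], strict: bool) -> PatientProfile:
    kar_text = (row.get("karyotype") or "").strip()
    karyotype: Karyotype | str
    if not kar_text or kar_text.lower() == "unknown":
        karyotype = "unknown"
    else:
        try:
            karyotype = parse_karyotype(kar_text, strict=True)
        except KaryotypeError:
            if strict:
                raise
            karyotype = "unknown"
    mut_field = (row.get("mutations") or "").strip()
    mutations = tuple(
        _parse_mutation_token(tok) for tok in mut_field.split(";") if tok.strip()
    )
    return PatientProfile(
        patient_id=row["patient_id"].strip(),
        age_years=int(row["age_years"]),
        sex=row["sex"].strip().lower(),
        intensive=_parse_bool(row["intensive"], "intensive"),
        midostaurin=_parse_bool(row.get("midostaurin", "0"), "midostaurin"),
        mutations=mutations,
        karyotype=karyotype,
        os_months=float(row["os_months"]),
        death=_parse_bool(row["death"], "death"),
    )


def load_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Load and validate a cohort table.

    In strict mode any malformed row aborts the load with a
    :class:`CohortValidationError` naming the row; otherwise malformed rows
    are dropped and logged to stderr with the failure reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    profiles: list[PatientProfile] = []
    dropped: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(COLUMNS) - set(reader.fieldnames or ()) - {"midostaurin"}
        if missing:
            raise CohortValidationError(f"missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                profiles.append(_row_to_profile(row, strict))
            except (CohortValidationError, KaryotypeError, ValueError, KeyError) as e:
                msg = f"{path.name}:{lineno}: {e}"
                if strict:
                    raise CohortValidationError(msg) from e
                dropped.append(msg)
                print(f"eln-aml: dropped row {msg}", file=sys.stderr)
    return CohortTable(
        profiles=profiles,
        metadata={"source": str(path), "dropped_rows": dropped},
    )


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to TSV/CSV (inverse of :func:`load_cohort`)."""
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for p in cohort:
            kar = p.karyotype if isinstance(p.karyotype, str) else p.karyotype.iscn
            writer.writerow(
                [
                    p.patient_id,
                    p.age_years,
                    p.sex,
                    int(p.intensive),
                    int(p.midostaurin),
                    kar,
                    ";".join(_format_mutation(m) for m in p.mutations),
                    f"{p.os_months:g}",
                    int(p.death),
                ]
            )
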