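"""Karyotype parsing and ELN-relevant cytogenetic lesion flags.

The parser accepts a restricted ISCN dialect sufficient for ELN risk
assignment: ``modal,sex[,abn1,abn2,...]`` where abnormality tokens are
``t(a;b)(p;q)``, ``inv(n)(p1q2)``, ``del(n)(q..)``, ``add(n)(band)``,
``+n`` (trisomy), ``-n`` (monosomy) and ``+mar``.  Composite karyotypes,
subclones and the full ISCN 2020 grammar are out of scope; in lenient mode
an unrecognised token is kept as an ``other-structural`` abnormality so
that complex-karyotype counting still sees it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Abnormality",
    "Karyotype",
    "CytogeneticFindings",
    "KaryotypeError",
    "parse_karyotype",
    "derive_findings",
]

STRUCTURAL_KINDS = frozenset(
    {"translocation", "inversion", "deletion", "addition", "marker", "other-structural"}
)
NUMERICAL_KINDS = frozenset({"monosomy", "trisomy"})

_SEX_TOKEN = re.compile(r"^[XY]{1,4}$")
_CHROM = r"(\d{1,2}|X|Y)"
_T_RE = re.compile(rf"^t\({_CHROM};{_CHROM}\)(?:\(([^;()]+);([^;()]+)\))?$")
_INV_RE = re.compile(rf"^inv\({_CHROM}\)(?:\(([^()]+)\))?$")
_DEL_RE = re.compile(rf"^del\({_CHROM}\)(?:\(([^()]+)\))?$")
_ADD_RE = re.compile(rf"^add\({_CHROM}\)(?:\(([^()]+)\))?$")
_GAIN_RE = re.compile(rf"^\+{_CHROM}$")
_LOSS_RE = re.compile(rf"^-{_CHROM}$")
_BAND_SPLIT = re.compile(r"[pq][\d.]*")


class KaryotypeError(ValueError):
    """Raised for karyotype strings outside the supported dialect."""


@dataclass(frozen=True)
class Abnormality:
    """A single clonal chromosome abnormality."""

    kind: str
    chromosomes: tuple[str, ...] = ()
    bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind in {"translocation", "inversion"} and len(self.chromosomes) < 1:
            raise ValueError(f"{self.kind} requires at least one chromosome")
        if self.kind in NUMERICAL_KINDS and len(self.chromosomes) != 1:
            raise ValueError(f"{self.kind} requires exactly one chromosome")

    @property
    def structural(self) -> bool:
        return self.kind in STRUCTURAL_KINDS


@dataclass(frozen=True)
class Karyotype:
    modal_number: int | None
    abnormalities: tuple[Abnormality, ...]
    normal: bool
    iscn: str = ""

    def __post_init__(self) -> None:
        if self.normal and self.abnormalities:
            raise ValueError("normal karyotype cannot carry abnormalities")
        if self.modal_number is not None and not (30 <= self.modal_number <= 100):
            raise ValueError(f"implausible modal number {self.modal_number}")


def _expand_bands(chrom: str, band_field: str | None) -> tuple[str, ...]:
    """``'q21q26.2'`` on chromosome 3 -> ``('3q21', '3q26.2')``."""
    if not band_field:
        return ()
    return tuple(f"{chrom}{b}" for b in _BAND_SPLIT.findall(band_field))


def _parse_token(token: str, strict: bool) -> Abnormality:
    if m := _T_RE.match(token):
        a, b, ba, bb = m.groups()
        bands = _expand_bands(a, ba) + _expand_bands(b, bb)
        return Abnormality("translocation", (a, b), bands)
    if m := _INV_RE.match(token):
        chrom, bandf = m.groups()
        return Abnormality("inversion", (chrom,), _expand_bands(chrom, bandf))
    if m := _DEL_RE.match(token):
        chrom, bandf = m.groups()
        return Abnormality("deletion", (chrom,), _expand_bands(chrom, bandf))
    if m := _ADD_RE.match(token):
        chrom, bandf = m.groups()
        return Abnormality("addition", (chrom,), _expand_bands(chrom, bandf))
    if m := _GAIN_RE.match(token):
        return Abnormality("trisomy", (m.group(1),))
    if m := _LOSS_RE.match(token):
        return Abnormality("monosomy", (m.group(1),))
    if token in {"+mar", "mar"}:
        return Abnormality("marker")
    if strict:
        raise KaryotypeError(f"unsupported karyotype token {token!r}")
    return Abnormality("other-structural")


def parse_karyotype(iscn: str, strict: bool = True) -> Karyotype:
    """Parse a restricted ISCN string into a structured :class:`Karyotype`.

    Parameters
    ----------
    iscn:
        e.g. ``"46,XX"``, ``"46,XY,t(8;21)(q22;q22)"`` or
        ``"49,XX,+8,+13,+21"``.
    strict:
        If True, an unparseable token raises :class:`KaryotypeError`;
        otherwise it is recorded as an ``other-structural`` abnormality.
    """
    text = iscn.strip()
    if not text:
        raise KaryotypeError("empty karyotype string")
    parts = [p.strip() for p in text.split(",")]
    try:
        modal = int(parts[0])
    except ValueError:
        raise KaryotypeError(f"malformed modal number {parts[0]!r}") from None
    rest = parts[1:]
    if rest and _SEX_TOKEN.match(rest[0]):
        rest = rest[1:]
    abns = tuple(_parse_token(tok, strict) for tok in rest if tok)
    return Karyotype(
        modal_number=modal, abnormalities=abns, normal=not abns, iscn=text
    )


@dataclass(frozen=True)
class CytogeneticFindings:
    """ELN-relevant lesion flags derived from one karyotype.

    ``complex_2017``/``complex_2022`` differ only in the hyperdiploid
    exemption: a karyotype whose abnormalities are exclusively three or
    more trisomies/polysomies without any structural change does not count
    as complex under the 2022 revision.
    """

    t_8_21: bool = False
    inv16_t16_16: bool = False
    t_9_11: bool = False
    t_v_11q23: bool = False
    t_6_9: bool = False
    t_9_22: bool = False
    t_8_16: bool = False
    inv3_t3_3: bool = False
    t_3q26_v: bool = False
    del5_minus5: bool = False
    minus7: bool = False
    minus17_abn17p: bool = False
    hyperdiploid_trisomies_only: bool = False
    monosomal: bool = False
    complex_2017: bool = False
    complex_2022: bool = False
    n_abnormalities: int = 0
    n_autosomal_monosomies: int = 0

    def __post_init__(self) -> None:
        if self.complex_2022 and not self.complex_2017:
            raise ValueError("complex_2022 implies complex_2017")
        if self.hyperdiploid_trisomies_only and self.complex_2022:
            raise ValueError("hyperdiploid exemption contradicts complex_2022")

    def complex_for(self, edition: int) -> bool:
        if edition == 2017:
            return self.complex_2017
        if edition == 2022:
            return self.complex_2022
        raise ValueError(f"unknown edition {edition}")


def _is_t(abn: Abnormality, a: str, b: str) -> bool:
    return abn.kind == "translocation" and set(abn.chromosomes) == {a, b}


def _has_band(abn: Abnormality, prefix: str) -> bool:
    return any(band.startswith(prefix) for band in abn.bands)


def derive_findings(k: Karyotype) -> CytogeneticFindings:
    """Derive lesion flags for both ELN editions from a parsed karyotype.

    Flag evaluation is a pure scan over the abnormality list; the two
    editions share every flag except the complex-karyotype pair.  Sex
    chromosome losses are ignored for monosomal-karyotype counting.
    """
    abns = k.abnormalities

    t_8_21 = any(_is_t(a, "8", "21") for a in abns)
    inv16 = any(
        (a.kind == "inversion" and a.chromosomes == ("16",)) or _is_t(a, "16", "16")
        for a in abns
    )
    t_9_11 = any(_is_t(a, "9", "11") for a in abns)
    t_v_11q23 = any(
        a.kind == "translocation"
        and "11" in a.chromosomes
        and _has_band(a, "11q23")
        and set(a.chromosomes) != {"9", "11"}
        for a in abns
    )
    t_6_9 = any(_is_t(a, "6", "9") for a in abns)
    t_9_22 = any(_is_t(a, "9", "22") for a in abns)
    t_8_16 = any(_is_t(a, "8", "16") for a in abns)
    inv3_t3_3 = any(
        (a.kind == "inversion" and a.chromosomes == ("3",)) or _is_t(a, "3", "3")
        for a in abns
    )
    t_3q26_v = any(
        a.kind == "translocation"
        and _has_band(a, "3q26")
        and set(a.chromosomes) != {"3"}
        for a in abns
    )
    del5_minus5 = any(
        (a.kind == "monosomy" and a.chromosomes == ("5",))
        or (
            a.kind == "deletion"
            and a.chromosomes == ("5",)
            and (not a.bands or _has_band(a, "5q"))
        )
        for a in abns
    )
    minus7 = any(a.kind == "monosomy" and a.chromosomes == ("7",) for a in abns)
    minus17_abn17p = any(
        (a.kind == "monosomy" and a.chromosomes == ("17",))
        or (
            a.kind in {"deletion", "addition", "translocation"}
            and _has_band(a, "17p")
        )
        for a in abns
    )

    n_abn = len(abns)
    n_auto_mono = sum(
        1
        for a in abns
        if a.kind == "monosomy" and a.chromosomes[0] not in {"X", "Y"}
    )
    any_structural = any(a.structural for a in abns)
    hyperdiploid_only = n_abn >= 3 and all(a.kind == "trisomy" for a in abns)
    monosomal = n_auto_mono >= 2 or (n_auto_mono == 1 and any_structural)

    # ELN convention: >=3 unrelated abnormalities, in the absence of one of
    # the recognised recurring translocations/inversions.
    recurring = (
        t_8_21
        or inv16
        or t_9_11
        or t_v_11q23
        or t_6_9
        or t_9_22
        or t_8_16
        or inv3_t3_3
        or t_3q26_v
    )
    complex_2017 = n_abn >= 3 and not recurring
    complex_2022 = complex_2017 and not hyperdiploid_only

    return CytogeneticFindings(
        t_8_21=t_8_21,
        inv16_t16_16=inv16,
        t_9_11=t_9_11,
        t_v_11q23=t_v_11q23,
        t_6_9=t_6_9,
        t_9_22=t_9_22,
        t_8_16=t_8_16,
        inv3_t3_3=inv3_t3_3,
        t_3q26_v=t_3q26_v,
        del5_minus5=del5_minus5,
        minus7=minus7,
        minus17_abn17p=minus17_abn17p,
        hyperdiploid_trisomies_only=hyperdiploid_only,
        monosomal=monosomal,
        complex_2017=complex_2017,
        complex_2022=complex_2022,
        n_abnormalities=n_abn,
        n_autosomal_monosomies=n_auto_mono,
    )
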