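"""The 2017 and 2022 classification engines: published example cases,
precedence resolution, and brute-force oracle equivalence."""

import dataclasses
import random

import pytest

from eln_aml import (
    ADVERSE,
    FAVORABLE,
    INTERMEDIATE,
    MutationCall,
    PatientProfile,
    ResolutionPolicy,
    UnresolvableError,
    classify_cohort,
    classify_patient,
    match_defining_lesions,
    parse_karyotype,
    resolve,
)
from conftest import random_profile
from oracles import oracle_classify


def make_patient(muts=(), kar="46,XX", **kw):
    karyotype = "unknown" if kar == "unknown" else parse_karyotype(kar)
    defaults = dict(
        patient_id="T1",
        age_years=55,
        sex="female",
        intensive=True,
        mutations=tuple(muts),
        karyotype=karyotype,
        os_months=10.0,
        death=False,
    )
    defaults.update(kw)
    return PatientProfile(**defaults)


NPM1 = MutationCall("NPM1", 0.42)
ITD_LOW = MutationCall("FLT3", 0.3, itd_allelic_ratio=0.3)
ITD_HIGH = MutationCall("FLT3", 0.3, itd_allelic_ratio=0.8)
SRSF2 = MutationCall("SRSF2", 0.35)
RUNX1 = MutationCall("RUNX1", 0.4)
TP53 = MutationCall("TP53", 0.5)
CEBPA_BZIP_MONO = MutationCall("CEBPA", 0.38, cebpa_biallelic=False, cebpa_bzip_inframe=True)
CEBPA_BI = MutationCall("CEBPA", 0.38, cebpa_biallelic=True, cebpa_bzip_inframe=False)


class TestEditionDeltas:
    """Profiles the two editions classify differently."""

    def test_npm1_with_low_ratio_itd_favorable_2017(self):
        p = make_patient([NPM1, ITD_LOW])
        assert classify_patient(p, 2017).resolved == FAVORABLE

    def test_npm1_with_low_ratio_itd_intermediate_2022(self):
        p = make_patient([NPM1, ITD_LOW])
        a = classify_patient(p, 2022)
        assert a.resolved == INTERMEDIATE and not a.ambiguous

    def test_lone_mds_gene_becomes_adverse_2022(self):
        p = make_patient([SRSF2])
        assert classify_patient(p, 2017).resolved == INTERMEDIATE
        a = classify_patient(p, 2022)
        assert a.resolved == ADVERSE
        assert a.matched[ADVERSE] == ["MDS-gene:SRSF2"]

    def test_monoallelic_bzip_cebpa_favorable_only_2022(self):
        p = make_patient([CEBPA_BZIP_MONO])
        assert classify_patient(p, 2017).resolved == INTERMEDIATE
        assert classify_patient(p, 2022).resolved == FAVORABLE

    def test_biallelic_non_bzip_cebpa_favorable_only_2017(self):
        p = make_patient([CEBPA_BI, SRSF2])
        assert classify_patient(p, 2017).resolved == FAVORABLE
        assert classify_patient(p, 2022).resolved == ADVERSE

    def test_npm1wt_high_ratio_itd_moves_adverse_to_intermediate(self):
        p = make_patient([ITD_HIGH])
        assert classify_patient(p, 2017).resolved == ADVERSE
        assert classify_patient(p, 2022).resolved == INTERMEDIATE

    def test_hyperdiploid_exemption(self):
        p = make_patient([], kar="49,XX,+8,+13,+21")
        assert classify_patient(p, 2017).resolved == ADVERSE
        assert classify_patient(p, 2022).resolved == INTERMEDIATE

    def test_adverse_cytogenetics_override_npm1_in_2022(self):
        p = make_patient([NPM1], kar="45,XY,-7")
        assert classify_patient(p, 2017).resolved == FAVORABLE  # NPM1 wins in 2017
        a = classify_patient(p, 2022)
        assert a.resolved == ADVERSE and not a.ambiguous  # NPM1 rule withheld

    def test_t8_16_adverse_only_2022(self):
        p = make_patient([], kar="46,XX,t(8;16)(p11.2;p13.3)")
        assert classify_patient(p, 2017).resolved == INTERMEDIATE
        assert classify_patient(p, 2022).resolved == ADVERSE


class TestAmbiguityResolution:
    def test_adverse_cytogenetics_plus_itd_resolved_adverse_2022(self):
        p = make_patient([ITD_HIGH], kar="45,XY,-7")
        a = classify_patient(p, 2022)
        assert a.resolved == ADVERSE and a.ambiguous
        assert set(a.matched_categories) == {INTERMEDIATE, ADVERSE}

    def test_cebpa_bzip_plus_itd_resolved_favorable_2022(self):
        p = make_patient([dataclasses.replace(CEBPA_BZIP_MONO, cebpa_biallelic=True), ITD_LOW])
        a = classify_patient(p, 2022)
        assert a.resolved == FAVORABLE and a.ambiguous

    def test_npm1_itd_high_runx1_resolved_intermediate_2017(self):
        p = make_patient([NPM1, ITD_HIGH, RUNX1])
        a = classify_patient(p, 2017)
        assert a.resolved == INTERMEDIATE and a.ambiguous

    def test_itd_high_biallelic_cebpa_resolved_favorable_2017(self):
        p = make_patient([CEBPA_BI, ITD_HIGH])
        a = classify_patient(p, 2017)
        assert a.resolved == FAVORABLE and a.ambiguous

    def test_single_match_not_ambiguous(self):
        a = classify_patient(make_patient([NPM1]), 2022)
        assert a.resolved == FAVORABLE and not a.ambiguous

    def test_no_lesions_fallback_intermediate(self):
        a = classify_patient(make_patient([]), 2022)
        assert a.resolved == INTERMEDIATE and not a.ambiguous
        assert a.matched[INTERMEDIATE] == ["other"]

    def test_mds_gene_with_itd_stays_intermediate_2022(self):
        # published intermediate group contained NPM1/FLT3-ITD patients
        # carrying one MDS gene
        p = make_patient([NPM1, ITD_HIGH, SRSF2])
        a = classify_patient(p, 2022)
        assert a.resolved == INTERMEDIATE and a.ambiguous

    def test_incomplete_policy_raises(self):
        matched = match_defining_lesions(make_patient([ITD_HIGH], kar="45,XY,-7"), 2022)
        bad = ResolutionPolicy("partial", ("favorable",))
        with pytest.raises(UnresolvableError, match="adverse"):
            resolve(matched, 2022, bad)

    def test_audit_records_every_fired_rule(self):
        a = classify_patient(make_patient([ITD_HIGH], kar="45,XY,-7"), 2022)
        assert any("-7" in line for line in a.audit)
        assert any("FLT3-ITD" in line for line in a.audit)
        assert "policy" in a.audit[-1]


class TestSubsets:
    @pytest.mark.parametrize(
        "muts,kar,label",
        [
            ([TP53], "43,XX,del(5)(q31),-12,add(17)(p13)", "(-5, -7, -17)"),
            ([TP53], "47,XX,add(1)(p36),del(9)(q22),+11", "Complex karyotype and TP53"),
            ([TP53], "46,XX", "Mutated TP53"),
            ([NPM1], "46,XX", "NPM1mut, FLT3-ITD WT"),
            ([SRSF2], "46,XX", "MDS-mutated genes"),
            ([], "46,XY,inv(3)(q21q26.2)", "inv(3)"),
            ([], "46,XX", "Other abnormalities"),
            ([], "46,XY,t(9;11)(p21;q23)", "t(9;11)"),
        ],
    )
    def test_first_match_subset_labels(self, muts, kar, label):
        a = classify_patient(make_patient(muts, kar=kar), 2022)
        assert a.subset == label


class TestInvariants:
    def test_determinism(self):
        rng = random.Random(7)
        for i in range(50):
            p = random_profile(rng, f"D{i}")
            for ed in (2017, 2022):
                a1 = classify_patient(p, ed)
                a2 = classify_patient(p, ed)
                assert (a1.resolved, a1.ambiguous, a1.matched) == (
                    a2.resolved,
                    a2.ambiguous,
                    a2.matched,
                )

    def test_mds_burden_never_improves_2022_category(self):
        rank = {FAVORABLE: 0, INTERMEDIATE: 1, ADVERSE: 2}
        rng = random.Random(11)
        for i in range(200):
            p = random_profile(rng, f"M{i}")
            if p.mutated("STAG2"):
                continue
            base = classify_patient(p, 2022)
            if base.resolved != INTERMEDIATE:
                continue
            added = dataclasses.replace(
                p, mutations=p.mutations + (MutationCall("STAG2", 0.3),)
            )
            after = classify_patient(added, 2022)
            assert rank[after.resolved] >= rank[base.resolved]

    def test_itd_ratio_irrelevant_in_2022(self):
        rng = random.Random(13)
        checked = 0
        for i in range(300):
            p = random_profile(rng, f"R{i}")
            itd = p.flt3_itd
            if itd is None:
                continue
            checked += 1
            other = tuple(m for m in p.mutations if not m.is_itd)
            for new_ratio in (0.01, 0.49, 0.5, 1.1):
                q = dataclasses.replace(
                    p,
                    mutations=other
                    + (dataclasses.replace(itd, itd_allelic_ratio=new_ratio),),
                )
                a, b = classify_patient(p, 2022), classify_patient(q, 2022)
                assert (a.resolved, a.ambiguous) == (b.resolved, b.ambiguous)
        assert checked > 30

    def test_engine_agrees_with_bruteforce_oracle_on_1000_profiles(self):
        rng = random.Random(20221794)
        for i in range(1000):
            p = random_profile(rng, f"O{i}")
            for edition in (2017, 2022):
                got = classify_patient(p, edition)
                want_cat, want_amb = oracle_classify(p, edition)
                assert got.resolved == want_cat, (i, edition, p)
                assert got.ambiguous == want_amb, (i, edition, p)


def test_classify_cohort_preserves_order_and_ids(fixture_cohort, a22):
    assert [a.patient_id for a in a22] == [p.patient_id for p in fixture_cohort]


def test_empty_cohort():
    from eln_aml import CohortTable

    assert classify_cohort(CohortTable(profiles=[]), 2022) == []
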