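import random

import pytest

from eln_aml import (
    MutationCall,
    PatientProfile,
    build_reclassification_fixture,
    build_transition_table,
    classify_cohort,
    parse_karyotype,
)

KARYOTYPE_POOL = [
    "46,XX",
    "46,XY",
    "unknown",
    "46,XY,t(8;21)(q22;q22)",
    "46,XX,inv(16)(p13.1q22)",
    "46,XY,t(9;11)(p21;q23)",
    "46,XX,t(6;9)(p23;q34)",
    "46,XY,t(9;22)(q34;q11)",
    "46,XX,t(8;16)(p11.2;p13.3)",
    "46,XY,inv(3)(q21q26.2)",
    "46,XX,t(3;21)(q26.2;q22)",
    "45,XY,-7",
    "46,XX,del(5)(q31)",
    "45,XX,-17",
    "46,XY,t(11;19)(q23;p13.1)",
    "49,XX,+8,+13,+21",
    "43,XX,del(5)(q31),-12,add(17)(p13)",
    "47,XX,add(1)(p36),del(9)(q22),+11",
    "44,XY,-5,-12",
]

MDS_POOL = ["ASXL1", "BCOR", "EZH2", "RUNX1", "SF3B1", "SRSF2", "STAG2", "U2AF1", "ZRSR2"]


def random_profile(rng: random.Random, pid: str) -> PatientProfile:
    """A random but schema-valid patient profile for property tests."""
    muts = []
    if rng.random() < 0.3:
        muts.append(MutationCall("NPM1", round(rng.uniform(0.05, 0.5), 3)))
    if rng.random() < 0.3:
        muts.append(
            MutationCall(
                "FLT3",
                0.3,
                itd_allelic_ratio=round(rng.uniform(0.0, 1.2), 2),
            )
        )
    if rng.random() < 0.2:
        muts.append(
            MutationCall(
                "CEBPA",
                0.38,
                cebpa_biallelic=rng.random() < 0.5,
                cebpa_bzip_inframe=rng.random() < 0.5,
            )
        )
    if rng.random() < 0.15:
        muts.append(MutationCall("TP53", round(rng.uniform(0.05, 0.8), 3)))
    for gene in MDS_POOL:
        if rng.random() < 0.08:
            muts.append(MutationCall(gene, round(rng.uniform(0.05, 0.5), 3)))
    if rng.random() < 0.2:
        muts.append(MutationCall("DNMT3A", 0.3))
    kar_text = rng.choice(KARYOTYPE_POOL)
    karyotype = "unknown" if kar_text == "unknown" else parse_karyotype(kar_text)
    return PatientProfile(
        patient_id=pid,
        age_years=rng.randint(18, 90),
        sex=rng.choice(["male", "female"]),
        intensive=True,
        mutations=tuple(muts),
        karyotype=karyotype,
        os_months=round(rng.uniform(0, 60), 1),
        death=rng.random() < 0.5,
    )


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_reclassification_fixture()


@pytest.fixture(scope="session")
def a17(fixture_cohort):
    return classify_cohort(fixture_cohort, 2017)


@pytest.fixture(scope="session")
def a22(fixture_cohort):
    return classify_cohort(fixture_cohort, 2022)


@pytest.fixture(scope="session")
def transition(fixture_cohort, a17, a22):
    return build_transition_table(a17, a22, fixture_cohort)
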