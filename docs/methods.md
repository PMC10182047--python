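# Methods

This note documents the models, conventions and design choices behind
the package, in the order the pipeline applies them.

## Variant reporting filter

Mutation calls enter classification only if they pass the consensus
reporting rule used by harmonized myeloid NGS panels: pathogenic (or
probably damaging) variants with VAF ≥ 5%, plus hotspot variants with
VAF in [1%, 5%). VAF is stored as a fraction in [0, 1]; the TSV loader
accepts percentage-formatted columns (`42%`) and converts. The filter is
applied uniformly, including to FLT3 records — whether panels exempted
FLT3-ITD allelic-ratio determination from the hotspot rule is not
documented anywhere we rely on, and a uniform rule is the conservative
choice. Hotspot status, CEBPA allelic state and bZIP in-frame status are
input annotations: no hotspot catalogue is bundled, and computing bZIP
in-frame status from raw HGVS is out of scope.

## Karyotype dialect and lesion flags

`parse_karyotype` accepts a restricted ISCN dialect —
`modal,sex[,token,...]` with tokens `t(a;b)(p;q)`, `inv(n)(p1q2)`,
`del(n)(q..)`, `add(n)(band)`, `+n`, `-n`, `+mar` — sufficient for ELN
assignment. Composite karyotypes, subclones and FISH nomenclature are
out of scope. Band fields are expanded with their chromosome prefix
(`inv(3)(q21q26.2)` → bands `3q21`, `3q26.2`) so lesion matching is a
prefix test.

Conventions in `derive_findings`, chosen where guidelines leave slack:

* **Complex karyotype**: ≥ 3 abnormality tokens in the absence of a
  recognized recurring translocation/inversion; "unrelated" is counted
  as distinct tokens. The threshold is the standard ELN convention.
* **2022 hyperdiploid exemption**: a karyotype whose abnormalities are
  exclusively ≥ 3 trisomies/polysomies clears the 2022 complex flag
  (`complex_2022 ⇒ complex_2017` always holds).
* **Monosomal karyotype**: ≥ 2 autosomal monosomies, or one autosomal
  monosomy plus ≥ 1 structural abnormality; sex-chromosome losses never
  count.
* **abn(17p)**: any deletion/addition/translocation carrying a band
  with prefix `17p`, plus monosomy 17.
* **t(v;11q23.3)**: any translocation with an `11q23` band whose
  partner set is not {9, 11}; t(9;11) carries its own flag. Bandless
  translocations involving chromosome 11 are not flagged (the band is
  the evidence).

Both editions' flags are derived in one pass; the editions differ only
in the complex-karyotype pair.

## Rule engines

The engines are two-stage. `match_defining_lesions` evaluates every
category-defining rule row and returns the full map `category →
[lesion labels]`:

**2017** — favorable: t(8;21); inv(16)/t(16;16); NPM1-mutated without
FLT3-ITD or with allelic ratio < 0.5; biallelic CEBPA. Intermediate
(defining): NPM1-mutated with ratio ≥ 0.5; t(9;11). Adverse: t(6;9),
t(v;11q23.3), t(9;22), inv(3)/t(3;3), −5/del(5q), −7, −17/abn(17p),
complex, monosomal; NPM1-wild-type with ratio ≥ 0.5; RUNX1; ASXL1;
TP53. RUNX1/ASXL1 do not count when a favorable-defining lesion
co-occurs (guideline footnote).

**2022** — favorable: t(8;21); inv(16)/t(16;16); NPM1-mutated without
FLT3-ITD *and without adverse cytogenetics* (the 2022 override);
in-frame bZIP CEBPA, mono- or biallelic. Intermediate (defining): any
FLT3-ITD (ratio ignored by construction); t(9;11). Adverse: the 2017
adverse cytogenetics plus t(8;16) and t(3q26.2;v), with the 2022
complex flag; each of the nine MDS genes; TP53. MDS-gene matches are
withheld when a favorable-defining lesion co-occurs (favorable-risk
patients carrying MDS mutations stay favorable); TP53 is never
withheld. The 10% VAF condition on TP53 is available as a switch
(`tp53_vaf_threshold=0.10`) and off by default.

Patients with no defining lesion fall back to intermediate with label
`other`; fallback rules never create ambiguity. Unknown karyotypes
contribute no cytogenetic flags and classify on molecular markers alone.

`resolve` applies an ordered precedence over *rule classes* (adverse
cytogenetics, CEBPA-bZIP favorable, FLT3-ITD/t(9;11) intermediate,
molecular adverse, residual favorable, residual intermediate). Policies
are data, not code, so the defaults can be overridden from YAML. The
2022 default order reproduces both published resolutions
(adverse-cytogenetics + FLT3-ITD → adverse; CEBPA-bZIP + FLT3-ITD →
favorable) and keeps FLT3-ITD carriers with a single MDS-gene mutation
intermediate, which is what the published intermediate-group composition
implies. The 2017 default places favorable above intermediate-defining
above adverse, reproducing the two documented 2017-ambiguous cases
(NPM1 + high-ratio ITD + RUNX1 → intermediate; high-ratio ITD +
biallelic CEBPA → favorable) *while leaving their ambiguity flags set*;
note the RUNX1 case is decided by the policy, not by the footnote
suppression, because NPM1 with a high-ratio ITD is intermediate- rather
than favorable-defining in 2017.

Genetic-subset labels within the resolved 2022 category are assigned by
first match in the outcome-table row order — adverse: inv(3);
(−5, −7, −17); CK+TP53; TP53; CK; MDS genes; t(v;11q23); t(6;9);
t(9;22) — with one deliberate deviation: t(9;11) is matched before the
"Other abnormalities" fallback, which is otherwise unreachable for
t(9;11) carriers. Where a patient qualifies for several adverse subsets
(e.g. −7 with TP53), first-match ordering decides; the source tables do
not specify the overlap rule, so the order is a documented repo choice.

## Refinements

Two switchable post-2022 proposals:

* **Very adverse**: resolved-adverse patients with inv(3)/t(3;3) or a
  mutated TP53; complex karyotype with TP53 is kept as a labelled
  sub-case rather than a third condition, since TP53 dominates
  prognosis regardless of karyotype complexity. TP53 VAF/allelic state
  is not consulted (future config).
* **MDS burden**: adverse patients whose only adverse-defining lesions
  are MDS-gene mutations and whose distinct-gene burden is exactly 1
  move to intermediate; ≥ 2 genes, or any co-occurring non-MDS adverse
  lesion, pins them. Reallocation runs before the very-adverse flag and
  only ever moves patients down; disabling both switches reproduces the
  base 2022 partition exactly.

## Reclassification analysis

Transition tables cross-classify per-patient assignments from both
editions (ids are checked). Reason labels are derived from the profile
and audit trail and phrased exactly as in the published reclassification
report so output is diffable. Percentages are printed to one decimal
with round-half-up, matching the source's printed precision. The
covariate association test is plain Pearson chi-square without
continuity correction; category columns nobody occupies are dropped, and
an empty covariate stratum yields an undefined (NaN) p-value.

## Survival estimation

Kaplan–Meier curves use the product-limit estimator with Greenwood
variance and exponential (log-log) 95% bands; the median is the first
time S(t) ≤ 0.5 and its CI comes from the threshold crossings of the
bands — chosen for robustness at small n, as the source does not name
its method. Medians of curves that never reach 0.5 are reported as not
reached (`inf`). The log-rank statistic is the k-group chi-square with
k−1 df, two-sided p. Cox fits use Efron tie handling (month-resolution
times are heavily tied) with Wald CIs; a stratum with zero events has an
unidentifiable hazard ratio and is reported as NaN rather than fitted.
lifelines provides all three estimators; the test suite independently
verifies them against hand product-limit computations, a brute-force
risk-set tabulation of the log-rank statistic, and numeric maximisation
of the Efron partial likelihood.

## Synthetic cohorts

**Deterministic fixture** (`build_reclassification_fixture`): 546
patients composed block-by-block so that the published cross-edition
arithmetic reproduces exactly — 2017 marginals 169/135/242, 2022
marginals 152/111/283, all seven reclassification-reason rows, ten
2022-ambiguous profiles (nine adverse-cytogenetics + FLT3-ITD +
NPM1-wild-type, one CEBPA-bZIP + FLT3-ITD). The 47 reclassified
MDS-gene carriers split 19 single-gene / 28 multi-gene, a documented
choice consistent with roughly 40% of the MDS adverse subgroup carrying
a single gene; the two 2017-ambiguous profiles live in the rules tests,
not in the counting cohort, so its 2017 ambiguity census is zero by
construction. Ages cycle deterministically over 28–82 years, sexes
alternate, and survival fields follow fixed per-block exponential
quantile schedules — the fixture's survival values are plumbing for
round-trip tests, not an analysis target.

**Stochastic generator** (`simulate_cohort`): per-stratum genotype
templates (each guaranteed to classify into its intended 2022 category)
drawn at configured prevalences; overall survival exponential with rate
ln 2 / median; censoring administrative at the horizon under uniform
accrual (follow-up = horizon − U(0, accrual)); identical config + seed
gives byte-identical cohorts. Default calibration, fixed as study
conditions: adverse median 15.2 months and adverse-vs-favorable hazard
ratio 3.5, hence favorable median 53.2 months; intermediate at hazard
ratio 1.5 (35.5 months); very-adverse 7.1; MDS burden ≥ 2 at 13.6; MDS
burden 1 at 45 (back-computed from its 3-year OS of 57.6% under the
exponential model, the printed median being unreached). With the default
36-month horizon the favorable and intermediate medians are typically
not reached, as intended. Default accrual window 12 months; the
parameter-recovery runs use accrual 0 so the censoring pattern matches
the stated administrative design.

What the generator does **not** emulate: co-mutation correlation beyond
what classification needs, age/genotype dependence, non-exponential
hazard shapes (no published curve data exist to fit), relapse,
transplant or MRD dynamics, and treatment effects (midostaurin is an
input covariate only). Passing parameter-recovery tests therefore
demonstrates the estimators and the pipeline, not real-world prognostic
performance.

## Problem sizes and numerics

Fixture analyses run on 546 patients in well under a second.
Parameter-recovery checks use 2000 patients per arm — large enough that
the Cox estimate's Monte-Carlo standard error (~0.15 on a hazard ratio
of 3.5 under 36-month censoring) sits inside the stated ±0.2 check, and
the KM median error inside ±1 month. Property suites use 1000 random
profiles for rule-engine/oracle equivalence and 500 random abnormality
lists for flag re-scans, all with fixed seeds. Simulated survival times
are rounded to 0.01 months, deliberately creating ties that exercise the
Efron correction.

## Known limitations

Only overall survival is modelled (no relapse-free survival or
competing risks); the ISCN dialect is a subset; pathogenicity,
hotspot and CEBPA-domain annotation are trusted inputs; the MRD-based
re-stratification of the 2022 guideline and pre-2017 editions are out
of scope.
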