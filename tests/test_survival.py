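"""Kaplan–Meier, log-rank and Cox estimators against hand-computed and
brute-force oracles, plus parameter recovery on simulated data."""

import math

import numpy as np
import pytest

from eln_aml import (
    CohortTable,
    GeneratorConfig,
    StratumSpec,
    cox_fit,
    km_fit,
    logrank,
    simulate_cohort,
    stratified_os_report,
)
from oracles import cox_binary_oracle, logrank_oracle


class TestKaplanMeier:
    def test_all_events_matches_hand_product_limit(self):
        km = km_fit([1, 2, 3, 4], [True] * 4)
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert km.survival_at(t) == pytest.approx(s)
        assert km.median == pytest.approx(2.0)

    def test_no_events_curve_stays_at_one(self):
        km = km_fit([5, 10, 15], [False] * 3)
        assert km.survival_at(20) == 1.0
        assert not km.median_reached
        assert km.n_events == 0

    def test_single_patient_step(self):
        km = km_fit([5.0], [True])
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == 0.0
        assert km.median == pytest.approx(5.0)

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=200)
        km = km_fit(t, np.ones(200, dtype=bool))
        for q in [2.0, 5.0, 10.0, 20.0]:
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_censoring_lifts_curve(self):
        full = km_fit([1, 2, 3, 4], [True] * 4)
        cens = km_fit([1, 2, 3, 4], [True, False, True, True])
        assert cens.survival_at(4) >= full.survival_at(4)

    def test_curve_nonincreasing_starts_at_one(self):
        rng = np.random.default_rng(5)
        km = km_fit(rng.exponential(12, 100), rng.random(100) < 0.7)
        s = km.curve["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
        assert km.survival_at(-0.001) == 1.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_fit([-1, 2], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4, 5], [True, True, False, True, False])
        stat, p = logrank([g, g])
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_risk_set_tabulation(self):
        rng = np.random.default_rng(11)
        groups = [
            (rng.exponential(m, 30), rng.random(30) < 0.8) for m in (5.0, 9.0, 20.0)
        ]
        stat, _ = logrank(groups)
        assert stat == pytest.approx(logrank_oracle(groups), rel=1e-6)

    def test_label_permutation_and_time_rescale_invariance(self):
        rng = np.random.default_rng(13)
        groups = [(rng.exponential(m, 40), rng.random(40) < 0.7) for m in (6.0, 15.0)]
        stat, _ = logrank(groups)
        stat_perm, _ = logrank(groups[::-1])
        stat_scaled, _ = logrank([(t * 12.0, e) for t, e in groups])
        assert stat == pytest.approx(stat_perm)
        assert stat == pytest.approx(stat_scaled)

    def test_distinct_hazards_detected(self):
        rng = np.random.default_rng(17)
        groups = []
        for m in (8.0, 20.0, 50.0):
            t = rng.exponential(m / math.log(2), 500)
            e = t <= 36.0
            groups.append((np.minimum(t, 36.0), e))
        _, p = logrank(groups)
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([([1, 2], [True, True])])

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([([1, 2], [False, False]), ([3], [False])])


class TestCox:
    def test_null_covariate_hr_one(self):
        rng = np.random.default_rng(19)
        t = rng.exponential(10, 300)
        e = rng.random(300) < 0.8
        g = ["a" if i % 2 else "b" for i in range(300)]
        eff = cox_fit(t, e, g, reference="a")
        assert eff[0].hr == pytest.approx(1.0, abs=0.35)
        assert eff[0].ci[0] < 1.0 < eff[0].ci[1]

    def test_matches_bruteforce_partial_likelihood(self):
        times = [3, 5, 5, 7, 8, 11, 13, 13, 16, 20]
        events = [1, 1, 1, 0, 1, 1, 0, 1, 1, 0]
        x = [1, 1, 0, 1, 0, 1, 0, 0, 1, 0]
        g = ["high" if v else "low" for v in x]
        eff = cox_fit(times, [bool(v) for v in events], g, reference="low")
        assert eff[0].hr == pytest.approx(
            cox_binary_oracle(times, events, x), rel=1e-3
        )

    def test_recovers_true_hazard_ratio_two(self):
        cfg = GeneratorConfig(
            strata=(
                StratumSpec("ref", 2000, 30.0, (("normal", 1.0),)),
                StratumSpec("risk", 2000, 15.0, (("minus7", 1.0),)),
            ),
            horizon_months=60.0,
            accrual_months=0.0,
            seed=23,
        )
        cohort = simulate_cohort(cfg)
        eff = cox_fit(
            [p.os_months for p in cohort],
            [p.death for p in cohort],
            [p.patient_id.rsplit("-", 1)[0] for p in cohort],
            reference="ref",
        )
        assert eff[0].hr == pytest.approx(2.0, abs=0.2)

    def test_stratum_without_events_unidentifiable(self):
        t = [1, 2, 3, 4, 10, 11, 12, 13]
        e = [True] * 4 + [False] * 4
        g = ["a"] * 4 + ["b"] * 4
        eff = cox_fit(t, e, g, reference="a")
        assert math.isnan(eff[0].hr)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            cox_fit([1, 2], [True, True], ["a", "a"], reference="z")


class TestStratifiedReport:
    def _cohort(self, medians, n=150, seed=29, horizon=36.0):
        strata = tuple(
            StratumSpec(label, n, m, (("normal", 1.0),)) for label, m in medians.items()
        )
        cfg = GeneratorConfig(
            strata=strata, horizon_months=horizon, accrual_months=0.0, seed=seed
        )
        cohort = simulate_cohort(cfg)
        labels = [p.patient_id.rsplit("-", 1)[0] for p in cohort]
        return cohort, labels

    def test_three_strata_curves_and_global_test(self):
        cohort, labels = self._cohort({"fav": 50.0, "int": 25.0, "adv": 8.0})
        rep = stratified_os_report(cohort, labels, reference="fav")
        assert [s.label for s in rep.strata] == ["fav", "int", "adv"]
        assert rep.logrank_p < 0.01
        assert {c.stratum for c in rep.cox} == {"int", "adv"}

    def test_configured_medians_recovered(self):
        cohort, labels = self._cohort(
            {"one": 45.0, "twoplus": 13.6}, n=2000, seed=31, horizon=60.0
        )
        rep = stratified_os_report(cohort, labels)
        by = {s.label: s.km.median for s in rep.strata}
        assert by["twoplus"] == pytest.approx(13.6, abs=1.0)
        assert by["one"] == pytest.approx(45.0, abs=3.0)

    def test_single_stratum_no_test(self):
        cohort, labels = self._cohort({"only": 20.0})
        rep = stratified_os_report(cohort, labels)
        assert rep.logrank_p is None and rep.cox == []

    def test_small_strata_dropped_with_warning(self):
        cohort, labels = self._cohort({"big": 20.0, "small": 10.0})
        labels = ["tiny" if i < 2 else l for i, l in enumerate(labels)]
        with pytest.warns(UserWarning, match="tiny"):
            rep = stratified_os_report(cohort, labels, min_n=5)
        assert "tiny" in rep.dropped
        assert all(s.label != "tiny" for s in rep.strata)

    def test_timepoint_os_rates_are_percentages(self):
        cohort, labels = self._cohort({"adv": 12.0})
        rep = stratified_os_report(cohort, labels, timepoints=(12.0,))
        rate = rep.strata[0].os_rates[12.0]
        assert 30 <= rate <= 70  # exponential with 12-month median: ~50%
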