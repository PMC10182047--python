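"""Kaplan–Meier estimation, log-rank testing and Cox models per stratum.

All estimators are backed by lifelines: product-limit survival with
exponential-Greenwood (log-log) 95% confidence bands, the k-group
log-rank chi-square test, and Cox partial-likelihood fits with Efron tie
handling (overall-survival times at month resolution are heavily tied).
Medians and their confidence intervals are read off the threshold
crossings of the curve and its bands; a stratum whose curve never falls
to 0.5 has an unreached median, reported as ``inf``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .cohort import CohortTable

__all__ = [
    "KMResult",
    "CoxEffect",
    "StratumSummary",
    "SurvivalSummary",
    "km_fit",
    "logrank",
    "cox_fit",
    "stratified_os_report",
]

NOT_REACHED = math.inf


@dataclass
class KMResult:
    """Product-limit curve with median and timepoint survival rates."""

    curve: pd.DataFrame  # columns: time, survival, ci_lower, ci_upper
    median: float  # months; inf when never reached
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t) from the fitted step function (1.0 before the first event)."""
        c = self.curve
        idx = c["time"].searchsorted(t, side="right") - 1
        return 1.0 if idx < 0 else float(c["survival"].iloc[idx])

    def os_rates(self, timepoints: tuple[float, ...] = (12, 24, 36)) -> dict[float, float]:
        """Overall-survival percentages at the requested months."""
        return {t: 100.0 * self.survival_at(t) for t in timepoints}


@dataclass
class CoxEffect:
    stratum: str
    reference: str
    hr: float  # NaN when unidentifiable (no events in a stratum)
    ci: tuple[float, float]
    p: float


@dataclass
class StratumSummary:
    label: str
    n: int
    km: KMResult
    os_rates: dict[float, float]


@dataclass
class SurvivalSummary:
    strata: list[StratumSummary]
    logrank_stat: float | None
    logrank_p: float | None
    cox: list[CoxEffect] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d vectors")
    if (t < 0).any():
        raise ValueError("negative survival times")
    return t, e


def km_fit(times, events) -> KMResult:
    """Kaplan–Meier fit of one stratum.

    All-censored input is valid: the curve stays at 1 and the median is
    reported as not reached (``inf``).
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, e)
    surv = kmf.survival_function_
    ci = kmf.confidence_interval_
    curve = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "ci_lower": ci.iloc[:, 0].to_numpy(dtype=float),
            "ci_upper": ci.iloc[:, 1].to_numpy(dtype=float),
        }
    )
    median = float(kmf.median_survival_time_)
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    lo = float(med_ci_df.iloc[0, 0])
    hi = float(med_ci_df.iloc[0, 1])
    return KMResult(
        curve=curve,
        median=median,
        median_ci=(lo, hi),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank(groups: list[tuple]) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square, two-sided p).

    ``groups`` is a list of ``(times, events)`` pairs.  Requires at least
    two groups and at least one event overall.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    ts, es, labels = [], [], []
    for i, (times, events) in enumerate(groups):
        t, e = _as_arrays(times, events)
        ts.append(t)
        es.append(e)
        labels.append(np.full(len(t), i))
    all_e = np.concatenate(es)
    if not all_e.any():
        raise ValueError("log-rank test undefined with zero events")
    res = multivariate_logrank_test(
        np.concatenate(ts), np.concatenate(labels), all_e
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times, events, group, reference: str
) -> list[CoxEffect]:
    """Cox proportional-hazards fit of a categorical stratum covariate.

    Dummy-codes ``group`` against ``reference`` and fits the partial
    likelihood with Efron tie handling; returns one hazard ratio with Wald
    95% CI and p per non-reference stratum.  A stratum with no events has
    an unidentifiable hazard ratio, reported as NaN.
    """
    t, e = _as_arrays(times, events)
    g = pd.Series(list(group), dtype="object")
    if len(g) != len(t):
        raise ValueError("group vector length mismatch")
    levels = [lv for lv in pd.unique(g) if lv != reference]
    if reference not in set(g):
        raise ValueError(f"reference level {reference!r} absent from data")
    if not levels:
        # single level: null covariate, HR identically 1
        return []
    events_per = {lv: int(e[(g == lv).to_numpy()].sum()) for lv in pd.unique(g)}
    df = pd.DataFrame({"T": t, "E": e.astype(int)})
    fit_levels = [lv for lv in levels if events_per[lv] > 0]
    for lv in fit_levels:
        df[str(lv)] = (g == lv).astype(float).to_numpy()
    out: list[CoxEffect] = []
    if fit_levels and events_per[reference] >= 0 and e.any():
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
        summ = cph.summary
        for lv in fit_levels:
            row = summ.loc[str(lv)]
            out.append(
                CoxEffect(
                    stratum=str(lv),
                    reference=reference,
                    hr=float(np.exp(row["coef"])),
                    ci=(
                        float(np.exp(row["coef lower 95%"])),
                        float(np.exp(row["coef upper 95%"])),
                    ),
                    p=float(row["p"]),
                )
            )
    for lv in levels:
        if lv not in fit_levels:
            out.append(
                CoxEffect(
                    stratum=str(lv),
                    reference=reference,
                    hr=float("nan"),
                    ci=(float("nan"), float("nan")),
                    p=float("nan"),
                )
            )
    return out


def stratified_os_report(
    cohort: CohortTable,
    labels: list[str],
    timepoints: tuple[float, ...] = (12, 24, 36),
    reference: str | None = None,
    min_n: int = 1,
) -> SurvivalSummary:
    """Per-stratum KM curves, timepoint OS rates, log-rank and Cox fits.

    ``labels`` assigns each patient a stratum (risk category, genetic
    subset, MDS burden, age band, ...).  Strata below ``min_n`` patients
    are dropped with a note, mirroring the practice of excluding
    vanishingly small genetic subsets from outcome comparisons.  With a
    single remaining stratum only the curve is reported (no test).
    """
    plist = list(cohort)
    if len(plist) != len(labels):
        raise ValueError("labels length mismatch")
    order: list[str] = []
    for lb in labels:
        if lb not in order:
            order.append(lb)
    dropped = [lb for lb in order if labels.count(lb) < min_n]
    kept = [lb for lb in order if lb not in dropped]
    for lb in dropped:
        warnings.warn(f"stratum {lb!r} dropped (n < {min_n})", stacklevel=2)

    strata: list[StratumSummary] = []
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    times_all, events_all, labels_all = [], [], []
    for lb in kept:
        idx = [i for i, x in enumerate(labels) if x == lb]
        t = np.array([plist[i].os_months for i in idx], dtype=float)
        e = np.array([plist[i].death for i in idx], dtype=bool)
        km = km_fit(t, e)
        strata.append(
            StratumSummary(label=lb, n=len(idx), km=km, os_rates=km.os_rates(timepoints))
        )
        groups.append((t, e))
        times_all.append(t)
        events_all.append(e)
        labels_all.extend([lb] * len(idx))

    lr_stat = lr_p = None
    if len(groups) >= 2 and any(e.any() for _, e in groups):
        lr_stat, lr_p = logrank(groups)

    cox: list[CoxEffect] = []
    if len(groups) >= 2 and reference is not None and reference in kept:
        cox = cox_fit(
            np.concatenate(times_all),
            np.concatenate(events_all),
            labels_all,
            reference=reference,
        )
    return SurvivalSummary(
        strata=strata, logrank_stat=lr_stat, logrank_p=lr_p, cox=cox, dropped=dropped
    )
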