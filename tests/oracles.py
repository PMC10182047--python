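"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from the rule definitions
directly — flat predicate lists, explicit risk-set tabulation, numeric
partial-likelihood optimisation — and shares no logic with the package
modules it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from eln_aml.cohort import MDS_GENES, PatientProfile
from eln_aml.cytogenetics import Karyotype

# ---------------------------------------------------------------------------
# karyotype flag re-scan (per-flag, loop-based)


def rescan_flags(k: Karyotype) -> dict:
    """Evaluate every lesion flag by an independent scan of the list."""
    out = {
        "t_8_21": False, "inv16_t16_16": False, "t_9_11": False,
        "t_v_11q23": False, "t_6_9": False, "t_9_22": False, "t_8_16": False,
        "inv3_t3_3": False, "t_3q26_v": False, "del5_minus5": False,
        "minus7": False, "minus17_abn17p": False,
    }
    n_mono_auto = 0
    n_structural = 0
    n_trisomy = 0
    for a in k.abnormalities:
        chroms = set(a.chromosomes)
        if a.kind == "translocation":
            n_structural += 1
            if chroms == {"8", "21"}:
                out["t_8_21"] = True
            if chroms == {"16"}:
                out["inv16_t16_16"] = True
            if chroms == {"9", "11"}:
                out["t_9_11"] = True
            if chroms == {"6", "9"}:
                out["t_6_9"] = True
            if chroms == {"9", "22"}:
                out["t_9_22"] = True
            if chroms == {"8", "16"}:
                out["t_8_16"] = True
            if chroms == {"3"}:
                out["inv3_t3_3"] = True
            for band in a.bands:
                if band.startswith("11q23") and chroms != {"9", "11"}:
                    out["t_v_11q23"] = True
                if band.startswith("3q26") and chroms != {"3"}:
                    out["t_3q26_v"] = True
                if band.startswith("17p"):
                    out["minus17_abn17p"] = True
        elif a.kind == "inversion":
            n_structural += 1
            if chroms == {"16"}:
                out["inv16_t16_16"] = True
            if chroms == {"3"}:
                out["inv3_t3_3"] = True
        elif a.kind == "deletion":
            n_structural += 1
            if chroms == {"5"} and (
                not a.bands or any(b.startswith("5q") for b in a.bands)
            ):
                out["del5_minus5"] = True
            if any(b.startswith("17p") for b in a.bands):
                out["minus17_abn17p"] = True
        elif a.kind == "addition":
            n_structural += 1
            if any(b.startswith("17p") for b in a.bands):
                out["minus17_abn17p"] = True
        elif a.kind in {"marker", "other-structural"}:
            n_structural += 1
        elif a.kind == "monosomy":
            c = a.chromosomes[0]
            if c not in {"X", "Y"}:
                n_mono_auto += 1
            if c == "5":
                out["del5_minus5"] = True
            if c == "7":
                out["minus7"] = True
            if c == "17":
                out["minus17_abn17p"] = True
        elif a.kind == "trisomy":
            n_trisomy += 1
    n = len(k.abnormalities)
    recurring = any(
        out[f]
        for f in (
            "t_8_21", "inv16_t16_16", "t_9_11", "t_v_11q23", "t_6_9",
            "t_9_22", "t_8_16", "inv3_t3_3", "t_3q26_v",
        )
    )
    out["hyperdiploid_trisomies_only"] = n >= 3 and n_trisomy == n
    out["monosomal"] = n_mono_auto >= 2 or (n_mono_auto == 1 and n_structural >= 1)
    out["complex_2017"] = n >= 3 and not recurring
    out["complex_2022"] = out["complex_2017"] and not out["hyperdiploid_trisomies_only"]
    out["n_abnormalities"] = n
    out["n_autosomal_monosomies"] = n_mono_auto
    return out


# ---------------------------------------------------------------------------
# brute-force risk classification


def _features(p: PatientProfile) -> dict:
    itd_ratio = None
    for m in p.mutations:
        if m.gene == "FLT3" and m.itd_allelic_ratio is not None:
            itd_ratio = m.itd_allelic_ratio
    cebpa_bi = cebpa_bzip = False
    for m in p.mutations:
        if m.gene == "CEBPA":
            cebpa_bi = bool(m.cebpa_biallelic)
            cebpa_bzip = bool(m.cebpa_bzip_inframe)
    genes = {m.gene for m in p.mutations}
    flags = (
        rescan_flags(p.karyotype)
        if not isinstance(p.karyotype, str)
        else {key: False for key in rescan_flags(Karyotype(46, (), True))}
    )
    return {
        "npm1": "NPM1" in genes,
        "itd": itd_ratio is not None,
        "itd_high": itd_ratio is not None and itd_ratio >= 0.5,
        "cebpa_bi": cebpa_bi,
        "cebpa_bzip": cebpa_bzip,
        "tp53": "TP53" in genes,
        "mds": sorted(genes & MDS_GENES),
        "f": flags,
    }


def oracle_classify(p: PatientProfile, edition: int) -> tuple[str, bool]:
    """(resolved category, ambiguous) by exhaustive rule-row testing."""
    x = _features(p)
    f = x["f"]
    if edition == 2017:
        fav = (
            f["t_8_21"]
            or f["inv16_t16_16"]
            or (x["npm1"] and not x["itd_high"])
            or x["cebpa_bi"]
        )
        fav_defining = fav
        inter = (x["npm1"] and x["itd_high"]) or f["t_9_11"]
        cyto_adv = (
            f["t_6_9"] or f["t_v_11q23"] or f["t_9_22"] or f["inv3_t3_3"]
            or f["del5_minus5"] or f["minus7"] or f["minus17_abn17p"]
            or f["complex_2017"] or f["monosomal"]
        )
        runx1_asxl1 = ({"RUNX1", "ASXL1"} & set(x["mds"])) and not fav_defining
        adv = (
            cyto_adv
            or (not x["npm1"] and x["itd_high"])
            or bool(runx1_asxl1)
            or x["tp53"]
        )
        n_cat = sum([fav, inter, adv])
        if fav:
            return "favorable", n_cat > 1
        if inter:
            return "intermediate", n_cat > 1
        if adv:
            return "adverse", n_cat > 1
        return "intermediate", False
    # 2022
    cyto_adv = (
        f["t_6_9"] or f["t_v_11q23"] or f["t_9_22"] or f["t_8_16"]
        or f["t_3q26_v"] or f["inv3_t3_3"] or f["del5_minus5"] or f["minus7"]
        or f["minus17_abn17p"] or f["complex_2022"] or f["monosomal"]
    )
    fav = (
        f["t_8_21"]
        or f["inv16_t16_16"]
        or (x["npm1"] and not x["itd"] and not cyto_adv)
        or x["cebpa_bzip"]
    )
    inter = x["itd"] or f["t_9_11"]
    mol_adv = (bool(x["mds"]) and not fav) or x["tp53"]
    adv = cyto_adv or mol_adv
    n_cat = sum([fav, inter, adv])
    ambiguous = n_cat > 1
    # precedence: adverse cytogenetics, then CEBPA bZIP, then FLT3-ITD /
    # t(9;11), then molecular adverse, then remaining favorable
    if cyto_adv:
        return "adverse", ambiguous
    if x["cebpa_bzip"]:
        return "favorable", ambiguous
    if inter:
        return "intermediate", ambiguous
    if mol_adv:
        return "adverse", ambiguous
    if fav:
        return "favorable", ambiguous
    return "intermediate", False


# ---------------------------------------------------------------------------
# survival oracles


def logrank_oracle(groups) -> float:
    """k-group log-rank chi-square by explicit risk-set tabulation."""
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    k = len(groups)
    event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))
    z = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        n_i = np.array([(tt >= t).sum() for tt in times], dtype=float)
        d_i = np.array(
            [((tt == t) & ee).sum() for tt, ee in zip(times, events)], dtype=float
        )
        N, D = n_i.sum(), d_i.sum()
        if N <= 1 or D == 0:
            continue
        e_i = D * n_i / N
        z += d_i - e_i
        c = D * (N - D) / (N - 1) / N**2
        for a in range(k):
            for b in range(k):
                V[a, b] += c * (N * n_i[a] * (a == b) - n_i[a] * n_i[b])
    zr, Vr = z[:-1], V[:-1, :-1]
    return float(zr @ np.linalg.pinv(Vr) @ zr)


def cox_binary_oracle(times, events, x) -> float:
    """HR for a single binary covariate by maximising the Efron partial
    likelihood numerically."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    x = np.asarray(x, float)

    def neg_loglik(beta: float) -> float:
        ll = 0.0
        for u in np.unique(t[e]):
            d_idx = (t == u) & e
            r_idx = t >= u
            d = int(d_idx.sum())
            s_d = x[d_idx].sum()
            risk = np.exp(beta * x[r_idx]).sum()
            tied = np.exp(beta * x[d_idx]).sum()
            ll += beta * s_d
            for l in range(d):
                ll -= np.log(risk - (l / d) * tied)
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-8, 8), method="bounded")
    return float(np.exp(res.x))
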