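"""Clinical association networks, iPCY scoring and survival analysis.

iPCY sums the ex vivo PCY scores of tested treatments whose component
set is contained in a patient's next clinical regimen; patients are
stratified at their subcohort's mean iPCY and compared by Kaplan-Meier /
log-rank with an O/E hazard-ratio estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "feature_drug_associations",
    "normalize_treatment_name",
    "compute_ipcy",
    "stratify_by_ipcy",
    "kaplan_meier",
    "km_logrank",
    "phenogroup_outcome_split",
    "SurvivalResult",
]

#: Editable alias table for clinical regimen name normalization.
TREATMENT_ALIASES = {
    "velcade": "bortezomib",
    "btz": "bortezomib",
    "revlimid": "lenalidomide",
    "len": "lenalidomide",
    "dex": "dexamethasone",
    "dexa": "dexamethasone",
    "prednisone": "dexamethasone",  # corticosteroids pooled
    "dara": "daratumumab",
    "elo": "elotuzumab",
    "pom": "pomalidomide",
    "kyprolis": "carfilzomib",
}


def normalize_treatment_name(name: str) -> str:
    key = name.strip().lower()
    return TREATMENT_ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# feature-drug association network


def feature_drug_associations(drug_matrix: pd.DataFrame,
                              features: pd.DataFrame, *,
                              p_cut: float = 0.01, n_cv: int = 100,
                              holdout_frac: float = 0.2,
                              min_group: int = 3, seed: int = 0,
                              imputed_mask: pd.DataFrame | None = None,
                              ) -> pd.DataFrame:
    """Per (feature, drug) one-way ANOVA + two-group t-test association.

    An edge is kept when both p-values are < ``p_cut``. For multi-level
    features the t-test compares the two levels with extreme group means.
    cv_fraction is the share of ``n_cv`` leave-``holdout_frac``-out
    resamples in which both tests stay significant. Imputed responses are
    excluded via the mask.
    """
    drugs = drug_matrix.copy()
    if imputed_mask is not None:
        drugs = drugs.mask(imputed_mask.reindex_like(drugs).fillna(False))
    rng = np.random.default_rng(seed)
    rows = []
    for feat in features.columns:
        fvals = features[feat]
        for drug in drugs.columns:
            y = drugs[drug]
            ok = y.notna() & fvals.notna()
            sub_y, sub_f = y[ok], fvals[ok]
            stat = _anova_ttest(sub_y, sub_f, min_group)
            if stat is None:
                continue
            F, p_a, p_t, direction = stat
            keep = (p_a < p_cut) and (p_t < p_cut)
            cv_hits, cv_total = 0, 0
            if keep and n_cv > 0:
                idx = np.arange(len(sub_y))
                n_drop = max(1, int(round(holdout_frac * len(idx))))
                for _ in range(n_cv):
                    kept_idx = rng.permutation(idx)[n_drop:]
                    s = _anova_ttest(sub_y.iloc[kept_idx], sub_f.iloc[kept_idx],
                                     min_group)
                    cv_total += 1
                    if s is not None and s[1] < p_cut and s[2] < p_cut:
                        cv_hits += 1
            rows.append({"feature": feat, "treatment": drug,
                         "anova_F": F, "p_anova": p_a, "p_ttest": p_t,
                         "direction": direction, "kept": keep,
                         "cv_fraction": (cv_hits / cv_total) if cv_total else np.nan,
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)


def _anova_ttest(y: pd.Series, f: pd.Series, min_group: int):
    groups = {}
    for level, sub in y.groupby(f):
        if len(sub) >= min_group:
            groups[level] = sub.to_numpy(dtype=float)
    if len(groups) < 2:
        return None
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return 0.0, 1.0, 1.0, "none"
    F, p_a = sps.f_oneway(*arrays)
    means = {lvl: a.mean() for lvl, a in groups.items()}
    hi = max(means, key=means.get)
    lo = min(means, key=means.get)
    if hi == lo:
        return float(F), float(p_a), 1.0, "none"
    t, p_t = sps.ttest_ind(groups[hi], groups[lo], equal_var=True)
    direction = f"better:{hi}"  # higher PCY = more ex vivo sensitive
    return float(F), float(p_a), float(p_t), direction


# ---------------------------------------------------------------------------
# iPCY


def compute_ipcy(responses: pd.Series, regimen, *,
                 treatment_components: dict[str, tuple[str, ...]] | None = None,
                 imputed: pd.Series | None = None,
                 mode: str = "subset") -> tuple[float, list[str]]:
    """Sum matched ex vivo PCY scores for one patient.

    ``regimen`` is an iterable of clinical drug names (or a '+'-joined
    string). A tested treatment matches when its component set is a
    subset of the normalized regimen (``mode='subset'``, so a tested
    combination counts in addition to its singles) or equals it exactly
    (``mode='exact'``). Imputed entries never contribute. Returns
    ``(ipcy, matched treatments)``; ipcy is NaN with no match.
    """
    if isinstance(regimen, str):
        regimen = regimen.split("+")
    reg = {normalize_treatment_name(r) for r in regimen}
    comps = treatment_components or {
        t: tuple(normalize_treatment_name(c) for c in str(t).split("+"))
        for t in responses.index}
    matched = []
    total = 0.0
    for trt, score in responses.items():
        if pd.isna(score):
            continue
        if imputed is not None and bool(imputed.get(trt, False)):
            continue
        cset = {normalize_treatment_name(c) for c in comps[trt]}
        hit = cset == reg if mode == "exact" else cset <= reg
        if hit:
            matched.append(trt)
            total += float(score)
    if not matched:
        return float("nan"), []
    return total, matched


def stratify_by_ipcy(ipcy: pd.Series, subcohort: pd.Series) -> pd.DataFrame:
    """Label patients sensitive/resistant at their subcohort mean iPCY.

    Sensitive iff ipcy is strictly above the subcohort mean; all-equal
    iPCYs therefore label everyone resistant (warned).
    """
    out = []
    for sc, grp in ipcy.groupby(subcohort):
        grp = grp.dropna()
        if len(grp) < 2:
            raise ValueError(f"subcohort {sc!r} has fewer than 2 patients")
        thr = float(grp.mean())
        if grp.nunique() == 1:
            warnings.warn(f"subcohort {sc!r}: all iPCYs equal; "
                          "everyone labeled resistant")
        for pid, v in grp.items():
            out.append({"patient_id": pid, "subcohort": sc, "ipcy": v,
                        "threshold": thr,
                        "label": "sensitive" if v > thr else "resistant"})
    return pd.DataFrame(out).set_index("patient_id")


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalResult:
    groups: list
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    observed: dict
    expected: dict
    km_curves: dict = field(default_factory=dict)
    at_risk: pd.DataFrame | None = None


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; returns step points at event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    surv = 1.0
    rows = [{"time": 0.0, "survival": 1.0, "at_risk": len(t), "events": 0}]
    for ti in np.unique(t[e == 1]):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(ti), "survival": surv,
                     "at_risk": at_risk, "events": d})
    return pd.DataFrame(rows)


def km_logrank(times, events, groups) -> SurvivalResult:
    """Two-group log-rank (Mantel-Cox) test with an O/E hazard ratio.

    HR = (O1/E1) / (O2/E2) for the first group vs the second (sorted
    label order); CI = exp(log HR +/- 1.96 sqrt(1/E1 + 1/E2)). A group
    with zero events yields an unbounded HR, reported with a warning.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    if e.sum() == 0:
        raise ValueError("no events observed")
    in1 = g == labels[0]
    O = {lab: 0.0 for lab in labels}
    E = {lab: 0.0 for lab in labels}
    V = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n = at.sum()
        n1 = (at & in1).sum()
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        O[labels[0]] += d1
        O[labels[1]] += d - d1
        E[labels[0]] += d * n1 / n
        E[labels[1]] += d * (n - n1) / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O[labels[0]] - E[labels[0]]) ** 2 / V if V > 0 else 0.0
    p = float(sps.chi2.sf(chi2, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rate1 = O[labels[0]] / E[labels[0]] if E[labels[0]] > 0 else np.nan
        rate2 = O[labels[1]] / E[labels[1]] if E[labels[1]] > 0 else np.nan
        if rate1 == 0 or rate2 == 0 or not np.isfinite(rate1 * rate2):
            warnings.warn("a group has zero observed events: HR is a bound")
            hr = np.inf if (rate2 == 0 or not np.isfinite(rate2)) else 0.0
            ci = (0.0, np.inf)
        else:
            hr = rate1 / rate2
            se = np.sqrt(1 / E[labels[0]] + 1 / E[labels[1]])
            ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    curves = {lab: kaplan_meier(t[g == lab], e[g == lab]) for lab in labels}
    event_times = np.unique(t[e == 1])
    at_risk = pd.DataFrame(
        {lab: [(t[g == lab] >= ti).sum() for ti in event_times]
         for lab in labels}, index=event_times)
    return SurvivalResult(labels, float(chi2), p, float(hr), ci,
                          {k: float(v) for k, v in O.items()},
                          {k: float(v) for k, v in E.items()},
                          curves, at_risk)


def phenogroup_outcome_split(clinical: pd.DataFrame, phenogroups: pd.Series,
                             split_group: str = "PG2", *,
                             time_col: str = "time_to_next_treatment_days",
                             event_col: str = "event") -> SurvivalResult:
    """Binary regrouping (one PG vs the rest) followed by km_logrank."""
    pg = phenogroups.reindex(clinical["patient_id"])
    side = np.where(pg.to_numpy() == split_group, split_group, "rest")
    if (side == split_group).sum() == 0 or (side == "rest").sum() == 0:
        raise ValueError(f"split on {split_group!r} leaves an empty side")
    return km_logrank(clinical[time_col].to_numpy(),
                      clinical[event_col].to_numpy(), side)
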