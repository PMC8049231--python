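"""Evaluation statistics for the score and its interpretation bands.

ROC/AUC with percentile-bootstrap CIs, exact binomial (Clopper-Pearson)
intervals, band-level diagnostics (NPV, PPV, sensitivity, specificity,
diagnostic odds ratio), Cohen's d effect sizes, two-sample and one-way group
tests, hospital-free days, Kaplan-Meier curves with the log-rank test, and
severity trends across bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by pair counting with ties counted 1/2 (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray,
                     n_boot: int = 1000, conf: float = 0.95,
                     rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling subjects with
    replacement (1000 replicates by default)."""
    rng = rng or np.random.default_rng(0)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(scores)
    aucs = []
    while len(aucs) < n_boot:
        idx = rng.integers(0, n, n)
        yb = labels[idx]
        if yb.min() == yb.max():
            continue  # degenerate resample: no AUC defined
        aucs.append(roc_auc(scores[idx], yb))
    alpha = (1 - conf) / 2
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI by inverting the tail probabilities."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class BandContingency:
    """Septic counts within the Green and Red interpretation bands."""

    n_green: int
    septic_green: int
    n_red: int
    septic_red: int

    def __post_init__(self) -> None:
        if not (0 <= self.septic_green <= self.n_green
                and 0 <= self.septic_red <= self.n_red):
            raise ValueError("band totals must be >= septic counts >= 0")


def band_diagnostics(ct: BandContingency, conf: float = 0.95) -> dict:
    """Green-band NPV/PPV/sensitivity/specificity and Green-vs-Red
    diagnostic odds ratio.

    Treating Red as test-positive and Green as test-negative: NPV is the
    non-septic fraction of the Green band; the DOR is the ratio of the odds
    of sepsis between the Red and Green bands.  Zero cells get the Haldane
    0.5 correction and are flagged.
    """
    tn = ct.n_green - ct.septic_green
    fn = ct.septic_green
    tp = ct.septic_red
    fp = ct.n_red - ct.septic_red
    out: dict = {}
    out["npv"] = tn / ct.n_green
    out["npv_ci"] = clopper_pearson(tn, ct.n_green, conf)
    out["ppv"] = tp / ct.n_red
    out["ppv_ci"] = clopper_pearson(tp, ct.n_red, conf)
    out["sensitivity"] = tp / (tp + fn)
    out["sensitivity_ci"] = clopper_pearson(tp, tp + fn, conf)
    out["specificity"] = tn / (tn + fp)
    out["specificity_ci"] = clopper_pearson(tn, tn + fp, conf)
    out["green_septic_fraction"] = fn / ct.n_green
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = (v + 0.5 for v in (tp, fp, fn, tn))
        out["dor_haldane_corrected"] = True
    else:
        out["dor_haldane_corrected"] = False
    out["diagnostic_odds_ratio"] = (tp / fp) / (fn / tn)
    return out


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference (mean_y - mean_x) / pooled SD, with
    (n-1)-weighted pooling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((y.mean() - x.mean()) / pooled)


def group_tests(*groups: np.ndarray, kind: str = "welch_t") -> tuple[float, float]:
    """Two-sided group comparison: Welch's t (Satterthwaite df),
    Mann-Whitney U (normal approximation with tie correction), or one-way
    ANOVA for three or more groups."""
    groups = tuple(np.asarray(g, dtype=float) for g in groups)
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if kind == "welch_t":
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    elif kind == "mann_whitney":
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative="two-sided", method="asymptotic")
    elif kind == "anova":
        res = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(res.statistic), float(res.pvalue)


def hospital_free_days(los_days, in_hospital_death):
    """28 days minus in-hospital length of stay, floored at zero;
    in-hospital death yields zero."""
    los = np.asarray(los_days, dtype=float)
    died = np.asarray(in_hospital_death).astype(bool)
    if np.any(los < 0):
        raise ValueError("negative length of stay")
    hfd = np.where(died, 0.0, np.maximum(0.0, 28.0 - los))
    return float(hfd) if np.isscalar(los_days) else hfd


def km_logrank(times: np.ndarray, event_flags: np.ndarray,
               groups: np.ndarray) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test.

    Right-censoring per the event flags (0 = censored at the recorded time).
    With two groups the statistic is chi-square with 1 df.  If no events
    occurred anywhere, the statistic is 0 with a warning.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags).astype(int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("negative times")
    names = [g for g in pd.unique(groups)]
    if len(names) < 2:
        raise ValueError("need >= 2 non-empty groups")
    curves = {}
    for g in names:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    if events.sum() == 0:
        warnings.warn("all subjects censored in all groups; log-rank statistic 0")
        return {"curves": curves, "statistic": 0.0, "p_value": 1.0}
    res = multivariate_logrank_test(times, groups, events)
    return {"curves": curves, "statistic": float(res.test_statistic),
            "p_value": float(res.p_value)}


def band_trend_report(subjects: pd.DataFrame, conf: float = 0.95) -> dict:
    """Severity-of-illness summaries per interpretation band.

    Expects columns band, sofa_3day_max, apache2, hospital_los,
    in_hospital_death, icu_admit.  Reports median (IQR) per band for SOFA,
    APACHE-II and hospital-free days, the ICU admission rate with its exact
    CI, and adjacent-band pairwise tests (Welch for the scores,
    Mann-Whitney for the skewed hospital-free days).
    """
    order = [b for b in ("Green", "Yellow", "Red")
             if (subjects["band"] == b).sum() > 0]
    notes = [f"band {b} empty; omitted" for b in ("Green", "Yellow", "Red")
             if b not in order]
    if len(order) < 2:
        raise ValueError("need >= 2 populated bands for a trend report")
    report: dict = {"bands": {}, "pairwise": {}, "notes": notes}
    work = subjects.copy()
    work["hfd"] = hospital_free_days(work["hospital_los"].to_numpy(),
                                     work["in_hospital_death"].to_numpy())
    measures = {"sofa_3day_max": "welch_t", "apache2": "welch_t",
                "hfd": "mann_whitney"}
    for b in order:
        grp = work[work["band"] == b]
        entry = {"n": int(len(grp))}
        for m in measures:
            v = grp[m].dropna().to_numpy(dtype=float)
            entry[m] = {"median": float(np.median(v)),
                        "iqr": [float(np.percentile(v, 25)),
                                float(np.percentile(v, 75))]}
        k = int(grp["icu_admit"].fillna(0).astype(bool).sum())
        entry["icu_rate"] = k / len(grp)
        entry["icu_rate_ci"] = clopper_pearson(k, len(grp), conf)
        report["bands"][b] = entry
    for b1, b2 in zip(order, order[1:]):
        g1 = work[work["band"] == b1]
        g2 = work[work["band"] == b2]
        entry = {}
        for m, kind in measures.items():
            stat, p = group_tests(g1[m].dropna().to_numpy(),
                                  g2[m].dropna().to_numpy(), kind=kind)
            entry[m] = {"kind": kind, "statistic": stat, "p": p}
        report["pairwise"][f"{b1}_vs_{b2}"] = entry
    return report
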