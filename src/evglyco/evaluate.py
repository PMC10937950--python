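"""Evaluation statistics for the glycan-signature pipeline.

Accuracy with exact (Clopper-Pearson) binomial confidence intervals, ROC
AUC with a DeLong interval, the two-sided Mann-Whitney U test, Kaplan-Meier
curves with the log-rank test, and Cox proportional-hazards regression
(uni- and multivariate, Efron ties), matching how the clinical cohorts are
analyzed. Standard machinery comes from scipy / scikit-learn / lifelines;
the DeLong variance estimator is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy_ci",
    "roc_auc",
    "mann_whitney_u",
    "km_logrank",
    "cox_ph",
    "KMResult",
]


def accuracy_ci(confusion, confidence: float = 0.95):
    """Overall accuracy (trace/total) with a Clopper-Pearson binomial CI."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.size == 0 or confusion.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = float(np.trace(confusion))
    n = float(confusion.sum())
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, (lo, hi)


def _delong_variance(scores, labels):
    """DeLong's estimator of var(AUC) using midrank placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        return stats.rankdata(x, method="average")

    all_s = np.concatenate([pos, neg])
    r_all = midrank(all_s)
    r_pos = midrank(pos)
    r_neg = midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # placement of each positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # placement of each negative
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(scores, labels, confidence: float = 0.95):
    """Trapezoidal AUC (midrank tie handling) with a DeLong CI, clipped to
    [0, 1]. ``labels`` must contain exactly two classes; 1/True marks the
    positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auc, var = _delong_variance(scores, labels)
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U: exact for small untied samples, otherwise
    the tie-corrected normal approximation (scipy's automatic policy).
    Returns (U of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    medians: dict  # group -> median survival time (NaN if never below 0.5)
    logrank_p: float
    logrank_stat: float


def km_logrank(records: pd.DataFrame, group_col: str = "signature_group",
               time_col: str = "time", event_col: str = "event") -> KMResult:
    """Product-limit survival per group plus the two-sided log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if records[event_col].sum() < 1:
        raise ValueError("need at least one observed event")
    curves, medians = {}, {}
    for grp, sub in records.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"group {grp!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[grp] = sf
        medians[grp] = float(kmf.median_survival_time_)
    lr = multivariate_logrank_test(records[time_col], records[group_col],
                                   records[event_col])
    return KMResult(curves=curves, medians=medians,
                    logrank_p=float(lr.p_value),
                    logrank_stat=float(lr.test_statistic))


def cox_ph(records: pd.DataFrame, covariates, mode: str = "uni",
           time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling via
    lifelines). ``mode='uni'`` fits each covariate on its own;
    ``mode='multi'`` fits them jointly. Returns hazard ratios with Wald 95%
    CIs and p-values, one row per covariate."""
    from lifelines import CoxPHFitter

    covariates = list(covariates)
    n_events = int(records[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError("too few events for the number of covariates")
    for cov in covariates:
        if records[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    if mode not in ("uni", "multi"):
        raise ValueError("mode must be 'uni' or 'multi'")
    groups = [[c] for c in covariates] if mode == "uni" else [covariates]
    rows = []
    for group in groups:
        cph = CoxPHFitter()
        cph.fit(records[[time_col, event_col] + group], duration_col=time_col,
                event_col=event_col)
        summ = cph.summary
        for cov in group:
            rows.append({
                "covariate": cov,
                "HR": float(summ.loc[cov, "exp(coef)"]),
                "ci_low": float(summ.loc[cov, "exp(coef) lower 95%"]),
                "ci_high": float(summ.loc[cov, "exp(coef) upper 95%"]),
                "p": float(summ.loc[cov, "p"]),
            })
    return pd.DataFrame(rows).set_index("covariate")
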