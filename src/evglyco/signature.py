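"""EV glycan signatures: weighted sums of three lectin intensities by LDA.

Three signatures share one construction — a linear discriminant score
s(x) = w^T x with w proportional to Sigma_pooled^-1 (mu_pos - mu_neg) — but
differ in preprocessing and class structure:

* diagnosis: per-lectin min-max scaling to [0, 1] on the training cohort,
  then a two-step classifier (LDA 1: breast cancer vs healthy donor; LDA 2,
  fitted on the cancer samples only: TNBC vs other subtypes);
* monitoring: per-patient baseline normalization (each follow-up divided by
  that patient's pre-treatment value, per lectin), then one LDA of
  progressive disease (PD) against response/stable disease (PR/SD);
* prognosis: min-max scaled baseline intensities, one LDA, and a median
  split of the score into high/low risk groups.

Scores are oriented so that the clinically adverse class (TNBC, PD,
high risk) has the larger score. The drug-efficacy index eta_EV is the
temporal change of the reciprocal monitoring score,
eta_EV = 1/s(t_eval) - 1/s(baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LECTINS",
    "ScalingParams",
    "DiscriminantModel",
    "SignatureModel",
    "fit_minmax",
    "apply_minmax",
    "baseline_normalize",
    "fit_lda",
    "fit_diagnostic",
    "predict_diagnostic",
    "fit_monitoring",
    "score_monitoring",
    "eta_ev",
    "fit_prognostic",
    "stratify_median",
]

LECTINS = ("ConA", "WGA", "RCA_I")


# ---------------------------------------------------------------- scaling

@dataclass
class ScalingParams:
    """Per-lectin training min/max for linear scaling onto [0, 1]."""

    minima: dict
    maxima: dict

    def __post_init__(self):
        for lec in self.minima:
            if not self.maxima[lec] > self.minima[lec]:
                raise ValueError(f"max must exceed min for {lec}")


def fit_minmax(train: pd.DataFrame, columns=LECTINS) -> ScalingParams:
    minima, maxima = {}, {}
    for col in columns:
        lo, hi = float(train[col].min()), float(train[col].max())
        if hi <= lo:
            raise ValueError(f"constant column {col!r}: cannot min-max scale")
        minima[col], maxima[col] = lo, hi
    return ScalingParams(minima=minima, maxima=maxima)


def apply_minmax(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Scale onto [0, 1] with the training min/max; out-of-range validation
    values are clipped to the unit interval."""
    out = table.copy()
    for col, lo in params.minima.items():
        hi = params.maxima[col]
        out[col] = ((table[col] - lo) / (hi - lo)).clip(0.0, 1.0)
    return out


def baseline_normalize(table: pd.DataFrame, columns=LECTINS,
                       patient_col: str = "patient_id",
                       time_col: str = "timepoint") -> pd.DataFrame:
    """Divide each intensity by the same patient's baseline (timepoint 0)
    value of the same lectin; baseline rows become exactly 1."""
    out = table.copy()
    out[list(columns)] = out[list(columns)].astype(float)
    for pid, grp in table.groupby(patient_col):
        base_rows = grp[grp[time_col] == 0]
        if base_rows.empty:
            raise ValueError(f"patient {pid!r} has no baseline (timepoint 0)")
        base = base_rows.iloc[0]
        for col in columns:
            if base[col] == 0:
                raise ValueError(f"zero baseline intensity for patient {pid!r}, {col}")
            out.loc[grp.index, col] = grp[col] / base[col]
    return out


# ---------------------------------------------------------------- LDA core

@dataclass
class DiscriminantModel:
    """Two-class linear discriminant: score s(x) = w.x, call positive when
    s >= threshold (equal-posterior point under the shared-covariance
    Gaussian model with the stored priors)."""

    classes: tuple  # (negative, positive)
    means: np.ndarray  # [2, p]
    pooled_cov: np.ndarray  # [p, p]
    weights: np.ndarray  # [p]
    priors: np.ndarray  # [2]
    threshold: float

    def score(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights

    def predict(self, X):
        s = self.score(X)
        return np.where(s >= self.threshold, self.classes[1], self.classes[0])


def fit_lda(X, y, positive_label=None, priors: str = "empirical") -> DiscriminantModel:
    """Pooled-covariance two-class LDA.

    ``positive_label`` names the class that should get the larger score
    (defaults to the second label in sorted order). ``priors`` is
    ``"empirical"`` (class proportions) or ``"equal"``. A singular pooled
    covariance is ridge-regularized by 1e-6 * trace/p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    if positive_label is None:
        positive_label = labels[1]
    if positive_label not in labels:
        raise ValueError(f"positive_label {positive_label!r} not in {labels}")
    neg = labels[0] if labels[1] == positive_label else labels[1]
    Xn, Xp = X[y == neg], X[y == positive_label]
    if len(Xn) < 2 or len(Xp) < 2:
        raise ValueError("need >= 2 samples per class")
    p = X.shape[1]
    mu_n, mu_p = Xn.mean(axis=0), Xp.mean(axis=0)
    Sn = np.cov(Xn, rowvar=False)
    Sp = np.cov(Xp, rowvar=False)
    cov = ((len(Xn) - 1) * Sn + (len(Xp) - 1) * Sp) / (len(Xn) + len(Xp) - 2)
    cov = np.atleast_2d(cov)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular pooled covariance: applying ridge regularization")
        cov = cov + np.eye(p) * 1e-6 * np.trace(cov) / p
    w = np.linalg.solve(cov, mu_p - mu_n)
    if priors == "empirical":
        pri = np.array([len(Xn), len(Xp)], dtype=float)
        pri /= pri.sum()
    elif priors == "equal":
        pri = np.array([0.5, 0.5])
    else:
        raise ValueError("priors must be 'empirical' or 'equal'")
    threshold = float(w @ (mu_n + mu_p) / 2.0 - np.log(pri[1] / pri[0]))
    return DiscriminantModel(classes=(neg, positive_label),
                             means=np.stack([mu_n, mu_p]), pooled_cov=cov,
                             weights=w, priors=pri, threshold=threshold)


# ---------------------------------------------------------------- signatures

@dataclass
class SignatureModel:
    """A fitted signature: preprocessing parameters plus one or two LDAs."""

    kind: str  # "diagnostic" | "monitoring" | "prognostic"
    scaling: ScalingParams | None
    baseline_normalized: bool
    models: dict  # name -> DiscriminantModel
    lectins: tuple = LECTINS


def _require_columns(table: pd.DataFrame, columns):
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing lectin columns: {missing}")


def fit_diagnostic(train: pd.DataFrame, group_col: str = "group",
                   priors: str = "empirical") -> SignatureModel:
    """Two-step diagnostic signature (TNBC / otherBC / HD).

    Step 1 separates breast cancer (TNBC + otherBC) from healthy donors;
    step 2, trained on the cancer samples only, separates TNBC from the
    other subtypes.
    """
    _require_columns(train, LECTINS)
    groups = set(train[group_col].unique())
    if not {"TNBC", "otherBC", "HD"} <= groups:
        raise ValueError("training table must contain TNBC, otherBC and HD samples")
    scaling = fit_minmax(train)
    scaled = apply_minmax(train, scaling)
    X = scaled[list(LECTINS)].to_numpy()
    is_bc = np.where(train[group_col].isin(["TNBC", "otherBC"]), "BC", "HD")
    lda1 = fit_lda(X, is_bc, positive_label="BC", priors=priors)
    bc_mask = train[group_col].isin(["TNBC", "otherBC"]).to_numpy()
    lda2 = fit_lda(X[bc_mask], train.loc[bc_mask, group_col].to_numpy(),
                   positive_label="TNBC", priors=priors)
    return SignatureModel(kind="diagnostic", scaling=scaling,
                          baseline_normalized=False,
                          models={"bc_vs_hd": lda1, "tnbc_vs_other": lda2})


def predict_diagnostic(model: SignatureModel, table: pd.DataFrame) -> pd.DataFrame:
    """Class calls and signature scores; the reported score belongs to the
    LDA step that produced the final call (step 1 for HD calls, step 2 for
    the cancer subtypes). A sample called HD by step 1 is never routed to
    step 2."""
    if model.kind != "diagnostic":
        raise ValueError("not a diagnostic model")
    _require_columns(table, model.lectins)
    scaled = apply_minmax(table, model.scaling)
    X = scaled[list(model.lectins)].to_numpy()
    lda1, lda2 = model.models["bc_vs_hd"], model.models["tnbc_vs_other"]
    call1 = lda1.predict(X)
    s1 = lda1.score(X)
    call2 = lda2.predict(X)
    s2 = lda2.score(X)
    final = np.where(call1 == "HD", "HD", call2)
    score = np.where(call1 == "HD", s1, s2)
    return pd.DataFrame({"predicted": final, "score": score}, index=table.index)


def fit_monitoring(train: pd.DataFrame, response_col: str = "response",
                   priors: str = "empirical") -> SignatureModel:
    """Monitoring signature from baseline-normalized follow-up rows, PD as
    the positive (higher-score) class against PR/SD."""
    _require_columns(train, LECTINS)
    normalized = baseline_normalize(train)
    follow = normalized[normalized["timepoint"] > 0]
    y = np.where(follow[response_col] == "PD", "PD", "PR/SD")
    if len(set(y)) < 2:
        raise ValueError("monitoring fit needs both PD and PR/SD follow-ups")
    X = follow[list(LECTINS)].to_numpy()
    lda = fit_lda(X, y, positive_label="PD", priors=priors)
    return SignatureModel(kind="monitoring", scaling=None,
                          baseline_normalized=True, models={"pd_vs_prsd": lda})


def score_monitoring(model: SignatureModel, table: pd.DataFrame) -> pd.Series:
    """TNBC^EGM scores for all rows (baseline rows score w.1 by definition)."""
    if model.kind != "monitoring":
        raise ValueError("not a monitoring model")
    normalized = baseline_normalize(table)
    X = normalized[list(model.lectins)].to_numpy()
    return pd.Series(model.models["pd_vs_prsd"].score(X), index=table.index,
                     name="signature")


def eta_ev(baseline_score: float, eval_score: float,
           days: float | None = None, rate: bool = False) -> float:
    """Drug-efficacy index: change of the reciprocal monitoring signature,
    1/s(t_eval) - 1/s(baseline); divided by the elapsed days when
    ``rate=True``. Scores must be positive (the reciprocal is undefined
    otherwise). Responders, whose signature falls, get eta_EV > 0."""
    if baseline_score <= 0 or eval_score <= 0:
        raise ValueError("eta_EV requires positive signature scores")
    value = 1.0 / eval_score - 1.0 / baseline_score
    if rate:
        if not days or days <= 0:
            raise ValueError("rate form needs elapsed days > 0")
        value /= days
    return value


def fit_prognostic(baseline: pd.DataFrame, label_col: str = "event",
                   priors: str = "empirical") -> SignatureModel:
    """Prognostic signature from baseline rows: min-max scaling then one LDA
    against the progression-event indicator (1 = progression observed)."""
    _require_columns(baseline, LECTINS)
    scaling = fit_minmax(baseline)
    scaled = apply_minmax(baseline, scaling)
    X = scaled[list(LECTINS)].to_numpy()
    y = baseline[label_col].astype(int).to_numpy()
    lda = fit_lda(X, y, positive_label=1, priors=priors)
    return SignatureModel(kind="prognostic", scaling=scaling,
                          baseline_normalized=False, models={"risk": lda})


def score_prognostic(model: SignatureModel, table: pd.DataFrame) -> pd.Series:
    if model.kind != "prognostic":
        raise ValueError("not a prognostic model")
    scaled = apply_minmax(table, model.scaling)
    X = scaled[list(model.lectins)].to_numpy()
    return pd.Series(model.models["risk"].score(X), index=table.index,
                     name="signature")


def stratify_median(scores) -> np.ndarray:
    """Split scores at their median: 'high' for score >= median (ties go
    high), 'low' below. Refuses fewer than 4 patients."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need >= 4 patients to stratify")
    med = np.median(scores)
    return np.where(scores >= med, "high", "low")
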