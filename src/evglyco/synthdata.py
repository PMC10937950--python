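"""Synthetic cohorts and measurements with the structure the pipeline assumes.

Fluorescence intensities are lognormal (positive, right-skewed) with a
common between-lectin correlation. Class effects are multiplicative and
reproduce the orderings observed in TNBC plasma profiling: breast cancer
above healthy donors on every lectin, and TNBC above the other subtypes on
WGA but below them on RCA I. Default effect sizes are deliberately generous
(>= 4 within-class standard deviations between neighboring classes on the
discriminating lectins) so that the default cohorts are separable by
construction; real plasma cohorts overlap far more, and all magnitudes are
configurable. Longitudinal series are multiplicative per-patient
trajectories (PD rising, PR falling, SD flat); survival times are
exponential with log-hazard linear in a true baseline signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signature import LECTINS
from .thermosim.particles import SizeDistribution
from .quantify import FluorescenceImage

__all__ = [
    "CohortSpec",
    "gen_diagnostic_cohort",
    "gen_longitudinal_cohort",
    "gen_survival_cohort",
    "gen_size_distribution",
    "gen_spot_image",
    "gen_coloc_events",
]


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohorts; defaults mirror the pilot study
    layout (training cohort 20 TNBC / 19 otherBC / 25 HD; 13 monitored
    patients, 5 responders / 8 non-responders; 25 baseline patients for
    survival)."""

    seed: int = 0
    # diagnostic cohort
    n_tnbc: int = 20
    n_otherbc: int = 19
    n_hd: int = 25
    hd_mean: dict = field(default_factory=lambda: {"ConA": 1000.0, "WGA": 800.0, "RCA_I": 900.0})
    bc_effect: dict = field(default_factory=lambda: {"ConA": 2.8, "WGA": 2.4, "RCA_I": 2.0})
    tnbc_effect: dict = field(default_factory=lambda: {"ConA": 1.05, "WGA": 2.0, "RCA_I": 0.55})
    log_sd: float = 0.12
    lectin_corr: float = 0.3
    # longitudinal cohort
    n_responders: int = 5
    n_nonresponders: int = 8
    pd_log_rise: float = 0.55  # PD follow-ups rise by >= ~70%
    pr_log_fall: float = 0.45  # PR follow-ups fall by ~35%
    traj_log_noise: float = 0.05
    # survival cohort
    n_survival: int = 25
    baseline_hazard: float = np.log(2) / 205.0  # per day; median 205 d at score 0
    hazard_ratio: float = 6.0
    censoring_rate: float = 0.2
    binary_covariate: bool = False

    def __post_init__(self):
        if min(self.n_tnbc, self.n_otherbc, self.n_hd, self.n_responders,
               self.n_nonresponders, self.n_survival) <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.log_sd <= 0 or self.traj_log_noise < 0:
            raise ValueError("spreads must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.pd_log_rise <= 0 or self.pr_log_fall <= 0:
            raise ValueError(
                "trajectory slopes inconsistent with labels: PD must rise and PR fall")


def _lognormal_block(rng, mean_by_lectin, log_sd, corr, n):
    """n samples of correlated lognormal intensities, medians per lectin."""
    p = len(LECTINS)
    C = np.full((p, p), corr) + (1 - corr) * np.eye(p)
    L = np.linalg.cholesky(C * log_sd**2)
    z = rng.standard_normal((n, p)) @ L.T
    mu = np.log([mean_by_lectin[lec] for lec in LECTINS])
    return np.exp(mu[None, :] + z)


def gen_diagnostic_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Three-group cross-sectional cohort with TNBC/otherBC/HD labels."""
    rng = np.random.default_rng(spec.seed)
    blocks = []
    group_means = {
        "HD": spec.hd_mean,
        "otherBC": {k: spec.hd_mean[k] * spec.bc_effect[k] for k in spec.hd_mean},
        "TNBC": {k: spec.hd_mean[k] * spec.bc_effect[k] * spec.tnbc_effect[k]
                 for k in spec.hd_mean},
    }
    sizes = {"TNBC": spec.n_tnbc, "otherBC": spec.n_otherbc, "HD": spec.n_hd}
    idx = 0
    for group in ("TNBC", "otherBC", "HD"):
        X = _lognormal_block(rng, group_means[group], spec.log_sd,
                             spec.lectin_corr, sizes[group])
        df = pd.DataFrame(X, columns=list(LECTINS))
        df.insert(0, "sample_id", [f"S{idx + i:03d}" for i in range(sizes[group])])
        df.insert(1, "group", group)
        idx += sizes[group]
        blocks.append(df)
    out = pd.concat(blocks, ignore_index=True)
    out["age"] = rng.integers(35, 75, size=len(out))
    return out


def gen_longitudinal_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Baseline + follow-up series per patient with PR/SD/PD row labels and a
    per-patient responder flag.

    Responders (no progression within 6 months) get PR/SD follow-ups at days
    90 and 180; non-responders progress at a day drawn within 6 months, with
    an SD visit halfway. Follow-up intensities are the patient's baseline
    times exp(+-slope + noise), identically across lectins.
    """
    rng = np.random.default_rng(spec.seed + 1)
    tnbc_mean = {k: spec.hd_mean[k] * spec.bc_effect[k] * spec.tnbc_effect[k]
                 for k in spec.hd_mean}
    rows = []
    n_total = spec.n_responders + spec.n_nonresponders
    baselines = _lognormal_block(rng, tnbc_mean, spec.log_sd,
                                 spec.lectin_corr, n_total)
    for i in range(n_total):
        responder = i < spec.n_responders
        pid = f"P{i + 1:02d}"
        base = baselines[i]
        rows.append({"patient_id": pid, "timepoint": 0, "response": "BS",
                     "responder": responder,
                     **dict(zip(LECTINS, base))})
        if responder:
            visits = [(90, rng.choice(["PR", "SD"], p=[0.7, 0.3])), (180, "PR")]
        else:
            t_pd = int(rng.integers(90, 181))
            visits = [(t_pd // 2, "SD"), (t_pd, "PD")]
        for day, label in visits:
            if label == "PD":
                shift = spec.pd_log_rise
            elif label == "PR":
                shift = -spec.pr_log_fall
            else:
                shift = 0.0
            noise = rng.normal(0.0, spec.traj_log_noise, size=len(LECTINS))
            vals = base * np.exp(shift + noise)
            rows.append({"patient_id": pid, "timepoint": day, "response": label,
                         "responder": responder, **dict(zip(LECTINS, vals))})
    return pd.DataFrame(rows)


def gen_survival_cohort(spec: CohortSpec = CohortSpec()):
    """Baseline lectin table plus progression-free-survival records.

    The true risk score is the standardized (ConA + WGA - RCA I) combination
    of log intensities. Event times are exponential with log-hazard linear
    in that score (or, with ``binary_covariate``, a two-group hazard with
    ratio ``hazard_ratio`` across the median split). Censoring is
    exponential with a per-subject rate chosen so the expected event
    fraction is exactly 1 - censoring_rate.
    """
    rng = np.random.default_rng(spec.seed + 2)
    tnbc_mean = {k: spec.hd_mean[k] * spec.bc_effect[k] * spec.tnbc_effect[k]
                 for k in spec.hd_mean}
    X = _lognormal_block(rng, tnbc_mean, spec.log_sd, spec.lectin_corr,
                         spec.n_survival)
    table = pd.DataFrame(X, columns=list(LECTINS))
    table.insert(0, "patient_id", [f"Q{i + 1:03d}" for i in range(spec.n_survival)])
    logx = np.log(X)
    raw = logx[:, 0] + logx[:, 1] - logx[:, 2]
    score = (raw - raw.mean()) / raw.std(ddof=0)
    beta = np.log(spec.hazard_ratio)
    if spec.binary_covariate:
        covariate = (score >= np.median(score)).astype(float)
        lam = spec.baseline_hazard * np.exp(beta * covariate)
    else:
        covariate = score
        lam = spec.baseline_hazard * np.exp(beta * score)
    t_event = rng.exponential(1.0 / lam)
    q = spec.censoring_rate
    if q > 0:
        lam_c = lam * q / (1.0 - q)
        t_cens = rng.exponential(1.0 / lam_c)
    else:
        t_cens = np.full(spec.n_survival, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    records = pd.DataFrame({
        "patient_id": table["patient_id"],
        "time": time,
        "event": event,
        "true_score": score,
        "true_covariate": covariate,
        "ca15_3": np.round(rng.lognormal(np.log(20.0) + 0.3 * score, 0.4), 1),
        "ki67_high": (rng.random(spec.n_survival) < 0.5).astype(int),
        "age": rng.integers(35, 75, size=spec.n_survival),
    })
    table["event"] = event
    return table, records


def gen_size_distribution(median_nm: float = 130.0, log_sd: float = 0.35,
                          n_particles: int | None = 2000, seed: int = 0,
                          lo_nm: float = 50.0, hi_nm: float = 290.0,
                          step_nm: float = 20.0) -> SizeDistribution:
    """NTA-style binned size distribution on 20 nm bins.

    Lognormal diameters (median 130 nm: ~24% of EVs below 100 nm). With
    ``n_particles`` set, weights carry multinomial sampling noise like a
    real NTA run; ``n_particles=None`` returns the exact bin probabilities.
    """
    centers = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm)
    edges = np.concatenate([centers - step_nm / 2, [centers[-1] + step_nm / 2]])
    from scipy.stats import lognorm

    dist = lognorm(s=log_sd, scale=median_nm)
    probs = np.diff(dist.cdf(edges))
    probs /= probs.sum()
    if n_particles is not None:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n_particles, probs)
        if counts.sum() == 0:
            raise ValueError("no particles sampled")
        weights = counts / counts.sum()
    else:
        weights = probs
    return SizeDistribution(bin_centers=centers * 1e-9, weights=weights)


def gen_spot_image(size: int = 128, pixel_size: float = 2.0,
                   amplitude: float = 1000.0, sigma_um: float = 25.0,
                   background: float = 100.0, noise_sd: float = 0.0,
                   seed: int = 0) -> FluorescenceImage:
    """Gaussian accumulation spot over a uniform background."""
    if amplitude < 0 or background < 0 or sigma_um <= 0:
        raise ValueError("invalid spot parameters")
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) * pixel_size**2
    img = background + amplitude * np.exp(-r2 / (2 * sigma_um**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, None)
    return FluorescenceImage(intensity=img, pixel_size=pixel_size)


def gen_coloc_events(p: float, n: int, seed: int = 0):
    """Bernoulli colocalization: k successes out of n at probability p."""
    if not 0 <= p <= 1 or n <= 0:
        raise ValueError("need 0 <= p <= 1 and n > 0")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n, p)), n
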