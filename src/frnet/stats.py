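"""Outcome statistics: ROC/AUC with bootstrap CIs, mixed models of event
features, rank-sum tests with Holm correction, PCA of the global measures,
and exact binomial confidence intervals.

The AUC is the Mann-Whitney pair probability (ties counted 1/2), which the
threshold-sweep ROC curve integrates to exactly; bootstrap CIs are
percentile intervals over stratified resamples of contacts.  Event spectral
features are modelled on the natural-log scale with a Gaussian linear mixed
model: random intercept per patient, fixed effects = SOZ indicator plus a
numeric anatomical-location code.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .core import PatientRecord, region_code

__all__ = [
    "ROCResult",
    "MixedModelResult",
    "PCAResult",
    "mann_whitney_auc",
    "roc_auc",
    "bootstrap_auc_ci",
    "auc_difference_test",
    "fit_feature_mixed_model",
    "ranksum_holm",
    "pca_global_measures",
    "binomial_ci",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Threshold-sweep ROC curve and its AUC; NaN AUC on single-class input."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        return ROCResult(
            thresholds=np.array([]),
            sensitivity=np.array([]),
            specificity=np.array([]),
            auc=math.nan,
        )
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def _stratified_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    return np.concatenate(
        [rng.choice(pos, size=pos.size, replace=True), rng.choice(neg, size=neg.size, replace=True)]
    )


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile 95% CI of the AUC over stratified resamples of contacts.

    Resampling is stratified within each label class, so a resample can
    never degenerate to a single class; the redraw guard is retained for
    robustness with pathological inputs.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = _stratified_indices(labels, rng)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
        aucs[b] = mann_whitney_auc(scores[idx], lab)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def auc_difference_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided bootstrap p-value for AUC(a) != AUC(b), paired over contacts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = _stratified_indices(labels, rng)
        lab = labels[idx]
        diffs[b] = mann_whitney_auc(scores_a[idx], lab) - mann_whitney_auc(scores_b[idx], lab)
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(min(1.0, p))


@dataclass
class MixedModelResult:
    response: str
    intercept: float
    soz_coefficient: float
    location_coefficient: float
    intercept_ci: tuple[float, float]
    soz_ci: tuple[float, float]
    location_ci: tuple[float, float]
    df_resid: int
    converged: bool
    used_ols_fallback: bool


def events_to_model_frame(records: list[PatientRecord], subtypes: set[str] | None = None) -> pd.DataFrame:
    """Long-format frame of events with patient, SOZ and location covariates."""
    rows = []
    for rec in records:
        soz = {c.contact_id: c.is_soz for c in rec.contacts}
        region = {c.contact_id: c.region for c in rec.contacts}
        for ev in rec.events:
            if subtypes is not None and ev.subtype not in subtypes:
                continue
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "soz": int(soz[ev.contact_id]),
                    "location": region_code(region[ev.contact_id]),
                    "peak_freq_hz": ev.peak_freq_hz,
                    "peak_power": ev.peak_power,
                    "duration_ms": ev.duration_ms,
                }
            )
    return pd.DataFrame(rows)


def fit_feature_mixed_model(
    frame: pd.DataFrame,
    response: str = "peak_freq_hz",
) -> MixedModelResult:
    """Gaussian LMM of log(response) ~ SOZ + location + (1 | patient).

    Falls back to fixed-effects-only OLS (flagged in the result) when the
    mixed fit is singular or cannot converge — e.g. a single patient, where
    the random-intercept variance is not identifiable and the mixed
    estimates coincide with ordinary least squares.
    """
    df = frame.copy()
    if response not in df.columns:
        raise ValueError(f"unknown response {response!r}")
    df["logy"] = np.log(df[response].astype(float))
    if df["patient_id"].nunique() < 1 or df["soz"].nunique() < 2:
        raise ValueError("need events from both SOZ classes")

    used_fallback = False
    converged = False
    try:
        if df["patient_id"].nunique() < 2:
            raise ValueError("single patient")
        model = smf.mixedlm("logy ~ soz + location", data=df, groups=df["patient_id"])
        with warnings.catch_warnings():
            # near-zero between-patient variance legitimately sits on the
            # boundary of the parameter space; the fixed effects are fine
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        converged = bool(fit.converged)
        if not converged or not np.all(np.isfinite(fit.bse_fe)):
            raise ValueError("singular mixed fit")
        params = fit.fe_params
        ci = fit.conf_int().loc[["Intercept", "soz", "location"]]
        df_resid = int(fit.df_resid)
    except Exception:
        used_fallback = True
        ols = smf.ols("logy ~ soz + location", data=df).fit()
        converged = True
        params = ols.params
        ci = ols.conf_int().loc[["Intercept", "soz", "location"]]
        df_resid = int(ols.df_resid)

    return MixedModelResult(
        response=response,
        intercept=float(params["Intercept"]),
        soz_coefficient=float(params["soz"]),
        location_coefficient=float(params["location"]),
        intercept_ci=(float(ci.loc["Intercept", 0]), float(ci.loc["Intercept", 1])),
        soz_ci=(float(ci.loc["soz", 0]), float(ci.loc["soz", 1])),
        location_ci=(float(ci.loc["location", 0]), float(ci.loc["location", 1])),
        df_resid=df_resid,
        converged=converged,
        used_ols_fallback=used_fallback,
    )


def ranksum_holm(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per comparison with Holm step-down correction.

    Returns one row per comparison with raw and adjusted p-values and
    rejection flags at family-wise error rate ``alpha``.  Small samples
    without ties use the exact null distribution.
    """
    raw = []
    for a, b in comparisons:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"empty group in comparison ({a}, {b})")
        stat = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
        raw.append(stat.pvalue)
    reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in comparisons],
            "group_b": [b for _, b in comparisons],
            "p_raw": raw,
            "p_holm": adjusted,
            "reject": reject,
        }
    )


@dataclass
class PCAResult:
    loadings: np.ndarray  # columns are principal axes
    scores: pd.DataFrame  # per-patient PC scores
    explained_variance: np.ndarray
    excluded_patients: list[str] = field(default_factory=list)


def pca_global_measures(measures: pd.DataFrame, columns: list[str] | None = None) -> PCAResult:
    """PCA of the standardized global-measure matrix across patients.

    Patients with any missing value are excluded (and listed in the result).
    Loadings are orthonormal columns with a deterministic sign convention:
    the largest-magnitude loading of each component is positive.
    """
    if columns is None:
        columns = ["mi_charpath", "mi_mean_local_eff_nonsoz", "mi_strength_diff"]
    df = measures.set_index("patient_id")[columns] if "patient_id" in measures.columns else measures[columns]
    complete = df.dropna()
    excluded = [str(p) for p in df.index.difference(complete.index)]
    if len(complete) < 3:
        raise ValueError("need at least 3 patients with complete measures")
    x = complete.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    var = svals**2
    explained = var / var.sum() if var.sum() > 0 else var
    scores = z @ loadings
    scores_df = pd.DataFrame(
        scores, index=complete.index, columns=[f"PC{k + 1}" for k in range(loadings.shape[1])]
    ).reset_index()
    return PCAResult(
        loadings=loadings,
        scores=scores_df,
        explained_variance=explained,
        excluded_patients=excluded,
    )


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi
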