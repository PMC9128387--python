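"""RBF-SVM classification of surgical non-responders from network features.

Per-patient predictors are the SOZ distance radius, the FR (>350 Hz)
distance and rate-distance radii, and the three MI global measures.  The
positive class is the non-responder.  Training z-scores the features with
training-set statistics only, sets the RBF bandwidth by the median pairwise
distance heuristic (operationalizing an automatically scaled kernel), and
calibrates a sigmoid (Platt) on the training decision scores so that a 0.5
score threshold is meaningful.  Patients whose MI network could not be
constructed carry NaN MI features, filled by the training median or a
constant sentinel; classification of such patients then relies on the
distance and rate-distance predictors.

Two training profiles mirror the two-model design: ``svm1`` trains on all
training patients; ``svm2`` excludes RNS-only / no-resection patients from
training.  A config flag additionally drops zero-FR patients (radius 0
across FR networks) from training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .stats import binomial_ci, roc_auc

__all__ = [
    "FEATURE_COLUMNS",
    "TrainedModel",
    "impute_missing",
    "train_svm",
    "predict_proba",
    "predict_and_score",
    "save_model",
    "load_model",
]

FEATURE_COLUMNS = [
    "soz_radius",
    "fr_distance_radius",
    "fr_rate_distance_radius",
    "mi_charpath",
    "mi_mean_local_eff_nonsoz",
    "mi_strength_diff",
]

SENTINEL_VALUE = 0.0


def impute_missing(
    features: pd.DataFrame,
    strategy: str = "median_of_training",
    training_medians: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill NaN feature values; returns (filled frame, boolean imputation mask).

    ``median_of_training`` uses the provided per-column medians (or, when
    training, medians of the frame itself); ``constant_sentinel`` fills a
    fixed sentinel.  A column with no observed value at all is an error.
    """
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    filled = features.copy()
    mask = features[cols].isna()
    if strategy == "median_of_training":
        medians = training_medians if training_medians is not None else features[cols].median()
        if medians.isna().any():
            bad = list(medians.index[medians.isna()])
            raise ValueError(f"feature column(s) entirely missing: {bad}")
        filled[cols] = features[cols].fillna(medians)
    elif strategy == "constant_sentinel":
        filled[cols] = features[cols].fillna(SENTINEL_VALUE)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return filled, mask


@dataclass
class TrainedModel:
    """A trained, JSON-serializable RBF-SVM with Platt calibration."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    imputation_strategy: str
    training_medians: dict[str, float]
    manifest: dict = field(default_factory=dict)

    def decision_function(self, z: np.ndarray) -> np.ndarray:
        d2 = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=-1)
        kernel = np.exp(-self.gamma * d2)
        return kernel @ self.dual_coef + self.intercept

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"feature column(s) missing from input: {missing}")
        filled, _ = impute_missing(
            features,
            strategy=self.imputation_strategy,
            training_medians=pd.Series(self.training_medians),
        )
        x = filled[self.feature_names].to_numpy(dtype=float)
        return (x - self.mean) / self.sd


def train_svm(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    profile: str = "svm1",
    outcomes: pd.Series | None = None,
    exclude_zero_fr: bool = False,
    imputation_strategy: str = "median_of_training",
    C: float = 1.0,
) -> TrainedModel:
    """Fit the standardized RBF-SVM with Platt-calibrated scores.

    ``features`` must contain ``patient_id`` and the six predictor columns;
    ``labels`` is 1 for non-responders.  ``profile="svm2"`` drops patients
    whose outcome is ``no_resection_rns`` from the training set (requires
    ``outcomes``); ``exclude_zero_fr`` drops patients with no FR network
    extent (all FR radii zero).  All statistics — imputation medians,
    standardization, bandwidth, calibration — come from the retained
    training patients only.
    """
    labels = np.asarray(labels).astype(int)
    keep = np.ones(len(features), dtype=bool)
    if profile == "svm2":
        if outcomes is None:
            raise ValueError("profile 'svm2' requires per-patient outcomes")
        keep &= (np.asarray(outcomes) != "no_resection_rns")
    elif profile != "svm1":
        raise ValueError(f"unknown profile {profile!r}")
    if exclude_zero_fr:
        fr_cols = ["fr_distance_radius", "fr_rate_distance_radius"]
        keep &= ~(features[fr_cols].fillna(0.0) == 0.0).all(axis=1).to_numpy()
    train = features.loc[keep].reset_index(drop=True)
    y = labels[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 training patients per class")

    # degraded mode: a cohort whose MI networks were never constructible has
    # all-NaN MI columns; classification then relies on the radii alone
    feature_cols = [c for c in FEATURE_COLUMNS if train[c].notna().any()]
    if not feature_cols:
        raise ValueError("no usable feature columns")
    medians = train[feature_cols].median()
    filled, _ = impute_missing(train, imputation_strategy, training_medians=medians)
    x = filled[feature_cols].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd

    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=-1)
    pair_d = np.sqrt(d2[np.triu_indices(len(z), k=1)])
    med = float(np.median(pair_d[pair_d > 0])) if np.any(pair_d > 0) else 1.0
    gamma = 1.0 / (2.0 * med**2)

    svc = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
    svc.fit(z, y)
    scores = svc.decision_function(z)
    platt = LogisticRegression(C=1.0, solver="lbfgs")
    platt.fit(scores.reshape(-1, 1), y)

    return TrainedModel(
        feature_names=list(feature_cols),
        mean=mean,
        sd=sd,
        gamma=gamma,
        support_vectors=z[svc.support_],
        dual_coef=svc.dual_coef_.ravel(),
        intercept=float(svc.intercept_[0]),
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
        imputation_strategy=imputation_strategy,
        training_medians={c: float(medians[c]) for c in feature_cols},
        manifest={
            "profile": profile,
            "seed": int(seed),
            "C": float(C),
            "exclude_zero_fr": bool(exclude_zero_fr),
            "training_patients": [str(p) for p in train.get("patient_id", pd.Series(range(len(train))))],
            "n_train": int(len(train)),
        },
    )


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Calibrated probability of the non-responder class per patient."""
    z = model.standardize(features)
    d = model.decision_function(z)
    return 1.0 / (1.0 + np.exp(-(model.platt_a * d + model.platt_b)))


def predict_and_score(
    model: TrainedModel,
    features: pd.DataFrame,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
) -> dict:
    """Per-patient probabilities/classes and, with labels, summary metrics.

    True positive = a non-responder correctly classified as such.
    Sensitivity, specificity, PPV, NPV and accuracy each carry an exact
    binomial (Clopper-Pearson) 95% CI; the full threshold-sweep ROC is
    included when labels are given.
    """
    proba = predict_proba(model, features)
    pred = (proba >= threshold).astype(int)
    out: dict = {
        "probability": proba,
        "predicted_class": pred,
        "threshold": float(threshold),
    }
    if labels is None:
        return out
    y = np.asarray(labels).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())

    def metric(k: int, n: int) -> dict:
        if n == 0:
            return {"value": float("nan"), "ci": (float("nan"), float("nan")), "n": 0}
        lo, hi = binomial_ci(k, n)
        return {"value": k / n, "ci": (lo, hi), "n": n}

    out.update(
        {
            "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
            "sensitivity": metric(tp, tp + fn),
            "specificity": metric(tn, tn + fp),
            "ppv": metric(tp, tp + fp),
            "npv": metric(tn, tn + fn),
            "accuracy": metric(tp + tn, len(y)),
            "roc": roc_auc(proba, y),
        }
    )
    return out


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the model as a versioned JSON bundle."""
    bundle = {
        "format": "frnet-svm/1",
        "feature_names": model.feature_names,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "gamma": model.gamma,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "platt_a": model.platt_a,
        "platt_b": model.platt_b,
        "imputation_strategy": model.imputation_strategy,
        "training_medians": model.training_medians,
        "manifest": model.manifest,
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, sort_keys=True, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format") != "frnet-svm/1":
        raise ValueError("not a frnet SVM bundle")
    return TrainedModel(
        feature_names=list(bundle["feature_names"]),
        mean=np.array(bundle["mean"], dtype=float),
        sd=np.array(bundle["sd"], dtype=float),
        gamma=float(bundle["gamma"]),
        support_vectors=np.array(bundle["support_vectors"], dtype=float),
        dual_coef=np.array(bundle["dual_coef"], dtype=float),
        intercept=float(bundle["intercept"]),
        platt_a=float(bundle["platt_a"]),
        platt_b=float(bundle["platt_b"]),
        imputation_strategy=str(bundle["imputation_strategy"]),
        training_medians={k: float(v) for k, v in bundle["training_medians"].items()},
        manifest=dict(bundle["manifest"]),
    )
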