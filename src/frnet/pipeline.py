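"""End-to-end orchestration: simulate -> networks -> measures -> stats -> classify.

A run is a pure function of (config, inputs): every stage draws its
randomness from seeds derived from the config seed, output files are
written with fixed float formatting and sorted JSON keys, and each output
directory carries a manifest (config hash, seed, package version) that
suffices to reproduce it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import predict_and_score, save_model, train_svm
from .core import (
    FR_SUBTYPES,
    EventFilter,
    PatientRecord,
    compute_rates,
    load_patient,
    save_patient,
)
from .measures import GlobalMeasures, compute_global_measures
from .networks import (
    MIConfig,
    build_distance_network,
    build_mi_network,
    build_rate_distance_network,
    network_to_edgelist,
    select_nodes,
)
from .stats import (
    bootstrap_auc_ci,
    events_to_model_frame,
    fit_feature_mixed_model,
    pca_global_measures,
    ranksum_holm,
    roc_auc,
)
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger("frnet")

__all__ = ["RunConfig", "run_patient", "run_cohort", "patient_measures", "CohortResult"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    subtypes: tuple[str, ...] = tuple(sorted(FR_SUBTYPES))
    min_freq_hz: float | None = 350.0
    mi_min_events_per_contact: int = 5
    mi_target_events_per_cell: int = 4
    radius_method: str = "shortest_path"
    normalize_strength_diff: bool = False
    classifier_profile: str = "svm1"
    imputation_strategy: str = "median_of_training"
    exclude_zero_fr: bool = False
    n_test: int = 0
    n_boot: int = 1000
    seed: int = 0

    @property
    def event_filter(self) -> EventFilter:
        return EventFilter(subtypes=frozenset(self.subtypes), min_freq_hz=self.min_freq_hz)

    @property
    def mi_config(self) -> MIConfig:
        return MIConfig(
            min_events_per_contact=self.mi_min_events_per_contact,
            target_events_per_cell=self.mi_target_events_per_cell,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("cohort", None)
        if data.get("subtypes") is not None:
            data["subtypes"] = tuple(data["subtypes"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "frnet_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2, default=str)
        fh.write("\n")


def patient_measures(record: PatientRecord, config: RunConfig) -> tuple[GlobalMeasures, dict]:
    """All networks and global measures for one patient."""
    flt = config.event_filter
    soz_contacts = [c for c in record.contacts if c.is_soz]
    fr_contacts = select_nodes(record, flt)
    fr_contacts_nonsoz = select_nodes(record, flt, nonsoz_only=True)
    rates = compute_rates(record, flt)

    soz_net = build_distance_network(soz_contacts)
    fr_dist_net = build_distance_network(fr_contacts)
    fr_rate_net = build_rate_distance_network(fr_contacts, rates)
    fr_rate_net_nonsoz = build_rate_distance_network(fr_contacts_nonsoz, rates)
    mi_net = build_mi_network(record, flt, config.mi_config)
    if mi_net is None:
        logger.info("patient %s: MI network not constructible (too few FR events)", record.patient_id)

    gm = compute_global_measures(
        record.patient_id,
        soz_net,
        fr_dist_net,
        fr_rate_net,
        fr_rate_net_nonsoz,
        mi_net,
        radius_method=config.radius_method,
        normalize_strength_diff=config.normalize_strength_diff,
    )
    networks = {
        "soz_distance": soz_net,
        "fr_distance": fr_dist_net,
        "fr_rate_distance": fr_rate_net,
        "fr_rate_distance_nonsoz": fr_rate_net_nonsoz,
        "mi": mi_net,
    }
    return gm, networks


def run_patient(record: PatientRecord, config: RunConfig, outdir: str | Path) -> GlobalMeasures:
    """Compute and write one patient's networks, measures row and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, networks = patient_measures(record, config)
    for name, net in networks.items():
        if net is None:
            continue
        network_to_edgelist(net, outdir / f"{name}_edges.csv", outdir / f"{name}_nodes.csv")
    row = pd.DataFrame([gm.as_dict()])
    row.to_csv(outdir / "measures.csv", index=False, float_format="%.17g")
    _write_manifest(outdir, config, {"patient_id": record.patient_id})
    return gm


@dataclass
class CohortResult:
    measures: pd.DataFrame
    roc_tables: dict
    mixed_model: pd.DataFrame
    pca_scores: pd.DataFrame | None
    ranksum: pd.DataFrame | None
    classifier_train: dict | None
    classifier_test: dict | None


def _binary_labels(records: list[PatientRecord]) -> np.ndarray:
    return np.array([int(r.is_binary_nonresponder) for r in records])


def run_cohort(
    records: list[PatientRecord],
    config: RunConfig,
    outdir: str | Path | None = None,
) -> CohortResult:
    """Cohort-level pipeline: measures table, radius ROC, mixed model, PCA, SVM.

    With ``config.n_test > 0`` the last ``n_test`` patients (catalog order)
    form a held-out test set; all training statistics are computed on the
    remaining patients only.  Patient exclusions (e.g. non-constructible MI
    networks dropped from the PCA) are logged with reasons.
    """
    rows = []
    for rec in records:
        gm, _ = patient_measures(rec, config)
        rows.append(gm.as_dict())
    measures = pd.DataFrame(rows)
    labels = _binary_labels(records)
    outcomes = pd.Series([r.outcome for r in records], name="outcome")
    measures["label"] = labels
    measures["outcome"] = outcomes

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    roc_tables: dict = {}
    for col in ("fr_rate_distance_radius", "fr_rate_distance_radius_nonsoz", "soz_radius", "fr_distance_radius"):
        scores = measures[col].to_numpy(dtype=float)
        roc = roc_auc(scores, labels)
        if math.isnan(roc.auc):
            roc_tables[col] = {"auc": math.nan, "ci": (math.nan, math.nan)}
            continue
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=config.n_boot, seed=rng)
        roc_tables[col] = {"auc": roc.auc, "ci": (lo, hi)}

    frame = events_to_model_frame(records, subtypes={"fRonO"})
    mm_rows = []
    if len(frame) and frame["soz"].nunique() == 2:
        res = fit_feature_mixed_model(frame, "peak_freq_hz")
        mm_rows.append(
            {
                "response": "log_peak_freq_fRonO",
                "intercept": res.intercept,
                "intercept_lo": res.intercept_ci[0],
                "intercept_hi": res.intercept_ci[1],
                "soz": res.soz_coefficient,
                "soz_lo": res.soz_ci[0],
                "soz_hi": res.soz_ci[1],
                "location": res.location_coefficient,
                "location_lo": res.location_ci[0],
                "location_hi": res.location_ci[1],
                "df_resid": res.df_resid,
                "ols_fallback": res.used_ols_fallback,
            }
        )
    mixed_model = pd.DataFrame(mm_rows)

    pca_scores = None
    ranksum = None
    complete = measures.dropna(subset=["mi_charpath", "mi_mean_local_eff_nonsoz", "mi_strength_diff"])
    dropped = sorted(set(measures["patient_id"]) - set(complete["patient_id"]))
    if dropped:
        logger.info("PCA excludes patients without MI networks: %s", dropped)
    if len(complete) >= 3 and complete["label"].nunique() == 2:
        pca = pca_global_measures(measures)
        scored = pca.scores.merge(measures[["patient_id", "label"]], on="patient_id")
        pca_scores = scored
        groups = {
            f"{pc}_{cls}": scored.loc[scored["label"] == lab, pc].to_numpy()
            for pc in ("PC1", "PC2", "PC3")
            for cls, lab in (("responder", 0), ("nonresponder", 1))
        }
        comparisons = [(f"PC{k}_responder", f"PC{k}_nonresponder") for k in (1, 2, 3)]
        ranksum = ranksum_holm(groups, comparisons)

    classifier_train = classifier_test = None
    n_test = config.n_test
    if n_test and len(records) - n_test >= 6:
        train_df = measures.iloc[: len(records) - n_test].reset_index(drop=True)
        test_df = measures.iloc[len(records) - n_test :].reset_index(drop=True)
        if train_df["label"].nunique() == 2 and test_df["label"].nunique() == 2:
            model = train_svm(
                train_df,
                train_df["label"].to_numpy(),
                seed=config.seed,
                profile=config.classifier_profile,
                outcomes=train_df["outcome"],
                exclude_zero_fr=config.exclude_zero_fr,
                imputation_strategy=config.imputation_strategy,
            )
            classifier_train = predict_and_score(model, train_df, train_df["label"].to_numpy())
            classifier_test = predict_and_score(model, test_df, test_df["label"].to_numpy())
            classifier_train["model"] = model

    result = CohortResult(
        measures=measures,
        roc_tables=roc_tables,
        mixed_model=mixed_model,
        pca_scores=pca_scores,
        ranksum=ranksum,
        classifier_train=classifier_train,
        classifier_test=classifier_test,
    )
    if outdir is not None:
        _write_cohort(result, config, Path(outdir))
    return result


def _metrics_jsonable(scored: dict | None) -> dict | None:
    if scored is None:
        return None
    out = {}
    for key in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        m = scored[key]
        out[key] = {"value": m["value"], "ci_lo": m["ci"][0], "ci_hi": m["ci"][1], "n": m["n"]}
    out["auc"] = scored["roc"].auc
    out["confusion"] = scored["confusion"]
    out["threshold"] = scored["threshold"]
    out["probability"] = [float(p) for p in scored["probability"]]
    out["predicted_class"] = [int(c) for c in scored["predicted_class"]]
    return out


def _write_cohort(result: CohortResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.measures.to_csv(outdir / "measures.csv", index=False, float_format="%.17g")
    with open(outdir / "roc_radius.json", "w") as fh:
        json.dump(result.roc_tables, fh, sort_keys=True, indent=2)
        fh.write("\n")
    result.mixed_model.to_csv(outdir / "mixed_model.csv", index=False, float_format="%.17g")
    if result.pca_scores is not None:
        result.pca_scores.to_csv(outdir / "pca_scores.csv", index=False, float_format="%.17g")
    if result.ranksum is not None:
        result.ranksum.to_csv(outdir / "ranksum_holm.csv", index=False, float_format="%.17g")
    metrics = {
        "train": _metrics_jsonable(result.classifier_train),
        "test": _metrics_jsonable(result.classifier_test),
    }
    with open(outdir / "classifier_metrics.json", "w") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=2)
        fh.write("\n")
    if result.classifier_train is not None and "model" in result.classifier_train:
        save_model(result.classifier_train["model"], outdir / "svm_model.json")
    _write_manifest(outdir, config, {"n_patients": int(len(result.measures))})


def simulate_to_dir(spec: CohortSpec, outdir: str | Path) -> list[PatientRecord]:
    """Generate a cohort and emit the per-patient CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(spec)
    for rec in records:
        pdir = outdir / rec.patient_id
        pdir.mkdir(exist_ok=True)
        save_patient(rec, pdir / "catalog.csv", pdir / "contacts.csv", pdir / "meta.json")
    with open(outdir / "cohort_spec.json", "w") as fh:
        json.dump(
            {
                "n_responders": spec.n_responders,
                "n_nonresponders": spec.n_nonresponders,
                "n_rns_nonresponders": spec.n_rns_nonresponders,
                "seed": spec.seed,
                "responder_params": dataclasses.asdict(spec.responder_params),
                "nonresponder_params": dataclasses.asdict(spec.nonresponder_params),
            },
            fh,
            sort_keys=True,
            indent=2,
        )
        fh.write("\n")
    return records


def load_cohort_dir(indir: str | Path) -> list[PatientRecord]:
    """Load every patient subdirectory (catalog.csv, contacts.csv, meta.json)."""
    indir = Path(indir)
    records = []
    for pdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        if not (pdir / "meta.json").exists():
            continue
        records.append(load_patient(pdir / "catalog.csv", pdir / "contacts.csv", pdir / "meta.json"))
    return records
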