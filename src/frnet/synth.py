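"""Synthetic stereo-EEG cohorts with responder / non-responder FR phenotypes.

No patient iEEG is bundled with this package, so every downstream stage is
exercised on simulated cohorts that emulate the relevant statistical
structure of clinical recordings:

* geometry — 8-16 linear depth electrodes with 7-15 contacts at 5 mm
  spacing inside a +/-70 mm MNI bounding box;
* fast-ripple event trains — per-contact Poisson backgrounds plus events
  copied from latent "mother" Poisson processes by independent thinning with
  Gaussian timing jitter (a common-input model, giving analytically
  controllable cross-contact dependence and hence mutual-information
  structure);
* spectral features — log-normal peak frequency with a seizure-onset-zone
  (SOZ) shift on the log scale, optionally truncated to the 250-600 Hz fast
  ripple detector band.

The two phenotypes differ in where fast ripples live: responders carry a
compact, high-rate FR focus confined to a spatially clustered SOZ sharing a
single mother process (hub-centred coupling), while non-responders show
widespread, elevated non-SOZ FR rates coupled through several decentralized
mothers.  Expected per-contact rate under thinning is
``base_rate + thinning_prob * mother_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats

from .core import Contact, HFOEvent, PatientRecord, REGIONS

__all__ = [
    "PhenotypeParams",
    "CohortSpec",
    "responder_defaults",
    "nonresponder_defaults",
    "generate_geometry",
    "generate_event_trains",
    "generate_patient",
    "generate_cohort",
]

_BOX_MM = 70.0  # half-width of the MNI bounding box


@dataclass(frozen=True)
class PhenotypeParams:
    """Generative parameters for one outcome phenotype.

    Rates are events/min, durations minutes, jitter milliseconds; the
    log-frequency parameters are on the natural-log Hz scale (so an
    intercept of 5.47 corresponds to exp(5.47) ~ 237 Hz).
    """

    n_electrodes: int = 10
    contacts_per_electrode: int = 11
    soz_fraction: float = 0.10
    base_rate_soz: float = 1.5
    base_rate_nonsoz: float = 0.2
    logfreq_intercept: float = 5.470
    logfreq_soz_shift: float = 0.178
    logfreq_sd: float = 0.15
    patient_intercept_sd: float = 0.05
    coupling_graph_spec: Literal["hub", "decentralized"] = "hub"
    n_mothers: int = 3  # used by the decentralized spec
    mother_rate: float = 0.5
    thinning_prob_soz: float = 0.4
    thinning_prob_nonsoz: float = 0.05
    jitter_ms: float = 10.0
    duration_min: float = 60.0
    contact_spacing_mm: float = 5.0
    frons_fraction: float = 0.10
    freq_band: tuple[float, float] | None = (250.0, 600.0)

    def __post_init__(self) -> None:
        if not 8 <= self.n_electrodes <= 16:
            raise ValueError("n_electrodes must be in 8..16")
        if not 7 <= self.contacts_per_electrode <= 15:
            raise ValueError("contacts_per_electrode must be in 7..15")
        for name in ("soz_fraction", "thinning_prob_soz", "thinning_prob_nonsoz", "frons_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("base_rate_soz", "base_rate_nonsoz", "mother_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.duration_min > 0:
            raise ValueError("duration_min must be > 0")


def responder_defaults(**overrides) -> PhenotypeParams:
    """Responder phenotype: hub-centred coupling, FR focus confined to a compact SOZ."""
    return replace(PhenotypeParams(), **overrides)


def nonresponder_defaults(**overrides) -> PhenotypeParams:
    """Non-responder phenotype: decentralized coupling, widespread non-SOZ FR."""
    base = PhenotypeParams(
        base_rate_soz=0.8,
        base_rate_nonsoz=0.8,
        logfreq_intercept=5.646,
        logfreq_soz_shift=-0.352,
        coupling_graph_spec="decentralized",
        thinning_prob_soz=0.1,
        thinning_prob_nonsoz=0.3,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class CohortSpec:
    """A reproducible cohort: phenotype parameters, counts and one seed."""

    n_responders: int
    n_nonresponders: int
    responder_params: PhenotypeParams = field(default_factory=responder_defaults)
    nonresponder_params: PhenotypeParams = field(default_factory=nonresponder_defaults)
    n_rns_nonresponders: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ValueError("patient counts must be >= 0")
        if self.n_rns_nonresponders > self.n_nonresponders:
            raise ValueError("n_rns_nonresponders cannot exceed n_nonresponders")


def _n_soz(params: PhenotypeParams) -> int:
    n = params.n_electrodes * params.contacts_per_electrode
    return int(math.floor(params.soz_fraction * n + 0.5))  # round-half-up


def generate_geometry(params: PhenotypeParams, rng: np.random.Generator) -> list[Contact]:
    """Contacts along linear electrode trajectories inside the MNI box.

    SOZ contacts are placed contiguously on the fewest electrodes that can
    hold them for the hub (responder) phenotype, and spread over at least
    three electrodes for the decentralized (non-responder) phenotype.
    """
    n_el, cpe = params.n_electrodes, params.contacts_per_electrode
    extent = (cpe - 1) * params.contact_spacing_mm
    if extent > 2 * _BOX_MM:
        raise ValueError("electrode longer than the bounding box")

    coords = np.empty((n_el * cpe, 3))
    for e in range(n_el):
        for _ in range(1000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            origin = rng.uniform(-_BOX_MM, _BOX_MM, size=3)
            tip = origin + direction * extent
            if np.all(np.abs(tip) <= _BOX_MM):
                break
        else:  # pragma: no cover - rejection virtually never exhausts
            direction = np.array([1.0, 0.0, 0.0])
            origin = np.array([-_BOX_MM, 0.0, 0.0])
        ks = np.arange(cpe)[:, None]
        coords[e * cpe : (e + 1) * cpe] = origin + ks * params.contact_spacing_mm * direction

    n_soz = _n_soz(params)
    if params.coupling_graph_spec == "hub":
        n_soz_el = max(1, math.ceil(n_soz / cpe))
    else:
        n_soz_el = max(3, math.ceil(n_soz / cpe)) if n_soz >= 3 else max(1, n_soz)
    n_soz_el = min(n_soz_el, n_el)
    soz_electrodes = rng.choice(n_el, size=n_soz_el, replace=False)

    soz_flags = np.zeros(n_el * cpe, dtype=bool)
    # distribute SOZ contacts round-robin over the chosen electrodes, filling
    # contiguously from the electrode tip
    per_el = [0] * n_soz_el
    for i in range(n_soz):
        per_el[i % n_soz_el] += 1
    for e_idx, count in zip(soz_electrodes, per_el):
        soz_flags[e_idx * cpe : e_idx * cpe + min(count, cpe)] = True

    contacts = []
    for e in range(n_el):
        region = REGIONS[e % len(REGIONS)]
        for k in range(cpe):
            i = e * cpe + k
            contacts.append(
                Contact(
                    contact_id=f"E{e + 1:02d}C{k + 1:02d}",
                    x=float(coords[i, 0]),
                    y=float(coords[i, 1]),
                    z=float(coords[i, 2]),
                    region=region,
                    is_soz=bool(soz_flags[i]),
                )
            )
    return contacts


def _poisson_train(rate_per_min: float, duration_min: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson onset times (seconds) on [0, duration)."""
    n = rng.poisson(rate_per_min * duration_min)
    return np.sort(rng.uniform(0.0, duration_min * 60.0, size=n))


def _sample_log_freq(
    n: int,
    mean: float,
    sd: float,
    band: tuple[float, float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if band is None:
        return rng.normal(mean, sd, size=n)
    lo, hi = math.log(band[0]), math.log(band[1])
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_event_trains(
    contacts: list[Contact],
    params: PhenotypeParams,
    rng: np.random.Generator,
) -> list[HFOEvent]:
    """Coupled fast-ripple event trains for one patient.

    Each contact's train is an independent Poisson background at its base
    rate superposed with events copied from a latent mother Poisson process
    by independent thinning (probability by SOZ status) and jittered by a
    zero-mean Gaussian (sd = ``jitter_ms``).  Under the hub spec every
    contact shares one mother; under the decentralized spec electrodes are
    distributed round-robin over ``n_mothers`` mothers.  Peak frequency is
    log-normal with the phenotype's SOZ shift and a per-patient random
    intercept, truncated to ``freq_band`` when set.
    """
    duration_s = params.duration_min * 60.0
    patient_intercept = rng.normal(0.0, params.patient_intercept_sd)

    n_mothers = 1 if params.coupling_graph_spec == "hub" else max(1, params.n_mothers)
    mothers = [_poisson_train(params.mother_rate, params.duration_min, rng) for _ in range(n_mothers)]

    events: list[HFOEvent] = []
    for contact in contacts:
        base = params.base_rate_soz if contact.is_soz else params.base_rate_nonsoz
        p_thin = params.thinning_prob_soz if contact.is_soz else params.thinning_prob_nonsoz
        times = _poisson_train(base, params.duration_min, rng)
        if n_mothers == 1:
            mother = mothers[0]
        else:
            e_idx = int(contact.contact_id[1:3]) - 1
            mother = mothers[e_idx % n_mothers]
        if p_thin > 0 and mother.size:
            keep = mother[rng.random(mother.size) < p_thin]
            if keep.size:
                jitter = rng.normal(0.0, params.jitter_ms / 1000.0, size=keep.size)
                coupled = np.clip(keep + jitter, 0.0, duration_s)
                times = np.sort(np.concatenate([times, coupled]))
        n = times.size
        if n == 0:
            continue
        mean_log = params.logfreq_intercept + (params.logfreq_soz_shift if contact.is_soz else 0.0)
        log_f = _sample_log_freq(n, mean_log + patient_intercept, params.logfreq_sd, params.freq_band, rng)
        freqs = np.exp(log_f)
        subtypes = np.where(rng.random(n) < params.frons_fraction, "fRonS", "fRonO")
        powers = np.exp(rng.normal(2.5, 0.5, size=n))
        durations = np.exp(rng.normal(2.3, 0.3, size=n))
        for i in range(n):
            events.append(
                HFOEvent(
                    contact_id=contact.contact_id,
                    onset_s=float(times[i]),
                    subtype=str(subtypes[i]),
                    peak_freq_hz=float(freqs[i]),
                    peak_power=float(powers[i]),
                    duration_ms=float(durations[i]),
                )
            )
    events.sort(key=lambda ev: (ev.onset_s, ev.contact_id))
    return events


def generate_patient(
    patient_id: str,
    params: PhenotypeParams,
    outcome: str,
    rng: np.random.Generator,
) -> PatientRecord:
    contacts = generate_geometry(params, rng)
    events = generate_event_trains(contacts, params, rng)
    return PatientRecord(
        patient_id=patient_id,
        contacts=contacts,
        events=events,
        duration_min=params.duration_min,
        outcome=outcome,
    )


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """A reproducible cohort of responders followed by non-responders.

    The last ``n_rns_nonresponders`` non-responders are labelled
    ``no_resection_rns`` (treated with RNS only or not offered resection;
    considered non-responders for binary classification but excludable from
    SVM-2 training).
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_responders + spec.n_nonresponders)
    records: list[PatientRecord] = []
    for i in range(spec.n_responders):
        rng = np.random.default_rng(children[i])
        records.append(generate_patient(f"R{i + 1:03d}", spec.responder_params, "responder", rng))
    for j in range(spec.n_nonresponders):
        rng = np.random.default_rng(children[spec.n_responders + j])
        outcome = (
            "no_resection_rns"
            if j >= spec.n_nonresponders - spec.n_rns_nonresponders
            else "non_responder"
        )
        records.append(
            generate_patient(f"N{j + 1:03d}", spec.nonresponder_params, outcome, rng)
        )
    return records
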