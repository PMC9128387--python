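"""Domain types and I/O for inter-ictal HFO event catalogs.

The unit of analysis is a patient: a set of depth-electrode contacts (with
normalized MNI coordinates and a seizure-onset-zone flag) and a catalog of
timestamped high-frequency-oscillation events detected on those contacts
during non-REM sleep iEEG.  Events carry a subtype (ripple / fast ripple, on
oscillation / on spike, or sharp-spike), a peak spectral frequency, peak
power and duration.  Everything downstream — rate tables, distance,
rate-distance and mutual-information networks — is built from these records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SUBTYPES",
    "FR_SUBTYPES",
    "OUTCOMES",
    "REGIONS",
    "SchemaError",
    "IntegrityError",
    "Contact",
    "HFOEvent",
    "PatientRecord",
    "EventFilter",
    "FR_GT_350",
    "load_patient",
    "save_patient",
    "filter_events",
    "compute_rates",
    "region_code",
]

#: Closed vocabulary of event subtypes.  Ripples (80-250 Hz) and fast
#: ripples (250-600 Hz) either ride on a background oscillation (onO) or are
#: superimposed on an epileptiform spike (onS); sharp-spikes are epileptiform
#: transients without true oscillatory content.
SUBTYPES = frozenset({"RonO", "RonS", "fRonO", "fRonS", "sharp_spike"})

#: Fast-ripple subtypes, the substrate of the FR networks.
FR_SUBTYPES = frozenset({"fRonO", "fRonS"})

OUTCOMES = frozenset({"responder", "non_responder", "no_resection_rns", "unknown"})

#: Fixed anatomical region order; the numeric location covariate used by the
#: mixed models is the index into this tuple.  Replaceable by downstream code
#: that carries its own coding table.
REGIONS = (
    "frontal",
    "temporal",
    "limbic",
    "hippocampus",
    "parietal",
    "occipital",
    "insula",
    "other",
)

_CATALOG_COLUMNS = ["contact_id", "onset_s", "subtype", "peak_freq_hz", "peak_power", "duration_ms"]
_CONTACT_COLUMNS = ["contact_id", "x_mni", "y_mni", "z_mni", "region", "is_soz"]


class SchemaError(ValueError):
    """A file does not conform to the expected tabular schema."""


class IntegrityError(ValueError):
    """Data violates a cross-record invariant (unknown contact, bad subtype, ...)."""


def region_code(region: str, regions: Sequence[str] = REGIONS) -> int:
    """Numeric location code for a region label (unknown labels map to 'other')."""
    try:
        return regions.index(region)
    except ValueError:
        return len(regions) - 1


@dataclass(frozen=True)
class Contact:
    """An electrode recording site with normalized MNI coordinates (mm)."""

    contact_id: str
    x: float
    y: float
    z: float
    region: str
    is_soz: bool

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise IntegrityError(f"contact {self.contact_id}: non-finite coordinate")


@dataclass(frozen=True)
class HFOEvent:
    """A single detected HFO / sharp-spike event on one contact."""

    contact_id: str
    onset_s: float
    subtype: str
    peak_freq_hz: float
    peak_power: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise IntegrityError(
                f"unknown subtype {self.subtype!r}; expected one of {sorted(SUBTYPES)}"
            )
        if self.onset_s < 0:
            raise IntegrityError(f"event on {self.contact_id}: negative onset {self.onset_s}")
        if not self.peak_freq_hz > 0:
            raise IntegrityError(f"event on {self.contact_id}: peak_freq_hz must be > 0")


@dataclass
class PatientRecord:
    """A patient's contacts, event catalog, recording duration and outcome.

    ``duration_min`` is the analyzed recording duration in minutes; event
    onsets are seconds from recording start.  ``outcome`` distinguishes
    surgical responders, non-responders, and patients treated with RNS only
    or not offered resection (considered non-responders for binary
    classification, but kept distinct in the data model).
    """

    patient_id: str
    contacts: list[Contact]
    events: list[HFOEvent]
    duration_min: float
    outcome: str = "unknown"

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise IntegrityError(f"{self.patient_id}: duration_min must be > 0")
        if self.outcome not in OUTCOMES:
            raise IntegrityError(
                f"{self.patient_id}: outcome {self.outcome!r} not in {sorted(OUTCOMES)}"
            )
        ids = [c.contact_id for c in self.contacts]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"{self.patient_id}: duplicate contact ids")
        known = set(ids)
        dur_s = self.duration_min * 60.0
        for ev in self.events:
            if ev.contact_id not in known:
                raise IntegrityError(
                    f"{self.patient_id}: event references unknown contact {ev.contact_id!r}"
                )
            if ev.onset_s > dur_s:
                raise IntegrityError(
                    f"{self.patient_id}: event onset {ev.onset_s:.3f}s exceeds recording "
                    f"duration {dur_s:.1f}s"
                )

    @property
    def contact_ids(self) -> list[str]:
        return [c.contact_id for c in self.contacts]

    @property
    def is_binary_nonresponder(self) -> bool:
        """Binary label: RNS-only / no-resection patients count as non-responders."""
        return self.outcome in ("non_responder", "no_resection_rns")


@dataclass(frozen=True)
class EventFilter:
    """A subtype + frequency filter.

    ``min_freq_hz`` is a strict lower bound on peak spectral frequency: an
    event at exactly the threshold is excluded.  ``None`` disables the
    frequency criterion.
    """

    subtypes: frozenset[str] = FR_SUBTYPES
    min_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if not self.subtypes:
            raise ValueError("subtypes must be non-empty")
        unknown = set(self.subtypes) - SUBTYPES
        if unknown:
            raise ValueError(f"unknown subtypes in filter: {sorted(unknown)}")

    def matches(self, event: HFOEvent) -> bool:
        if event.subtype not in self.subtypes:
            return False
        if self.min_freq_hz is not None and not event.peak_freq_hz > self.min_freq_hz:
            return False
        return True


#: The headline filter: fast ripples with peak spectral frequency above 350 Hz.
FR_GT_350 = EventFilter(subtypes=FR_SUBTYPES, min_freq_hz=350.0)


def filter_events(
    record: PatientRecord,
    subtypes: Iterable[str] | EventFilter,
    min_freq_hz: float | None = None,
) -> list[HFOEvent]:
    """Events of the requested subtypes with peak frequency strictly above threshold.

    Order of the catalog is preserved; an empty result is valid.
    """
    if isinstance(subtypes, EventFilter):
        flt = subtypes
    else:
        flt = EventFilter(subtypes=frozenset(subtypes), min_freq_hz=min_freq_hz)
    return [ev for ev in record.events if flt.matches(ev)]


def compute_rates(
    record: PatientRecord,
    event_filter: EventFilter | None = None,
) -> dict[str, float]:
    """Per-contact event rate (events/min) under a filter.

    Every contact appears in the result; contacts with no matching events get
    rate 0.  Rates are exact counts divided by ``duration_min``.
    """
    if not record.duration_min > 0:
        raise ValueError("duration_min must be > 0")
    events = record.events if event_filter is None else filter_events(record, event_filter)
    counts: dict[str, int] = {cid: 0 for cid in record.contact_ids}
    for ev in events:
        counts[ev.contact_id] += 1
    return {cid: n / record.duration_min for cid, n in counts.items()}


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def load_patient(
    catalog_path: str | Path,
    contacts_path: str | Path,
    meta_path: str | Path,
) -> PatientRecord:
    """Read a patient from the catalog CSV, contact CSV and metadata JSON."""
    contacts_df = pd.read_csv(contacts_path, dtype={"contact_id": str}, float_precision="round_trip")
    _require_columns(contacts_df, _CONTACT_COLUMNS, f"contacts file {contacts_path}")
    catalog_df = pd.read_csv(catalog_path, dtype={"contact_id": str}, float_precision="round_trip")
    _require_columns(catalog_df, _CATALOG_COLUMNS, f"catalog file {catalog_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("patient_id", "duration_min", "outcome"):
        if key not in meta:
            raise SchemaError(f"metadata file {meta_path}: missing key {key!r}")

    contacts = [
        Contact(
            contact_id=row.contact_id,
            x=float(row.x_mni),
            y=float(row.y_mni),
            z=float(row.z_mni),
            region=str(row.region),
            is_soz=bool(int(row.is_soz)),
        )
        for row in contacts_df.itertuples(index=False)
    ]
    events = [
        HFOEvent(
            contact_id=row.contact_id,
            onset_s=float(row.onset_s),
            subtype=str(row.subtype),
            peak_freq_hz=float(row.peak_freq_hz),
            peak_power=float(row.peak_power),
            duration_ms=float(row.duration_ms),
        )
        for row in catalog_df.itertuples(index=False)
    ]
    return PatientRecord(
        patient_id=str(meta["patient_id"]),
        contacts=contacts,
        events=events,
        duration_min=float(meta["duration_min"]),
        outcome=str(meta["outcome"]),
    )


def save_patient(
    record: PatientRecord,
    catalog_path: str | Path,
    contacts_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write a patient back to the three-file on-disk form (CSV + CSV + JSON)."""
    contacts_df = pd.DataFrame(
        [
            {
                "contact_id": c.contact_id,
                "x_mni": c.x,
                "y_mni": c.y,
                "z_mni": c.z,
                "region": c.region,
                "is_soz": int(c.is_soz),
            }
            for c in record.contacts
        ],
        columns=_CONTACT_COLUMNS,
    )
    catalog_df = pd.DataFrame(
        [
            {
                "contact_id": ev.contact_id,
                "onset_s": ev.onset_s,
                "subtype": ev.subtype,
                "peak_freq_hz": ev.peak_freq_hz,
                "peak_power": ev.peak_power,
                "duration_ms": ev.duration_ms,
            }
            for ev in record.events
        ],
        columns=_CATALOG_COLUMNS,
    )
    contacts_df.to_csv(contacts_path, index=False, float_format="%.17g")
    catalog_df.to_csv(catalog_path, index=False, float_format="%.17g")
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "patient_id": record.patient_id,
                "duration_min": record.duration_min,
                "outcome": record.outcome,
            },
            fh,
            sort_keys=True,
            indent=2,
        )
        fh.write("\n")
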