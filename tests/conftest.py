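import numpy as np
import pytest

from frnet.core import Contact, HFOEvent, PatientRecord
from frnet.networks import Network


def make_contact(cid, x=0.0, y=0.0, z=0.0, region="temporal", is_soz=False):
    return Contact(contact_id=cid, x=x, y=y, z=z, region=region, is_soz=is_soz)


def make_event(cid, onset_s, subtype="fRonO", peak_freq_hz=400.0, peak_power=5.0, duration_ms=12.0):
    return HFOEvent(
        contact_id=cid,
        onset_s=onset_s,
        subtype=subtype,
        peak_freq_hz=peak_freq_hz,
        peak_power=peak_power,
        duration_ms=duration_ms,
    )


def make_network(adjacency, kind="mi", is_soz=None, ids=None):
    adjacency = np.asarray(adjacency, dtype=float)
    n = adjacency.shape[0]
    return Network(
        node_ids=ids or [f"C{i}" for i in range(n)],
        is_soz=np.zeros(n, dtype=bool) if is_soz is None else np.asarray(is_soz, bool),
        adjacency=adjacency,
        kind=kind,
    )


@pytest.fixture
def tiny_record():
    """Three contacts on a line, a handful of events across subtypes."""
    contacts = [
        make_contact("A", 0, 0, 0, is_soz=True),
        make_contact("B", 3, 4, 0),
        make_contact("C", 10, 0, 0),
    ]
    events = [
        make_event("A", 1.0, "fRonO", 360.0),
        make_event("A", 2.0, "fRonO", 340.0),
        make_event("B", 3.0, "fRonS", 350.0),
        make_event("B", 4.0, "RonO", 120.0),
        make_event("C", 5.0, "sharp_spike", 200.0),
        make_event("C", 6.0, "fRonO", 500.0),
    ]
    return PatientRecord(
        patient_id="P1", contacts=contacts, events=events, duration_min=6.0, outcome="responder"
    )


def random_symmetric_network(rng, n, kind="mi", density=0.7, scale=1.0):
    """Random symmetric non-negative zero-diagonal weighted graph."""
    w = rng.uniform(0.1, scale, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return make_network(w, kind=kind)
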