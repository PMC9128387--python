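"""Weighted graph-theoretic measures of the per-patient FR networks.

Path-based measures run on a length matrix derived from the adjacency by the
kind-appropriate convention: for distance and rate-distance networks the
weight IS a length; for MI (correlational) networks length = 1/weight, the
standard weight-to-length conversion, with zero-weight pairs disconnected.

Conventions for degenerate graphs, chosen so that every patient gets finite
features (a patient with no fast ripples above threshold has the minimal
network extent, not a missing value):

* empty or single-node network -> radius 0;
* disconnected network -> radius and characteristic path length over the
  largest connected component (infinite pairs excluded);
* characteristic path length of a <2-node network -> NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .networks import Network

__all__ = [
    "GlobalMeasures",
    "length_matrix",
    "shortest_paths",
    "radius",
    "characteristic_path_length",
    "local_efficiency",
    "nodal_strength",
    "compute_global_measures",
]


def length_matrix(network: Network) -> np.ndarray:
    """Edge lengths from weights (inf = no edge), by network kind."""
    w = network.adjacency
    n = network.n_nodes
    lengths = np.full((n, n), np.inf)
    mask = w > 0
    if network.kind == "mi":
        lengths[mask] = 1.0 / w[mask]
    else:
        lengths[mask] = w[mask]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(network: Network) -> np.ndarray:
    """All-pairs shortest-path lengths; unreachable pairs are +inf."""
    if network.n_nodes == 0:
        return np.zeros((0, 0))
    lengths = length_matrix(network)
    finite = np.where(np.isinf(lengths), 0.0, lengths)
    return shortest_path(finite, method="D", directed=False, unweighted=False)


def _largest_component(network: Network) -> np.ndarray:
    """Indices of the largest connected component (ties: lowest label wins)."""
    mask = network.adjacency > 0
    n_comp, labels = connected_components(mask, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return np.flatnonzero(labels == int(np.argmax(sizes)))


def radius(network: Network, method: str = "shortest_path") -> float:
    """Min over nodes of eccentricity (max path length to any other node).

    ``method="shortest_path"`` (default) uses the shortest-path metric;
    ``method="direct"`` uses raw adjacency entries as the distances (the two
    coincide for Euclidean distance networks).  Empty and single-node
    networks have radius 0; disconnected networks are measured on the
    largest connected component.
    """
    if network.n_nodes <= 1:
        return 0.0
    comp = _largest_component(network)
    if comp.size <= 1:
        return 0.0
    sub = Network(
        node_ids=[network.node_ids[i] for i in comp],
        is_soz=network.is_soz[comp],
        adjacency=network.adjacency[np.ix_(comp, comp)],
        kind=network.kind,
    )
    if method == "direct":
        d = length_matrix(sub)
    elif method == "shortest_path":
        d = shortest_paths(sub)
    else:
        raise ValueError(f"unknown radius method {method!r}")
    ecc = np.nanmax(np.where(np.isinf(d), np.nan, d), axis=1)
    return float(np.nanmin(ecc))


def characteristic_path_length(network: Network) -> float:
    """Mean finite off-diagonal shortest-path length; NaN for <2 nodes."""
    if network.n_nodes < 2:
        return math.nan
    d = shortest_paths(network)
    off = ~np.eye(network.n_nodes, dtype=bool)
    vals = d[off]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def nodal_strength(network: Network, node: int | str) -> float:
    """Sum of the node's incident edge weights."""
    i = network.node_ids.index(node) if isinstance(node, str) else node
    return float(network.adjacency[i].sum())


def local_efficiency(network: Network, node: int | str) -> float:
    """Weighted local efficiency of one node.

    Efficiency of the subgraph induced by the node's neighbours: for
    neighbour pairs (j, h), combine the connecting weights w_uj, w_uh with
    the inverse shortest-path length between j and h inside the
    neighbourhood via cube-root weighting, and normalize by k(k-1):

        E_loc(u) = sum_{j != h} (w_uj * w_uh / d_jh)^(1/3) / (k (k - 1))

    Nodes with fewer than two neighbours have local efficiency 0.
    """
    u = network.node_ids.index(node) if isinstance(node, str) else node
    w = network.adjacency
    nbrs = np.flatnonzero(w[u] > 0)
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = Network(
        node_ids=[network.node_ids[i] for i in nbrs],
        is_soz=network.is_soz[nbrs],
        adjacency=w[np.ix_(nbrs, nbrs)],
        kind=network.kind,
    )
    d = shortest_paths(sub)
    with np.errstate(divide="ignore"):
        inv_d = np.where(d > 0, 1.0 / d, 0.0)
    inv_d[np.isinf(d)] = 0.0
    np.fill_diagonal(inv_d, 0.0)
    wu = w[u, nbrs]
    terms = np.cbrt(wu[:, None] * wu[None, :] * inv_d)
    np.fill_diagonal(terms, 0.0)
    return float(terms.sum() / (k * (k - 1)))


@dataclass
class GlobalMeasures:
    """Per-patient feature vector consumed by the outcome classifier.

    Radii in mm (distance) or mm*events/min (rate-distance); the three MI
    measures are the characteristic path length (1/bits length units), the
    mean local efficiency of non-SOZ nodes, and the summed nodal-strength
    difference of non-SOZ minus SOZ nodes (bits).  NaN marks measures of a
    non-constructible MI network.
    """

    patient_id: str
    soz_radius: float
    fr_distance_radius: float
    fr_rate_distance_radius: float
    fr_rate_distance_radius_nonsoz: float
    mi_charpath: float
    mi_mean_local_eff_nonsoz: float
    mi_strength_diff: float

    FIELDS = (
        "soz_radius",
        "fr_distance_radius",
        "fr_rate_distance_radius",
        "fr_rate_distance_radius_nonsoz",
        "mi_charpath",
        "mi_mean_local_eff_nonsoz",
        "mi_strength_diff",
    )

    def as_dict(self) -> dict[str, float]:
        return {"patient_id": self.patient_id, **{f: getattr(self, f) for f in self.FIELDS}}


def compute_global_measures(
    patient_id: str,
    soz_distance_net: Network,
    fr_distance_net: Network,
    fr_rate_net: Network,
    fr_rate_net_nonsoz: Network,
    mi_net: Network | None,
    radius_method: str = "shortest_path",
    normalize_strength_diff: bool = False,
) -> GlobalMeasures:
    """Assemble the radii and the three MI global measures for one patient.

    ``mi_strength_diff`` is the unnormalized sum over non-SOZ nodes minus
    the sum over SOZ nodes; ``normalize_strength_diff`` divides each sum by
    its node count (mean-per-node variant, off by default).  A missing MI
    network yields NaN for the three MI measures while the radii are still
    computed.
    """
    if mi_net is None:
        charpath = eff = sdiff = math.nan
    else:
        charpath = characteristic_path_length(mi_net)
        nonsoz = np.flatnonzero(~mi_net.is_soz)
        soz = np.flatnonzero(mi_net.is_soz)
        # empty non-SOZ node set in a constructible network -> 0 (no
        # non-SOZ connectivity), distinct from the NaN of a missing network
        eff = (
            float(np.mean([local_efficiency(mi_net, int(i)) for i in nonsoz]))
            if nonsoz.size
            else 0.0
        )
        s_nonsoz = float(sum(nodal_strength(mi_net, int(i)) for i in nonsoz))
        s_soz = float(sum(nodal_strength(mi_net, int(i)) for i in soz))
        if normalize_strength_diff:
            s_nonsoz = s_nonsoz / nonsoz.size if nonsoz.size else 0.0
            s_soz = s_soz / soz.size if soz.size else 0.0
        sdiff = s_nonsoz - s_soz
    return GlobalMeasures(
        patient_id=patient_id,
        soz_radius=radius(soz_distance_net, radius_method),
        fr_distance_radius=radius(fr_distance_net, radius_method),
        fr_rate_distance_radius=radius(fr_rate_net, radius_method),
        fr_rate_distance_radius_nonsoz=radius(fr_rate_net_nonsoz, radius_method),
        mi_charpath=charpath,
        mi_mean_local_eff_nonsoz=eff,
        mi_strength_diff=sdiff,
    )
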