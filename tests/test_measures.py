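import math

import numpy as np
import pytest

from frnet.measures import (
    characteristic_path_length,
    compute_global_measures,
    local_efficiency,
    nodal_strength,
    radius,
    shortest_paths,
)
from frnet.networks import build_distance_network

from conftest import make_contact, make_network, random_symmetric_network


# ---------------------------------------------------------------- oracles


def floyd_warshall_oracle(lengths):
    """Classic triple-loop all-pairs shortest paths on a length matrix."""
    n = lengths.shape[0]
    d = lengths.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def to_lengths(net):
    w = net.adjacency
    lengths = np.full_like(w, np.inf)
    mask = w > 0
    lengths[mask] = 1.0 / w[mask] if net.kind == "mi" else w[mask]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def radius_oracle(net):
    d = floyd_warshall_oracle(to_lengths(net))
    n = d.shape[0]
    if n <= 1:
        return 0.0
    # largest connected component (lowest label on ties)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in range(n) if v != u and net.adjacency[u, v] > 0)
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=len)
    if len(comp) <= 1:
        return 0.0
    sub = d[np.ix_(comp, comp)]
    return float(min(max(row) for row in sub))


def charpath_oracle(net):
    d = floyd_warshall_oracle(to_lengths(net))
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d)) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else math.nan


def local_efficiency_oracle(net, u):
    w = net.adjacency
    nbrs = [j for j in range(net.n_nodes) if w[u, j] > 0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    sub = make_network(w[np.ix_(nbrs, nbrs)], kind=net.kind)
    d = floyd_warshall_oracle(to_lengths(sub))
    total = 0.0
    for a in range(k):
        for b in range(k):
            if a == b or not np.isfinite(d[a, b]) or d[a, b] == 0:
                continue
            total += (w[u, nbrs[a]] * w[u, nbrs[b]] / d[a, b]) ** (1.0 / 3.0)
    return total / (k * (k - 1))


# ---------------------------------------------------------------- examples


class TestShortestPaths:
    def test_collinear_distance_network_uses_direct_edges(self):
        contacts = [make_contact(c, x) for c, x in (("A", 0.0), ("B", 10.0), ("C", 20.0))]
        net = build_distance_network(contacts)
        d = shortest_paths(net)
        assert d[0, 2] == pytest.approx(20.0)

    def test_rate_distance_detour_is_shorter(self):
        net = make_network([[0, 10, 60], [10, 0, 30], [60, 30, 0]], kind="rate_distance")
        d = shortest_paths(net)
        assert d[0, 2] == pytest.approx(40.0)

    def test_mi_reciprocal_lengths(self):
        net = make_network([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]], kind="mi")
        d = shortest_paths(net)
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 2] == pytest.approx(4.0)


class TestRadius:
    def test_symmetric_pair(self):
        net = make_network([[0, 10], [10, 0]], kind="distance")
        assert radius(net) == pytest.approx(10.0)

    def test_hand_computed_eccentricities(self):
        net = make_network([[0, 10, 60], [10, 0, 30], [60, 30, 0]], kind="rate_distance")
        # shortest paths AB=10, BC=30, AC=40 -> eccentricities 40, 30, 40
        assert radius(net) == pytest.approx(30.0)

    def test_empty_and_singleton_are_zero(self):
        assert radius(make_network(np.zeros((0, 0)))) == 0.0
        assert radius(make_network(np.zeros((1, 1)))) == 0.0

    def test_disconnected_uses_largest_component(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 2.0
        w[2, 3] = w[3, 2] = 5.0
        w[3, 4] = w[4, 3] = 7.0
        net = make_network(w, kind="distance")
        assert radius(net) == pytest.approx(7.0)  # component {2,3,4}, centre 3

    def test_direct_method_matches_on_distance_networks(self):
        rng = np.random.default_rng(0)
        contacts = [make_contact(f"C{i}", *rng.uniform(-50, 50, 3)) for i in range(8)]
        net = build_distance_network(contacts)
        assert radius(net, "direct") == pytest.approx(radius(net, "shortest_path"))


class TestCharPath:
    def test_mi_chain(self):
        net = make_network([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]], kind="mi")
        assert characteristic_path_length(net) == pytest.approx(8.0 / 3.0)

    def test_unit_mi_triangle(self):
        net = make_network(1 - np.eye(3), kind="mi")
        assert characteristic_path_length(net) == pytest.approx(1.0)

    def test_single_node_undefined(self):
        assert math.isnan(characteristic_path_length(make_network(np.zeros((1, 1)))))


class TestLocalEfficiencyAndStrength:
    def test_isolated_node_zero(self):
        w = np.zeros((3, 3))
        w[1, 2] = w[2, 1] = 1.0
        assert local_efficiency(make_network(w), 0) == 0.0

    def test_unit_triangle_is_one(self):
        net = make_network(1 - np.eye(3), kind="mi")
        for u in range(3):
            assert local_efficiency(net, u) == pytest.approx(1.0)

    def test_strength_sum_and_handshake(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.3
        net = make_network(w)
        assert nodal_strength(net, 0) == pytest.approx(0.5)
        assert nodal_strength(net, "C1") == pytest.approx(0.2)
        total = sum(nodal_strength(net, u) for u in range(3))
        assert total == pytest.approx(2 * w[np.triu_indices(3, 1)].sum())


# ---------------------------------------------------------------- properties


@pytest.mark.parametrize("kind", ["distance", "rate_distance", "mi"])
def test_measures_match_brute_force_oracles(kind):
    rng = np.random.default_rng(hash(kind) % (2**31))
    for _ in range(40):
        n = int(rng.integers(2, 11))
        net = random_symmetric_network(rng, n, kind=kind, density=float(rng.uniform(0.3, 1.0)))
        assert radius(net) == pytest.approx(radius_oracle(net), abs=1e-9)
        cp, cpo = characteristic_path_length(net), charpath_oracle(net)
        assert (math.isnan(cp) and math.isnan(cpo)) or cp == pytest.approx(cpo, abs=1e-9)
        for u in range(n):
            assert local_efficiency(net, u) == pytest.approx(local_efficiency_oracle(net, u), abs=1e-9)
            assert nodal_strength(net, u) == pytest.approx(net.adjacency[u].sum(), abs=1e-12)


def test_radius_never_exceeds_diameter():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n = int(rng.integers(2, 10))
        net = random_symmetric_network(rng, n, kind="mi", density=1.0)
        d = shortest_paths(net)
        ecc = d.max(axis=1)
        assert ecc.min() <= ecc.max() + 1e-12
        assert radius(net) == pytest.approx(ecc.min())


def test_euclidean_shortest_paths_equal_direct_edges():
    rng = np.random.default_rng(13)
    contacts = [make_contact(f"C{i}", *rng.uniform(-70, 70, 3)) for i in range(10)]
    net = build_distance_network(contacts)
    assert np.allclose(shortest_paths(net), net.adjacency, atol=1e-9)


# ---------------------------------------------------------------- global measures


class TestGlobalMeasures:
    def _distance_pair(self):
        return build_distance_network([make_contact("A", 0), make_contact("B", 10)])

    def test_equal_strength_half_soz_gives_zero_diff(self):
        w = 0.4 * (1 - np.eye(4))
        mi = make_network(w, kind="mi", is_soz=[True, True, False, False])
        gm = compute_global_measures("p", self._distance_pair(), self._distance_pair(), self._distance_pair(), self._distance_pair(), mi)
        assert gm.mi_strength_diff == pytest.approx(0.0)

    def test_all_nonsoz_diff_is_total_strength(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[1, 2] = w[2, 1] = 0.3
        mi = make_network(w, kind="mi")
        gm = compute_global_measures("p", self._distance_pair(), self._distance_pair(), self._distance_pair(), self._distance_pair(), mi)
        assert gm.mi_strength_diff == pytest.approx(2 * 0.5)

    def test_missing_mi_network_yields_nan_markers_but_radii(self):
        gm = compute_global_measures("p", self._distance_pair(), self._distance_pair(), self._distance_pair(), self._distance_pair(), None)
        assert math.isnan(gm.mi_charpath)
        assert math.isnan(gm.mi_mean_local_eff_nonsoz)
        assert math.isnan(gm.mi_strength_diff)
        assert gm.soz_radius == pytest.approx(10.0)

    def test_normalized_strength_variant(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.6
        mi = make_network(w, kind="mi", is_soz=[True, False, False])
        gm = compute_global_measures(
            "p", self._distance_pair(), self._distance_pair(), self._distance_pair(), self._distance_pair(), mi,
            normalize_strength_diff=True,
        )
        assert gm.mi_strength_diff == pytest.approx((0.6 + 0.0) / 2 - 0.6 / 1)
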