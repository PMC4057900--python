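"""Congener parsing, canonicalization, and skeleton-graph distances."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.sparse.csgraph import floyd_warshall

from mdevqspr import (
    CongenerSpec,
    all_pairs_distances,
    build_skeleton,
    enumerate_canonical_congeners,
    parse_congener,
)
from mdevqspr.congener_graph import SkeletonGraph
from mdevqspr.errors import (
    ConnectivityError,
    DuplicateSubstitutionError,
    EmptySpecError,
    InvalidPositionError,
)

ring_strategy = st.frozensets(st.sampled_from([2, 3, 4, 5, 6]), max_size=5)
spec_strategy = st.builds(CongenerSpec, ring_strategy, ring_strategy)


@pytest.mark.parametrize(
    "text, ring_a, ring_b",
    [
        ("2,2′,4,4′", {2, 4}, {2, 4}),
        ("2,2',4,4'", {2, 4}, {2, 4}),  # ASCII apostrophes
        (" 2 , 2' , 4 , 4' ", {2, 4}, {2, 4}),
        ("3", {3}, set()),
        ("2,4 -dibro", {2, 4}, set()),  # tolerated homolog suffix
        ("2,4'", {2}, {4}),
    ],
)
def test_parse_congener(text, ring_a, ring_b):
    spec = parse_congener(text)
    assert spec.ring_a == frozenset(ring_a)
    assert spec.ring_b == frozenset(ring_b)


@pytest.mark.parametrize(
    "text, error",
    [
        ("1,4", InvalidPositionError),   # ipso carbon cannot carry Br
        ("2,11", InvalidPositionError),
        ("2,2", DuplicateSubstitutionError),
        ("", EmptySpecError),
        ("   ", EmptySpecError),
        ("2,,4", EmptySpecError),
        ("x,4", InvalidPositionError),
    ],
)
def test_parse_errors(text, error):
    with pytest.raises(error):
        parse_congener(text)


def test_ring_swap_and_mirror_give_one_canonical_form():
    assert parse_congener("2,6") == parse_congener("2′,6′")
    # mirror: position p <-> 8-p
    assert parse_congener("2,4") == parse_congener("4,6")
    assert parse_congener("2,4'").name == "2,4′-diBDE"
    assert parse_congener("2,2',4,4'").name == "2,2′,4,4′-tetraBDE"


@given(spec_strategy)
def test_canonicalization_is_idempotent_and_symmetry_invariant(spec):
    canon = spec.canonical()
    assert canon.canonical() == canon
    swapped = CongenerSpec(spec.ring_b, spec.ring_a)
    mirrored = CongenerSpec(
        frozenset(8 - p for p in spec.ring_a), spec.ring_b
    )
    assert swapped.canonical() == canon
    assert mirrored.canonical() == canon


def test_invalid_positions_rejected_at_construction():
    with pytest.raises(InvalidPositionError):
        CongenerSpec(frozenset({1}), frozenset())


@pytest.mark.parametrize(
    "ring_a, ring_b, n_vertices, n_edges",
    [
        ({2, 4}, {2, 4}, 16, 17),
        (set(), set(), 12, 13),  # bare diphenyl skeleton
        ({2, 3, 4, 5, 6}, {2, 3, 4, 5, 6}, 22, 23),  # decabromo
    ],
)
def test_skeleton_counts(ring_a, ring_b, n_vertices, n_edges):
    spec = CongenerSpec(frozenset(ring_a), frozenset(ring_b))
    sk = build_skeleton(spec)
    assert sk.graph.number_of_nodes() == n_vertices
    assert sk.graph.number_of_edges() == n_edges
    assert len(sk.ring_carbons("A")) == len(sk.ring_carbons("B")) == 6
    assert all(sk.graph.degree[b] == 1 for b in sk.bromines)


def test_distance_matrix_is_metric():
    sk = build_skeleton(parse_congener("2,3',4,4',6"))
    d = all_pairs_distances(sk)
    assert (d == d.T).all()
    assert (np.diag(d) == 0).all()
    n = d.shape[0]
    for k in range(n):
        assert (d <= d[:, [k]] + d[[k], :]).all()


def test_adjacent_ring_carbons_at_unit_distance():
    sk = build_skeleton(CongenerSpec(frozenset(), frozenset()))
    d = all_pairs_distances(sk)
    i = {n: k for k, n in enumerate(sk.nodes)}
    assert d[i["A1"], i["A2"]] == 1
    assert d[i["A1"], i["B1"]] == 1  # contracted ether bridge


def test_tetra_congener_br_br_distances_match_worked_expansion():
    sk = build_skeleton(parse_congener("2,2',4,4'"))
    d = all_pairs_distances(sk)
    i = {n: k for k, n in enumerate(sk.nodes)}
    pairs = sorted(
        d[i[a], i[b]] for a, b in itertools.combinations(sk.bromines, 2)
    )
    assert pairs == [4, 4, 5, 7, 7, 9]


def test_cross_ring_br_distance_closed_form():
    """Br(p, ring A) to Br(q, ring B) distance is 3 + ringdist(p,1) + ringdist(q,1)."""

    def ringdist(p, q):
        a = abs(p - q)
        return min(a, 6 - a)

    for p, q in itertools.product(range(2, 7), repeat=2):
        sk = build_skeleton(CongenerSpec(frozenset({p}), frozenset({q})))
        d = all_pairs_distances(sk)
        i = {n: k for k, n in enumerate(sk.nodes)}
        assert d[i[f"BrA{p}"], i[f"BrB{q}"]] == 3 + ringdist(p, 1) + ringdist(q, 1)


def test_bfs_distances_match_floyd_warshall_on_random_specs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        ring_a = frozenset(int(p) for p in rng.choice([2, 3, 4, 5, 6], rng.integers(0, 6), replace=False))
        ring_b = frozenset(int(p) for p in rng.choice([2, 3, 4, 5, 6], rng.integers(0, 6), replace=False))
        sk = build_skeleton(CongenerSpec(ring_a, ring_b))
        d = all_pairs_distances(sk)
        adj = nx.to_numpy_array(sk.graph, nodelist=sk.nodes, nonedge=np.inf)
        fw = floyd_warshall(np.where(adj == 0, np.inf, adj))
        np.fill_diagonal(fw, 0)
        assert (d == fw.astype(int)).all()


def test_disconnected_graph_raises():
    g = nx.Graph()
    g.add_nodes_from(["A1", "B1"], element="C", ring="A")
    sk = SkeletonGraph(g)
    with pytest.raises(ConnectivityError):
        all_pairs_distances(sk)


def test_enumeration_yields_209_distinct_congeners():
    congeners = enumerate_canonical_congeners()
    assert len(congeners) == 209
    assert len(set(congeners)) == 209
    assert all(c.is_canonical() and c.n_bromines >= 1 for c in congeners)


def test_edge_list_export_lists_every_bond():
    sk = build_skeleton(parse_congener("2,4"))
    lines = sk.edge_list().splitlines()
    assert len(lines) == sk.graph.number_of_edges()
    assert all(len(line.split("\t")) == 2 for line in lines)
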