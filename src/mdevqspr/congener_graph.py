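"""PBDE congener nomenclature and the molecular skeleton graph.

Polybrominated diphenyl ethers (PBDEs) share a diphenyl ether skeleton: two
benzene rings joined by an ether oxygen, carrying 0-10 bromine substituents
on ring positions 2-6 and 2'-6' (position 1/1' is the ipso carbon bearing
the ether bridge and is never substituted).  A congener is fully described
by the two sets of brominated positions, which is how the field's
"2,2',4,4'"-style nomenclature encodes it.

For topological descriptor work the molecule is reduced to a graph in which
every non-hydrogen heavy atom is a vertex and every bond a unit-length
edge, with one convention: the bridging ether oxygen is contracted so the
two ipso carbons are adjacent.  Distances are shortest-path bond counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (
    ConnectivityError,
    DuplicateSubstitutionError,
    EmptySpecError,
    InvalidPositionError,
)

__all__ = [
    "CongenerSpec",
    "SkeletonGraph",
    "parse_congener",
    "build_skeleton",
    "all_pairs_distances",
]

_VALID_POSITIONS = frozenset({2, 3, 4, 5, 6})

_HOMOLOG = {
    0: "", 1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}

#: Unicode prime characters accepted (and normalised) in congener strings.
_PRIME_CHARS = "′'ʹ´’"

PRIME = "′"


def _mirror_normalize(positions: frozenset[int]) -> tuple[int, ...]:
    """Lowest-locant form of one ring's positions under the 2<->6, 3<->5 mirror."""
    direct = tuple(sorted(positions))
    mirrored = tuple(sorted(8 - p for p in positions))
    return min(direct, mirrored)


@dataclass(frozen=True)
class CongenerSpec:
    """A PBDE congener: brominated positions on the two phenyl rings.

    Positions are locants in {2..6}; ring A is the unprimed ring, ring B the
    primed one.  Construction validates locants; :meth:`canonical` returns
    the symmetry-normalised representative (per-ring mirror 2<->6 / 3<->5
    and ring swap) used for naming and deduplication.
    """

    ring_a: frozenset[int]
    ring_b: frozenset[int]

    def __post_init__(self) -> None:
        for ring in (self.ring_a, self.ring_b):
            bad = set(ring) - _VALID_POSITIONS
            if bad:
                raise InvalidPositionError(
                    f"invalid bromine position(s) {sorted(bad)}; "
                    "substitutable positions are 2-6"
                )
        object.__setattr__(self, "ring_a", frozenset(self.ring_a))
        object.__setattr__(self, "ring_b", frozenset(self.ring_b))

    @property
    def n_bromines(self) -> int:
        return len(self.ring_a) + len(self.ring_b)

    def canonical(self) -> "CongenerSpec":
        """Symmetry-normalised representative of this congener.

        Each ring's locants are mirror-normalised to their lowest-locant
        form; the more substituted ring becomes ring A (ties broken by the
        lexicographically smaller locant tuple), matching BDE nomenclature.
        """
        a = _mirror_normalize(self.ring_a)
        b = _mirror_normalize(self.ring_b)
        if (len(b), ) > (len(a), ) or (len(b) == len(a) and b < a):
            a, b = b, a
        return CongenerSpec(frozenset(a), frozenset(b))

    def is_canonical(self) -> bool:
        return self == self.canonical()

    @property
    def name(self) -> str:
        """BDE-style name of the canonical form, e.g. ``2,2′,4,4′-tetraBDE``."""
        canon = self.canonical()
        if canon.n_bromines == 0:
            return "diphenyl ether"
        locants = [(p, "") for p in canon.ring_a] + [(p, PRIME) for p in canon.ring_b]
        locants.sort()
        body = ",".join(f"{p}{mark}" for p, mark in locants)
        return f"{body}-{_HOMOLOG[canon.n_bromines]}BDE"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_congener(text: str) -> CongenerSpec:
    """Parse a locant string like ``"2,2',4,4'"`` into a canonical spec.

    Primed locants (ASCII apostrophe or Unicode prime, in any mix) belong to
    the second ring.  Whitespace and a trailing homolog suffix such as
    ``-tetraBDE`` or ``-tetrabro`` are tolerated.

    Raises
    ------
    EmptySpecError
        For an empty/blank string.  (A zero-bromine spec is constructible
        programmatically but has no locant representation.)
    InvalidPositionError
        For locants outside 2-6, including the ipso position 1.
    DuplicateSubstitutionError
        If one ring lists the same locant twice.
    """
    cleaned = text.strip()
    # tolerate a homolog-name suffix after the locant list
    if "-" in cleaned:
        cleaned = cleaned.split("-", 1)[0].strip()
    if not cleaned:
        raise EmptySpecError("empty congener string")
    ring_a: set[int] = set()
    ring_b: set[int] = set()
    for token in cleaned.split(","):
        token = token.strip()
        if not token:
            raise EmptySpecError(f"empty locant in {text!r}")
        primed = token[-1] in _PRIME_CHARS
        digits = token.rstrip(_PRIME_CHARS).strip()
        if not digits.isdigit():
            raise InvalidPositionError(f"unparseable locant {token!r} in {text!r}")
        pos = int(digits)
        if pos not in _VALID_POSITIONS:
            raise InvalidPositionError(
                f"position {pos} is not substitutable (valid: 2-6; "
                "1 is the ipso carbon)"
            )
        ring = ring_b if primed else ring_a
        if pos in ring:
            raise DuplicateSubstitutionError(
                f"locant {token!r} listed twice in {text!r}"
            )
        ring.add(pos)
    return CongenerSpec(frozenset(ring_a), frozenset(ring_b)).canonical()


@dataclass
class SkeletonGraph:
    """Heavy-atom skeleton of a PBDE congener.

    Vertices are carbons ``A1``..``A6``, ``B1``..``B6`` and bromines
    ``BrA<p>`` / ``BrB<p>``; edges are unit-length bonds.  The ether oxygen
    is contracted: the ipso carbons ``A1`` and ``B1`` are directly bonded,
    which is the convention under which the descriptor reproduces the
    published PBDE values.
    """

    graph: nx.Graph
    nodes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.graph.nodes)

    @property
    def bromines(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.graph.nodes[n]["element"] == "Br")

    def ring_carbons(self, ring: str) -> tuple[str, ...]:
        return tuple(
            n for n in self.nodes
            if self.graph.nodes[n]["element"] == "C"
            and self.graph.nodes[n]["ring"] == ring
        )

    def edge_list(self) -> str:
        """Two-column text edge list (debugging aid; not a stable format)."""
        return "\n".join(f"{u}\t{v}" for u, v in self.graph.edges)


def build_skeleton(spec: CongenerSpec) -> SkeletonGraph:
    """Build the heavy-atom skeleton graph for a congener.

    Two 6-cycles of carbons, one ipso-ipso bridge edge, and a pendant Br
    vertex on every substituted position.
    """
    g = nx.Graph()
    for ring, positions in (("A", spec.ring_a), ("B", spec.ring_b)):
        carbons = [f"{ring}{i}" for i in range(1, 7)]
        g.add_nodes_from(carbons, element="C", ring=ring)
        g.add_edges_from(zip(carbons, carbons[1:] + carbons[:1]))
        for p in sorted(positions):
            br = f"Br{ring}{p}"
            g.add_node(br, element="Br", ring=None)
            g.add_edge(f"{ring}{p}", br)
    g.add_edge("A1", "B1")  # ether oxygen contracted
    return SkeletonGraph(g)


def all_pairs_distances(skeleton: SkeletonGraph) -> np.ndarray:
    """All-pairs shortest-path bond counts, by BFS from every vertex.

    Returns an integer matrix indexed like ``skeleton.nodes``.  Raises
    :class:`ConnectivityError` if the graph is disconnected (impossible for
    graphs built from valid specs; guards programmatic misuse).
    """
    nodes = skeleton.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), -1, dtype=int)
    for source in nodes:
        lengths = nx.single_source_shortest_path_length(skeleton.graph, source)
        if len(lengths) != n:
            raise ConnectivityError("skeleton graph is disconnected")
        i = index[source]
        for target, d in lengths.items():
            dist[i, index[target]] = d
    return dist


def enumerate_canonical_congeners() -> list[CongenerSpec]:
    """All distinct canonical PBDE congeners with at least one bromine.

    Enumerates the 2^10 substitution patterns and collapses them modulo the
    molecular symmetries; yields the classical count of 209 congeners.
    """
    seen: dict[CongenerSpec, None] = {}
    positions = sorted(_VALID_POSITIONS)
    for mask_a, mask_b in itertools.product(range(32), repeat=2):
        if mask_a == 0 and mask_b == 0:
            continue
        ring_a = frozenset(p for i, p in enumerate(positions) if mask_a >> i & 1)
        ring_b = frozenset(p for i, p in enumerate(positions) if mask_b >> i & 1)
        seen.setdefault(CongenerSpec(ring_a, ring_b).canonical())
    return list(seen)
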