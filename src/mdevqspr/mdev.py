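"""Molecular distance-edge vector (MDEV) index for PBDE congeners.

The MDEV index summarises a molecule's topology as reciprocal-square sums
of shortest-path distances between typed structural features.  For PBDEs
the two feature types are bromine atoms (type 1) and benzene rings
(type 2), giving a descriptor triple

    mu1 = M11 = sum over unordered pairs of distinct bromines of 1/d^2
    mu2 = M12 = sum over (bromine, ring) pairs of 1/d^2
    mu3 = M22 = 1/d^2 for the single ring-ring pair

where d is the shortest-path bond count; a bromine-to-ring distance is the
distance to the nearest carbon of that ring (1 for its own ring).  With the
ether oxygen contracted the two rings are adjacent, so mu3 = 1 for every
PBDE and carries no information; mu1 and mu2 are the modelling descriptors.
Relative electronegativities of bromine and the benzene ring are taken as
1, so no weighting enters the sums.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .congener_graph import CongenerSpec, all_pairs_distances, build_skeleton
from .errors import DatasetError

__all__ = ["MdevIndex", "compute_mdev", "mdev_table"]


@dataclass(frozen=True)
class MdevIndex:
    """Descriptor triple (mu1, mu2, mu3) = (M11, M12, M22)."""

    mu1: float
    mu2: float
    mu3: float

    def rounded(self, ndigits: int = 4) -> tuple[float, float]:
        """(mu1, mu2) at tabulation precision."""
        return round(self.mu1, ndigits), round(self.mu2, ndigits)


def compute_mdev(spec: CongenerSpec) -> MdevIndex:
    """Compute the MDEV index of a congener from its skeleton graph.

    Distances come from BFS on the oxygen-contracted skeleton.  Sums run
    over unordered *distinct* pairs within a type (a self-pair would divide
    by zero; monobromo congeners correctly get mu1 = 0) and over all cross
    pairs between types.
    """
    skeleton = build_skeleton(spec)
    dist = all_pairs_distances(skeleton)
    index = {n: i for i, n in enumerate(skeleton.nodes)}
    bromines = skeleton.bromines
    rings = [skeleton.ring_carbons("A"), skeleton.ring_carbons("B")]

    mu1 = 0.0
    for u, v in itertools.combinations(bromines, 2):
        d = dist[index[u], index[v]]
        mu1 += 1.0 / d**2

    mu2 = 0.0
    for br in bromines:
        for carbons in rings:
            d = min(dist[index[br], index[c]] for c in carbons)
            mu2 += 1.0 / d**2

    # ring-ring term: nearest carbons of the two rings are the bonded ipso pair
    d_rings = min(
        dist[index[a], index[b]] for a in rings[0] for b in rings[1]
    )
    mu3 = 1.0 / d_rings**2

    return MdevIndex(float(mu1), float(mu2), float(mu3))


def mdev_table(specs: list[CongenerSpec]) -> pd.DataFrame:
    """Descriptor table (name, mu1, mu2) for a list of congeners.

    Values are full precision; round for display.  Errors in individual
    specs are re-raised with the offending row index.
    """
    if not specs:
        raise DatasetError("mdev_table requires at least one congener")
    rows = []
    for i, spec in enumerate(specs):
        try:
            idx = compute_mdev(spec)
        except Exception as exc:  # re-raise with row context
            raise DatasetError(f"row {i}: {exc}") from exc
        rows.append({"name": spec.name, "mu1": idx.mu1, "mu2": idx.mu2})
    return pd.DataFrame(rows)
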