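"""Periodic bridges between segments and the contact graph built from them.

A *bridge* is a periodic adjacency: an occupied boundary voxel whose
26-neighbor, after wrapping around the cell, is occupied too.  Each
bridge carries the integer lattice shift (in lattice-vector units, so
triclinic cells need no special casing) of the neighboring segment's
image and an occupancy count of how many voxel pairs realize it.

Bridges with a common segment pair are trimmed to the single
highest-occupancy shift: rarely occurring diagonal bridges would
otherwise divert the shortest-path completion.  Segments connected by
the trimmed edges form the final objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .segmentation import NEIGHBOR_OFFSETS, SegmentLabels
from .voxelization import VoxelGrid

__all__ = ["Bridge", "ContactGraph", "detect_bridges", "trim_graph", "group_objects"]


@dataclass(frozen=True)
class Bridge:
    """A periodic contact between two segments (or a segment and itself).

    ``shift`` means: the image of ``seg_b`` touching ``seg_a`` is
    displaced by ``shift`` lattice vectors, i.e. translating ``seg_b`` by
    ``shift`` attaches it to ``seg_a``.  Contacts are symmetric:
    ``Bridge(a, b, s)`` is the same contact as ``Bridge(b, a, -s)``; the
    canonical form has ``seg_a <= seg_b``.
    """

    seg_a: int
    seg_b: int
    shift: tuple[int, int, int]
    occupancy: int


def _canonical_key(a: int, b: int, shift: tuple[int, int, int]):
    if a > b:
        a, b = b, a
        shift = tuple(-s for s in shift)
    elif a == b and shift > tuple(-s for s in shift):
        shift = tuple(-s for s in shift)
    return a, b, shift


def detect_bridges(grid: VoxelGrid, labels: SegmentLabels) -> list[Bridge]:
    """Find all periodic voxel adjacencies, each counted exactly once.

    Only boundary voxels on the three *low* faces (index 0 along any
    axis) are scanned — periodic contacts are symmetric, so every
    crossing has exactly one representative whose shift vector starts
    with a negative component, and that representative's source voxel
    sits on a low face of its first crossed axis.
    """
    occ = grid.occupancy
    dims = grid.dims
    lab = labels.voxel_label

    occ_idx = np.argwhere(occ)
    low = occ_idx[(occ_idx == 0).any(axis=1)]
    counts: dict[tuple, int] = {}
    for off in NEIGHBOR_OFFSETS:
        nbr = low + off
        shift = np.floor_divide(nbr, dims)  # per-axis face-crossing, in {-1,0,1}
        crossing = shift.any(axis=1)
        if not crossing.any():
            continue
        # canonical representative: first nonzero shift component is -1
        first_nz = np.argmax(shift != 0, axis=1)
        canon = crossing & (shift[np.arange(len(low)), first_nz] == -1)
        if not canon.any():
            continue
        src = low[canon]
        s = shift[canon]
        dst = nbr[canon] - s * dims
        hit = occ[dst[:, 0], dst[:, 1], dst[:, 2]]
        for v, w, sh in zip(src[hit], dst[hit], s[hit]):
            key = _canonical_key(int(lab[tuple(v)]), int(lab[tuple(w)]), tuple(int(x) for x in sh))
            counts[key] = counts.get(key, 0) + 1
    return [Bridge(a, b, sh, n) for (a, b, sh), n in sorted(counts.items())]


@dataclass
class ContactGraph:
    """Segments as nodes, trimmed periodic bridges as edges.

    After trimming there is at most one edge — one shift — per unordered
    segment pair.  Self-bridges never become edges: a segment bridged to
    its own image is periodic along the crossing axes (only *partially*
    completable there) and is annotated instead in ``periodic_axes``.
    """

    graph: nx.Graph
    periodic_axes: dict[int, frozenset[int]] = field(default_factory=dict)

    def objects(self) -> list[frozenset[int]]:
        return group_objects(self)


def trim_graph(
    bridges: list[Bridge], labels: SegmentLabels | None = None
) -> ContactGraph:
    """Keep, per segment pair, only the highest-occupancy shift.

    Ties are broken by the lexicographically smallest shift vector, so
    the result is deterministic.  Node attributes carry voxel counts
    when ``labels`` is given (needed to pick each object's anchor).
    """
    g = nx.Graph()
    if labels is not None:
        counts = labels.voxel_counts()
        g.add_nodes_from(
            (seg, {"voxels": int(counts[seg - 1])})
            for seg in range(1, labels.n_segments + 1)
        )
    periodic: dict[int, set[int]] = {}
    best: dict[tuple[int, int], tuple[int, tuple[int, int, int]]] = {}
    for b in bridges:
        if b.seg_a == b.seg_b:
            periodic.setdefault(b.seg_a, set()).update(
                int(ax) for ax in np.flatnonzero(b.shift)
            )
            continue
        pair = (b.seg_a, b.seg_b)
        # maximize occupancy; ties -> lexicographically smallest shift
        cand = (-b.occupancy, b.shift)
        if pair not in best or cand < best[pair]:
            best[pair] = cand
    for (a, b), (neg_occ, shift) in best.items():
        g.add_edge(a, b, shift=np.array(shift, dtype=int), occupancy=-neg_occ, a=a, b=b)
    return ContactGraph(g, {k: frozenset(v) for k, v in periodic.items()})


def group_objects(graph: ContactGraph) -> list[frozenset[int]]:
    """Connected components of the trimmed graph, sorted by smallest member."""
    comps = [frozenset(c) for c in nx.connected_components(graph.graph)]
    return sorted(comps, key=min)
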