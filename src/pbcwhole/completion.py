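"""Make objects and molecules whole.

Each object is completed around its largest segment (in voxels): a
breadth-first shortest path (fewest edges) is found from the anchor to
every other segment, and the segment's final shift is the signed sum of
the bridge shifts along that path.  Because every displacement is an
integer combination of lattice vectors, wrapping the output reproduces
the input exactly (up to floating-point rounding) — no information is
ever lost.

Molecular completion reattaches bonded atoms by minimum-image placement
along the bond graph; associative completion extends a completed
subselection (e.g. lipid tails) to the unselected atoms of the same
molecules.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bridge_graph import ContactGraph
from .geometry import (
    Box,
    PointCloud,
    apply_shift,
    minimum_image_shift,
    wrap_coords,
)
from .segmentation import SegmentLabels
from .voxelization import VoxelGrid

__all__ = [
    "SegmentShiftMap",
    "compose_shifts",
    "apply_completion",
    "make_molecules_whole",
    "associative_completion",
]


class MissingBondsError(ValueError):
    """Molecular/associative completion needs a bond graph."""

    def __init__(self) -> None:
        super().__init__(
            "no bonded information available; provide a topology that carries "
            "bonds (e.g. a TPR file) to use molecular or associative completion"
        )


@dataclass
class SegmentShiftMap:
    """Integer lattice shift per segment, zero for every object's anchor."""

    shifts: dict[int, np.ndarray]
    anchors: dict[int, frozenset[int]] = field(default_factory=dict)
    """anchor segment -> the object (set of segments) it anchors."""

    def shift_of(self, segment: int) -> np.ndarray:
        return self.shifts.get(segment, np.zeros(3, dtype=int))


def compose_shifts(graph: ContactGraph) -> SegmentShiftMap:
    """Compose bridge shifts along best paths to each object's anchor.

    The anchor is the segment with the most voxels in its object (ties:
    smallest label) and never moves.  Paths are widest-first: among all
    routes to the anchor the one maximizing the minimum bridge occupancy
    wins, ties broken by fewest edges and then by label order.  The
    occupancy criterion guards against rare corner contacts between a
    pair of segments that touch nowhere else — per-pair trimming cannot
    remove those, and a hop-count-only path would happily route through
    them.  With equal occupancies this reduces to plain breadth-first
    shortest paths.  An edge stored as ``(a, b, s)`` contributes ``+s``
    traversed a->b and ``-s`` traversed b->a.
    """
    g = graph.graph
    shifts: dict[int, np.ndarray] = {}
    anchors: dict[int, frozenset[int]] = {}
    for comp in sorted((frozenset(c) for c in nx.connected_components(g)), key=min):
        anchor = min(comp, key=lambda n: (-g.nodes[n].get("voxels", 0), n))
        anchors[anchor] = comp
        shifts[anchor] = np.zeros(3, dtype=int)
        # widest-path Dijkstra: priority = (-bottleneck occupancy, hops, label)
        best: dict[int, tuple[float, int]] = {anchor: (-np.inf, 0)}
        heap: list[tuple[float, int, int]] = [(-np.inf, 0, anchor)]
        while heap:
            neg_bottleneck, hops, node = heapq.heappop(heap)
            if best.get(node) != (neg_bottleneck, hops):
                continue  # stale entry
            for nbr in sorted(g.neighbors(node)):
                data = g.edges[node, nbr]
                cand = (
                    max(neg_bottleneck, -data.get("occupancy", 1)),
                    hops + 1,
                )
                if nbr in best and best[nbr] <= cand:
                    continue
                best[nbr] = cand
                step = data["shift"] if data["a"] == node else -data["shift"]
                shifts[nbr] = shifts[node] + step
                heapq.heappush(heap, (*cand, nbr))
    return SegmentShiftMap(shifts, anchors)


def apply_completion(
    points: PointCloud,
    grid: VoxelGrid,
    labels: SegmentLabels,
    shifts: SegmentShiftMap,
    box: Box,
) -> PointCloud:
    """Displace every selected point by its segment's lattice shift.

    Shifts are applied per voxel label (all atoms of a voxel share one
    label by construction), so the voxel<->point mapping stays
    consistent; unselected points are untouched.
    """
    out = points.copy()
    max_label = labels.n_segments
    table = np.zeros((max_label + 1, 3), dtype=int)
    for seg, s in shifts.shifts.items():
        table[seg] = s
    sel = grid.selection
    per_atom = table[labels.atom_label[sel]]
    out.coords[sel] = out.coords[sel] + per_atom.astype(float) @ box.vectors
    return out


def _molecule_groups(molecule_id: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(molecule_id, kind="stable")
    ids = molecule_id[order]
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    bounds = np.append(starts, len(ids))
    return [order[bounds[i]:bounds[i + 1]] for i in range(len(starts))]


def _adjacency(n_atoms: int, bonds: np.ndarray) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _bfs_min_image(
    coords: np.ndarray,
    adj: list[list[int]],
    seeds: np.ndarray,
    box: Box,
    movable: np.ndarray | None = None,
) -> None:
    """Place atoms at the minimum image of their already-placed neighbor.

    In-place breadth-first traversal from ``seeds`` (whose positions are
    kept fixed).  ``movable`` restricts which atoms may be displaced;
    atoms outside it are traversed but not moved.
    """
    placed = np.zeros(len(coords), dtype=bool)
    placed[seeds] = True
    queue = deque(int(s) for s in np.sort(seeds))
    while queue:
        ref = queue.popleft()
        for nbr in adj[ref]:
            if placed[nbr]:
                continue
            placed[nbr] = True
            if movable is None or movable[nbr]:
                delta = coords[nbr] - coords[ref]
                s = minimum_image_shift(delta, box)[0]
                if s.any():
                    coords[nbr] = apply_shift(coords[nbr], s, box)
            queue.append(nbr)


def make_molecules_whole(
    points: PointCloud,
    box: Box,
    anchor_mask: np.ndarray | None = None,
    only_molecules_of: np.ndarray | None = None,
) -> PointCloud:
    """Rejoin each molecule across the periodic boundary via its bond graph.

    Every molecule is traversed breadth-first; each newly visited atom is
    placed at the minimum image relative to its already-placed bonded
    neighbor, leaving all bonds shorter than half the smallest cell
    height.  By default the traversal is anchored at the molecule's
    first atom; with ``anchor_mask`` it starts from the flagged atoms
    (kept fixed), which is how completion results are preserved when
    repairing molecules after object completion.  Molecules already
    whole are left untouched.

    ``only_molecules_of`` (atom mask) restricts the repair to molecules
    containing at least one flagged atom.
    """
    if points.bonds is None:
        raise MissingBondsError()
    if points.molecule_id is None:
        raise ValueError("molecule_id per atom is required")
    out = points.copy()
    adj = _adjacency(points.n_atoms, points.bonds)
    for mol in _molecule_groups(np.asarray(points.molecule_id)):
        if only_molecules_of is not None and not only_molecules_of[mol].any():
            continue
        if anchor_mask is not None and anchor_mask[mol].any():
            seeds = mol[anchor_mask[mol]][:1]  # first flagged atom anchors
        else:
            seeds = mol[:1]
        _bfs_min_image(out.coords, adj, seeds, box)
    return out


def associative_completion(
    points: PointCloud,
    selection_mask: np.ndarray,
    box: Box,
) -> PointCloud:
    """Extend a completed subselection to the rest of each molecule.

    ``points`` must already carry the object-completed coordinates of
    the selected atoms.  Per molecule containing at least one selected
    atom, the unselected atoms are re-placed by bond-graph traversal
    anchored at the (already shifted) selected atoms; molecules with no
    selected atom are only wrapped into the cell.
    """
    if points.bonds is None:
        raise MissingBondsError()
    if points.molecule_id is None:
        raise ValueError("molecule_id per atom is required")
    mask = np.asarray(selection_mask, dtype=bool)
    out = points.copy()
    adj = _adjacency(points.n_atoms, points.bonds)
    for mol in _molecule_groups(np.asarray(points.molecule_id)):
        sel = mask[mol]
        if sel.any():
            _bfs_min_image(out.coords, adj, mol[sel], box)
        else:
            out.coords[mol] = wrap_coords(out.coords[mol], box)
    return out
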