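"""Synthetic broken assemblies with known ground truth, plus a brute-force
replication oracle.

Each fixture is built whole first (possibly extending outside the cell),
then wrapped; the integer lattice shift that un-wraps every point is
recorded as ground truth.  Point positions sit on a jittered lattice so
that voxel-based and distance-based clustering agree: with jitter of
0.1 of the lattice spacing, neighboring points are never farther apart
than 1.35 spacings, safely inside the oracle cutoff of 1.5 spacings.

The oracle does what this package deliberately avoids: it replicates the
system over all 27 neighbor images, clusters non-periodically with a
distance cutoff, and reads each point's image shift off the cluster that
contains the anchor image.  That is memory-hungry and test-only, but
independent of the voxel/graph pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .geometry import Box, PointCloud, rhombic_dodecahedron, to_fractional, wrap_coords

__all__ = ["Fixture", "make_fixture", "replication_oracle", "OracleResult", "DESCRIPTORS"]

DESCRIPTORS = (
    "split_sphere",
    "periodic_slab",
    "hex_tubes",
    "dodecahedral_vesicle",
    "chain_polymer",
)

_JITTER = 0.1  # fraction of the lattice spacing
ORACLE_CUTOFF_FACTOR = 1.5  # oracle cutoff = factor * lattice spacing
_ORACLE_MAX_POINTS = 10_000


@dataclass
class Fixture:
    """A wrapped ("broken") synthetic assembly with known repair shifts."""

    points: PointCloud
    box: Box
    ground_truth_shifts: np.ndarray  # (N, 3) int; points + s @ vectors = whole
    descriptor: str
    spacing: float  # lattice spacing of the generator
    resolution: float  # recommended voxel size for this fixture

    @property
    def whole_coords(self) -> np.ndarray:
        return self.points.coords + self.ground_truth_shifts.astype(float) @ self.box.vectors

    def to_universe(self):
        """Build an in-memory MDAnalysis Universe (fixture nm -> MDA Angstrom)."""
        import MDAnalysis as mda
        from MDAnalysis.lib import mdamath

        pts = self.points
        n = pts.n_atoms
        resindex = (
            np.asarray(pts.molecule_id)
            if pts.molecule_id is not None
            else np.zeros(n, dtype=int)
        )
        _, resindex = np.unique(resindex, return_inverse=True)
        u = mda.Universe.empty(
            n, n_residues=int(resindex.max()) + 1, atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", ["BB"] * n)
        u.add_TopologyAttr("resnames", ["FIX"] * (int(resindex.max()) + 1))
        u.add_TopologyAttr("resids", np.arange(int(resindex.max()) + 1) + 1)
        if pts.bonds is not None and len(pts.bonds):
            u.add_bonds([tuple(b) for b in pts.bonds])
        u.atoms.positions = pts.coords * 10.0
        u.dimensions = mdamath.triclinic_box(*(self.box.vectors * 10.0))
        return u

    def write_gro(self, path) -> None:
        self.to_universe().atoms.write(str(path))


def _lattice(lo: np.ndarray, hi: np.ndarray, h: float, rng) -> np.ndarray:
    axes = [np.arange(a + h / 2.0, b, h) for a, b in zip(lo, hi)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts + rng.uniform(-_JITTER * h, _JITTER * h, pts.shape)


def _finish(whole: np.ndarray, box: Box, descriptor: str, spacing: float,
            resolution: float, *, molecule_id=None, bonds=None) -> Fixture:
    wrapped = wrap_coords(whole, box)
    shifts = np.round(to_fractional(whole - wrapped, box)).astype(int)
    pts = PointCloud(coords=wrapped, molecule_id=molecule_id, bonds=bonds)
    return Fixture(pts, box, shifts, descriptor, spacing, resolution)


def _split_sphere(seed: int, box_edge: float = 10.0, radius: float = 3.0,
                  spacing: float = 0.35, n_faces: int = 1) -> Fixture:
    """A solid ball whose center sits on 1-3 cell faces, so wrapping
    splits it into 2, 4 or 8 pieces."""
    rng = np.random.default_rng(seed)
    box = Box.cubic(box_edge)
    ball = _lattice(np.full(3, -radius), np.full(3, radius), spacing, rng)
    ball = ball[np.linalg.norm(ball, axis=1) <= radius]
    center = np.where(np.arange(3) < n_faces, 0.0, box_edge / 2.0)
    return _finish(ball + center, box, "split_sphere", spacing, 1.0)


def _periodic_slab(seed: int, box_edge: float = 8.0, thickness: float = 1.6,
                   spacing: float = 0.4) -> Fixture:
    """A slab filling the whole xy-plane, centered on the z face: broken
    in z into two halves, and bridged to its own image in x and y.
    Built from bonded vertical 4-bead columns so molecular completion
    can be exercised."""
    rng = np.random.default_rng(seed)
    box = Box.cubic(box_edge)
    nxy = int(round(box_edge / spacing))
    nz = int(round(thickness / spacing))
    xy = np.stack(
        np.meshgrid(np.arange(nxy) * spacing + spacing / 2.0,
                    np.arange(nxy) * spacing + spacing / 2.0, indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)
    z = (np.arange(nz) - (nz - 1) / 2.0) * spacing  # straddles z = 0
    whole = np.concatenate(
        [np.column_stack([np.repeat(c[None, :], nz, axis=0), z]) for c in xy]
    )
    whole += rng.uniform(-_JITTER * spacing, _JITTER * spacing, whole.shape)
    molecule_id = np.repeat(np.arange(len(xy)), nz)
    first = np.arange(len(whole)).reshape(len(xy), nz)
    bonds = np.concatenate([np.column_stack([f[:-1], f[1:]]) for f in first])
    return _finish(whole, box, "periodic_slab", spacing, 0.8,
                   molecule_id=molecule_id, bonds=bonds)


def _hex_tubes(seed: int, box_edge: float = 9.0, radius: float = 1.0,
               spacing: float = 0.4) -> Fixture:
    """Parallel solid tubes spanning the box along z (periodic there),
    one centered on the xy corner so it wraps into four quadrants."""
    rng = np.random.default_rng(seed)
    box = Box.cubic(box_edge)
    centers = [(0.0, 0.0), (box_edge / 2.0, box_edge / 2.0)]
    parts = []
    for cx, cy in centers:
        block = _lattice(
            np.array([cx - radius, cy - radius, 0.0]),
            np.array([cx + radius, cy + radius, box_edge]),
            spacing, rng,
        )
        r = np.linalg.norm(block[:, :2] - (cx, cy), axis=1)
        parts.append(block[r <= radius])
    return _finish(np.concatenate(parts), box, "hex_tubes", spacing, 0.9)


def _dodecahedral_vesicle(seed: int, d: float = 10.0, radius: float = 3.4,
                          thickness: float = 0.5, spacing: float = 0.35) -> Fixture:
    """A spherical shell centered on the origin of a rhombic-dodecahedral
    cell, wrapped into many fragments across its faces."""
    rng = np.random.default_rng(seed)
    box = rhombic_dodecahedron(d)
    block = _lattice(np.full(3, -radius - thickness), np.full(3, radius + thickness),
                     spacing, rng)
    r = np.linalg.norm(block, axis=1)
    shell = block[(r >= radius - thickness / 2.0) & (r <= radius + thickness / 2.0)]
    return _finish(shell, box, "dodecahedral_vesicle", spacing, 1.0)


def _chain_polymer(seed: int, n_beads: int = 60, box_edge: float = 5.0) -> Fixture:
    """A bonded open chain wrapped into a small box.

    The chain traces a 300-degree circular arc of diameter 0.7 box
    edges in a random orientation at a random center.  The arc never
    approaches itself (end gap = one radius) and its extent keeps every
    point well clear of its own periodic images, so the only periodic
    contacts are the genuine face crossings — a curve built from a
    random walk cannot guarantee either.
    """
    rng = np.random.default_rng(seed)
    box = Box.cubic(box_edge)
    radius = 0.35 * box_edge
    theta = np.linspace(0.0, np.deg2rad(300.0), n_beads)
    flat = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_beads)]
    )
    rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    whole = flat @ rot.T + rng.uniform(0, box_edge, 3)
    spacing = float(np.linalg.norm(whole[1] - whole[0]))
    bonds = np.column_stack([np.arange(n_beads - 1), np.arange(1, n_beads)])
    return _finish(whole, box, "chain_polymer", spacing, 0.5,
                   molecule_id=np.zeros(n_beads, dtype=int), bonds=bonds)


_MAKERS = {
    "split_sphere": _split_sphere,
    "periodic_slab": _periodic_slab,
    "hex_tubes": _hex_tubes,
    "dodecahedral_vesicle": _dodecahedral_vesicle,
    "chain_polymer": _chain_polymer,
}


def make_fixture(descriptor: str, seed: int = 0, **size_params) -> Fixture:
    """Build a named fixture; deterministic for a given seed."""
    try:
        maker = _MAKERS[descriptor]
    except KeyError:
        raise ValueError(
            f"unknown fixture {descriptor!r}; choose from {DESCRIPTORS}"
        ) from None
    return maker(seed, **size_params)


@dataclass
class OracleResult:
    """Ground truth from brute-force 3x3x3 replication."""

    point_object: np.ndarray  # (N,) object id per point
    point_shift: np.ndarray  # (N, 3) int image shift into the anchor cluster
    periodic_axes: dict[int, frozenset[int]]  # object id -> axes touching own image


def replication_oracle(points: PointCloud | np.ndarray, box: Box,
                       cutoff: float) -> OracleResult:
    """Cluster the 27-fold replicated system non-periodically.

    For every object the cluster holding the most zero-shift images is
    the anchor; each point's shift is that of its image inside the
    anchor cluster.  A point appearing there through several images
    marks the object as periodic along the differing axes.  Test-only:
    refuses systems above 10^4 points.
    """
    coords = points.coords if isinstance(points, PointCloud) else np.asarray(points)
    n = len(coords)
    if n > _ORACLE_MAX_POINTS:
        raise ValueError(f"replication oracle refuses systems > {_ORACLE_MAX_POINTS} points")
    shifts27 = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=int)
    images = (coords[None, :, :] + (shifts27.astype(float) @ box.vectors)[:, None, :])
    flat = images.reshape(-1, 3)

    tree = cKDTree(flat)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(27 * n, 27 * n)
    )
    _, cluster = sparse.csgraph.connected_components(adj, directed=False)

    # two points belong to one object iff some cluster holds images of both
    orig = np.tile(np.arange(n), 27)
    order = np.argsort(cluster, kind="stable")
    c_sorted, o_sorted = cluster[order], orig[order]
    same_cluster = c_sorted[1:] == c_sorted[:-1]
    links = sparse.coo_matrix(
        (np.ones(int(same_cluster.sum())),
         (o_sorted[:-1][same_cluster], o_sorted[1:][same_cluster])),
        shape=(n, n),
    )
    n_obj, point_object = sparse.csgraph.connected_components(links, directed=False)

    zero_block = int(np.flatnonzero((shifts27 == 0).all(axis=1))[0])
    zero_clusters = cluster[zero_block * n:(zero_block + 1) * n]

    point_shift = np.zeros((n, 3), dtype=int)
    periodic_axes: dict[int, frozenset[int]] = {}
    img_cluster = cluster.reshape(27, n)
    for obj in range(n_obj):
        members = np.flatnonzero(point_object == obj)
        vals, counts = np.unique(zero_clusters[members], return_counts=True)
        anchor = int(vals[counts == counts.max()].min())
        axes: set[int] = set()
        in_anchor = img_cluster[:, members] == anchor  # (27, m)
        for col, i in enumerate(members):
            hits = np.flatnonzero(in_anchor[:, col])
            if len(hits) == 0:
                raise ValueError(
                    "object extends beyond one replication shell; oracle not applicable"
                )
            hit_shifts = shifts27[hits]
            best = hits[np.lexsort((hit_shifts[:, 2], hit_shifts[:, 1],
                                    hit_shifts[:, 0], np.abs(hit_shifts).sum(axis=1)))][0]
            point_shift[i] = shifts27[best]
            if len(hits) > 1:
                diffs = hit_shifts - hit_shifts[0]
                axes.update(int(a) for a in np.flatnonzero(diffs.any(axis=0)))
        if axes:
            periodic_axes[obj] = frozenset(axes)
    return OracleResult(point_object, point_shift, periodic_axes)
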