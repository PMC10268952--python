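"""Triclinic cell geometry: fractional coordinates, wrapping, lattice shifts.

The periodic cell is a parallelepiped spanned by three lattice vectors
``a``, ``b``, ``c`` stored as the rows of a 3x3 matrix.  Everything here
works in the units of those vectors (nm for GRO-class input, Angstrom for
PDB) and handles cubic, orthorhombic and fully triclinic cells through one
code path: Cartesian coordinates are mapped to fractional coordinates
``f = x @ inv(vectors)`` and back with ``x = f @ vectors``.

Only translational periodicity is supported; rotational or screw symmetry
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Box",
    "PointCloud",
    "to_fractional",
    "from_fractional",
    "wrap",
    "wrap_coords",
    "apply_shift",
    "cell_volume",
    "minimum_image_shift",
    "rhombic_dodecahedron",
]

# Determinant below this (relative to the cube of the largest vector norm)
# is treated as a degenerate cell.
_SINGULAR_RTOL = 1e-12


class SingularBoxError(ValueError):
    """The lattice matrix is not invertible (zero-volume cell)."""


@dataclass(frozen=True)
class Box:
    """A triclinic periodic cell.

    Parameters
    ----------
    vectors
        3x3 matrix whose rows are the lattice vectors ``a``, ``b``, ``c``.
        Canonical (Gromacs/GRO) orientation is lower-triangular: ``a``
        along x, ``b`` in the xy-plane.  Use :meth:`from_vectors` to
        canonicalize an arbitrarily rotated cell together with its
        coordinates.
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"lattice matrix must be 3x3, got {v.shape}")
        scale = float(np.abs(v).max())
        if scale == 0.0 or abs(np.linalg.det(v)) <= _SINGULAR_RTOL * scale**3:
            raise SingularBoxError("lattice matrix is singular (zero-volume cell)")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "_inverse", np.linalg.inv(v))

    @property
    def inverse(self) -> np.ndarray:
        """Inverse of the lattice matrix (cached)."""
        return self._inverse  # type: ignore[attr-defined]

    @property
    def lengths(self) -> np.ndarray:
        """Euclidean norms of the three lattice vectors."""
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    @property
    def is_lower_triangular(self) -> bool:
        v = self.vectors
        scale = float(np.abs(v).max())
        return bool(np.all(np.abs(np.triu(v, k=1)) <= 1e-9 * scale))

    @classmethod
    def cubic(cls, edge: float) -> "Box":
        return cls(np.eye(3) * float(edge))

    @classmethod
    def from_vectors(
        cls, vectors: np.ndarray, coords: np.ndarray | None = None
    ) -> tuple["Box", np.ndarray | None]:
        """Build a canonical (lower-triangular) box from arbitrary vectors.

        A rotated cell is brought into the Gromacs convention by a rigid
        rotation; the same rotation is applied to ``coords`` so the
        geometry is preserved.  Returns the box and the rotated
        coordinates (or ``None`` if no coordinates were given).
        """
        v = np.asarray(vectors, dtype=float)
        box = cls(v)
        if box.is_lower_triangular:
            return box, (None if coords is None else np.asarray(coords, dtype=float))
        # v.T = Q R  =>  v = R.T Q.T ; R.T is lower-triangular, Q.T the rotation
        q, r = np.linalg.qr(v.T)
        # fix signs so the diagonal is positive (right-handed, a along +x)
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        q = q * signs
        r = r * signs[:, None]
        canonical = cls(r.T)
        rotated = None if coords is None else np.asarray(coords, dtype=float) @ q
        return canonical, rotated


@dataclass
class PointCloud:
    """Per-particle coordinates plus the identity needed downstream.

    ``molecule_id`` partitions atoms into molecules; ``bonds`` (pairs of
    atom indices) are optional and only required for molecular or
    associative completion.  Every bond must connect atoms of the same
    molecule.
    """

    coords: np.ndarray
    atom_names: np.ndarray | None = None
    residue_names: np.ndarray | None = None
    residue_ids: np.ndarray | None = None
    molecule_id: np.ndarray | None = None
    bonds: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if len(self.coords) < 1:
            raise ValueError("point cloud must contain at least one point")
        if self.bonds is not None:
            self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
            if self.molecule_id is not None and len(self.bonds):
                mid = np.asarray(self.molecule_id)
                if not np.all(mid[self.bonds[:, 0]] == mid[self.bonds[:, 1]]):
                    raise ValueError("bonds must connect atoms of one molecule")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "PointCloud":
        return PointCloud(
            coords=self.coords.copy(),
            atom_names=self.atom_names,
            residue_names=self.residue_names,
            residue_ids=self.residue_ids,
            molecule_id=self.molecule_id,
            bonds=self.bonds,
        )


def to_fractional(coords: np.ndarray, box: Box) -> np.ndarray:
    """Cartesian -> fractional coordinates (``coords = f @ box.vectors``)."""
    return np.asarray(coords, dtype=float) @ box.inverse


def from_fractional(frac: np.ndarray, box: Box) -> np.ndarray:
    """Fractional -> Cartesian coordinates."""
    return np.asarray(frac, dtype=float) @ box.vectors


def wrap_coords(coords: np.ndarray, box: Box) -> np.ndarray:
    """Translate every point into the primary cell by integer lattice shifts.

    Fractional coordinates land in the half-open interval ``[0, 1)`` (a
    point exactly on the upper face maps to the lower one), so downstream
    voxel indexing never overflows.  Idempotent.
    """
    out = np.array(coords, dtype=float)
    # translate by integer shifts only: points already inside keep their
    # exact bit pattern, which makes wrapping exactly idempotent
    for _ in range(8):
        shift = np.floor(to_fractional(out, box)).astype(int)
        moving = shift.any(axis=1)
        if not moving.any():
            return out
        out[moving] -= shift[moving].astype(float) @ box.vectors
    # pathological boundary oscillation: reconstruct from fractional
    frac = to_fractional(out, box)
    frac -= np.floor(frac)
    frac[frac >= 1.0] -= 1.0
    return from_fractional(frac, box)


def wrap(points: PointCloud, box: Box) -> PointCloud:
    """:func:`wrap_coords` lifted to a :class:`PointCloud`."""
    out = points.copy()
    out.coords = wrap_coords(points.coords, box)
    return out


def apply_shift(coords: np.ndarray, shift: np.ndarray, box: Box) -> np.ndarray:
    """Displace coordinates by an integer combination of lattice vectors."""
    s = np.asarray(shift)
    if not np.all(s == np.round(s)):
        raise ValueError(f"lattice shift must be integer, got {shift!r}")
    return np.asarray(coords, dtype=float) + np.asarray(s, dtype=float) @ box.vectors


def cell_volume(box: Box) -> float:
    """Volume of the cell, ``|det(vectors)|``."""
    return box.volume


def minimum_image_shift(delta: np.ndarray, box: Box) -> np.ndarray:
    """Integer lattice shift bringing ``delta`` closest to zero, per row.

    Uses the fractional-rounding convention: the shift is
    ``-round(delta @ inv(vectors))``.  Exact for displacements shorter
    than half the smallest cell height, which covers chemical bonds.
    """
    frac = to_fractional(np.atleast_2d(delta), box)
    return -np.round(frac).astype(int)


def rhombic_dodecahedron(d: float = 1.0) -> Box:
    """Rhombic-dodecahedral cell with inscribed-sphere diameter ``d``.

    Gromacs xy-square convention: rows ``(d,0,0)``, ``(0,d,0)``,
    ``(d/2, d/2, d*sqrt(2)/2)``.  Its volume is ``sqrt(2)/2`` of the cube
    with the same inscribed sphere, which is why it is the cell of choice
    for roughly spherical solutes.
    """
    d = float(d)
    return Box(np.array([
        [d, 0.0, 0.0],
        [0.0, d, 0.0],
        [d / 2.0, d / 2.0, d * np.sqrt(2.0) / 2.0],
    ]))
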