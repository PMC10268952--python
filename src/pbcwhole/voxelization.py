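"""Point cloud -> occupancy voxel grid, in fractional space.

The grid is laid out along the lattice vectors, so cubic and triclinic
cells share one binning path: point ``p`` falls into voxel
``floor(frac(p)[i] * dims[i])`` per axis.  The grid dimensions are
resolved from the target voxel edge length (the *resolution*); the sign
of the resolution is a mode flag, see :func:`resolve_dims`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Box, PointCloud, to_fractional

__all__ = [
    "VoxelGrid",
    "ResolutionError",
    "resolve_dims",
    "voxelize",
    "default_selection",
    "DEFAULT_SELECTION",
]

#: Relative deviation of the realized voxel edge from the target above
#: which a positive resolution refuses to voxelize.
MAX_VOXEL_DEVIATION = 0.05

#: Default atom selection: everything except the most common
#: coarse-grained solvent residues (water, antifreeze water, ions).
DEFAULT_SELECTION = "not resname W WF ION"


class ResolutionError(ValueError):
    """Realized voxel size deviates too much from the requested resolution."""

    def __init__(self, axis: int, deviation: float, target: float):
        self.axis = axis
        self.deviation = deviation
        super().__init__(
            f"voxel size along axis {axis} deviates {deviation * 100:.2f}% from the "
            f"target resolution {target:g} (limit {MAX_VOXEL_DEVIATION * 100:.0f}%); "
            f"use a negative resolution to continue with the rounded grid anyway"
        )


class EmptySelectionError(ValueError):
    """The selection contains no atoms, nothing to voxelize."""


def default_selection() -> str:
    """The default selection expression, ``"not resname W WF ION"``."""
    return DEFAULT_SELECTION


@dataclass
class VoxelGrid:
    """Boolean occupancy grid with a bidirectional point<->voxel mapping.

    Attributes
    ----------
    dims
        Grid size per lattice axis, each >= 1.
    occupancy
        Boolean array of shape ``dims``; true iff the voxel holds points.
    point_voxel
        (N, 3) voxel index per atom; rows of unselected atoms are -1.
    selection
        Boolean per-atom mask of the voxelized selection.
    resolution_target
        The signed resolution the grid was requested at.
    resolution_actual
        Realized voxel edge length along each lattice vector.
    """

    dims: np.ndarray
    occupancy: np.ndarray
    point_voxel: np.ndarray
    selection: np.ndarray
    resolution_target: float
    resolution_actual: np.ndarray

    def voxel_to_points(self) -> dict[tuple[int, int, int], np.ndarray]:
        """Map each occupied voxel to the atom indices it contains."""
        sel_idx = np.flatnonzero(self.selection)
        vox = self.point_voxel[sel_idx]
        flat = np.ravel_multi_index(vox.T, self.dims)
        order = np.argsort(flat, kind="stable")
        flat, sel_idx = flat[order], sel_idx[order]
        uniq, starts = np.unique(flat, return_index=True)
        out: dict[tuple[int, int, int], np.ndarray] = {}
        bounds = np.append(starts, len(flat))
        for k, f in enumerate(uniq):
            key = tuple(int(i) for i in np.unravel_index(f, self.dims))
            out[key] = sel_idx[bounds[k]:bounds[k + 1]]
        return out

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


def resolve_dims(box: Box, resolution: float) -> np.ndarray:
    """Number of voxels along each lattice vector for a target voxel edge.

    ``dims[i] = round(|v_i| / |resolution|)`` (round-half-to-even),
    floored at 1.  With a positive resolution the realized voxel edge
    ``|v_i| / dims[i]`` must stay within 5% of the target on every axis,
    otherwise :class:`ResolutionError` is raised; a negative resolution
    accepts the rounded dimensions regardless, allowing a run to continue
    on frames (or whole systems) whose box does not divide cleanly.
    """
    if resolution == 0:
        raise ValueError("resolution must be nonzero")
    target = abs(float(resolution))
    lengths = box.lengths
    dims = np.maximum(np.round(lengths / target).astype(int), 1)
    if resolution > 0:
        realized = lengths / dims
        deviation = np.abs(realized - target) / target
        worst = int(np.argmax(deviation))
        if deviation[worst] > MAX_VOXEL_DEVIATION:
            raise ResolutionError(worst, float(deviation[worst]), target)
    return dims


def voxelize(
    points: PointCloud,
    selection_mask: np.ndarray,
    box: Box,
    resolution: float,
) -> VoxelGrid:
    """Bin the selected (already wrapped) points into an occupancy grid.

    Points exactly on the upper fractional boundary (``frac == 1`` after
    floating-point error) are clamped into the last voxel rather than
    wrapped again, so no mass moves across the cell.
    """
    mask = np.asarray(selection_mask, dtype=bool)
    if mask.shape != (points.n_atoms,):
        raise ValueError("selection mask must be one boolean per atom")
    if not mask.any():
        raise EmptySelectionError("selection matches zero atoms")
    dims = resolve_dims(box, resolution)

    frac = to_fractional(points.coords[mask], box)
    idx = np.floor(frac * dims).astype(int)
    np.clip(idx, 0, dims - 1, out=idx)

    occupancy = np.zeros(tuple(dims), dtype=bool)
    occupancy[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    point_voxel = np.full((points.n_atoms, 3), -1, dtype=int)
    point_voxel[mask] = idx

    return VoxelGrid(
        dims=dims,
        occupancy=occupancy,
        point_voxel=point_voxel,
        selection=mask,
        resolution_target=float(resolution),
        resolution_actual=box.lengths / dims,
    )
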