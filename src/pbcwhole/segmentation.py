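"""Segment labels for voxels and atoms.

Segments are either connected components of the occupancy grid under
26-connectivity (face + edge + corner neighbors), computed *without*
periodic wrap-around — joining segments across the boundary is the job of
the bridge graph — or they are ingested from an external per-atom label
array produced by a third-party clustering tool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import PointCloud
from .voxelization import EmptySelectionError, VoxelGrid

__all__ = [
    "NEIGHBOR_OFFSETS",
    "SegmentLabels",
    "label_components",
    "load_external_labels",
    "external_labels_for_frame",
    "labels_from_external",
]

#: The 26-neighbor stencil: every nonzero offset in {-1, 0, 1}^3.
NEIGHBOR_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
    dtype=int,
)

#: Corresponding scipy.ndimage structuring element (full 3x3x3 cube).
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentLabels:
    """Per-voxel and per-atom segment labels.

    Labels of occupied voxels form the contiguous range ``1..K``; 0 marks
    background voxels and unselected atoms.  All atoms of one voxel carry
    that voxel's label, so shifts applied per segment always move whole
    voxels (required for exact reversibility).
    """

    voxel_label: np.ndarray  # int array, shape = grid dims
    atom_label: np.ndarray  # int per atom, 0 = unselected
    n_segments: int
    source: str  # "internal" | "external"

    def voxel_counts(self) -> np.ndarray:
        """Number of voxels per segment, index ``s-1`` for segment ``s``."""
        return np.bincount(self.voxel_label.ravel(), minlength=self.n_segments + 1)[1:]


def _renumber_scan_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels so segment 1 is first encountered in C scan order."""
    flat = labels.ravel()
    occupied = flat[flat > 0]
    first = {}
    order = []
    for lab in occupied:
        if lab not in first:
            first[lab] = True
            order.append(lab)
    remap = np.zeros(int(flat.max()) + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels]


def label_components(grid: VoxelGrid) -> SegmentLabels:
    """Non-periodic 26-connectivity connected components of the grid.

    Deterministic: labels are renumbered by the scan order of each
    segment's first voxel.
    """
    if grid.n_occupied < 1:
        raise ValueError("grid has no occupied voxels")
    raw, n = ndimage.label(grid.occupancy, structure=STRUCTURE_26)
    voxel_label = _renumber_scan_order(raw)
    atom_label = np.zeros(len(grid.selection), dtype=int)
    sel = grid.selection
    atom_label[sel] = voxel_label[
        grid.point_voxel[sel, 0], grid.point_voxel[sel, 1], grid.point_voxel[sel, 2]
    ]
    return SegmentLabels(voxel_label, atom_label, int(n), "internal")


def load_external_labels(path: str | Path, n_frames_expected: int | None = None) -> np.ndarray:
    """Load a ``.npy`` segment-ID array of shape ``[n_frames, n_atoms]``.

    The array carries one integer segment ID per atom per frame; ID 0
    means "not part of any segment" (the conventional noise label of
    upstream segmentation tools).
    """
    arr = np.load(Path(path))
    if arr.ndim != 2:
        raise ValueError(
            f"label array must have shape [n_frames, n_atoms]; found {arr.ndim}D shape {arr.shape}"
        )
    if n_frames_expected is not None and arr.shape[0] != n_frames_expected:
        raise ValueError(
            f"label array covers {arr.shape[0]} frame(s) but the trajectory has "
            f"{n_frames_expected}; per-frame labels are required"
        )
    return np.asarray(arr)


def external_labels_for_frame(
    labels: np.ndarray, frame_index: int, atoms: PointCloud
) -> np.ndarray:
    """Extract and validate one frame's per-atom labels.

    The nonzero entries define the selection (an external array overrides
    any selection expression).
    """
    if frame_index >= labels.shape[0]:
        raise IndexError(
            f"frame {frame_index} beyond label array with {labels.shape[0]} frame(s)"
        )
    if labels.shape[1] != atoms.n_atoms:
        raise ValueError(
            f"label array has {labels.shape[1]} atoms per frame, structure has {atoms.n_atoms}"
        )
    row = np.asarray(labels[frame_index], dtype=int)
    if not (row != 0).any():
        raise EmptySelectionError("external label row selects zero atoms (all labels 0)")
    return row


def labels_from_external(grid: VoxelGrid, atom_label_in: np.ndarray) -> SegmentLabels:
    """Project external per-atom labels onto the voxel grid.

    A mixed voxel (atoms of several segment IDs) takes the majority
    label, ties broken by the smallest label; atoms then follow their
    voxel's final label so that every voxel moves as one unit.  Labels
    are renumbered to the contiguous range ``1..K`` in increasing order
    of the external IDs.
    """
    ids = np.unique(atom_label_in[atom_label_in != 0])
    remap = {int(old): new for new, old in enumerate(ids, start=1)}

    voxel_label = np.zeros(tuple(grid.dims), dtype=int)
    for vox, atom_idx in grid.voxel_to_points().items():
        labs = atom_label_in[atom_idx]
        vals, counts = np.unique(labs, return_counts=True)
        winner = vals[counts == counts.max()].min()  # majority, ties -> smallest ID
        voxel_label[vox] = remap[int(winner)]

    atom_label = np.zeros(len(grid.selection), dtype=int)
    sel = grid.selection
    atom_label[sel] = voxel_label[
        grid.point_voxel[sel, 0], grid.point_voxel[sel, 1], grid.point_voxel[sel, 2]
    ]
    return SegmentLabels(voxel_label, atom_label, len(ids), "external")
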