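# pbcwhole

Repair molecules and molecular assemblies that appear broken across
periodic boundary conditions (PBC) in particle-based simulation data —
single frames or whole trajectories, cubic or fully triclinic cells
(including rhombic-dodecahedral boxes).

Molecular dynamics engines keep every particle image inside the unit
cell, so a vesicle, lipid phase, polymer aggregate or any other
assembly that crosses a box face is stored in pieces. That breaks
visualization and any analysis that assumes Euclidean geometry.
`pbcwhole` reassembles such objects without ever replicating the
system in memory.

## Algorithm

For each frame, with cell vectors **a**, **b**, **c** (rows of the
lattice matrix *V*):

1. **Select** the density of interest (default: `not resname W WF ION`,
   i.e. everything but common coarse-grained solvent).
2. **Voxelize** the wrapped selection in fractional space: point *p*
   falls into voxel `floor(f_i(p) · n_i)` with *f* = *x V*⁻¹ and grid
   dimensions `n_i = round(|v_i| / res)`. The voxel size must stay
   within 5% of the requested resolution; a negative resolution skips
   that check.
3. **Segment** occupied voxels by non-periodic 26-connectivity
   connected components (or ingest per-atom segment IDs from a `.npy`
   array of shape `[n_frames, n_atoms]`, which overrides the selection).
4. **Detect periodic bridges**: for boundary voxels, 26-neighbor
   offsets that leave the grid are wrapped, recording the integer
   lattice shift **s** ∈ ℤ³ of the neighboring segment's image and an
   occupancy count per (segment pair, shift). Per pair only the
   highest-occupancy shift is kept; segments connected by bridges form
   objects. A segment bridged to its own image is periodic along that
   axis and can only be partially completed.
5. **Compose shifts**: each object is completed around its largest
   segment; every other segment receives the signed sum of bridge
   shifts along its path to that anchor (widest path by bridge
   occupancy, ties broken by fewest edges).
6. **Apply**: each selected point moves by `s · V` of its segment —
   an integer lattice translation, so *wrapping the output reproduces
   the input exactly*; nothing is ever lost.

Optionally, molecules are then made whole along their bond graphs by
minimum-image placement (`-mol`), and a completed subselection (e.g.
lipid tails) can pull the remaining bonded atoms of its molecules into
place (`-asso`).

## Worked example

A ball of 2638 beads in a 10 nm cubic box, centered on a box face so
it is stored in two pieces:

```python
import numpy as np
import pbcwhole as pw

fx = pw.make_fixture("split_sphere", seed=1)          # broken ball, GRO-writable
result = pw.make_whole_frame(fx.points, fx.box, resolution=1.0)

print("segments:", result.labels.n_segments, "objects:", len(result.objects))
for seg, s in sorted(result.shifts.shifts.items()):
    print("segment", seg, "shift", s)
err = np.abs(pw.wrap_coords(result.points.coords, fx.box) - fx.points.coords).max()
print("max |wrap(output) - input|:", err)
```

prints

```
segments: 2 objects: 1
segment 1 shift [0 0 0]
segment 2 shift [-1  0  0]
max |wrap(output) - input|: 0.0
```

Two voxel segments were found, bridged across the x face into one
object; the smaller piece is translated by −**a** onto the larger
(anchor) piece. The x-extent of the point cloud shrinks from 10 nm
(box-spanning) to 5.67 nm (the ball's diameter), and re-wrapping the
output reproduces the input bit for bit.

The same run from the shell:

```bash
pbcwhole -f ball.gro -x ball.gro -o whole.gro
pbcwhole -f system.tpr -x traj.xtc -o whole.xtc -sel "name C4A C4B" \
         -mol True -asso True -wa True -res -1
pbcwhole -f system.gro -x system.gro -clusters clusters.npy -o whole.gro
```

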