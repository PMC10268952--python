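# Methods

## Model and assumptions

`pbcwhole` treats a simulation frame as a point cloud in a triclinic
cell under translation-only crystallographic periodicity: the cell,
spanned by lattice vectors **a**, **b**, **c** (rows of a 3×3 matrix
*V*), tiles space by integer translations `s·V`, `s ∈ ℤ³`. Rotational
or screw symmetries are not supported. All internal geometry runs in
fractional coordinates `f = x V⁻¹`, so cubic, orthorhombic and fully
triclinic cells (e.g. the rhombic dodecahedron, whose volume is √2/2
of the cube with an equal inscribed sphere) share one code path.
Boxes are canonicalized to the Gromacs lower-triangular convention;
arbitrarily rotated cells are rotated together with their coordinates,
which preserves all geometry.

Every displacement the pipeline ever applies — wrapping, segment
shifts, molecular completion — is an integer lattice translation.
This is the source of the method's central guarantee: wrapping the
output reproduces the input except for floating-point rounding, so
completion is lossless and can be run as a throw-away visualization
step or as a permanent trajectory transformation. Wrapping itself only
translates points whose integer shift is nonzero, which makes it
exactly idempotent (already-wrapped points keep their bit pattern).

## Pipeline parameters

- **resolution** (`-res`, default 1, units of the coordinate input
  file: nm for GRO/XTC/TRR/TPR, Å for PDB): target voxel edge. Grid
  dimensions are `round(|v_i|/|res|)` per axis (round-half-to-even,
  floored at 1), recomputed each frame from that frame's box so
  barostat fluctuations are handled. If the realized voxel edge
  deviates more than 5% from the target on any axis, a positive
  resolution raises an error; a negative resolution proceeds with the
  rounded grid — the escape hatch for small boxes (a 6.4 cell at
  target 1 gives 6 voxels of 1.067, a 6.7% deviation) and for
  occasional outlier frames in long trajectories. Coarser grids are
  faster and more tolerant of sparse selections but may fuse nearby
  objects; finer grids resolve objects better but require the
  selection to be dense enough to stay voxel-connected.
- **selection** (`-sel`, default `not resname W WF ION`): any
  MDAnalysis selection expression. The default strips the common
  coarse-grained solvent residues.
- **-clusters**: a `.npy` integer array `[n_frames, n_atoms]` of
  per-atom segment IDs from an external segmentation tool; 0 means
  unselected. It overrides the selection. A voxel containing atoms of
  several IDs takes the majority ID (ties: smallest); all atoms of a
  voxel then follow the voxel, which keeps shifting reversible. A
  single-frame array with a multi-frame trajectory is an error rather
  than an implicit broadcast.
- **-mol / -asso** (default off): molecular and associative
  completion, both requiring bonded topology (e.g. TPR). See below.

## Bridge detection and trimming

Periodic contacts are detected with the same 26-offset stencil used
for segmentation. Only voxels on the three low faces are scanned:
every periodic adjacency has exactly one representative whose shift
vector's first nonzero component is −1, and that representative's
source voxel lies on a low face, so each contact is counted once
without a second dedup pass. Shifts are integers in lattice-vector
units, so triclinic cells need no special treatment.

Per unordered segment pair, only the highest-occupancy shift is kept
(ties: lexicographically smallest shift). This suppresses rare
diagonal face/corner contacts of the "wrong" image when a dominant
contact exists for the same pair. Self-bridges (a segment touching
its own image) flag the segment's object as periodic — only partially
completable — along the crossing axes, and are never path edges.

## Shift composition

Each object is completed around its largest segment (most voxels;
ties: smallest label), which never moves. Other segments receive the
signed sum of edge shifts along their path to the anchor. The path
search is *widest-first*: it maximizes the minimum bridge occupancy
along the route, breaking ties by fewest edges and then label order.
With equal occupancies this is exactly breadth-first shortest-path
composition. The occupancy criterion exists because per-pair trimming
cannot remove a rare spurious contact that is the only bridge of its
pair; an edge-count-only search would take such a 1-voxel bridge as a
shortcut and misplace the segment by a lattice vector, which we
observed on vesicle fragments in dodecahedral cells. A widest path
routes through well-supported bridges whenever the graph allows it,
and degrades to the rare bridge only when it is the sole connection.

## Molecular and associative completion

After object completion, molecules can still be fragmented (their
segment may be periodic, or bonded atoms may lie outside the
selection). `-mol` traverses each molecule's bond graph breadth-first
from its first selected atom — keeping the object-completed placement
— and puts every newly visited atom at the minimum image relative to
its already-placed neighbor (shift `−round(Δf)`, exact for bonds
shorter than half the smallest cell height). `-asso` anchors the
traversal at *all* selected atoms of a molecule and re-places only the
unselected ones, re-attaching e.g. lipid head groups to completed tail
beads; molecules with no selected atom are only wrapped. The
standalone `make_molecules_whole` defaults to first-atom anchoring.
All placements are integer lattice shifts, so reversibility holds
throughout.

## Synthetic fixtures and the replication oracle

The fixture generator builds assemblies whole, wraps them, and records
the unwrapping shift per point as ground truth. Shapes: a solid ball
centered on 1–3 box faces (2–8 fragments), a box-spanning slab of
bonded 4-bead columns straddling the z face (periodic in x/y), solid
tubes spanning z with one tube on the xy corner, a spherical shell at
the origin of a rhombic-dodecahedral cell, and a bonded open chain.
Points sit on a jittered lattice (jitter 0.1 spacing), so neighboring
points are never farther apart than 1.35 spacings and the distance
oracle's cutoff of 1.5 spacings cannot split a contiguous body. The
chain is a 300° circular arc in a random orientation: unlike a random
walk it cannot re-trace itself, so distinct strands never merge within
one voxel, and its extent (0.7 box edges) keeps all its periodic
contacts genuine. Default sizes are 0.6–3k points per fixture — small
enough for the 27-fold replication oracle, dense enough that voxel and
distance clustering agree.

These fixtures emulate the brokenness patterns of real systems
(aggregates, lamellar and inverted phases, vesicles in dodecahedral
cells), not their physics: points are uniform lattices, not force-field
configurations; there is no solvent unless a fixture adds unselected
molecules. Passing tests therefore demonstrate correct periodic
reassembly, voxel bookkeeping and graph logic — they do not validate
behaviour on selections too sparse to stay voxel-connected at the
chosen resolution, which remains the user's resolution choice.

The test oracle replicates a fixture over all 27 neighbor images,
clusters with a distance cutoff (SciPy cKDTree + sparse connected
components), takes, per object, the cluster holding the most central
images as the anchor, and reads each point's lattice shift off its
image in that cluster — the memory-hungry ad hoc approach the pipeline
replaces, deliberately independent of the voxel/graph code. Pipeline
and oracle must agree up to one global lattice shift per object
(completion fixes the anchor, the oracle fixes its anchor cluster;
both reconstructions are translates of the same object).

## Numerical choices

- Wrapping uses the half-open fractional interval [0, 1); a point on
  the upper face maps to the lower one, and voxel indices are clamped
  to `dims−1` so float-boundary points never overflow the grid.
- `round-half-to-even` for grid dimensions: symmetric and
  reproducible across platforms.
- Segment labels are renumbered to first-appearance order in C scan
  order; all tie-breaks (trim shifts, anchors, path choices) are
  lexicographic — two runs on the same input are byte-identical.
- Degenerate cells (singular lattice matrix) and empty selections are
  rejected with specific errors; a frame that fails mid-trajectory
  aborts the run with its frame index (use a negative resolution to
  continue past voxelization failures).
- The per-frame error wrapper re-raises the original exception type
  with the frame index prepended, so callers can still catch
  `ResolutionError` etc.

## Known limitations

- Objects periodic along an axis are completed only in their other
  axes (inherent to periodicity, flagged via `periodic_axes`).
- No box re-centering around a completed object, and no re-imaging of
  solvent around it.
- Bridges are only sought one image away; assemblies crossing the box
  several times are handled through shift composition along chains of
  segments, not by multi-image detection.
- Writing multi-frame output requires a trajectory-capable format
  (XTC/TRR/multi-model PDB); plain GRO holds a single frame.
- If two genuinely distinct objects pass within one voxel of each
  other they are segmented as one; choose a finer resolution or supply
  external cluster labels in that case.
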