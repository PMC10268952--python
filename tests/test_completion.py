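"""Shift composition, object completion, and molecular completion."""

import numpy as np
import pytest

import pbcwhole as pw
from pbcwhole.bridge_graph import Bridge
from pbcwhole.completion import MissingBondsError
from tests.conftest import pipeline_point_shifts


def graph_with_voxels(bridges, voxels):
    graph = pw.trim_graph(bridges)
    for seg, n in voxels.items():
        graph.graph.add_node(seg, voxels=n)
    return graph


class TestComposeShifts:
    def test_four_segment_chain(self):
        # A(1)-B(2)-C(3)-D(4), anchor A; the composed shift for D is the
        # signed sum of the bridge shifts along the chain
        bridges = [
            Bridge(1, 2, (1, 0, -1), 5),
            Bridge(2, 3, (0, -1, 0), 5),
            Bridge(3, 4, (-1, 0, 0), 5),
        ]
        graph = graph_with_voxels(bridges, {1: 100, 2: 10, 3: 10, 4: 10})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(1).tolist() == [0, 0, 0]
        assert shifts.shift_of(2).tolist() == [1, 0, -1]
        assert shifts.shift_of(3).tolist() == [1, -1, -1]
        assert shifts.shift_of(4).tolist() == [0, -1, -1]

    def test_singleton_object(self):
        graph = graph_with_voxels([], {1: 7})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(1).tolist() == [0, 0, 0]
        assert 1 in shifts.anchors

    def test_triangle_uses_direct_edge(self):
        # equal occupancies: C is reached through the one-edge path A-C
        bridges = [
            Bridge(1, 2, (1, 0, 0), 2),
            Bridge(2, 3, (0, 1, 0), 2),
            Bridge(1, 3, (0, 0, 1), 2),
        ]
        graph = graph_with_voxels(bridges, {1: 50, 2: 5, 3: 5})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(3).tolist() == [0, 0, 1]

    def test_rare_bridge_bypassed_by_dominant_route(self):
        # a 1-voxel corner contact disagrees with the dominant two-edge
        # route; the widest (highest-bottleneck-occupancy) path wins
        bridges = [
            Bridge(1, 2, (1, 0, 0), 40),
            Bridge(2, 3, (0, 1, 0), 40),
            Bridge(1, 3, (1, 1, -1), 1),
        ]
        graph = graph_with_voxels(bridges, {1: 50, 2: 20, 3: 20})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(3).tolist() == [1, 1, 0]

    def test_edge_sign_orientation(self):
        # anchor on the b-side of a stored edge: traversal contributes -s
        bridges = [Bridge(1, 2, (0, 0, 1), 3)]
        graph = graph_with_voxels(bridges, {1: 5, 2: 50})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(2).tolist() == [0, 0, 0]
        assert shifts.shift_of(1).tolist() == [0, 0, -1]

    def test_anchor_largest_ties_to_smallest_label(self):
        bridges = [Bridge(1, 2, (1, 0, 0), 3)]
        graph = graph_with_voxels(bridges, {1: 10, 2: 10})
        shifts = pw.compose_shifts(graph)
        assert shifts.shift_of(1).tolist() == [0, 0, 0]


class TestApplyCompletion:
    def test_zero_shifts_identity(self):
        fx = pw.make_fixture("split_sphere", seed=0)
        grid = pw.voxelize(fx.points, np.ones(fx.points.n_atoms, bool), fx.box, 1.0)
        labels = pw.label_components(grid)
        shifts = pw.SegmentShiftMap(
            {s: np.zeros(3, int) for s in range(1, labels.n_segments + 1)}
        )
        out = pw.apply_completion(fx.points, grid, labels, shifts, fx.box)
        assert np.array_equal(out.coords, fx.points.coords)

    def test_split_sphere_becomes_compact(self):
        fx = pw.make_fixture("split_sphere", seed=2)
        result, _ = pipeline_point_shifts(fx)
        extent = result.points.coords.max(axis=0) - result.points.coords.min(axis=0)
        assert np.all(extent < fx.box.lengths[0] * 0.8)

    def test_wrap_of_output_reproduces_input(self):
        fx = pw.make_fixture("split_sphere", seed=3)
        result, _ = pipeline_point_shifts(fx)
        back = pw.wrap_coords(result.points.coords, fx.box)
        assert np.abs(back - fx.points.coords).max() < 1e-6

    def test_unselected_points_untouched(self):
        fx = pw.make_fixture("split_sphere", seed=1)
        mask = np.ones(fx.points.n_atoms, bool)
        mask[:100] = False
        result = pw.make_whole_frame(
            fx.points, fx.box, resolution=fx.resolution, selection_mask=mask
        )
        assert np.array_equal(result.points.coords[:100], fx.points.coords[:100])

    def test_anchor_segment_never_moves(self):
        for seed in range(4):
            fx = pw.make_fixture("dodecahedral_vesicle", seed=seed)
            result, shifts = pipeline_point_shifts(fx)
            counts = result.labels.voxel_counts()
            for anchor in result.shifts.anchors:
                moved = shifts[result.labels.atom_label == anchor]
                assert not moved.any()
                members = list(result.shifts.anchors[anchor])
                assert counts[anchor - 1] == max(counts[s - 1] for s in members)

    def test_idempotent_up_to_global_shift(self):
        fx = pw.make_fixture("dodecahedral_vesicle", seed=5)
        result, _ = pipeline_point_shifts(fx)
        rewrapped = fx.points.copy()
        rewrapped.coords = pw.wrap_coords(result.points.coords, fx.box)
        again = pw.make_whole_frame(rewrapped, fx.box, resolution=fx.resolution)
        diff = pw.to_fractional(again.points.coords - result.points.coords, fx.box)
        diff = np.round(diff).astype(int)
        assert len(np.unique(diff, axis=0)) == 1


class TestMakeMoleculesWhole:
    def test_two_atom_minimum_image(self):
        box = pw.Box.cubic(10.0)
        cloud = pw.PointCloud(
            coords=np.array([[0.05, 5.0, 5.0], [9.95, 5.0, 5.0]]),
            molecule_id=np.zeros(2, int),
            bonds=np.array([[0, 1]]),
        )
        out = pw.make_molecules_whole(cloud, box)
        assert np.allclose(out.coords[1], [-0.05, 5.0, 5.0])
        assert np.linalg.norm(out.coords[1] - out.coords[0]) == pytest.approx(0.1)

    def test_whole_molecule_unchanged(self):
        box = pw.Box.cubic(10.0)
        coords = np.array([[4.0, 5.0, 5.0], [4.3, 5.0, 5.0], [4.6, 5.0, 5.0]])
        cloud = pw.PointCloud(
            coords=coords, molecule_id=np.zeros(3, int), bonds=np.array([[0, 1], [1, 2]])
        )
        out = pw.make_molecules_whole(cloud, box)
        assert np.array_equal(out.coords, coords)

    def test_prewrapped_polymer_recovers_ground_truth(self):
        for seed in range(5):
            fx = pw.make_fixture("chain_polymer", seed=seed)
            out = pw.make_molecules_whole(fx.points, fx.box)
            bond_len = np.linalg.norm(np.diff(out.coords, axis=0), axis=1)
            assert bond_len.max() < fx.box.lengths.min() / 2
            diff = pw.to_fractional(out.coords - fx.whole_coords, fx.box)
            diff = np.round(diff).astype(int)
            assert len(np.unique(diff, axis=0)) == 1  # global lattice shift only

    def test_missing_bonds_is_instructive_error(self):
        cloud = pw.PointCloud(coords=np.zeros((2, 3)), molecule_id=np.zeros(2, int))
        with pytest.raises(MissingBondsError, match="topology"):
            pw.make_molecules_whole(cloud, pw.Box.cubic(1.0))


class TestAssociativeCompletion:
    def _lipid_like(self):
        # molecule 0: "tail" atoms 0-1 selected, "head" atom 2 unselected and
        # wrapped to the far side; molecule 1: unselected solvent outside box
        box = pw.Box.cubic(10.0)
        coords = np.array([
            [1.0, 5.0, 5.0],
            [0.4, 5.0, 5.0],
            [9.8, 5.0, 5.0],  # head, true position -0.2
            [12.0, 5.0, 5.0],  # solvent, outside the cell
        ])
        cloud = pw.PointCloud(
            coords=coords,
            molecule_id=np.array([0, 0, 0, 1]),
            bonds=np.array([[0, 1], [1, 2]]),
        )
        return box, cloud, np.array([True, True, False, False])

    def test_head_reattached_to_shifted_tail(self):
        box, cloud, mask = self._lipid_like()
        out = pw.associative_completion(cloud, mask, box)
        assert np.allclose(out.coords[2], [-0.2, 5.0, 5.0])

    def test_fully_selected_molecule_is_noop(self):
        box, cloud, _ = self._lipid_like()
        mask = np.array([True, True, True, False])
        out = pw.associative_completion(cloud, mask, box)
        assert np.array_equal(out.coords[:3], cloud.coords[:3])

    def test_unselected_molecule_only_wrapped(self):
        box, cloud, mask = self._lipid_like()
        out = pw.associative_completion(cloud, mask, box)
        assert np.allclose(out.coords[3], [2.0, 5.0, 5.0])
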