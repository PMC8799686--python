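"""Assessment metrics: topology, centeredness, replication, invariance."""

import numpy as np
import pytest

import voxelskel as vs
from voxelskel.assessment import (
    ScalabilityReport,
    centeredness,
    noise_robustness_scan,
    replication_metrics,
    rotational_invariance,
    topology_report,
)
from voxelskel.errors import InvalidParameterError

from oracles import betti_oracle


class TestTopologyReport:
    def test_solid_cube(self):
        cells = {(i, j, k) for i in range(4) for j in range(4) for k in range(4)}
        g = vs.VoxelGrid.from_occupancy(cells)
        assert topology_report(g).betti == (1, 0, 0)

    def test_torus(self, torus_grid):
        assert topology_report(torus_grid).betti == (1, 1, 0)
        assert topology_report(torus_grid).euler == 0

    def test_hollow_shell(self):
        cells = {
            (i, j, k)
            for i in range(5) for j in range(5) for k in range(5)
            if i in (0, 4) or j in (0, 4) or k in (0, 4)
        }
        g = vs.VoxelGrid.from_occupancy(cells)
        rep = topology_report(g)
        assert rep.betti == (1, 0, 1)
        assert rep.euler == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_blobs_match_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cells = {tuple(c) for c in rng.integers(0, 7, size=(120, 3))}
        g = vs.VoxelGrid.from_occupancy(cells)
        assert topology_report(g).betti == betti_oracle(g.data)


class TestCenteredness:
    def test_skeleton_on_centerline_all_correct(self, cylinder_phantom, cylinder_skeleton):
        idx = np.array(cylinder_skeleton.indices, dtype=float)
        rep = centeredness(cylinder_skeleton, idx)
        assert rep.correct_fraction == 1.0

    def test_offset_by_one_voxel_is_acceptable(self, cylinder_skeleton):
        idx = np.array(cylinder_skeleton.indices, dtype=float) + np.array([1.0, 0, 0])
        rep = centeredness(cylinder_skeleton, idx)
        assert rep.correct_fraction == 0.0
        assert rep.acceptable_fraction == 1.0

    def test_cylinder_pipeline_meets_87_percent(self, cylinder_phantom, cylinder_skeleton):
        # ground-truth axis in the padded lattice frame (pad=2 shift)
        cl = cylinder_phantom.centerline_points()
        shift = -np.array(sorted(cylinder_phantom.occupancy)).min(axis=0) + 2
        ref = cl + shift
        rep = centeredness(cylinder_skeleton, ref)
        assert rep.within_acceptable >= 0.87

    def test_fractions_sum_to_one(self, cylinder_skeleton):
        idx = np.array(cylinder_skeleton.indices, dtype=float)
        rep = centeredness(cylinder_skeleton, idx + 0.3)
        assert rep.correct_fraction + rep.acceptable_fraction + rep.poor_fraction == pytest.approx(1.0)

    def test_empty_reference_raises(self, cylinder_skeleton):
        with pytest.raises(InvalidParameterError):
            centeredness(cylinder_skeleton, np.empty((0, 3)))


class TestReplication:
    def test_identical_grids(self, cylinder_grid):
        rep = replication_metrics(cylinder_grid, cylinder_grid)
        assert rep.replicated_fraction == 1.0 and rep.correct_fraction == 1.0

    def test_doubling_superset(self, cylinder_grid):
        data = cylinder_grid.data.copy()
        free = np.argwhere(~data)
        data[tuple(free[: cylinder_grid.count].T)] = True
        sup = cylinder_grid.with_data(data)
        rep = replication_metrics(cylinder_grid, sup)
        assert rep.replicated_fraction == 1.0
        assert rep.correct_fraction == pytest.approx(0.5)

    def test_half_subset(self, cylinder_grid):
        occ = np.argwhere(cylinder_grid.data)
        half = occ[: len(occ) // 2]
        data = np.zeros_like(cylinder_grid.data)
        data[tuple(half.T)] = True
        rep = replication_metrics(cylinder_grid, cylinder_grid.with_data(data))
        assert rep.correct_fraction == 1.0
        assert rep.replicated_fraction == pytest.approx(0.5, abs=0.01)

    def test_symmetry_under_swap(self, cylinder_grid):
        data = np.roll(cylinder_grid.data, 1, axis=0)
        other = cylinder_grid.with_data(data)
        ab = replication_metrics(cylinder_grid, other)
        ba = replication_metrics(other, cylinder_grid)
        assert ab.replicated_fraction == pytest.approx(ba.correct_fraction)
        assert ab.correct_fraction == pytest.approx(ba.replicated_fraction)

    def test_mismatched_grids_raise(self, cylinder_grid, torus_grid):
        with pytest.raises(InvalidParameterError):
            replication_metrics(cylinder_grid, torus_grid)

    def test_three_way_labelling_partitions(self, cylinder_grid, cylinder_skeleton):
        rec = vs.reconstruct_circular(cylinder_skeleton, 2)
        rep = replication_metrics(cylinder_grid, rec.grid)
        lab = rep.labelling(cylinder_grid, rec.grid)
        assert len(lab["common"]) == rep.n_common
        assert len(lab["common"]) + len(lab["missing"]) == rep.n_original
        assert len(lab["common"]) + len(lab["redundant"]) == rep.n_reconstructed


class TestRotationalInvariance:
    def test_z_cylinder_rotation_about_z_full_overlap(self):
        ph = vs.make_cylinder(3, 16)
        g = vs.grid_from_phantom(ph)
        res = rotational_invariance(g, "z")
        assert res["overlap_fraction"] == pytest.approx(1.0)
        assert res["topology_invariant"]

    def test_asymmetric_phantom_small_deviation(self, y_phantom):
        g = vs.grid_from_phantom(y_phantom)
        res = rotational_invariance(g, "z")
        assert res["topology_invariant"]
        assert res["max_deviation"] <= 2.0

    def test_bad_axis_raises(self, cylinder_grid):
        with pytest.raises(InvalidParameterError):
            rotational_invariance(cylinder_grid, "w")


class TestNoiseRobustness:
    def test_zero_sigma_no_failures(self):
        ph = vs.make_torus(6, 1.5)
        res = noise_robustness_scan(ph, [0.0], trials=2, seed=3)
        assert res["failure_rates"] == [0.0]

    def test_unsorted_sigmas_raise(self):
        with pytest.raises(InvalidParameterError):
            noise_robustness_scan(vs.make_torus(6, 1.5), [0.5, 0.1], trials=1)


def test_scalability_report_records_steps():
    rep = ScalabilityReport()
    with rep.time("7_thinning"):
        sum(range(1000))
    rep.input_bytes = 1000
    rep.output_bytes = 10
    assert "7_thinning" in rep.step_seconds
    assert rep.reduction_percentage == pytest.approx(1.0)
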