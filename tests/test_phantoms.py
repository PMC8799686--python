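"""Phantom generators: occupancy correctness, ground truth, sampling."""

import numpy as np
import pytest

import voxelskel as vs
from voxelskel.errors import InvalidParameterError
from voxelskel.phantoms import exposed_faces

from oracles import betti_oracle


class TestCylinder:
    def test_degenerate_radius_is_a_line(self):
        ph = vs.make_cylinder(0.5, 5)
        assert len(ph.occupancy) == 5
        cl = ph.centerline_points()
        assert {tuple(map(int, p)) for p in cl} == ph.occupancy

    def test_occupancy_matches_brute_force_distance_test(self):
        r, L = 3, 20
        ph = vs.make_cylinder(r, L)
        expected = {
            (dx, dy, z)
            for dx in range(-4, 5)
            for dy in range(-4, 5)
            for z in range(L)
            if dx * dx + dy * dy <= r * r
        }
        assert ph.occupancy == expected

    def test_betti_matches_oracle(self):
        ph = vs.make_cylinder(3, 20)
        g = vs.grid_from_phantom(ph)
        assert betti_oracle(g.data) == ph.betti == (1, 0, 0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            vs.make_cylinder(0, 5)
        with pytest.raises(InvalidParameterError):
            vs.make_cylinder(2, 0)


class TestEllipticalTube:
    def test_circle_is_er_one_ellipse(self):
        assert vs.make_elliptical_tube(3, 3, 8).occupancy == vs.make_cylinder(3, 8).occupancy

    def test_er_ground_truth(self):
        ph = vs.make_elliptical_tube(6, 2, 10)
        assert ph.elliptical_ratio == pytest.approx(3.0)
        for prof in ph.radius_profile:
            p = np.asarray(prof)
            assert np.all(p[:, 0] / p[:, 1] == 3.0)

    def test_slice_occupancy_matches_membership_oracle(self):
        a, b = 6, 2
        ph = vs.make_elliptical_tube(a, b, 4)
        slice0 = {(x, y) for (x, y, z) in ph.occupancy if z == 0}
        expected = {
            (x, y)
            for x in range(-7, 8)
            for y in range(-3, 4)
            if (x / a) ** 2 + (y / b) ** 2 <= 1
        }
        assert slice0 == expected

    def test_major_less_than_minor_raises(self):
        with pytest.raises(InvalidParameterError):
            vs.make_elliptical_tube(2, 3, 5)


class TestTorus:
    def test_betti_one_loop_no_cavity(self, torus_phantom, torus_grid):
        assert betti_oracle(torus_grid.data) == torus_phantom.betti == (1, 1, 0)

    def test_centerline_is_closed(self, torus_phantom):
        ring = torus_phantom.centerline[0]
        gap = np.abs(np.round(ring[0]) - np.round(ring[-1]))
        assert gap.max() <= 1  # first and last cells 26-adjacent

    def test_two_disjoint_tori_union(self):
        t1 = vs.make_torus(6, 1.5)
        occ2 = {(i + 40, j, k) for (i, j, k) in t1.occupancy}
        union = vs.VoxelGrid.from_occupancy(t1.occupancy | occ2)
        assert betti_oracle(union.data) == (2, 2, 0)

    def test_overlapping_tube_raises(self):
        with pytest.raises(InvalidParameterError):
            vs.make_torus(2, 2)


class TestYJunction:
    def test_three_chains_meet_at_one_point(self, y_phantom):
        assert len(y_phantom.centerline) == 3
        j = y_phantom.junction
        for chain in y_phantom.centerline[1:]:
            assert np.allclose(chain[0], j)
        assert np.allclose(y_phantom.centerline[0][-1], j)

    def test_betti(self, y_phantom):
        g = vs.grid_from_phantom(y_phantom)
        assert betti_oracle(g.data) == (1, 0, 0)

    def test_degenerate_angle_raises(self):
        with pytest.raises(InvalidParameterError):
            vs.make_y_junction(2, 2, angles=(0.0, 30.0))


class TestSampling:
    def test_zero_noise_points_near_boundary(self):
        ph = vs.make_cylinder(3, 10)
        boundary = np.array(sorted({c for c, _ in exposed_faces(ph.occupancy)}), float) + 0.5
        # without surface skin, points lie on the boundary faces themselves:
        # within half a voxel diagonal of a boundary cell center
        flat = vs.sample_surface_cloud(ph, vs.SamplingSpec(skin_ratio=0.0, seed=3))
        d = np.min(np.linalg.norm(flat.points[:, None, :] - boundary[None], axis=2), axis=1)
        assert d.max() <= np.sqrt(3) / 2 + 1e-9
        # with the default half-voxel skin the extra normal offset is <= 0.5
        skinned = vs.sample_surface_cloud(ph, vs.SamplingSpec(seed=3))
        d = np.min(np.linalg.norm(skinned.points[:, None, :] - boundary[None], axis=2), axis=1)
        assert d.max() <= np.sqrt(3) / 2 + 0.5 + 1e-9

    def test_same_seed_identical_clouds(self):
        ph = vs.make_cylinder(3, 10)
        spec = vs.SamplingSpec(noise_sigma_ratio=0.4, seed=11)
        c1 = vs.sample_surface_cloud(ph, spec)
        c2 = vs.sample_surface_cloud(ph, spec)
        assert np.array_equal(c1.points, c2.points)

    def test_jitter_standard_deviation(self):
        ph = vs.make_cylinder(6, 40)
        spec = vs.SamplingSpec(
            points_per_unit_area=40, noise_sigma_ratio=0.5, skin_ratio=0.0, seed=5
        )
        noisy = vs.sample_surface_cloud(ph, spec)
        clean = vs.sample_surface_cloud(
            vs.make_cylinder(6, 40),
            vs.SamplingSpec(points_per_unit_area=40, noise_sigma_ratio=0.0,
                            skin_ratio=0.0, seed=5),
        )
        jitter = (noisy.points - clean.points).ravel()
        assert len(jitter) > 1e5
        assert np.std(jitter) == pytest.approx(0.5, rel=0.02)

    def test_holes_remove_a_cap(self):
        ph = vs.make_cylinder(4, 20)
        full = vs.sample_surface_cloud(ph, vs.SamplingSpec(seed=2))
        holed = vs.sample_surface_cloud(
            ph, vs.SamplingSpec(seed=2, hole_specs=[((0, 0, 1), 30.0)])
        )
        assert len(holed) < len(full)
        # no remaining point inside the cap
        centroid = np.array(sorted(ph.occupancy), float).mean(axis=0) + 0.5
        rel = holed.points - centroid
        cos = rel[:, 2] / np.linalg.norm(rel, axis=1)
        assert np.all(cos < np.cos(np.radians(30.0)))


@pytest.mark.parametrize("make", [
    lambda: vs.make_cylinder(4, 16),
    lambda: vs.make_elliptical_tube(5, 2, 12),
    lambda: vs.make_torus(8, 2),
])
def test_noise_free_roundtrip_recovers_occupancy(make):
    """Sampling, voxelizing, denoising and filling recovers >= 99% of occupancy."""
    from voxelskel.morphology import denoise, fill_internal
    from voxelskel.voxel_grid import voxelize

    ph = make()
    cloud = vs.sample_surface_cloud(ph, vs.SamplingSpec(seed=7))
    grid = voxelize(cloud, voxel_size=ph.voxel_size)
    grid, _ = denoise(grid, keep_first=True)
    grid = fill_internal(grid)
    base = np.round(grid.origin / ph.voxel_size).astype(int)
    recovered = {tuple(i + base) for i in np.argwhere(grid.data)}
    frac = len(ph.occupancy & recovered) / len(ph.occupancy)
    assert frac >= 0.99


def test_phantom_serialization_roundtrip(tmp_path):
    ph = vs.make_torus(6, 1.5)
    from voxelskel.phantoms import load_phantom, save_phantom

    save_phantom(ph, tmp_path / "t.txt")
    back = load_phantom(tmp_path / "t.txt")
    assert back.occupancy == ph.occupancy
    assert back.betti == ph.betti
    assert np.allclose(back.centerline[0], ph.centerline[0])
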