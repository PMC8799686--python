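"""Denoising, surface filling and internal filling."""

import numpy as np
import pytest

import voxelskel as vs
from voxelskel.errors import InvalidParameterError, TieBreakError
from voxelskel.morphology import FillList, denoise, fill_internal, fill_surface, suggest_holes

from oracles import betti_oracle, bfs_cavities


def bar_grid():
    cells = {(i, j, k) for i in range(3) for j in range(3) for k in range(10)}
    return vs.VoxelGrid.from_occupancy(cells)


def shell_grid(missing=None):
    cells = {
        (i, j, k)
        for i in range(5)
        for j in range(5)
        for k in range(5)
        if i in (0, 4) or j in (0, 4) or k in (0, 4)
    }
    if missing:
        cells -= {missing}
    return vs.VoxelGrid.from_occupancy(cells)


class TestDenoise:
    def test_removes_isolated_voxel(self):
        g = bar_grid()
        data = g.data.copy()
        data[-1, -1, -1] = True
        noisy = g.with_data(data)
        cleaned, removed = denoise(noisy)
        assert removed == 1
        assert np.array_equal(cleaned.data, g.data)

    def test_corner_touching_blob_removed_despite_26_connection(self):
        """6-connectivity is the denoising criterion; 26-linked blobs go."""
        cells = {(i, j, k) for i in range(4) for j in range(4) for k in range(4)}
        blob = {(4 + i, 4 + j, 4 + k) for i in range(2) for j in range(2) for k in range(2)}
        g = vs.VoxelGrid.from_occupancy(cells | blob)
        cleaned, removed = denoise(g)
        assert removed == 8

    def test_single_component_unchanged(self):
        g = bar_grid()
        cleaned, removed = denoise(g)
        assert removed == 0
        assert np.array_equal(cleaned.data, g.data)

    def test_tie_raises_unless_flagged(self):
        g = vs.VoxelGrid.from_occupancy({(0, 0, 0), (5, 5, 5)})
        with pytest.raises(TieBreakError):
            denoise(g)
        with pytest.warns(UserWarning):
            cleaned, removed = denoise(g, keep_first=True)
        assert removed == 1
        assert cleaned.is_object((1, 1, 1))  # padded position of (0,0,0)

    def test_never_increases_occupancy(self):
        rng = np.random.default_rng(0)
        cells = {tuple(c) for c in rng.integers(0, 10, size=(150, 3))}
        g = vs.VoxelGrid.from_occupancy(cells)
        cleaned, _ = denoise(g, keep_first=True)
        assert cleaned.count <= g.count


class TestFillSurface:
    def test_empty_fill_list_unchanged(self):
        g = bar_grid()
        out = fill_surface(g, FillList())
        assert np.array_equal(out.data, g.data)

    def test_knocked_out_shell_cell_restores_cavity(self):
        hole = (2, 0, 2)
        g = shell_grid(missing=hole)
        assert bfs_cavities(g.data) == 0
        # padded grid shifts indices by +1
        filled = fill_surface(g, FillList(indices=[(3, 1, 3)]))
        assert bfs_cavities(filled.data) == 1

    def test_idempotent(self):
        g = shell_grid(missing=(2, 0, 2))
        fills = FillList(indices=[(3, 1, 3)])
        once = fill_surface(g, fills)
        with pytest.warns(UserWarning):
            twice = fill_surface(once, fills)
        assert np.array_equal(once.data, twice.data)

    def test_out_of_bounds_raises(self):
        with pytest.raises(InvalidParameterError):
            fill_surface(bar_grid(), FillList(indices=[(99, 0, 0)]))

    def test_json_roundtrip(self, tmp_path):
        fl = FillList(indices=[(1, 2, 3), (4, 5, 6)], label="under deck",
                      voxel_size_check=1.0)
        fl.to_json(tmp_path / "f.json")
        back = FillList.from_json(tmp_path / "f.json")
        assert back.indices == fl.indices and back.label == fl.label


class TestSuggestHoles:
    def test_solid_cube_has_no_candidates(self):
        cells = {(i, j, k) for i in range(4) for j in range(4) for k in range(4)}
        g = vs.VoxelGrid.from_occupancy(cells)
        assert suggest_holes(g, 5) == []

    def test_missing_face_cell_found(self):
        g = shell_grid(missing=(2, 0, 2))
        cands = suggest_holes(g, 4)
        assert (3, 1, 3) in [c for c, _ in cands]

    def test_threshold_above_six_always_empty(self):
        g = shell_grid(missing=(2, 0, 2))
        assert suggest_holes(g, 7) == []


class TestFillInternal:
    def test_hollow_shell_filled(self):
        g = shell_grid()
        filled = fill_internal(g)
        assert filled.count - g.count == 27
        assert bfs_cavities(filled.data) == 0

    def test_solid_cube_unchanged(self):
        cells = {(i, j, k) for i in range(4) for j in range(4) for k in range(4)}
        g = vs.VoxelGrid.from_occupancy(cells)
        assert np.array_equal(fill_internal(g).data, g.data)

    def test_torus_hole_is_external(self, torus_grid):
        filled = fill_internal(torus_grid)
        assert np.array_equal(filled.data, torus_grid.data)
        assert betti_oracle(filled.data) == (1, 1, 0)

    def test_void_single_component_after(self):
        g = shell_grid()
        filled = fill_internal(g)
        from oracles import union_find_components

        void = np.argwhere(~filled.data)
        assert len(union_find_components(void, code=6)) == 1


def test_pipeline_order_idempotent():
    """denoise -> fill_surface -> fill_internal applied twice equals once."""
    g = shell_grid(missing=(2, 0, 2))
    data = g.data.copy()
    data[-1, -1, -1] = True
    g = g.with_data(data)
    fills = FillList(indices=[(3, 1, 3)])

    def pipe(grid):
        grid, _ = denoise(grid, keep_first=True)
        grid = fill_surface(grid, fills)
        return fill_internal(grid)

    once = pipe(g)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        twice = pipe(once)
    assert np.array_equal(once.data, twice.data)
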