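"""Occupancy lattices: voxelization, connectivity primitives, text serialization.

A :class:`VoxelGrid` is an axis-aligned lattice of cubic cells.  A cell is
"object" when at least one cloud point falls inside its half-open box
``[corner, corner + voxel_size)``; all other cells are "void".  The grid is
always padded by one layer of void cells on every face so that an external
void region exists for flood filling and so that template matching at the
data boundary is well defined (out-of-grid counts as void).

Indices are 0-based integer triples; world coordinates of a cell corner are
``origin + index * voxel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "VoxelGrid",
    "voxelize",
    "neighbors",
    "connected_components",
    "structuring_element",
    "save_grid",
    "load_grid",
]

#: 26-neighbourhood offsets (Chebyshev distance 1).
OFFSETS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)
#: 18-neighbourhood: faces and edges.
OFFSETS_18 = tuple(o for o in OFFSETS_26 if abs(o[0]) + abs(o[1]) + abs(o[2]) <= 2)
#: 6-neighbourhood: faces only.
OFFSETS_6 = tuple(o for o in OFFSETS_26 if abs(o[0]) + abs(o[1]) + abs(o[2]) == 1)

_OFFSETS = {6: OFFSETS_6, 18: OFFSETS_18, 26: OFFSETS_26}


def structuring_element(code: int) -> np.ndarray:
    """3x3x3 boolean structuring element for the given connectivity code."""
    if code not in _OFFSETS:
        raise InvalidParameterError(f"connectivity must be 6, 18 or 26, got {code}")
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = True
    for o in _OFFSETS[code]:
        s[1 + o[0], 1 + o[1], 1 + o[2]] = True
    return s


@dataclass
class VoxelGrid:
    """Axis-aligned occupancy lattice.

    Attributes
    ----------
    dims:
        Lattice extents ``(nx, ny, nz)``.
    origin:
        World coordinate of the corner of cell ``(0, 0, 0)``.
    voxel_size:
        Cell edge length in metres.
    data:
        Dense boolean occupancy array of shape ``dims`` (True = object).
    depth:
        Octree depth used during voxelization, if any (informational).
    """

    dims: tuple[int, int, int]
    origin: np.ndarray
    voxel_size: float
    data: np.ndarray
    depth: int | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.data = np.asarray(self.data, dtype=bool)
        if self.voxel_size <= 0:
            raise InvalidParameterError("voxel_size must be positive")
        if self.data.shape != tuple(self.dims):
            raise InvalidParameterError(
                f"data shape {self.data.shape} != dims {self.dims}"
            )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_occupancy(
        cls,
        occupancy: Iterable[tuple[int, int, int]],
        voxel_size: float = 1.0,
        origin: Sequence[float] | None = None,
        pad: int = 1,
        depth: int | None = None,
    ) -> "VoxelGrid":
        """Build a padded grid from a set of occupied index triples.

        Indices are shifted so the minimum occupied index maps to ``pad``;
        ``origin`` (if given) refers to the *unshifted* corner of the input
        index (0,0,0) and is adjusted accordingly.
        """
        occ = np.array(sorted(set(map(tuple, occupancy))), dtype=int)
        if occ.size == 0:
            raise EmptyInputError("occupancy is empty")
        lo = occ.min(axis=0) - pad
        hi = occ.max(axis=0) + pad
        dims = tuple(int(d) for d in hi - lo + 1)
        data = np.zeros(dims, dtype=bool)
        data[tuple((occ - lo).T)] = True
        base = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
        return cls(dims, base + lo * voxel_size, voxel_size, data, depth)

    # -- accessors ---------------------------------------------------------
    @property
    def occupancy(self) -> set[tuple[int, int, int]]:
        """Occupied cells as a set of index triples (the public contract)."""
        return set(map(tuple, np.argwhere(self.data)))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def in_bounds(self, index: Sequence[int]) -> bool:
        return all(0 <= index[a] < self.dims[a] for a in range(3))

    def is_object(self, index: Sequence[int]) -> bool:
        """Object state of a cell; cells outside the grid count as void."""
        if not self.in_bounds(index):
            return False
        return bool(self.data[tuple(index)])

    def world(self, index: Sequence[int], center: bool = True) -> np.ndarray:
        """World coordinates of a cell corner (or center)."""
        p = self.origin + np.asarray(index, dtype=float) * self.voxel_size
        if center:
            p = p + 0.5 * self.voxel_size
        return p

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.dims, self.origin.copy(), self.voxel_size,
                         self.data.copy(), self.depth)

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.dims, self.origin.copy(), self.voxel_size,
                         np.asarray(data, dtype=bool), self.depth)


def voxelize(
    cloud,
    depth: int | None = None,
    voxel_size: float | None = None,
    origin: Sequence[float] | None = None,
) -> VoxelGrid:
    """Voxelize a point cloud at a given octree depth or explicit edge length.

    Exactly one of ``depth`` / ``voxel_size`` must be given.  With ``depth``,
    the bounding cube side equals ``voxel_size * 2**depth`` where the edge
    length is derived from the cloud's largest extent (an octree of that depth
    splits the bounding cube into ``2**depth`` cells per axis).  A cell is
    object iff at least one point falls in its half-open box.  The resulting
    grid is padded with one layer of void cells on all faces.

    ``origin`` optionally pins the lattice to a known frame (used when
    comparing against a phantom's own lattice); it must lie at or below the
    cloud's minimum corner.
    """
    pts = np.asarray(cloud.points, dtype=float)
    if pts.size == 0:
        raise EmptyInputError("cannot voxelize an empty cloud")
    if (depth is None) == (voxel_size is None):
        raise InvalidParameterError("give exactly one of depth or voxel_size")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if depth is not None:
        if depth < 1:
            raise InvalidParameterError("depth must be >= 1")
        side = float((hi - lo).max())
        if side <= 0:
            side = 1.0
        voxel_size = side / (2 ** depth)
    assert voxel_size is not None
    if origin is None:
        # Snap to the voxel lattice so results are translation-robust and a
        # noise-free surface sample lands exactly on its source cells.
        base = np.floor(lo / voxel_size) * voxel_size
    else:
        base = np.asarray(origin, dtype=float)
        if np.any(base > lo + 1e-12):
            raise InvalidParameterError("origin must not exceed the cloud minimum")
    idx = np.floor((pts - base) / voxel_size).astype(int)
    grid = VoxelGrid.from_occupancy(
        map(tuple, idx), voxel_size=voxel_size, origin=base, pad=1, depth=depth
    )
    # Warn when the voxel size underruns the point spacing so badly that the
    # surface is likely to be riddled with holes.
    n_cells = grid.count
    if n_cells > 4 * len(pts):
        import warnings

        warnings.warn(
            "voxel_size is small relative to point density; surface holes likely",
            stacklevel=2,
        )
    return grid


def neighbors(grid: VoxelGrid, index: Sequence[int], code: int = 26) -> set[tuple[int, int, int]]:
    """Adjacent indices of a cell under 6/18/26-connectivity, clipped to the grid."""
    if code not in _OFFSETS:
        raise InvalidParameterError(f"connectivity must be 6, 18 or 26, got {code}")
    if not grid.in_bounds(index):
        raise InvalidParameterError(f"index {tuple(index)} out of bounds {grid.dims}")
    i, j, k = index
    out = set()
    for o in _OFFSETS[code]:
        n = (i + o[0], j + o[1], k + o[2])
        if grid.in_bounds(n):
            out.add(n)
    return out


def connected_components(
    grid: VoxelGrid,
    cell_set: Iterable[tuple[int, int, int]] | None = None,
    code: int = 26,
) -> list[set[tuple[int, int, int]]]:
    """Partition a cell set into maximal connected groups, largest first.

    With ``cell_set=None`` the grid's occupancy is used.  Ties in size are
    ordered by smallest member index so the result is deterministic.
    """
    if cell_set is None:
        mask = grid.data
    else:
        mask = np.zeros(grid.dims, dtype=bool)
        cells = list(cell_set)
        if not cells:
            return []
        arr = np.array(cells, dtype=int)
        mask[tuple(arr.T)] = True
    labels, n = ndimage.label(mask, structure=structuring_element(code))
    comps: list[set[tuple[int, int, int]]] = []
    for lab in range(1, n + 1):
        comps.append(set(map(tuple, np.argwhere(labels == lab))))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


# -- text serialization ----------------------------------------------------

def save_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Write occupied indices as columnar text plus a JSON header sidecar."""
    path = Path(path)
    occ = np.argwhere(grid.data)
    np.savetxt(path, occ, fmt="%d")
    header = {
        "dims": list(grid.dims),
        "origin": [float(v) for v in grid.origin],
        "voxel_size": grid.voxel_size,
        "depth": grid.depth,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def load_grid(path: str | Path) -> VoxelGrid:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    occ = np.loadtxt(path, dtype=int, ndmin=2)
    data = np.zeros(tuple(header["dims"]), dtype=bool)
    if occ.size:
        data[tuple(occ.T)] = True
    return VoxelGrid(
        tuple(header["dims"]),
        np.array(header["origin"]),
        header["voxel_size"],
        data,
        header.get("depth"),
    )
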