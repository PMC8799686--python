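"""Sequential, directional, template-driven voxel thinning.

The thinning loop repeats full cycles until a cycle deletes nothing.  Each
cycle runs the 38 template configurations as sub-passes in the fixed order
A-rotations, then B, C, D.  Per sub-pass, all object voxels matching the
configuration (against both the sub-pass-start grid and the cycle-start
grid — see below) form the candidate set; each candidate is checked against
the four deletion criteria and every passing candidate is deleted
simultaneously.

Deletion criteria for a candidate ``x`` (evaluated on the sub-pass-start
grid, with ``y`` ranging over the sub-pass candidate set):

a. all 26-adjacent object voxels of ``x`` form a single 26-connected
   component;
b. the void voxels of the 18-neighbourhood that are 6-adjacent to ``x``
   belong to a single 6-connected component of the 18-neighbourhood void
   (and at least one void face neighbour exists);
c. for any candidate ``y`` 26-adjacent to ``x``, some object voxel ``z``
   (candidate or not) is 26-adjacent to both — vacuously true without
   such ``y``;
d. for any candidate ``y`` 6-adjacent to ``x``, two void voxels ``z, t``
   complete a unit square with ``x`` and ``y`` — vacuously true without
   such ``y``.

Criteria (a) and (b) are the local simple-point conditions (object chains
are not broken; cavities are not merged); (c) and (d) make simultaneous
deletion within a sub-pass safe.  Curve ends — voxels with exactly one
26-adjacent object voxel whose sole neighbour is itself a chain voxel — are
excluded from candidacy so terminal branches survive; stubs attached to
thick material stay deletable, which suppresses spurs at eroding ends.

A sub-pass candidate must match its configuration on the cycle-start grid
as well as the current grid.  This restricts each cycle to the erosion
front that existed when the cycle began (one shell per direction per
cycle); without it, successive orientations cascade along thin plates and
destroy both centring and the iteration-of-exposure radius proxy.

During thinning the cycle index at which each face of each surviving voxel
first became void-adjacent is recorded; the sorted first four values are
the iterations of exposure I1..I4 used for volume reconstruction (faces
already exposed before the first cycle log 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ContractViolation, VoxelskelError
from .templates import TemplateMask, expand_rotations, match_array
from .voxel_grid import (
    OFFSETS_6,
    OFFSETS_18,
    OFFSETS_26,
    VoxelGrid,
    structuring_element,
)

__all__ = ["Skeleton", "SkeletonVoxel", "thin", "is_deletable", "thinness_check",
           "is_simple"]

Index = tuple[int, int, int]

_S26 = structuring_element(26)
_S6 = structuring_element(6)
_K26 = np.ones((3, 3, 3), dtype=np.uint8)
_K26[1, 1, 1] = 0
_K6 = _S6.astype(np.uint8).copy()
_K6[1, 1, 1] = 0

# face directions in a fixed order (+x, -x, +y, -y, +z, -z)
FACE_DIRS: tuple[Index, ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


@dataclass
class SkeletonVoxel:
    """One skeleton lattice cell with its exposure record."""

    index: Index
    world: np.ndarray
    exposure: tuple[int, int, int, int]  # I1 <= I2 <= I3 <= I4
    exposed_faces: int
    face_exposure: dict[Index, int]  # face direction -> cycle of first exposure

    @property
    def I1(self) -> int:
        return self.exposure[0]

    @property
    def I2(self) -> int:
        return self.exposure[1]

    @property
    def I3(self) -> int:
        return self.exposure[2]

    @property
    def I4(self) -> int:
        return self.exposure[3]


@dataclass
class Skeleton:
    """Thinning output: surviving voxels plus lattice metadata."""

    voxels: list[SkeletonVoxel]
    dims: tuple[int, int, int]
    origin: np.ndarray
    voxel_size: float
    cycles: int
    deletion_log: list[tuple[Index, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def indices(self) -> list[Index]:
        return [v.index for v in self.voxels]

    def as_grid(self) -> VoxelGrid:
        data = np.zeros(self.dims, dtype=bool)
        for v in self.voxels:
            data[v.index] = True
        return VoxelGrid(self.dims, self.origin.copy(), self.voxel_size, data)

    def by_index(self) -> dict[Index, SkeletonVoxel]:
        return {v.index: v for v in self.voxels}

    def to_csv(self, path: str | Path) -> None:
        """CSV export: i,j,k,x,y,z,I1..I4,exposed_faces (+ JSON header sidecar)."""
        import json

        path = Path(path)
        with open(path, "w") as fh:
            fh.write("i,j,k,x,y,z,I1,I2,I3,I4,exposed_faces\n")
            for v in self.voxels:
                i, j, k = v.index
                x, y, z = v.world
                fh.write(
                    f"{i},{j},{k},{x:.6f},{y:.6f},{z:.6f},"
                    f"{v.I1},{v.I2},{v.I3},{v.I4},{v.exposed_faces}\n"
                )
        header = {
            "dims": list(self.dims),
            "origin": [float(v) for v in self.origin],
            "voxel_size": self.voxel_size,
            "cycles": self.cycles,
            "voxel_count": len(self.voxels),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


# ---------------------------------------------------------------------------
# deletion criteria
# ---------------------------------------------------------------------------

def _block(data: np.ndarray, x: Index) -> np.ndarray:
    """3x3x3 neighbourhood of x, padded with void outside the array."""
    blk = np.zeros((3, 3, 3), dtype=bool)
    for a0 in (-1, 0, 1):
        for a1 in (-1, 0, 1):
            for a2 in (-1, 0, 1):
                i, j, k = x[0] + a0, x[1] + a1, x[2] + a2
                if 0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]:
                    blk[a0 + 1, a1 + 1, a2 + 1] = data[i, j, k]
    return blk


def _criterion_a(block: np.ndarray) -> bool:
    nb = block.copy()
    nb[1, 1, 1] = False
    if not nb.any():
        return False
    _, n = ndimage.label(nb, structure=_S26)
    return n == 1


def _criterion_b(block: np.ndarray) -> bool:
    void18 = np.zeros((3, 3, 3), dtype=bool)
    for o in OFFSETS_18:
        if not block[1 + o[0], 1 + o[1], 1 + o[2]]:
            void18[1 + o[0], 1 + o[1], 1 + o[2]] = True
    faces = [(1 + o[0], 1 + o[1], 1 + o[2]) for o in OFFSETS_6]
    if not any(void18[f] for f in faces):
        return False
    labels, _ = ndimage.label(void18, structure=_S6)
    return len({labels[f] for f in faces if labels[f] > 0}) == 1


def _criterion_c(data: np.ndarray, x: Index, candidates: set[Index]) -> bool:
    i, j, k = x
    for o in OFFSETS_26:
        y = (i + o[0], j + o[1], k + o[2])
        if y not in candidates:
            continue
        found = False
        for o2 in OFFSETS_26:
            z = (y[0] + o2[0], y[1] + o2[1], y[2] + o2[2])
            if z == x or z == y:
                continue
            if max(abs(z[0] - i), abs(z[1] - j), abs(z[2] - k)) > 1:
                continue
            if (0 <= z[0] < data.shape[0] and 0 <= z[1] < data.shape[1]
                    and 0 <= z[2] < data.shape[2] and data[z]):
                found = True
                break
        if not found:
            return False
    return True


def _criterion_d(data: np.ndarray, x: Index, candidates: set[Index]) -> bool:
    def void(c: Index) -> bool:
        if not (0 <= c[0] < data.shape[0] and 0 <= c[1] < data.shape[1]
                and 0 <= c[2] < data.shape[2]):
            return True
        return not data[c]

    for ax in range(3):
        for s in (-1, 1):
            y = list(x)
            y[ax] += s
            y_t = tuple(y)
            if y_t not in candidates:
                continue
            ok = False
            for ax2 in range(3):
                if ax2 == ax:
                    continue
                for s2 in (-1, 1):
                    z = list(x)
                    z[ax2] += s2
                    t = list(y_t)
                    t[ax2] += s2
                    if void(tuple(z)) and void(tuple(t)):
                        ok = True
                        break
                if ok:
                    break
            if not ok:
                return False
    return True


def is_deletable(grid: VoxelGrid, x: Index, candidate_set: set[Index]) -> bool:
    """All four deletion criteria for candidate ``x`` of the current sub-pass.

    Criteria (a) and (b) are the local simple-point conditions evaluated on
    the given grid state; (c) and (d) are evaluated with ``y`` ranging over
    the candidate set.  The thinning loop calls this immediately before
    each deletion so that (a)/(b) always reflect the current grid — every
    deletion is then simple at its moment, which guarantees homotopy.
    """
    if x not in candidate_set:
        raise ContractViolation(f"{x} is not in the candidate set")
    data = grid.data
    blk = _block(data, x)
    return (
        _criterion_a(blk)
        and _criterion_b(blk)
        and _criterion_c(data, x, candidate_set)
        and _criterion_d(data, x, candidate_set)
    )


def is_simple(data: np.ndarray, x: Index) -> bool:
    """Local simple-point test (criteria (a) and (b) only)."""
    blk = _block(data, x)
    return _criterion_a(blk) and _criterion_b(blk)


# ---------------------------------------------------------------------------
# the thinning loop
# ---------------------------------------------------------------------------

def _now_protected(data: np.ndarray, x: Index) -> bool:
    """Re-check curve-end protection at deletion time.

    Earlier deletions in the same sub-pass may have turned ``x`` into a
    chain end (or isolated it); such voxels must not be nibbled within the
    sub-pass that exposed them.
    """
    blk = _block(data, x).copy()
    blk[1, 1, 1] = False
    deg = int(blk.sum())
    if deg == 0:
        return True
    if deg > 1:
        return False
    n_off = np.argwhere(blk)[0] - 1
    n = (x[0] + n_off[0], x[1] + n_off[1], x[2] + n_off[2])
    nblk = _block(data, n).copy()
    nblk[1, 1, 1] = False
    return int(nblk.sum()) <= 2


def _protected_ends(data: np.ndarray, deg26: np.ndarray) -> np.ndarray:
    """Curve ends to protect: degree-1 voxels whose sole neighbour has degree <= 2."""
    prot = np.zeros_like(data)
    for x in zip(*np.nonzero(data & (deg26 == 1))):
        blk = _block(data, x).copy()
        blk[1, 1, 1] = False
        n_off = np.argwhere(blk)[0] - 1
        n = (x[0] + n_off[0], x[1] + n_off[1], x[2] + n_off[2])
        if deg26[n] <= 2:
            prot[x] = True
    return prot


def thin(
    grid: VoxelGrid,
    record_exposure: bool = True,
    templates: list[TemplateMask] | None = None,
    keep_log: bool = False,
) -> Skeleton:
    """Thin a denoised, internally filled grid to a 1-voxel curve skeleton.

    Returns the surviving voxels with their iterations of exposure.  Raises
    if the loop fails to terminate within ``2 * max(dims) + 8`` cycles (a
    guard against template/criteria inconsistencies).
    """
    configs = expand_rotations(templates)
    data = grid.data.copy()
    exposure: dict[Index, dict[Index, int]] = {}
    if record_exposure:
        for x in map(tuple, np.argwhere(data)):
            for d in FACE_DIRS:
                n = (x[0] + d[0], x[1] + d[1], x[2] + d[2])
                if not (grid.in_bounds(n) and data[n]):
                    exposure.setdefault(x, {})[d] = 0
    log: list[tuple[Index, int, int]] = []
    cycle = 0
    max_cycles = 2 * max(grid.dims) + 8
    while True:
        cycle += 1
        if cycle > max_cycles:
            raise VoxelskelError("thinning loop did not terminate (internal error)")
        cycle_start = data.copy()
        deleted_this_cycle = False
        for sub, tpl in enumerate(configs):
            m = match_array(data, tpl) & match_array(cycle_start, tpl)
            if not m.any():
                continue
            deg26 = ndimage.convolve(data.astype(np.uint8), _K26, mode="constant")
            m &= ~_protected_ends(data, deg26)
            if not m.any():
                continue
            candidates = set(map(tuple, np.argwhere(m)))
            sub_grid = grid.with_data(data)  # shares `data`: stays current
            # Deletion is sequential in index order with re-validation on the
            # current grid, so every performed deletion is simple at its
            # moment regardless of what earlier candidates did.
            deleted_here = False
            for x in sorted(tuple(map(int, c)) for c in candidates):
                if _now_protected(data, x):
                    continue
                if not is_deletable(sub_grid, x, candidates):
                    continue
                data[x] = False
                deleted_here = True
                if record_exposure:
                    for d in FACE_DIRS:
                        n = (x[0] + d[0], x[1] + d[1], x[2] + d[2])
                        if grid.in_bounds(n) and data[n]:
                            back = (-d[0], -d[1], -d[2])
                            exposure.setdefault(n, {}).setdefault(back, cycle)
                if keep_log:
                    log.append((x, cycle, sub))
            if deleted_here:
                deleted_this_cycle = True
        if not deleted_this_cycle:
            break
    # assemble skeleton voxels
    voxels: list[SkeletonVoxel] = []
    for x in (tuple(map(int, c)) for c in np.argwhere(data)):
        fe = exposure.get(x, {}) if record_exposure else {}
        vals = sorted(fe.values())
        exposed = len(vals)
        padded = (vals + [cycle] * 4)[:4]  # unexposed faces count as final cycle
        voxels.append(
            SkeletonVoxel(
                index=x,
                world=grid.world(x),
                exposure=tuple(padded),
                exposed_faces=exposed,
                face_exposure=dict(fe),
            )
        )
    voxels.sort(key=lambda v: v.index)
    return Skeleton(voxels, grid.dims, grid.origin.copy(), grid.voxel_size,
                    cycle, log)


def thinness_check(skeleton_grid: VoxelGrid) -> bool:
    """True iff no non-curve-end voxel is a simple point.

    This is the thinness assessment: in a properly thinned skeleton no
    object voxel can be deleted without changing topology (curve ends are
    exempt — removing an end shortens a branch but is topologically
    simple by construction).
    """
    data = skeleton_grid.data
    deg26 = ndimage.convolve(data.astype(np.uint8), _K26, mode="constant")
    for x in map(tuple, np.argwhere(data)):
        if deg26[x] <= 1:
            continue
        if is_simple(data, x):
            return False
    return True
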