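"""Deletion templates for sequential voxel thinning.

Four base templates describe, for a candidate voxel's 26-neighbourhood,
positions that must be void, positions that must be object, and positions
whose state does not matter.  Applying all 24 proper cube rotations and
deduplicating identical patterns yields 6, 12, 8 and 12 unique
configurations for families A-D respectively, 38 in total.  A template
matches an object voxel when every constrained neighbour position agrees
with the grid; cells outside the grid count as void.

The four families act as directional border selectors:

* **A** (6 rotations) - face border: void at one face neighbour, object at
  the opposite face.  The workhorse: it selects any surface voxel that has
  material behind it along a lattice axis.
* **B** (12) - edge border: void at two adjacent faces and the edge between
  them, object at the opposite edge neighbour.  Selects convex-edge and
  staircase voxels whose support is edge-diagonal only.
* **C** (8) - corner border: void in the open octant around one corner,
  object at the opposite corner neighbour.  Selects convex corners with
  corner-diagonal support.
* **D** (12) - lateral rim: object at both face neighbours along one axis,
  void in a quarter-wedge orthogonal to it.  Selects rim voxels of
  one-voxel plates and laterally exposed column voxels, which have no
  opposite void/object face pair and therefore match none of A-C.

Every template requires at least one void neighbour (so interior voxels
never match) and at least one object neighbour (so isolated voxels never
match).  One-voxel-wide curves are protected by the thinning loop rather
than by non-matching: chain interiors fail deletion criterion (a) (their
two neighbours are separate local components) and chain endpoints are
excluded from candidacy by the curve-end guard.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ContractViolation, InvalidParameterError
from .voxel_grid import VoxelGrid

__all__ = ["TemplateMask", "base_templates", "expand_rotations", "matches",
           "rotation_matrices"]

Offset = tuple[int, int, int]


@dataclass(frozen=True)
class TemplateMask:
    """A 3x3x3 deletion pattern around a candidate voxel.

    ``void_offsets`` must be void, ``object_offsets`` must be object; the
    remaining neighbour positions are unconstrained.  ``family`` is one of
    A-D, ``rotation_id`` indexes the deduplicated rotations of that family.
    """

    family: str
    rotation_id: int
    void_offsets: frozenset[Offset]
    object_offsets: frozenset[Offset]

    def __post_init__(self) -> None:
        if self.void_offsets & self.object_offsets:
            raise InvalidParameterError("void and object offsets overlap")
        for o in self.void_offsets | self.object_offsets:
            if o == (0, 0, 0) or any(abs(v) > 1 for v in o):
                raise InvalidParameterError(f"offset {o} outside the 26-neighbourhood")

    @property
    def pattern(self) -> dict[Offset, str]:
        """All 26 neighbour positions mapped to 'void' / 'object' / 'free'."""
        pat = {}
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    if (i, j, k) == (0, 0, 0):
                        continue
                    o = (i, j, k)
                    if o in self.void_offsets:
                        pat[o] = "void"
                    elif o in self.object_offsets:
                        pat[o] = "object"
                    else:
                        pat[o] = "free"
        return pat

    def key(self) -> tuple:
        """Canonical identity of the constrained pattern (family-agnostic)."""
        return (tuple(sorted(self.void_offsets)), tuple(sorted(self.object_offsets)))

    def rotate(self, R: np.ndarray) -> "TemplateMask":
        rot = lambda off: tuple(int(v) for v in R @ np.asarray(off))
        return TemplateMask(
            self.family,
            self.rotation_id,
            frozenset(map(rot, self.void_offsets)),
            frozenset(map(rot, self.object_offsets)),
        )


@lru_cache(maxsize=1)
def rotation_matrices() -> tuple[np.ndarray, ...]:
    """The 24 proper rotations of the cube, as integer matrices."""
    rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]])
    ry = np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]])
    rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
    seen = {tuple(np.eye(3, dtype=int).ravel())}
    frontier = [np.eye(3, dtype=int)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (rx, ry, rz):
                c = g @ m
                k = tuple(c.ravel())
                if k not in seen:
                    seen.add(k)
                    nxt.append(c)
        frontier = nxt
    mats = tuple(np.array(k, dtype=int).reshape(3, 3) for k in sorted(seen))
    assert len(mats) == 24
    return mats


def base_templates() -> list[TemplateMask]:
    """The four base masks A-D (canonical orientation: void side toward +)."""
    A = TemplateMask(
        "A", 0,
        void_offsets=frozenset({(0, 0, 1)}),
        object_offsets=frozenset({(0, 0, -1)}),
    )
    B = TemplateMask(
        "B", 0,
        void_offsets=frozenset({(0, 1, 0), (0, 0, 1), (0, 1, 1)}),
        object_offsets=frozenset({(0, -1, -1)}),
    )
    C = TemplateMask(
        "C", 0,
        void_offsets=frozenset({
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
        }),
        object_offsets=frozenset({(-1, -1, -1)}),
    )
    D = TemplateMask(
        "D", 0,
        void_offsets=frozenset({(1, 0, 0), (0, 1, 0), (1, 1, 0)}),
        object_offsets=frozenset({(0, 0, 1), (0, 0, -1)}),
    )
    return [A, B, C, D]


def expand_rotations(templates: list[TemplateMask] | None = None) -> list[TemplateMask]:
    """All unique rotations of the base templates, ordered A, B, C, D.

    Duplicate patterns within a family are removed; a duplicate across
    families would be an internal inconsistency and raises.
    """
    if templates is None:
        templates = base_templates()
    out: list[TemplateMask] = []
    seen_global: dict[tuple, str] = {}
    for base in templates:
        uniq: dict[tuple, TemplateMask] = {}
        for R in rotation_matrices():
            r = base.rotate(R)
            k = r.key()
            if k not in uniq:
                uniq[k] = TemplateMask(base.family, len(uniq),
                                       r.void_offsets, r.object_offsets)
        for k, tpl in uniq.items():
            if k in seen_global:
                raise ContractViolation(
                    f"template duplicated across families {seen_global[k]} and {tpl.family}"
                )
            seen_global[k] = tpl.family
        out.extend(uniq.values())
    return out


def matches(grid: VoxelGrid, index: tuple[int, int, int], mask: TemplateMask) -> bool:
    """True iff the neighbourhood of an object voxel agrees with the mask.

    Constrained positions must match exactly; cells outside the grid count
    as void.
    """
    if not grid.is_object(index):
        raise ContractViolation(f"{index} is not an object voxel")
    i, j, k = index
    for o in mask.void_offsets:
        if grid.is_object((i + o[0], j + o[1], k + o[2])):
            return False
    for o in mask.object_offsets:
        if not grid.is_object((i + o[0], j + o[1], k + o[2])):
            return False
    return True


def match_array(data: np.ndarray, mask: TemplateMask) -> np.ndarray:
    """Vectorised matching over a dense occupancy array (border = void)."""
    m = data.copy()
    for o in mask.void_offsets:
        m &= ~_shift(data, o)
    for o in mask.object_offsets:
        m &= _shift(data, o)
    return m


def _shift(a: np.ndarray, off: Offset) -> np.ndarray:
    """result[i] = a[i + off], out-of-range reads as False."""
    res = np.zeros_like(a)
    src, dst = [], []
    for n, d in zip(a.shape, off):
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    res[tuple(dst)] = a[tuple(src)]
    return res
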