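"""Voxel-model clean-up: denoising, surface filling, internal filling.

These are steps 4-6 of the workflow.  Denoising keeps only the largest
6-connected component of the object (26-connectivity keeps too many loose
ends that would survive into the skeleton).  Surface holes caused by
occlusion or poor sampling are filled from an explicit, versionable
:class:`FillList` — the workflow treats hole filling as a recorded manual
step, with :func:`suggest_holes` as an advisory helper.  Internal filling
assumes the external void is a single 6-connected group and fills every
void cell not 6-connected to it, so the object becomes solid (no cavities).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, TieBreakError
from .voxel_grid import VoxelGrid, structuring_element

__all__ = ["FillList", "denoise", "fill_surface", "fill_internal", "suggest_holes"]


@dataclass
class FillList:
    """Indices to force to object, with a free-text provenance label."""

    indices: list[tuple[int, int, int]] = field(default_factory=list)
    label: str = ""
    voxel_size_check: float | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "FillList":
        doc = json.loads(Path(path).read_text())
        return cls(
            indices=[tuple(i) for i in doc.get("fills", [])],
            label=doc.get("label", ""),
            voxel_size_check=doc.get("voxel_size_check"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "voxel_size_check": self.voxel_size_check,
                    "fills": [list(i) for i in self.indices],
                    "label": self.label,
                },
                indent=1,
            )
        )


def denoise(grid: VoxelGrid, keep_first: bool = False) -> tuple[VoxelGrid, int]:
    """Keep only the largest 6-connected object component.

    Returns the cleaned grid and the number of removed voxels.  A tie for
    the largest component raises :class:`TieBreakError` unless
    ``keep_first`` is set, in which case the component containing the
    smallest index wins (logged via a warning).
    """
    if grid.count == 0:
        raise InvalidParameterError("grid has no object voxels")
    labels, n = ndimage.label(grid.data, structure=structuring_element(6))
    if n <= 1:
        return grid.copy(), 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    top = sizes.max()
    winners = np.nonzero(sizes == top)[0] + 1
    if len(winners) > 1:
        if not keep_first:
            raise TieBreakError(
                f"{len(winners)} components tie for largest ({int(top)} voxels); "
                "pass keep_first=True to keep the first in index order"
            )
        first = min(
            (tuple(idx) for w in winners for idx in np.argwhere(labels == w)[:1]),
        )
        win = int(labels[first])
        warnings.warn(f"component tie resolved toward index {first}", stacklevel=2)
    else:
        win = int(winners[0])
    cleaned = grid.with_data(labels == win)
    return cleaned, grid.count - cleaned.count


def fill_surface(grid: VoxelGrid, fills: FillList) -> VoxelGrid:
    """Force the fill-list cells to object (idempotent union)."""
    if fills.voxel_size_check is not None and not np.isclose(
        fills.voxel_size_check, grid.voxel_size
    ):
        raise InvalidParameterError(
            f"fill list was authored for voxel_size={fills.voxel_size_check}, "
            f"grid has {grid.voxel_size}"
        )
    data = grid.data.copy()
    for idx in fills.indices:
        if not grid.in_bounds(idx):
            raise InvalidParameterError(f"fill index {idx} outside grid dims {grid.dims}")
        if data[tuple(idx)]:
            warnings.warn(f"fill index {idx} is already object", stacklevel=2)
        data[tuple(idx)] = True
    return grid.with_data(data)


def suggest_holes(grid: VoxelGrid, min_object_face_neighbors: int = 4) -> list[tuple[tuple[int, int, int], int]]:
    """Advisory hole candidates: void cells with many object face-neighbours.

    Returns ``(index, count)`` pairs ranked by descending count.  Never
    applied automatically — hole filling stays an explicit, recorded step.
    """
    s6 = structuring_element(6).astype(np.uint8)
    s6[1, 1, 1] = 0
    counts = ndimage.convolve(grid.data.astype(np.uint8), s6, mode="constant")
    mask = (~grid.data) & (counts >= min_object_face_neighbors)
    cands = [(tuple(i), int(counts[tuple(i)])) for i in np.argwhere(mask)]
    cands.sort(key=lambda t: (-t[1], t[0]))
    return cands


def fill_internal(grid: VoxelGrid) -> VoxelGrid:
    """Fill every void not 6-connected to the external void.

    The grid's one-cell void padding guarantees the external void exists and
    is reachable from any boundary cell.  After filling, the void is a
    single 6-connected component and the object has no cavities.
    """
    void = ~grid.data
    labels, _ = ndimage.label(void, structure=structuring_element(6))
    external = set()
    for sl in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
               labels[:, :, 0], labels[:, :, -1]):
        external |= set(np.unique(sl))
    external.discard(0)
    keep_void = np.isin(labels, sorted(external))
    return grid.with_data(~keep_void)
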