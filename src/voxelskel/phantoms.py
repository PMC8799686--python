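"""Synthetic voxel phantoms with known ground truth.

Every downstream stage of the pipeline is testable without survey data by
generating tubular objects on the lattice: straight cylinders, elliptical
tubes (constant elliptical ratio a/b), tori (one anastomotic loop) and
Y-junctions (one branching point).  Each phantom carries its ground-truth
centerline, per-centerline-point radius profile ``(a, b)`` in voxel widths,
and Betti triple ``(b0, b1, b2)``.

``sample_surface_cloud`` emulates what photogrammetry sees: points drawn on
the exposed boundary faces of the occupancy, optionally jittered with
i.i.d. Gaussian noise whose standard deviation is a multiple of the voxel
size, with optional spherical-cap holes (occlusion gaps) cut out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cloud_io import PointCloud
from .errors import EmptyInputError, InvalidParameterError
from .voxel_grid import OFFSETS_6, VoxelGrid

__all__ = [
    "VoxelPhantom",
    "SamplingSpec",
    "make_cylinder",
    "make_elliptical_tube",
    "make_torus",
    "make_y_junction",
    "sample_surface_cloud",
    "grid_from_phantom",
    "save_phantom",
    "load_phantom",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class VoxelPhantom:
    """Synthetic lattice object with ground truth.

    ``centerline`` is a list of ordered chains of real-valued lattice points
    (one chain per axis segment; a torus has a single closed chain).
    ``radius_profile`` holds one ``(a, b)`` pair per centerline point, major
    axis first, in voxel widths.  ``betti`` is ``(b0, b1, b2)``.
    """

    occupancy: set[tuple[int, int, int]]
    voxel_size: float
    centerline: list[np.ndarray]
    radius_profile: list[np.ndarray]
    betti: tuple[int, int, int]
    name: str = "phantom"

    def __post_init__(self) -> None:
        if not self.occupancy:
            raise InvalidParameterError("phantom occupancy is empty")
        if self.voxel_size <= 0:
            raise InvalidParameterError("voxel_size must be positive")
        if any(b < 0 for b in self.betti):
            raise InvalidParameterError("betti numbers must be >= 0")
        for prof in self.radius_profile:
            p = np.asarray(prof, dtype=float).reshape(-1, 2)
            if np.any(p[:, 0] < p[:, 1]) or np.any(p[:, 1] <= 0):
                raise InvalidParameterError("radius profile requires a >= b > 0")

    @property
    def elliptical_ratio(self) -> float:
        """Ground-truth elliptical ratio a/b (mean over the profile)."""
        pairs = np.concatenate([np.asarray(p).reshape(-1, 2) for p in self.radius_profile])
        return float(np.mean(pairs[:, 0] / pairs[:, 1]))

    def centerline_points(self) -> np.ndarray:
        return np.concatenate([np.asarray(c).reshape(-1, 3) for c in self.centerline])


@dataclass
class SamplingSpec:
    """How to sample a surface cloud from a phantom.

    ``points_per_unit_area`` is the expected number of points per exposed
    voxel face (face area = voxel_size**2).  ``noise_sigma_ratio`` scales the
    per-coordinate Gaussian jitter by the voxel size.  ``skin_ratio`` gives
    the surface a physical thickness: each point is offset along the face
    normal by Uniform(-skin, +skin) voxel widths, emulating the sub-voxel
    spread (bark roughness, reconstruction error) of real survey clouds;
    points stay within half a voxel diagonal of the boundary.  ``hole_specs``
    is a list of ``(direction, angular_radius_deg)`` spherical-cap cutouts
    about the phantom centroid.
    """

    points_per_unit_area: float = 24.0
    noise_sigma_ratio: float = 0.0
    skin_ratio: float = 0.5
    hole_specs: list[tuple[Sequence[float], float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.points_per_unit_area <= 0:
            raise InvalidParameterError("density must be positive")
        if self.noise_sigma_ratio < 0:
            raise InvalidParameterError("noise_sigma_ratio must be >= 0")
        if not (0 <= self.skin_ratio <= 0.5):
            raise InvalidParameterError("skin_ratio must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _permute(idx: tuple[int, int, int], axis: str) -> tuple[int, int, int]:
    """Map a z-axis construction to the requested axis."""
    a = _AXES[axis]
    if a == 2:
        return idx
    if a == 0:  # z -> x
        return (idx[2], idx[0], idx[1])
    return (idx[1], idx[2], idx[0])  # z -> y


def make_cylinder(radius: float, length: int, axis: str = "z",
                  voxel_size: float = 1.0) -> VoxelPhantom:
    """Solid circular tube: cells whose centers lie within ``radius`` of the axis."""
    if radius <= 0 or length < 1:
        raise InvalidParameterError("radius must be > 0 and length >= 1")
    if axis not in _AXES:
        raise InvalidParameterError("axis must be one of x, y, z")
    rr = int(math.floor(radius))
    occ = set()
    for dx in range(-rr, rr + 1):
        for dy in range(-rr, rr + 1):
            if dx * dx + dy * dy <= radius * radius:
                for z in range(length):
                    occ.add(_permute((dx, dy, z), axis))
    chain = np.array([_permute((0, 0, z), axis) for z in range(length)], dtype=float)
    prof = np.tile((max(radius, 0.5), max(radius, 0.5)), (length, 1))
    return VoxelPhantom(occ, voxel_size, [chain], [prof], (1, 0, 0),
                        name=f"cylinder_r{radius}_l{length}_{axis}")


def make_elliptical_tube(a: float, b: float, length: int, axis: str = "z",
                         voxel_size: float = 1.0) -> VoxelPhantom:
    """Solid tube with elliptical cross-section (x/a)^2 + (y/b)^2 <= 1."""
    if b < 1 or a < b:
        raise InvalidParameterError("require a >= b >= 1")
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    if axis not in _AXES:
        raise InvalidParameterError("axis must be one of x, y, z")
    occ = set()
    for dx in range(-int(a), int(a) + 1):
        for dy in range(-int(b), int(b) + 1):
            if (dx / a) ** 2 + (dy / b) ** 2 <= 1.0:
                for z in range(length):
                    occ.add(_permute((dx, dy, z), axis))
    chain = np.array([_permute((0, 0, z), axis) for z in range(length)], dtype=float)
    prof = np.tile((a, b), (length, 1))
    return VoxelPhantom(occ, voxel_size, [chain], [prof], (1, 0, 0),
                        name=f"ellip_a{a}_b{b}_l{length}_{axis}")


def make_torus(major_radius: float, minor_radius: float, plane: str = "xy",
               voxel_size: float = 1.0) -> VoxelPhantom:
    """Solid torus: one component, one loop, no cavity; centerline is the closed ring."""
    if minor_radius < 1:
        raise InvalidParameterError("minor_radius must be >= 1")
    if major_radius <= minor_radius:
        raise InvalidParameterError("major_radius must exceed minor_radius (tube overlap)")
    if plane not in ("xy", "xz", "yz"):
        raise InvalidParameterError("plane must be xy, xz or yz")
    normal = {"xy": "z", "xz": "y", "yz": "x"}[plane]
    ext = int(math.ceil(major_radius + minor_radius)) + 1
    zext = int(math.ceil(minor_radius)) + 1
    occ = set()
    for x in range(-ext, ext + 1):
        for y in range(-ext, ext + 1):
            rho = math.hypot(x, y)
            d2 = (rho - major_radius) ** 2
            for z in range(-zext, zext + 1):
                if d2 + z * z <= minor_radius ** 2:
                    occ.add(_permute((x, y, z), normal))
    n_steps = max(16, int(math.ceil(2 * math.pi * major_radius)))
    ring = np.array(
        [
            _permute(
                (major_radius * math.cos(t), major_radius * math.sin(t), 0.0), normal
            )
            for t in np.linspace(0, 2 * math.pi, n_steps, endpoint=False)
        ],
        dtype=float,
    )
    prof = np.tile((minor_radius, minor_radius), (len(ring), 1))
    return VoxelPhantom(occ, voxel_size, [ring], [prof], (1, 1, 0),
                        name=f"torus_R{major_radius}_r{minor_radius}_{plane}")


def make_y_junction(trunk_radius: float, branch_radius: float,
                    angles: tuple[float, float] = (35.0, 35.0),
                    trunk_length: int = 12, branch_length: int = 12,
                    voxel_size: float = 1.0) -> VoxelPhantom:
    """Vertical trunk splitting into two straight branches in the x-z plane.

    ``angles`` are the branch inclinations from the vertical, in degrees,
    each in (0, 90].  The single ground-truth junction point is the trunk
    top; the phantom has three curve ends (trunk base and two branch tips).
    """
    if trunk_radius < 1 or branch_radius < 1:
        raise InvalidParameterError("radii must be >= 1")
    for ang in angles:
        if not (0.0 < ang <= 90.0):
            raise InvalidParameterError("branch angles must lie in (0, 90] degrees")
    j = np.array([0.0, 0.0, float(trunk_length)])
    dirs = [
        np.array([math.sin(math.radians(angles[0])), 0.0, math.cos(math.radians(angles[0]))]),
        np.array([-math.sin(math.radians(angles[1])), 0.0, math.cos(math.radians(angles[1]))]),
    ]
    tips = [j + d * branch_length for d in dirs]
    # branches must separate beyond the junction region, else the phantom has
    # no meaningful branching point
    sep = np.linalg.norm(tips[0] - tips[1])
    if sep <= 2 * branch_radius:
        raise InvalidParameterError("branch angles too shallow: branches overlap beyond junction")
    segs = [
        (np.array([0.0, 0.0, 0.0]), j, trunk_radius),
        (j, tips[0], branch_radius),
        (j, tips[1], branch_radius),
    ]
    occ = set()
    for p0, p1, r in segs:
        v = p1 - p0
        vv = float(v @ v)
        lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    p = np.array((x, y, z), dtype=float)
                    t = min(max(float((p - p0) @ v) / vv, 0.0), 1.0)
                    if float(np.sum((p - p0 - t * v) ** 2)) <= r * r:
                        occ.add((x, y, z))
    chains = []
    profs = []
    n = trunk_length + 1
    trunk_chain = np.stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)], axis=1)
    chains.append(trunk_chain)
    profs.append(np.tile((trunk_radius, trunk_radius), (n, 1)))
    for d in dirs:
        ts = np.arange(0.0, branch_length + 0.5)
        chain = j[None, :] + ts[:, None] * d[None, :]
        chains.append(chain)
        profs.append(np.tile((branch_radius, branch_radius), (len(chain), 1)))
    ph = VoxelPhantom(occ, voxel_size, chains, profs, (1, 0, 0),
                      name=f"yjunction_rt{trunk_radius}_rb{branch_radius}")
    ph.junction = j  # ground-truth junction point (lattice coordinates)
    return ph


# ---------------------------------------------------------------------------
# sampling and conversion
# ---------------------------------------------------------------------------

def grid_from_phantom(phantom: VoxelPhantom, pad: int = 2) -> VoxelGrid:
    """Phantom occupancy as a padded :class:`VoxelGrid` (origin at index frame)."""
    return VoxelGrid.from_occupancy(
        phantom.occupancy, voxel_size=phantom.voxel_size, pad=pad
    )


def exposed_faces(occupancy: set[tuple[int, int, int]]) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """(cell, outward face direction) pairs for all boundary faces."""
    out = []
    for c in sorted(occupancy):
        for d in OFFSETS_6:
            n = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if n not in occupancy:
                out.append((c, d))
    return out


def sample_surface_cloud(phantom: VoxelPhantom, spec: SamplingSpec) -> PointCloud:
    """Sample points on the phantom's exposed surface.

    Points are drawn uniformly per exposed face (Poisson counts with mean
    ``points_per_unit_area``), nudged a hair inside the owning cell so a
    noise-free cloud voxelizes exactly onto the boundary cells, then jittered
    with i.i.d. Gaussian noise of standard deviation
    ``noise_sigma_ratio * voxel_size`` per coordinate.  Points falling inside
    any spherical-cap hole are removed.  Deterministic for a fixed seed.
    """
    if not phantom.occupancy:
        raise EmptyInputError("phantom has no occupancy")
    rng = np.random.default_rng(spec.seed)
    vs = phantom.voxel_size
    faces = exposed_faces(phantom.occupancy)
    if spec.points_per_unit_area * len(faces) < len(faces):
        import warnings

        warnings.warn("sampling density below one point per face; surface cover incomplete",
                      stacklevel=2)
    counts = rng.poisson(spec.points_per_unit_area, size=len(faces))
    eps = 1e-6
    pts = []
    for (cell, d), k in zip(faces, counts):
        if k == 0:
            continue
        u = rng.random((k, 2))
        base = np.asarray(cell, dtype=float)
        p = np.empty((k, 3))
        free_axes = [a for a in range(3) if d[a] == 0]
        fixed_axis = [a for a in range(3) if d[a] != 0][0]
        p[:, free_axes[0]] = base[free_axes[0]] + u[:, 0]
        p[:, free_axes[1]] = base[free_axes[1]] + u[:, 1]
        # face plane (nudged a hair inside so the zero-skin case is exact),
        # plus the surface-skin offset along the outward normal
        face_coord = base[fixed_axis] + (1.0 - eps if d[fixed_axis] > 0 else eps)
        if spec.skin_ratio > 0:
            offset = rng.uniform(-spec.skin_ratio, spec.skin_ratio, size=k)
            face_coord = face_coord + offset * d[fixed_axis]
        p[:, fixed_axis] = face_coord
        pts.append(p)
    if not pts:
        raise EmptyInputError("no surface points sampled")
    pts_arr = np.concatenate(pts) * vs
    if spec.noise_sigma_ratio > 0:
        pts_arr = pts_arr + rng.normal(0.0, spec.noise_sigma_ratio * vs, pts_arr.shape)
    if spec.hole_specs:
        centroid = np.array(sorted(phantom.occupancy), dtype=float).mean(axis=0)
        centroid = (centroid + 0.5) * vs
        keep = np.ones(len(pts_arr), dtype=bool)
        for direction, ang_deg in spec.hole_specs:
            dvec = np.asarray(direction, dtype=float)
            dvec = dvec / np.linalg.norm(dvec)
            rel = pts_arr - centroid
            norm = np.linalg.norm(rel, axis=1)
            with np.errstate(invalid="ignore"):
                cosang = np.where(norm > 0, rel @ dvec / np.maximum(norm, 1e-30), 1.0)
            keep &= cosang < math.cos(math.radians(ang_deg))
        pts_arr = pts_arr[keep]
        if len(pts_arr) == 0:
            raise EmptyInputError("hole specs removed every sampled point")
    return PointCloud(pts_arr, label=phantom.name)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Columnar occupancy text plus JSON sidecar with the ground truth."""
    path = Path(path)
    occ = np.array(sorted(phantom.occupancy), dtype=int)
    np.savetxt(path, occ, fmt="%d")
    sidecar = {
        "voxel_size": phantom.voxel_size,
        "betti": list(phantom.betti),
        "name": phantom.name,
        "centerline": [np.asarray(c).tolist() for c in phantom.centerline],
        "radius_profile": [np.asarray(p).tolist() for p in phantom.radius_profile],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_phantom(path: str | Path) -> VoxelPhantom:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    occ = np.loadtxt(path, dtype=int, ndmin=2)
    return VoxelPhantom(
        set(map(tuple, occ)),
        meta["voxel_size"],
        [np.array(c, dtype=float) for c in meta["centerline"]],
        [np.array(p, dtype=float) for p in meta["radius_profile"]],
        tuple(meta["betti"]),
        name=meta.get("name", path.stem),
    )
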