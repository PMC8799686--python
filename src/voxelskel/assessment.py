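"""Skeleton quality assessment.

Seven characteristics are measured: homotopy (Betti triple preservation),
thinness, centeredness, volume reconstructibility, scalability, sample
robustness to noise, and rotational invariance.

Topology is summarised by the Betti triple (b0, b1, b2): 26-connected
object components, independent loops, and cavities (6-connected void
components not reaching the boundary).  b1 is derived from the Euler
characteristic of the cubical complex, chi = V - E + F - C, via
b1 = b0 + b2 - chi — exact and cheap, with no explicit loop detection.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .phantoms import SamplingSpec, VoxelPhantom, grid_from_phantom, sample_surface_cloud
from .voxel_grid import VoxelGrid, structuring_element
from .thinning import Skeleton, thin

__all__ = [
    "TopologyReport",
    "CenterednessReport",
    "ReplicationReport",
    "topology_report",
    "euler_characteristic",
    "centeredness",
    "replication_metrics",
    "rotational_invariance",
    "noise_robustness_scan",
    "ScalabilityReport",
]


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyReport:
    b0: int
    b1: int
    b2: int
    euler: int

    @property
    def betti(self) -> tuple[int, int, int]:
        return (self.b0, self.b1, self.b2)


def euler_characteristic(data: np.ndarray) -> int:
    """chi = V - E + F - C of the cubical complex spanned by occupied cells."""
    occ = np.argwhere(data)
    if len(occ) == 0:
        return 0
    corners = np.array([(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    V = len(np.unique((occ[:, None, :] + corners[None]).reshape(-1, 3), axis=0))
    E = 0
    F = 0
    for ax in range(3):
        # edges along ax: identified by their lowest vertex
        e_off = np.array([c for c in corners if c[ax] == 0])
        arr = (occ[:, None, :] + e_off[None]).reshape(-1, 3)
        E += len(np.unique(arr, axis=0))
        # faces normal to ax: identified by their lowest vertex
        f_off = np.array([c for c in corners
                          if all(c[a] == 0 for a in range(3) if a != ax)])
        arr = (occ[:, None, :] + f_off[None]).reshape(-1, 3)
        F += len(np.unique(arr, axis=0))
    return int(V - E + F - len(occ))


def topology_report(grid: VoxelGrid) -> TopologyReport:
    """Exact Betti triple via component labelling + cubical Euler characteristic."""
    data = grid.data
    _, b0 = ndimage.label(data, structure=structuring_element(26))
    labels, n_void = ndimage.label(~data, structure=structuring_element(6))
    border = set()
    for sl in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
               labels[:, :, 0], labels[:, :, -1]):
        border |= set(np.unique(sl))
    border.discard(0)
    b2 = n_void - len(border)
    chi = euler_characteristic(data)
    b1 = b0 + b2 - chi
    return TopologyReport(int(b0), int(b1), int(b2), chi)


# ---------------------------------------------------------------------------
# centeredness
# ---------------------------------------------------------------------------

@dataclass
class CenterednessReport:
    """Per-voxel deviation from the reference line, binned at 0.5 / 1.5 widths."""

    deviations: np.ndarray
    correct_fraction: float
    acceptable_fraction: float
    poor_fraction: float

    @property
    def within_acceptable(self) -> float:
        return self.correct_fraction + self.acceptable_fraction


def centeredness(skeleton: Skeleton, reference: np.ndarray) -> CenterednessReport:
    """Min distance (in voxel widths) of each skeleton voxel to the reference.

    ``reference`` is an (n, 3) array of ground-truth centerline points in
    lattice coordinates (synthetic mode) or section centroids.  Bins:
    correct <= 0.5, acceptable <= 1.5, poor beyond.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if len(ref) == 0:
        raise InvalidParameterError("reference is empty")
    if len(skeleton) == 0:
        return CenterednessReport(np.empty(0), 0.0, 0.0, 0.0)
    # skeleton indices are offset by the grid padding; both skeleton and
    # reference must be in the same lattice frame (the caller aligns them)
    pts = np.array(skeleton.indices, dtype=float)
    d = np.min(np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=2), axis=1)
    correct = float(np.mean(d <= 0.5))
    acceptable = float(np.mean((d > 0.5) & (d <= 1.5)))
    poor = float(np.mean(d > 1.5))
    return CenterednessReport(d, correct, acceptable, poor)


# ---------------------------------------------------------------------------
# volume reconstructibility
# ---------------------------------------------------------------------------

@dataclass
class ReplicationReport:
    """Replication of the original object by a reconstruction.

    ``replicated_fraction``: share of original object voxels present in the
    reconstruction.  ``correct_fraction``: share of reconstructed voxels
    present in the original.
    """

    replicated_fraction: float
    correct_fraction: float
    n_original: int
    n_reconstructed: int
    n_common: int

    def labelling(self, original: VoxelGrid, reconstruction: VoxelGrid) -> dict[str, np.ndarray]:
        """Three-way voxel classes: common / missing (original only) / redundant."""
        common = original.data & reconstruction.data
        missing = original.data & ~reconstruction.data
        redundant = reconstruction.data & ~original.data
        return {"common": np.argwhere(common),
                "missing": np.argwhere(missing),
                "redundant": np.argwhere(redundant)}


def replication_metrics(original: VoxelGrid, reconstruction: VoxelGrid) -> ReplicationReport:
    if original.dims != reconstruction.dims or not np.isclose(
        original.voxel_size, reconstruction.voxel_size
    ):
        raise InvalidParameterError("grids must share dims and voxel_size")
    n_orig = original.count
    n_rec = reconstruction.count
    n_common = int((original.data & reconstruction.data).sum())
    return ReplicationReport(
        replicated_fraction=n_common / n_orig if n_orig else 0.0,
        correct_fraction=n_common / n_rec if n_rec else 0.0,
        n_original=n_orig,
        n_reconstructed=n_rec,
        n_common=n_common,
    )


# ---------------------------------------------------------------------------
# rotational invariance
# ---------------------------------------------------------------------------

_AXIS_TO_PLANES = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}


def rotational_invariance(grid: VoxelGrid, axis: str = "z") -> dict:
    """Thin the grid and its 90-degree rotation; compare the skeletons.

    Returns the shared-voxel (overlap) fraction after rotating the second
    skeleton back, the maximum nearest-voxel deviation in voxel widths, and
    whether the two runs preserve identical topology reports.
    """
    if axis not in _AXIS_TO_PLANES:
        raise InvalidParameterError("axis must be x, y or z")
    a, b = _AXIS_TO_PLANES[axis]
    sk1 = thin(grid)
    rot_data = np.rot90(grid.data, k=1, axes=(a, b)).copy()
    rot = VoxelGrid(rot_data.shape, grid.origin.copy(), grid.voxel_size, rot_data)
    sk2 = thin(rot)
    back = np.rot90(sk2.as_grid().data, k=-1, axes=(a, b))
    s1 = sk1.as_grid().data
    inter = int((s1 & back).sum())
    union_max = max(int(s1.sum()), int(back.sum()))
    overlap = inter / union_max if union_max else 1.0
    p1 = np.argwhere(s1)
    p2 = np.argwhere(back)
    if len(p1) and len(p2):
        d12 = np.sqrt(((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2))
        max_dev = float(max(d12.min(axis=1).max(), d12.min(axis=0).max()))
    else:
        max_dev = float("inf")
    t_in = topology_report(grid)
    t1 = topology_report(sk1.as_grid())
    t2 = topology_report(sk2.as_grid())
    return {
        "overlap_fraction": overlap,
        "max_deviation": max_dev,
        "topology_input": t_in,
        "topology_skeleton": t1,
        "topology_rotated": t2,
        "topology_invariant": t1 == t2 == t_in,
    }


# ---------------------------------------------------------------------------
# sample robustness
# ---------------------------------------------------------------------------

def _pipeline_betti(phantom: VoxelPhantom, sigma_ratio: float, seed: int,
                    density: float = 24.0) -> tuple[int, int, int]:
    """Sample -> voxelize -> denoise -> fill -> thin; Betti of the skeleton."""
    from .morphology import denoise, fill_internal
    from .voxel_grid import voxelize

    spec = SamplingSpec(points_per_unit_area=density,
                        noise_sigma_ratio=sigma_ratio, seed=seed)
    cloud = sample_surface_cloud(phantom, spec)
    grid = voxelize(cloud, voxel_size=phantom.voxel_size)
    grid, _ = denoise(grid, keep_first=True)
    grid = fill_internal(grid)
    sk = thin(grid, record_exposure=False)
    return topology_report(sk.as_grid()).betti


def noise_robustness_scan(
    phantom: VoxelPhantom,
    sigma_ratios: list[float],
    trials: int = 10,
    seed: int = 0,
    density: float = 24.0,
) -> dict:
    """Topology-failure rate of the full pipeline per noise level.

    Failure means the skeleton's Betti triple differs from the noise-free
    skeleton's.  Returns per-sigma rates and the smallest sigma whose
    failure rate exceeds 0.5 (None if none does).
    """
    if sorted(sigma_ratios) != list(sigma_ratios):
        raise InvalidParameterError("sigma_ratios must be sorted ascending")
    if trials < 1:
        raise InvalidParameterError("trials must be >= 1")
    reference = _pipeline_betti(phantom, 0.0, seed, density)
    rates = []
    for s_i, sigma in enumerate(sigma_ratios):
        fails = 0
        for t in range(trials):
            b = _pipeline_betti(phantom, sigma, seed + 1000 * s_i + t, density)
            if b != reference:
                fails += 1
        rates.append(fails / trials)
    first_failure = None
    for sigma, rate in zip(sigma_ratios, rates):
        if rate > 0.5:
            first_failure = sigma
            break
    return {
        "sigma_ratios": list(sigma_ratios),
        "failure_rates": rates,
        "first_failure_sigma": first_failure,
        "reference_betti": reference,
    }


# ---------------------------------------------------------------------------
# scalability
# ---------------------------------------------------------------------------

@dataclass
class ScalabilityReport:
    """Per-step wall times and data sizes; reported, never asserted."""

    step_seconds: dict[str, float] = field(default_factory=dict)
    step_counts: dict[str, int] = field(default_factory=dict)
    input_bytes: int = 0
    output_bytes: int = 0

    @property
    def reduction_percentage(self) -> float:
        if self.input_bytes == 0:
            return float("nan")
        return 100.0 * self.output_bytes / self.input_bytes

    def time(self, step: str):
        report = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                report.step_seconds[step] = report.step_seconds.get(step, 0.0) + (
                    time.perf_counter() - self.t0
                )
                return False

        return _Timer()
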