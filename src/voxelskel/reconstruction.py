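"""Iteration-of-exposure volume reconstruction (step 9).

During thinning, a voxel's nth face becomes void-adjacent at cycle I_n;
because one cycle erodes roughly one shell, I_n is a proxy for the local
radius.  Circular mode (9a) builds a filled disk of radius
``radius_scale * I_n`` voxel widths in the horizontal (xy) plane around
each skeleton voxel.  Elliptical mode (9b) predicts the elliptical ratio
ER (major/minor axis) from the ratio I4:I1 via a linear model fitted on
samples with known ER, then builds in-plane ellipses: for n in {1, 2}
(early exposures track the minor axis) the minor semi-axis is
``radius_scale * I_n`` and the major is ER times that; for n in {3, 4} the
major semi-axis is ``radius_scale * I_n`` and the minor is that divided
by ER.

The major-axis direction is the in-plane cardinal direction whose opposing
faces were exposed latest; ties resolve toward x.  Cross-sections are
built in the global xy plane stepped along z, mirroring the thinning
critique that reconstruction is in-plane while thinning is 3D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ContractViolation, InvalidParameterError
from .thinning import Skeleton
from .voxel_grid import VoxelGrid

__all__ = [
    "EllipseRatioModel",
    "ReconstructionResult",
    "reconstruct_circular",
    "reconstruct_elliptical",
    "fit_ellipse_ratio_model",
    "PREDICTORS",
]

PREDICTORS = ("I2:I1", "I3:I1", "I4:I1", "mean:I1")


@dataclass
class EllipseRatioModel:
    """Linear map from an exposure ratio to the elliptical ratio ER.

    ``predictor`` names which ratio the model maps (one of
    ``I2:I1``, ``I3:I1``, ``I4:I1`` or ``mean:I1`` where mean is
    (I2+I3+I4)/3).  Predictions are clamped to [1, er_max].
    """

    slope: float
    intercept: float
    r_squared: float
    predictor: str = "I4:I1"
    er_max: float = 6.0
    candidate_r2: dict[str, float] = field(default_factory=dict)

    def predict(self, ratio: float) -> float:
        er = self.slope * ratio + self.intercept
        return float(min(max(er, 1.0), self.er_max))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "predictor": self.predictor,
            "er_max": self.er_max, "candidate_r2": self.candidate_r2,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EllipseRatioModel":
        doc = json.loads(Path(path).read_text())
        return cls(doc["slope"], doc["intercept"], doc["r_squared"],
                   doc.get("predictor", "I4:I1"), doc.get("er_max", 6.0),
                   doc.get("candidate_r2", {}))


@dataclass
class ReconstructionResult:
    """Rebuilt occupancy plus the settings that produced it."""

    grid: VoxelGrid
    mode: str
    exposure_index_used: int
    radius_scale: float
    circular_fallbacks: int = 0


def _ratio(I: tuple[int, int, int, int], predictor: str) -> float | None:
    i1 = I[0]
    if i1 <= 0:
        return None
    if predictor == "I2:I1":
        return I[1] / i1
    if predictor == "I3:I1":
        return I[2] / i1
    if predictor == "I4:I1":
        return I[3] / i1
    if predictor == "mean:I1":
        return (I[1] + I[2] + I[3]) / 3.0 / i1
    raise InvalidParameterError(f"unknown predictor {predictor}")


def reconstruct_circular(skeleton: Skeleton, n: int = 2,
                         radius_scale: float = 1.0) -> ReconstructionResult:
    """Circular cross-sections of radius ``radius_scale * I_n`` per voxel.

    The skeleton voxel itself is always occupied, so I_n = 0 reconstructs
    the skeleton as a one-voxel tube.
    """
    if n not in (1, 2, 3, 4):
        raise InvalidParameterError("exposure index n must be in 1..4")
    if radius_scale <= 0:
        raise InvalidParameterError("radius_scale must be positive")
    data = np.zeros(skeleton.dims, dtype=bool)
    for v in skeleton.voxels:
        r = radius_scale * v.exposure[n - 1]
        _fill_ellipse(data, v.index, r, r)
    grid = VoxelGrid(skeleton.dims, skeleton.origin.copy(), skeleton.voxel_size, data)
    return ReconstructionResult(grid, "circular", n, radius_scale)


def reconstruct_elliptical(skeleton: Skeleton, model: EllipseRatioModel,
                           n: int = 1, radius_scale: float = 1.0) -> ReconstructionResult:
    """Elliptical cross-sections using the fitted ER model.

    Voxels with I1 = 0 have an undefined ratio and fall back to a circular
    section of radius ``radius_scale * I_n`` (counted in the result).
    """
    if n not in (1, 2, 3, 4):
        raise InvalidParameterError("exposure index n must be in 1..4")
    if radius_scale <= 0:
        raise InvalidParameterError("radius_scale must be positive")
    data = np.zeros(skeleton.dims, dtype=bool)
    fallbacks = 0
    for v in skeleton.voxels:
        In = v.exposure[n - 1]
        ratio = _ratio(v.exposure, model.predictor)
        if ratio is None:
            fallbacks += 1
            _fill_ellipse(data, v.index, radius_scale * In, radius_scale * In)
            continue
        er = model.predict(ratio)
        if n in (1, 2):
            minor = radius_scale * In
            major = er * minor
        else:
            major = radius_scale * In
            minor = major / er
        if _major_axis_is_x(v):
            _fill_ellipse(data, v.index, major, minor)
        else:
            _fill_ellipse(data, v.index, minor, major)
    grid = VoxelGrid(skeleton.dims, skeleton.origin.copy(), skeleton.voxel_size, data)
    return ReconstructionResult(grid, "elliptical", n, radius_scale, fallbacks)


def _major_axis_is_x(v) -> bool:
    """Major axis = in-plane direction whose opposing faces exposed latest."""
    fe = v.face_exposure
    ex = max(fe.get((1, 0, 0), 0), fe.get((-1, 0, 0), 0))
    ey = max(fe.get((0, 1, 0), 0), fe.get((0, -1, 0), 0))
    return ex >= ey


def _fill_ellipse(data: np.ndarray, idx, semi_x: float, semi_y: float) -> None:
    """Mark the in-plane filled ellipse around idx; the center cell always."""
    i0, j0, k0 = idx
    data[i0, j0, k0] = True
    if semi_x <= 0 or semi_y <= 0:
        return
    ri = int(np.floor(semi_x))
    rj = int(np.floor(semi_y))
    for di in range(-ri, ri + 1):
        for dj in range(-rj, rj + 1):
            if (di / semi_x) ** 2 + (dj / semi_y) ** 2 <= 1.0:
                i, j = i0 + di, j0 + dj
                if 0 <= i < data.shape[0] and 0 <= j < data.shape[1]:
                    data[i, j, k0] = True


def fit_ellipse_ratio_model(
    samples: list[tuple[tuple[int, int, int, int], float]],
    predictor_choice: str = "I4:I1",
    er_max: float = 6.0,
) -> EllipseRatioModel:
    """OLS fit of true ER on the chosen exposure ratio.

    ``samples`` holds ``((I1, I2, I3, I4), true_ER)`` pairs with I1 > 0.
    The model for the chosen predictor is returned, together with R^2 for
    every candidate predictor so the best can be selected the way the
    workflow does.
    """
    if predictor_choice not in PREDICTORS:
        raise InvalidParameterError(f"predictor must be one of {PREDICTORS}")
    if len(samples) < 3:
        raise InvalidParameterError("need at least 3 samples")
    for I, _ in samples:
        if I[0] <= 0:
            raise InvalidParameterError("all samples must have I1 > 0")
    ers = np.array([er for _, er in samples], dtype=float)
    candidate_r2: dict[str, float] = {}
    fits: dict[str, tuple[float, float, float]] = {}
    for pred in PREDICTORS:
        ratios = np.array([_ratio(I, pred) for I, _ in samples], dtype=float)
        if np.ptp(ratios) == 0:
            if pred == predictor_choice:
                raise ContractViolation(
                    f"predictor {pred} has zero variance; degenerate fit"
                )
            candidate_r2[pred] = float("nan")
            continue
        res = stats.linregress(ratios, ers)
        candidate_r2[pred] = float(res.rvalue ** 2)
        fits[pred] = (float(res.slope), float(res.intercept), float(res.rvalue ** 2))
    slope, intercept, r2 = fits[predictor_choice]
    return EllipseRatioModel(slope, intercept, r2, predictor_choice, er_max,
                             candidate_r2)
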