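"""Point-cloud I/O and rigid pre-processing (orientation, scaling).

Supported formats: whitespace-delimited XYZ, PLY (ASCII and binary little
endian) and PCD v0.7 (ASCII).  The format is sniffed from the file extension
unless given explicitly.

``orient_by_pca`` implements the workflow's first step: the cloud is
translated to its centroid and rotated so its longest principal axis lies
along +z, which minimises the void voxel space of the subsequent
voxelization.  The transform is a proper rigid rotation; pairwise distances
are preserved to floating-point accuracy.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, EmptyInputError, InvalidParameterError, ParseError

__all__ = ["PointCloud", "read_cloud", "write_cloud", "orient_by_pca", "apply_scale"]


@dataclass
class PointCloud:
    """World-coordinate 3D points (metres) with optional colour and label."""

    points: np.ndarray
    colors: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise InvalidParameterError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if len(self.colors) != len(self.points):
                raise InvalidParameterError("colors must match points in length")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = path.suffix.lstrip(".").lower() or "xyz"
    if f not in ("xyz", "ply", "pcd", "txt"):
        raise InvalidParameterError(f"unsupported cloud format: {f}")
    return "xyz" if f == "txt" else f


def read_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud; raises :class:`ParseError` naming the bad line."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "xyz":
        cloud = _read_xyz(path)
    elif fmt == "ply":
        cloud = _read_ply(path)
    else:
        cloud = _read_pcd(path)
    if len(cloud) == 0:
        raise EmptyInputError(f"{path}: cloud contains no points")
    cloud.label = path.stem
    return cloud


def write_cloud(cloud: PointCloud, path: str | Path, format: str | None = None,
                binary: bool = False) -> None:
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.9g")
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        _write_pcd(cloud, path)


def _read_xyz(path: Path) -> PointCloud:
    pts = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 columns")
            try:
                pts.append([float(v) for v in parts[:3]])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
    return PointCloud(np.array(pts).reshape(-1, 3))


_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4), "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "int16": ("h", 2), "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: missing 'ply' magic")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            raw = fh.readline()
            if not raw:
                raise ParseError(f"{path}: header not terminated")
            line = raw.decode("ascii", "replace").strip()
            if line.startswith("comment"):
                continue
            if line.startswith("format"):
                fmt = line.split()[1]
            elif line.startswith("element"):
                _, name, cnt = line.split()
                in_vertex = name == "vertex"
                if in_vertex:
                    n_vertex = int(cnt)
            elif line.startswith("property") and in_vertex:
                parts = line.split()
                if parts[1] == "list":
                    raise ParseError(f"{path}: list property on vertex unsupported")
                props.append((parts[1], parts[2]))
            elif line == "end_header":
                break
        names = [p[1] for p in props]
        for c in ("x", "y", "z"):
            if c not in names:
                raise ParseError(f"{path}: vertex element lacks '{c}' property")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline().decode("ascii", "replace").split()
                if len(line) < len(props):
                    raise ParseError(f"{path}: vertex row {i} truncated")
                rows.append([float(v) for v in line[: len(props)]])
            arr = np.array(rows).reshape(-1, len(props))
        elif fmt == "binary_little_endian":
            fmt_str = "<" + "".join(_PLY_TYPES[t][0] for t, _ in props)
            size = struct.calcsize(fmt_str)
            buf = fh.read(size * n_vertex)
            if len(buf) < size * n_vertex:
                raise ParseError(f"{path}: binary payload truncated at byte {len(buf)}")
            arr = np.array(
                [struct.unpack_from(fmt_str, buf, i * size) for i in range(n_vertex)],
                dtype=float,
            ).reshape(-1, len(props))
        else:
            raise ParseError(f"{path}: unsupported PLY format '{fmt}'")
        ix, iy, iz = (names.index(c) for c in ("x", "y", "z"))
        pts = arr[:, [ix, iy, iz]]
        colors = None
        if all(c in names for c in ("red", "green", "blue")):
            colors = arr[:, [names.index(c) for c in ("red", "green", "blue")]].astype(np.uint8)
        return PointCloud(pts, colors)


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    has_color = cloud.colors is not None
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += [f"property float {c}" for c in "xyz"]
    if has_color:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header.append("end_header")
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            pts = cloud.points.astype("<f4")
            if has_color:
                cols = np.asarray(cloud.colors, dtype=np.uint8)
                for p, c in zip(pts, cols):
                    fh.write(struct.pack("<fffBBB", *p, *c))
            else:
                fh.write(pts.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            if has_color:
                cols = np.asarray(cloud.colors, dtype=np.uint8)
                for p, c in zip(cloud.points, cols):
                    fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {c[0]} {c[1]} {c[2]}\n")
            else:
                for p in cloud.points:
                    fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def _read_pcd(path: Path) -> PointCloud:
    fields: list[str] = []
    n_points = 0
    data_mode = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key = line.split()[0].upper()
            if data_mode is None:
                if key == "FIELDS":
                    fields = line.split()[1:]
                elif key == "POINTS":
                    n_points = int(line.split()[1])
                elif key == "DATA":
                    data_mode = line.split()[1]
                    if data_mode != "ascii":
                        raise ParseError(f"{path}:{ln}: only ascii PCD supported")
                continue
            parts = line.split()
            try:
                rows.append([float(v) for v in parts])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
    if data_mode is None:
        raise ParseError(f"{path}: missing DATA line")
    if len(rows) != n_points:
        raise ParseError(f"{path}: POINTS={n_points} but {len(rows)} data rows")
    for c in ("x", "y", "z"):
        if c not in fields:
            raise ParseError(f"{path}: FIELDS lacks '{c}'")
    arr = np.array(rows, dtype=float).reshape(-1, len(fields))
    return PointCloud(arr[:, [fields.index(c) for c in ("x", "y", "z")]])


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
        )
        for p in cloud.points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


# ---------------------------------------------------------------------------
# rigid pre-processing
# ---------------------------------------------------------------------------

def orient_by_pca(cloud: PointCloud) -> PointCloud:
    """Rotate the cloud so its longest principal axis lies along +z.

    Uses centroid-centred PCA.  The rotated cloud is centred at the origin.
    Eigenvector signs are fixed so the oriented cloud has non-negative
    skewness along each axis (ties resolve toward +); the rotation is made
    proper (det = +1) by flipping the x axis if needed.
    """
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points for PCA orientation")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 0 or evals[1] / evals[-1] < 1e-12:
        raise DegenerateGeometryError("degenerate covariance: cloud is collinear or coincident")
    # rows of R: (v_small, v_mid, v_large) so the largest axis maps to +z
    R = evecs.T
    rotated = centred @ R.T
    # sign convention: non-negative third moment along each principal axis
    for a in range(3):
        m3 = np.sum(rotated[:, a] ** 3)
        if m3 < 0:
            R[a] = -R[a]
            rotated[:, a] = -rotated[:, a]
    if np.linalg.det(R) < 0:
        R[0] = -R[0]
        rotated[:, 0] = -rotated[:, 0]
    return PointCloud(rotated, cloud.colors, cloud.label)


def apply_scale(
    cloud: PointCloud,
    reference_length_measured: float,
    reference_length_in_cloud: float,
) -> PointCloud:
    """Uniformly scale the cloud by measured / in-cloud reference length."""
    if reference_length_measured <= 0 or reference_length_in_cloud <= 0:
        raise InvalidParameterError("reference lengths must be positive")
    factor = reference_length_measured / reference_length_in_cloud
    return PointCloud(cloud.points * factor, cloud.colors, cloud.label)
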