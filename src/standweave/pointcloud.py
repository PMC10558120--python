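"""Plot-level point clouds: I/O, cleaning, and voxelization.

A :class:`PointCloud` holds the 3D points of one plot scan together with the
scanner origin (tripod position, 1.3 m above ground in generated data). A
:class:`VoxelGrid` is its occupancy discretization at a fixed cubic voxel
size (5 cm by default), the substrate for the vertical-stratification (ENL)
component of the stand structural complexity index.

Supported on-disk formats are whitespace-delimited XYZ text and vertex-only
binary PLY (double precision, so round-trips are exact).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PointCloud",
    "VoxelGrid",
    "read_cloud",
    "write_cloud",
    "clip_to_plot",
    "remove_soil_layer",
    "voxelize",
    "CloudParseError",
    "EmptyCloudError",
]


class CloudParseError(ValueError):
    """A point-cloud file could not be parsed (reports the offending line)."""


class EmptyCloudError(ValueError):
    """An operation that requires points received an empty cloud."""


@dataclass
class PointCloud:
    """Points of one plot scan, in meters, relative to the plot frame.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of x, y, z coordinates.
    scanner_origin
        Position of the scanner; generated data place it at the plot center
        at a height of 1.3 m.
    plot_id
        Optional plot label carried through the pipeline.
    """

    points: np.ndarray
    scanner_origin: tuple[float, float, float] | None = None
    plot_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0


@dataclass
class VoxelGrid:
    """Occupancy grid of a cloud at cubic ``voxel_size``.

    The grid is anchored at the cloud's minimum corner, with half-open
    voxel intervals ``[min + i*s, min + (i+1)*s)`` on each axis. ``indices``
    holds the unique filled voxel index triples; ``n_total`` is the number
    of voxels in the tight axis-aligned bounding box.
    """

    voxel_size: float
    origin: np.ndarray
    indices: np.ndarray  # (m, 3) int, unique, sorted lexicographically
    shape: tuple[int, int, int]
    counts: np.ndarray = field(default=None)  # points per filled voxel

    @property
    def n_filled(self) -> int:
        return len(self.indices)

    @property
    def n_total(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fill_ratio(self) -> float:
        return self.n_filled / self.n_total


# ---------------------------------------------------------------------------
# I/O

_PLY_HEADER = (
    "ply\nformat binary_little_endian 1.0\n"
    "element vertex {n}\n"
    "property double x\nproperty double y\nproperty double z\n"
    "end_header\n"
)


def write_cloud(cloud: PointCloud, path: str | Path, format: str | None = None) -> Path:
    """Write a cloud as XYZ text or binary PLY (inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.8f")
    else:
        with open(path, "wb") as fh:
            fh.write(_PLY_HEADER.format(n=len(cloud)).encode("ascii"))
            fh.write(np.ascontiguousarray(cloud.points, dtype="<f8").tobytes())
    return path


def read_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read an XYZ or PLY file.

    XYZ lines hold three whitespace-separated floats; ``#`` starts a
    comment. A malformed line raises :class:`CloudParseError` naming the
    line number. An empty file yields an empty cloud with a warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    pts = _read_xyz(path) if fmt == "xyz" else _read_ply(path)
    if len(pts) == 0:
        warnings.warn(f"{path} contains no points", stacklevel=2)
    return PointCloud(points=pts)


def _infer_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"xyz", "ply", "txt"}:
        raise ValueError(f"unsupported point-cloud format: {fmt!r}")
    return "ply" if fmt == "ply" else "xyz"


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) != 3:
                raise CloudParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from None
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline()
            if not line:
                raise CloudParseError(f"{path}: truncated PLY header")
            header.append(line.decode("ascii", "replace").strip())
            if header[-1] == "end_header":
                break
        if not header or header[0] != "ply":
            raise CloudParseError(f"{path}: not a PLY file")
        n = None
        for entry in header:
            if entry.startswith("element vertex"):
                n = int(entry.split()[-1])
        if n is None:
            raise CloudParseError(f"{path}: no vertex element in PLY header")
        if "format binary_little_endian 1.0" not in header:
            raise CloudParseError(f"{path}: only binary_little_endian PLY supported")
        raw = fh.read(n * 24)
        if len(raw) != n * 24:
            raise CloudParseError(f"{path}: truncated PLY payload")
    return np.frombuffer(raw, dtype="<f8").reshape(n, 3).copy()


# ---------------------------------------------------------------------------
# Cleaning

def clip_to_plot(cloud: PointCloud, bounds: tuple[float, float, float, float]) -> PointCloud:
    """Keep points whose (x, y) fall inside a horizontal rectangle.

    ``bounds`` is ``(xmin, ymin, xmax, ymax)``; membership is closed on the
    minimum edges and open on the maximum edges of both axes, so a point
    exactly on the max-x edge is excluded.
    """
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("bounds must be a non-degenerate rectangle")
    x, y = cloud.points[:, 0], cloud.points[:, 1]
    keep = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    return PointCloud(cloud.points[keep], cloud.scanner_origin, cloud.plot_id)


def remove_soil_layer(cloud: PointCloud, soil_height: float = 0.10) -> PointCloud:
    """Strip the soil-surface layer: points with ``z <= z_min + soil_height``.

    ``z_min`` is taken from the (already clipped) cloud itself. Removing
    every point triggers an empty-cloud warning rather than an error, so
    callers can decide how to treat bare plots.
    """
    if soil_height < 0:
        raise ValueError("soil_height must be >= 0")
    if cloud.is_empty:
        return cloud
    z = cloud.points[:, 2]
    keep = z > z.min() + soil_height
    if not keep.any():
        warnings.warn("soil removal left no points", stacklevel=2)
    return PointCloud(cloud.points[keep], cloud.scanner_origin, cloud.plot_id)


# ---------------------------------------------------------------------------
# Voxelization

def voxel_indices(points: np.ndarray, origin: np.ndarray, voxel_size: float) -> np.ndarray:
    """Integer voxel index of each point under half-open binning."""
    return np.floor((points - origin) / voxel_size).astype(np.int64)


def voxelize(cloud: PointCloud, voxel_size: float = 0.05) -> VoxelGrid:
    """Discretize a cloud into a cubic occupancy grid.

    The grid is anchored at the cloud's minimum corner and each voxel is the
    half-open cube ``[o + i*s, o + (i+1)*s)``. A voxel is filled when it
    contains at least one point.
    """
    if cloud.is_empty:
        raise EmptyCloudError("cannot voxelize an empty cloud")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    origin = cloud.points.min(axis=0)
    idx = voxel_indices(cloud.points, origin, voxel_size)
    filled, counts = np.unique(idx, axis=0, return_counts=True)
    shape = tuple(int(v) for v in filled.max(axis=0) + 1)
    return VoxelGrid(
        voxel_size=voxel_size, origin=origin, indices=filled, shape=shape, counts=counts
    )
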