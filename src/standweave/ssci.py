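"""Stand structural complexity index (SSCI) from a single central scan.

SSCI summarizes the 3D heterogeneity of a stand's point cloud as

    SSCI = MeanFrac ** ln(ENL)

where *ENL* (effective number of layers) is the inverse Simpson diversity
of filled-voxel proportions across 25 cm horizontal slices of a 5 cm voxel
grid — the vertical-stratification component — and *MeanFrac* is the mean
fractal dimension of azimuthal cross-section polygons around the scanner —
the density/convolution component. A single-layer stand has ENL = 1 and
hence SSCI = 1 regardless of MeanFrac; likewise MeanFrac = 1 (all sections
square-like) forces SSCI = 1.

Cross sections divide the full circle around the scanner into ``n_sections``
equal azimuthal sectors (4500 by default). Within a sector each point maps
to the vertical half-plane coordinates (d, z) = (horizontal distance from
the scanner, height relative to the scanner). Points sorted by elevation
angle and closed through the scanner position form a simple, star-shaped
polygon whose perimeter P and area A give the fractal (shape-complexity)
dimension

    FRAC = 2 ln(0.25 P) / ln(A),   clamped to [1, 2],

which equals 1 for squares of any size and grows with boundary convolution.
Sections with fewer than 3 points, non-positive area, or area within 1e-6
of 1 m² (where ln A degenerates) are flagged and excluded from MeanFrac.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pointcloud import EmptyCloudError, PointCloud, VoxelGrid, remove_soil_layer, voxelize

__all__ = [
    "CrossSection",
    "SSCIResult",
    "effective_number_of_layers",
    "build_cross_sections",
    "fractal_dimension",
    "mean_frac",
    "compute_ssci",
]

#: area (m²) within this distance of 1.0 makes ln(A) degenerate
AREA_LOG_EPS = 1e-6


@dataclass
class CrossSection:
    """One azimuthal cross-section polygon.

    ``vertices`` are (d, z) pairs ordered by elevation angle, *excluding*
    the scanner vertex at (0, 0) through which the polygon is closed.
    """

    azimuth_index: int
    vertices: np.ndarray  # (k, 2)
    perimeter: float
    area: float

    @property
    def n_points(self) -> int:
        return len(self.vertices)

    @property
    def is_degenerate(self) -> bool:
        return self.n_points < 3 or self.area <= 0.0


@dataclass
class SSCIResult:
    """ENL, MeanFrac and SSCI for one plot, with intermediate detail."""

    enl: float
    mean_frac: float
    ssci: float
    n_valid_sections: int
    n_sections: int
    layer_profile: np.ndarray  # per-layer filled-voxel proportions, sums to 1
    plot_id: str | None = None


def effective_number_of_layers(
    grid: VoxelGrid, slice_thickness: float = 0.25
) -> tuple[float, np.ndarray]:
    """Inverse Simpson diversity of filled voxels across horizontal layers.

    Layers of ``slice_thickness`` are stacked from the lowest filled voxel
    upward; layer proportions p_i are filled-voxel counts normalized by the
    total filled count, and ENL = 1 / sum(p_i**2). ENL is 1 when one layer
    holds everything and equals the layer count when they are equally
    filled.

    Returns
    -------
    enl, layer_profile
    """
    if grid.n_filled == 0:
        raise EmptyCloudError("grid has no filled voxels")
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    k = grid.indices[:, 2]
    # voxel-center height above the lowest filled voxel avoids float
    # boundary ambiguity when slice/voxel is an integer ratio
    center_z = (k - k.min() + 0.5) * grid.voxel_size
    layer = np.floor(center_z / slice_thickness).astype(np.int64)
    counts = np.bincount(layer)
    p = counts / counts.sum()
    enl = 1.0 / float(np.sum(p**2))
    return enl, p


def build_cross_sections(
    cloud: PointCloud,
    scanner_origin: tuple[float, float, float] | None = None,
    n_sections: int = 4500,
) -> list[CrossSection]:
    """Bin points into equal azimuthal sectors and polygonize each one.

    Every sector yields a :class:`CrossSection` (so ``n_sections`` objects
    are always returned); sectors with fewer than 3 points are degenerate
    and carry zero perimeter/area. Perimeter is the closed edge-length sum
    and area the shoelace value over the elevation-sorted vertices plus the
    scanner vertex (0, 0).
    """
    if cloud.is_empty:
        raise EmptyCloudError("cannot build cross sections of an empty cloud")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    origin = scanner_origin or cloud.scanner_origin
    if origin is None:
        raise ValueError("scanner_origin is required (cloud carries none)")
    ox, oy, oz = origin

    dx = cloud.points[:, 0] - ox
    dy = cloud.points[:, 1] - oy
    z = cloud.points[:, 2] - oz
    azimuth = np.arctan2(dy, dx) % (2.0 * math.pi)
    sector = np.minimum(
        (azimuth / (2.0 * math.pi) * n_sections).astype(np.int64), n_sections - 1
    )
    d = np.hypot(dx, dy)
    elevation = np.arctan2(z, d)

    order = np.lexsort((elevation, sector))
    sector, d, z = sector[order], d[order], z[order]
    boundaries = np.flatnonzero(np.diff(sector)) + 1
    chunks = np.split(np.column_stack([d, z]), boundaries)
    present = np.concatenate([[sector[0]], sector[boundaries]]) if len(sector) else []

    sections: dict[int, CrossSection] = {}
    for idx, verts in zip(present, chunks):
        sections[int(idx)] = _polygonize(int(idx), verts)
    empty = np.empty((0, 2))
    return [
        sections.get(i, CrossSection(i, empty, 0.0, 0.0)) for i in range(n_sections)
    ]


def _polygonize(azimuth_index: int, verts: np.ndarray) -> CrossSection:
    if len(verts) < 3:
        return CrossSection(azimuth_index, verts, 0.0, 0.0)
    ring = np.vstack([[0.0, 0.0], verts])  # closed through the scanner
    nxt = np.roll(ring, -1, axis=0)
    perimeter = float(np.sum(np.hypot(*(nxt - ring).T)))
    area = float(
        abs(np.sum(ring[:, 0] * nxt[:, 1] - nxt[:, 0] * ring[:, 1])) / 2.0
    )
    return CrossSection(azimuth_index, verts, perimeter, area)


def fractal_dimension(section: CrossSection) -> float | None:
    """Shape-complexity dimension of one section; ``None`` when excluded.

    FRAC = 2 ln(0.25 P) / ln(A), clamped to [1, 2]. Squares of any side
    attain the minimum of 1. Sections that are degenerate or whose area is
    within :data:`AREA_LOG_EPS` of 1 m² are excluded.
    """
    if section.is_degenerate:
        return None
    if abs(section.area - 1.0) <= AREA_LOG_EPS:
        return None
    frac = 2.0 * math.log(0.25 * section.perimeter) / math.log(section.area)
    return min(2.0, max(1.0, frac))


def mean_frac(sections: list[CrossSection]) -> tuple[float, int]:
    """Arithmetic mean of FRAC over valid sections and their count."""
    values = [f for f in map(fractal_dimension, sections) if f is not None]
    if not values:
        raise ValueError(
            "no valid cross sections: every sector was degenerate "
            "(fewer than 3 points) or log-degenerate (area near 1 m²)"
        )
    return float(np.mean(values)), len(values)


def compute_ssci(
    cloud: PointCloud,
    voxel_size: float = 0.05,
    slice_thickness: float = 0.25,
    n_sections: int = 4500,
    soil_height: float = 0.10,
    scanner_origin: tuple[float, float, float] | None = None,
) -> SSCIResult:
    """Full SSCI computation for one (already plot-clipped) cloud.

    The soil surface layer is stripped first; the remaining cloud is
    voxelized for ENL and sectioned for MeanFrac, and SSCI is
    ``MeanFrac ** ln(ENL)``.
    """
    cleaned = remove_soil_layer(cloud, soil_height=soil_height)
    if cleaned.is_empty:
        raise EmptyCloudError("no points left after soil removal")
    grid = voxelize(cleaned, voxel_size=voxel_size)
    enl, profile = effective_number_of_layers(grid, slice_thickness=slice_thickness)
    sections = build_cross_sections(cleaned, scanner_origin, n_sections=n_sections)
    mfrac, n_valid = mean_frac(sections)
    ssci = mfrac ** math.log(enl)
    return SSCIResult(
        enl=enl,
        mean_frac=mfrac,
        ssci=ssci,
        n_valid_sections=n_valid,
        n_sections=n_sections,
        layer_profile=profile,
        plot_id=cloud.plot_id,
    )
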