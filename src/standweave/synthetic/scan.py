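"""Central-scanner point-cloud simulation for a planted plot.

Each living tree contributes stem points along a tapered vertical segment
of its height and crown points sampled uniformly inside an ellipsoid hung
from the tree top. Crown depth follows the species' crown parameters, which
the default pool ties to shade tolerance: tolerant species hold deeper
crowns reaching further down, intolerant species are taller with shallower
crowns. Mixtures of species differing in tolerance therefore occupy more
vertical layers than monocultures — the stratification mechanism the SSCI
pipeline is meant to detect. A thin ground-point layer is added so that
soil removal is exercised; no occlusion or scanner physics is modeled.

The scanner origin is recorded at the plot center, 1.3 m above ground.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..pointcloud import EmptyCloudError, PointCloud
from .design import PlotSpec, SpeciesSpec

__all__ = ["simulate_scan", "SCANNER_HEIGHT"]

SCANNER_HEIGHT = 1.3  # m, tripod height at the plot center


def _ellipsoid_points(rng: np.random.Generator, n: int, semi: np.ndarray) -> np.ndarray:
    """Uniform samples inside an axis-aligned ellipsoid centered at 0."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None] * semi


def simulate_scan(
    plot: PlotSpec,
    census: pd.DataFrame,
    pool: dict[str, SpeciesSpec],
    points_per_tree: int = 800,
    crown_point_fraction: float = 0.7,
    noise_sd: float = 0.01,
    n_ground_points: int = 400,
    seed: int = 0,
) -> PointCloud:
    """Simulate a TLS-like cloud of one plot at the t2 census.

    Dead trees contribute no points. Ground points are spread uniformly in
    a 5 cm layer above z = 0. All coordinates are meters in the plot frame;
    Gaussian jitter of ``noise_sd`` is added to every vegetation point.
    """
    if census.empty:
        raise EmptyCloudError(f"census for plot {plot.plot_id} is empty")
    if points_per_tree < 10:
        raise ValueError("points_per_tree must be >= 10")
    if not 0.0 <= crown_point_fraction <= 1.0:
        raise ValueError("crown_point_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_crown = int(round(points_per_tree * crown_point_fraction))
    n_stem = points_per_tree - n_crown

    chunks: list[np.ndarray] = []
    living = census[census["alive"]]
    for species_id, group in living.groupby("species_id", sort=True):
        sp = pool[species_id]
        x0 = group["x"].to_numpy()
        y0 = group["y"].to_numpy()
        h = group["H2"].to_numpy()
        d = group["D2"].to_numpy()
        k = len(group)
        if n_stem:
            # tapered stem: radius shrinks linearly from D/2 at the base to 0
            u = rng.random((k, n_stem))
            z = u * h[:, None]
            taper = (1.0 - u) * (d[:, None] / 2.0)
            theta = rng.uniform(0, 2 * np.pi, (k, n_stem))
            rad = np.sqrt(rng.random((k, n_stem))) * taper
            pts = np.stack(
                [
                    x0[:, None] + rad * np.cos(theta),
                    y0[:, None] + rad * np.sin(theta),
                    z,
                ],
                axis=-1,
            ).reshape(-1, 3)
            chunks.append(pts)
        if n_crown:
            depth = sp.crown_depth_frac * h
            centers = np.stack([x0, y0, h - depth / 2.0], axis=1)
            semi = np.stack(
                [np.full_like(h, sp.crown_radius), np.full_like(h, sp.crown_radius), depth / 2.0],
                axis=1,
            )
            pts = np.concatenate(
                [
                    c + _ellipsoid_points(rng, n_crown, s)
                    for c, s in zip(centers, semi)
                ]
            )
            chunks.append(pts)

    if chunks:
        veg = np.concatenate(chunks)
        veg = veg + rng.normal(0.0, noise_sd, veg.shape)
        veg[:, 2] = np.maximum(veg[:, 2], 0.0)
    else:
        veg = np.empty((0, 3))

    x0b, y0b, x1b, y1b = plot.bounds
    ground = np.column_stack(
        [
            rng.uniform(x0b, x1b, n_ground_points),
            rng.uniform(y0b, y1b, n_ground_points),
            rng.uniform(0.0, 0.05, n_ground_points),
        ]
    )
    cx, cy = plot.center
    return PointCloud(
        points=np.concatenate([ground, veg]),
        scanner_origin=(cx, cy, SCANNER_HEIGHT),
        plot_id=plot.plot_id,
    )
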