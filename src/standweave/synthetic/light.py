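"""Ground-level light sensor simulation.

Four sensors per plot, laid out as a square around the plot center at 20 cm
height, log hourly light intensity over one month (31 days). Daytime
incident light follows a sinusoidal diel curve; each sensor's reading is
attenuated by Beer-Lambert extinction through the leaf area of crowns
overhanging it, ``I0(t) * exp(-k * L_above)``, plus non-negative clipped
Gaussian sensor noise. Nighttime readings are exactly zero, which is how
downstream summaries identify and exclude them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import PlotSpec, SpeciesSpec

__all__ = ["simulate_light", "sensor_positions", "overhead_leaf_area"]

N_SENSORS = 4
N_DAYS = 31
DAY_START, DAY_END = 6, 18  # daylight hours of the diel curve


def sensor_positions(plot: PlotSpec, offset: float = 2.0) -> np.ndarray:
    """Square layout of the 4 sensors around the plot center."""
    cx, cy = plot.center
    return np.array(
        [
            [cx - offset, cy - offset],
            [cx - offset, cy + offset],
            [cx + offset, cy - offset],
            [cx + offset, cy + offset],
        ]
    )


def overhead_leaf_area(
    sensors: np.ndarray, census: pd.DataFrame, pool: dict[str, SpeciesSpec]
) -> np.ndarray:
    """Leaf-area proxy above each sensor.

    Each living tree contributes its crown depth (m) weighted by a linear
    falloff of horizontal distance out to twice its crown radius — the
    factor of two accounts for oblique light paths through neighboring
    crowns rather than strictly vertical transmission. Trees beyond that
    reach contribute nothing.
    """
    living = census[census["alive"]]
    L = np.zeros(len(sensors))
    if living.empty:
        return L
    xy = living[["x", "y"]].to_numpy()
    depth = np.array(
        [pool[s].crown_depth_frac for s in living["species_id"]]
    ) * living["H2"].to_numpy()
    radius = np.array([pool[s].crown_radius for s in living["species_id"]])
    for i, (sx, sy) in enumerate(sensors):
        dist = np.hypot(xy[:, 0] - sx, xy[:, 1] - sy)
        w = np.maximum(0.0, 1.0 - dist / (2.0 * radius))
        L[i] = float(np.sum(w * depth))
    return L


def diel_curve(hours: np.ndarray, i0_peak: float = 1000.0) -> np.ndarray:
    """Half-sine daylight curve; zero outside the daylight window."""
    h = hours % 24
    day = (h >= DAY_START) & (h < DAY_END)
    return np.where(
        day, i0_peak * np.sin(np.pi * (h - DAY_START) / (DAY_END - DAY_START)), 0.0
    )


def simulate_light(
    plot: PlotSpec,
    census: pd.DataFrame,
    pool: dict[str, SpeciesSpec],
    i0_peak: float = 1000.0,
    extinction_k: float = 0.5,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly readings of the plot's 4 sensors over one month.

    Returns a long-format table (plot_id, sensor_id, hour, value) of
    ``N_DAYS * 24`` readings per sensor; values are clipped at 0 and
    nighttime hours are exactly 0.
    """
    if extinction_k < 0:
        raise ValueError("extinction_k must be >= 0")
    rng = np.random.default_rng(seed)
    hours = np.arange(N_DAYS * 24)
    i0 = diel_curve(hours, i0_peak)
    day = i0 > 0
    L = overhead_leaf_area(sensor_positions(plot), census, pool)

    frames = []
    for sensor in range(1, N_SENSORS + 1):
        values = i0 * np.exp(-extinction_k * L[sensor - 1])
        noise = rng.normal(0.0, noise_sd, len(hours))
        values = np.where(day, np.maximum(values + noise, 0.0), 0.0)
        frames.append(
            pd.DataFrame(
                {"plot_id": plot.plot_id, "sensor_id": sensor, "hour": hours, "value": values}
            )
        )
    return pd.concat(frames, ignore_index=True)
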