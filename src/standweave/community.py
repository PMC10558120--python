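"""Community trait metrics and the ground-light interception proxy.

CWM (community-weighted mean) and FDis (functional dispersion) summarize
the shade-tolerance composition of each plot, weighted by mortality-
corrected abundances (living-tree counts at the second census). FDis here
is the single-trait specialization — the abundance-weighted mean absolute
deviation of species trait values from the abundance-weighted centroid —
which is what the general Gower-distance formulation reduces to in one
dimension. The light proxy averages strictly positive sensor readings
(zeros mark nighttime) per sensor and then across a plot's four sensors;
lower values indicate stronger light interception by the canopy.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTraits",
    "LightSummary",
    "cwm",
    "fdis",
    "community_traits",
    "light_interception_proxy",
    "classify_quantiles",
]


@dataclass
class CommunityTraits:
    """CWM and FDis of a trait for one plot."""

    plot_id: str | None
    cwm: float
    fd: float
    abundances: dict[str, float]
    traits: dict[str, float]


@dataclass
class LightSummary:
    """Mean daytime light intensity at ground level for one plot."""

    plot_id: str | None
    mean_intensity: float
    per_sensor: dict[int, float]


def _weights(x: Sequence[float], a: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if len(x) != len(a):
        raise ValueError("trait and abundance vectors must have equal length")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundances sum to zero: community has no living trees")
    return x, a / total


def cwm(x: Sequence[float], a: Sequence[float]) -> float:
    """Abundance-weighted mean of a trait."""
    x, w = _weights(x, a)
    return float(np.sum(w * x))


def fdis(x: Sequence[float], a: Sequence[float]) -> float:
    """Single-trait functional dispersion.

    Abundance-weighted mean absolute distance of trait values to the
    abundance-weighted centroid; 0 for monocultures.
    """
    x, w = _weights(x, a)
    c = np.sum(w * x)
    return float(np.sum(w * np.abs(x - c)))


def community_traits(
    census: pd.DataFrame, traits: dict[str, float], plot_id: str | None = None
) -> CommunityTraits:
    """CWM and FDis from a plot census and a species trait table.

    Abundances are living-tree counts at the second census (mortality-
    corrected planting densities).
    """
    counts = census[census["alive"]].groupby("species_id").size()
    if counts.empty:
        raise ValueError("census has no living trees")
    species = list(counts.index)
    x = [traits[s] for s in species]
    a = counts.to_numpy(dtype=float)
    return CommunityTraits(
        plot_id=plot_id,
        cwm=cwm(x, a),
        fd=fdis(x, a),
        abundances=dict(zip(species, a)),
        traits={s: float(traits[s]) for s in species},
    )


def light_interception_proxy(series: pd.DataFrame) -> LightSummary:
    """Plot-level mean daytime light intensity from the 4-sensor series.

    Only strictly positive readings count (zeros are nighttime); each
    sensor is averaged first, then sensors are averaged.
    """
    sensors = sorted(series["sensor_id"].unique())
    if len(sensors) != 4:
        raise ValueError(f"expected 4 sensors, found {len(sensors)}")
    per_sensor: dict[int, float] = {}
    for sensor in sensors:
        values = series.loc[series["sensor_id"] == sensor, "value"]
        positive = values[values > 0]
        if positive.empty:
            raise ValueError(f"sensor {sensor} has no positive readings")
        per_sensor[int(sensor)] = float(positive.mean())
    plot_id = series["plot_id"].iloc[0] if len(series) else None
    return LightSummary(
        plot_id=plot_id,
        mean_intensity=float(np.mean(list(per_sensor.values()))),
        per_sensor=per_sensor,
    )


def classify_quantiles(
    mean_intensities: pd.Series, q_low: float = 0.25, q_high: float = 0.75
) -> pd.Series:
    """Classify plots as low / mid / high light vs. the 25%/75% quantiles."""
    lo = mean_intensities.quantile(q_low)
    hi = mean_intensities.quantile(q_high)
    if lo == hi:
        warnings.warn("degenerate quantile split: all plots classified mid", stacklevel=2)
    out = pd.Series("mid", index=mean_intensities.index, dtype=object)
    out[mean_intensities <= lo] = "low"
    out[mean_intensities >= hi] = "high"
    if lo == hi:
        out[:] = "mid"
    return out
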