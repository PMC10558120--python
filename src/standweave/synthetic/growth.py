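"""Tree growth and mortality simulation with an injectable diversity effect.

Growth between the planting census (t1) and the second census (t2) is drawn
per tree from its species' expected t2 size, scaled by a community-level
overyielding factor ``1 + diversity_effect * log2(S)`` where S is plot
richness. ``diversity_effect`` is thus the fractional growth bonus per
doubling of species richness — the injectable ground truth that downstream
biodiversity-effect estimators should recover. Mortality is drawn
independently per tree; dead trees keep their planting size and contribute
neither growth nor canopy points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SpeciesSpec

__all__ = ["simulate_growth"]


def simulate_growth(
    trees: pd.DataFrame,
    pool: dict[str, SpeciesSpec],
    diversity_effect: float = 0.044,
    mortality_prob: float | dict[str, float] = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill in the t2 census (D2, H2, alive) for one plot's planting table.

    Parameters
    ----------
    trees
        Planting census from :func:`~standweave.synthetic.design.layout_plot`.
    pool
        Species parameter pool.
    diversity_effect
        Fractional growth bonus per unit log2 richness; must be >= -1.
        0 gives the null community where expected growth is independent of
        richness.
    mortality_prob
        Death probability per tree over the census interval, scalar or per
        species.
    """
    if diversity_effect < -1:
        raise ValueError("diversity_effect must be >= -1")
    probs = (
        {s: float(mortality_prob) for s in pool}
        if np.isscalar(mortality_prob)
        else dict(mortality_prob)
    )
    if any(not 0 <= p <= 1 for p in probs.values()):
        raise ValueError("mortality probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    out = trees.copy()
    S = out["species_id"].nunique()
    boost = 1.0 + diversity_effect * np.log2(S)

    species = out["species_id"].to_numpy()
    d2_mean = np.array([pool[s].d2_mean for s in species])
    h2_mean = np.array([pool[s].h2_mean for s in species])
    sigma = np.array([pool[s].growth_sigma for s in species])
    p_death = np.array([probs[s] for s in species])

    noise = rng.lognormal(0.0, sigma, size=(2, len(out)))
    d2 = np.maximum(d2_mean * boost * noise[0], out["D1"].to_numpy())
    h2 = np.maximum(h2_mean * boost * noise[1], out["H1"].to_numpy())
    alive = rng.random(len(out)) >= p_death

    out["D2"] = np.where(alive, d2, out["D1"])
    out["H2"] = np.where(alive, h2, out["H1"])
    out["alive"] = alive
    return out
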