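"""Synthetic tree-diversity experiment designs.

Emulates the layout rules of a two-block, 80-plot tree diversity experiment
crossing species richness (1, 2, 4) with mycorrhizal association (AM-only,
EM-only, AM+EM) over a pool of 10 species (5 arbuscular, 5 ecto):

* 20 monocultures — each species twice, once per block;
* 30 two-species plots — all 10 AM pairs, all 10 EM pairs, and 10
  seeded-random mixed AM×EM pairs, no composition repeated;
* 30 four-species plots — all 5 AM 4-subsets twice, all 5 EM 4-subsets
  twice, and 10 seeded-random distinct compositions of 2 AM + 2 EM species.

Each 11 m × 11 m plot is planted with 140 trees on a 12 × 12 grid at 1 m
spacing with the four corner positions left empty; species are assigned to
positions by a seeded random permutation with exact per-species counts
(140, 70 or 35 for richness 1, 2, 4). The central 8 m × 8 m window of that
grid holds exactly 64 trees, the subset used for growth analyses.

The shipped species pool is synthetic: shade-tolerance indices are
placeholder values on a 0-5 scale, not measurements of any real species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesSpec",
    "PlotSpec",
    "ExperimentDesign",
    "InvalidPoolError",
    "default_species_pool",
    "generate_design",
    "planting_grid",
    "layout_plot",
    "PLOT_SIZE",
    "N_TREES_PER_PLOT",
]

PLOT_SIZE = 11.0  # m, side of the square plot
N_TREES_PER_PLOT = 140
GRID_POSITIONS = 12  # 12 x 12 grid at 1 m spacing spans 11 m


class InvalidPoolError(ValueError):
    """Species pool does not hold exactly 5 AM and 5 EM species."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: mycorrhizal type, shade tolerance, growth and crown form.

    ``shade_tolerance`` is a dimensionless index (higher = more tolerant of
    low light). Growth parameters are expected diameters/heights (m) at the
    planting census (t1) and the second census (t2) with a common lognormal
    dispersion sigma. Crown parameters are the crown depth as a fraction of
    tree height and the crown radius in meters.
    """

    species_id: str
    mycorrhizal_type: str  # "AM" | "EM"
    shade_tolerance: float
    d1_mean: float = 0.012
    h1_mean: float = 0.70
    d2_mean: float = 0.060
    h2_mean: float = 6.0
    growth_sigma: float = 0.15
    crown_depth_frac: float = 0.45
    crown_radius: float = 0.75  # crowns touch/overlap at the 1 m planting pitch

    def __post_init__(self) -> None:
        if self.mycorrhizal_type not in ("AM", "EM"):
            raise ValueError(f"mycorrhizal_type must be AM or EM, got {self.mycorrhizal_type!r}")
        if not np.isfinite(self.shade_tolerance):
            raise ValueError("shade_tolerance must be finite")
        for name in ("d1_mean", "h1_mean", "d2_mean", "h2_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PlotSpec:
    """One experimental community: composition, association, geometry."""

    plot_id: str
    block: int
    richness: int
    mycorrhizal_association: str  # "AM" | "EM" | "AM+EM"
    composition: tuple[str, ...]
    bounds: tuple[float, float, float, float] = (0.0, 0.0, PLOT_SIZE, PLOT_SIZE)

    def __post_init__(self) -> None:
        if len(self.composition) != self.richness:
            raise ValueError("composition size must equal richness")
        if self.richness not in (1, 2, 4):
            raise ValueError("richness must be 1, 2 or 4")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bounds
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class ExperimentDesign:
    """The full 80-plot design over a 10-species pool."""

    plots: list[PlotSpec]
    species_pool: dict[str, SpeciesSpec]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One row per plot: id, block, richness, association, composition."""
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "block": [p.block for p in self.plots],
                "richness": [p.richness for p in self.plots],
                "mycorrhizal_association": [p.mycorrhizal_association for p in self.plots],
                "composition": ["+".join(p.composition) for p in self.plots],
            }
        )


# synthetic placeholder shade-tolerance indices (0-5 scale), chosen to span
# the tolerant-intolerant gradient evenly within each mycorrhizal type
_SHADE_TOLERANCE = {
    "AM1": 1.2, "AM2": 2.1, "AM3": 3.0, "AM4": 3.9, "AM5": 4.8,
    "EM1": 1.5, "EM2": 2.4, "EM3": 3.3, "EM4": 4.2, "EM5": 4.6,
}


def default_species_pool(stratification: float = 1.0) -> dict[str, SpeciesSpec]:
    """Build the synthetic 10-species pool (5 AM + 5 EM).

    ``stratification`` scales how strongly shade tolerance differentiates
    species' vertical structure: shade-intolerant species grow taller with
    shallower crowns, tolerant species stay shorter with deeper crowns that
    reach further down. At 0 every species shares the same expected heights
    and crown form, giving a structural null community.
    """
    mid, span = 3.0, 3.6  # center and range of the tolerance scale above
    pool: dict[str, SpeciesSpec] = {}
    for sp, st in _SHADE_TOLERANCE.items():
        zscore = (mid - st) / span  # positive = intolerant
        h2 = 6.0 * (1.0 + stratification * 0.35 * zscore)
        d2 = 0.060 * (h2 / 6.0)
        depth = 0.45 - stratification * 0.25 * zscore
        pool[sp] = SpeciesSpec(
            species_id=sp,
            mycorrhizal_type="AM" if sp.startswith("AM") else "EM",
            shade_tolerance=st,
            d2_mean=d2,
            h2_mean=h2,
            crown_depth_frac=float(np.clip(depth, 0.2, 0.75)),
        )
    return pool


def generate_design(pool: dict[str, SpeciesSpec], seed: int) -> ExperimentDesign:
    """Generate the full 80-plot design from a 10-species pool.

    All combinatorics that the design fixes are deterministic; only the
    mixed-type compositions (AM×EM pairs, 2 AM + 2 EM quartets) and block
    assignment of unreplicated plots are seeded-random draws.
    """
    am = sorted(s for s, sp in pool.items() if sp.mycorrhizal_type == "AM")
    em = sorted(s for s, sp in pool.items() if sp.mycorrhizal_type == "EM")
    if len(pool) != 10 or len(am) != 5 or len(em) != 5:
        raise InvalidPoolError(
            f"pool must hold exactly 5 AM and 5 EM species, got {len(am)} AM / {len(em)} EM"
        )
    rng = np.random.default_rng(seed)

    # composition, association, replicated?
    comps: list[tuple[tuple[str, ...], str, bool]] = []
    for sp in am + em:
        t = pool[sp].mycorrhizal_type
        comps.append(((sp,), t, True))
    for pair in combinations(am, 2):
        comps.append((pair, "AM", False))
    for pair in combinations(em, 2):
        comps.append((pair, "EM", False))
    cross = [(a, e) for a in am for e in em]
    for i in rng.choice(len(cross), size=10, replace=False):
        comps.append((tuple(sorted(cross[i])), "AM+EM", False))
    for quad in combinations(am, 4):
        comps.append((quad, "AM", True))
    for quad in combinations(em, 4):
        comps.append((quad, "EM", True))
    mixed_quads = [tuple(sorted(a + e)) for a in combinations(am, 2) for e in combinations(em, 2)]
    for i in rng.choice(len(mixed_quads), size=10, replace=False):
        comps.append((mixed_quads[i], "AM+EM", False))

    plots: list[PlotSpec] = []
    # replicated compositions get one plot per block; unreplicated ones are
    # split between blocks by a seeded shuffle within each stratum
    unreplicated_blocks: dict[int, np.ndarray] = {}
    strata: dict[tuple[int, str], list[int]] = {}
    for i, (c, assoc, rep) in enumerate(comps):
        if not rep:
            strata.setdefault((len(c), assoc), []).append(i)
    for members in strata.values():
        half = len(members) // 2
        order = rng.permutation(len(members))
        for rank, j in enumerate(order):
            unreplicated_blocks[members[j]] = 1 if rank < half else 2

    n = 0
    for i, (comp, assoc, replicated) in enumerate(comps):
        blocks = (1, 2) if replicated else (unreplicated_blocks[i],)
        for b in blocks:
            n += 1
            plots.append(
                PlotSpec(
                    plot_id=f"P{n:03d}",
                    block=b,
                    richness=len(comp),
                    mycorrhizal_association=assoc,
                    composition=tuple(sorted(comp)),
                )
            )
    return ExperimentDesign(plots=plots, species_pool=dict(pool), seed=seed)


def planting_grid(bounds: tuple[float, float, float, float] = (0.0, 0.0, PLOT_SIZE, PLOT_SIZE)) -> np.ndarray:
    """140 planting positions: a 12 × 12 grid at 1 m spacing minus corners."""
    x0, y0, _, _ = bounds
    xs, ys = np.meshgrid(np.arange(GRID_POSITIONS), np.arange(GRID_POSITIONS))
    pos = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    last = GRID_POSITIONS - 1
    corners = {(0.0, 0.0), (0.0, float(last)), (float(last), 0.0), (float(last), float(last))}
    keep = [tuple(p) not in corners for p in pos]
    return pos[keep] + [x0, y0]


def layout_plot(plot: PlotSpec, seed: int, pool: dict[str, SpeciesSpec] | None = None) -> pd.DataFrame:
    """Plant one plot: assign species to grid positions at random.

    Returns the planting census as a table with one row per tree (columns
    ``tree_id, plot_id, species_id, x, y, D1, H1, D2, H2, alive``). Planting
    sizes D1/H1 are drawn around the species' t1 expectations with the
    species' lognormal dispersion; D2/H2 are initialized to D1/H1 and
    ``alive`` to True until a growth simulation fills them in.
    """
    S = plot.richness
    if N_TREES_PER_PLOT % S:
        raise ValueError(f"richness {S} does not divide {N_TREES_PER_PLOT}")
    rng = np.random.default_rng(seed)
    pos = planting_grid(plot.bounds)
    species = np.repeat(sorted(plot.composition), N_TREES_PER_PLOT // S)
    species = species[rng.permutation(N_TREES_PER_PLOT)]

    if pool is None:
        d1 = np.full(N_TREES_PER_PLOT, 0.012)
        h1 = np.full(N_TREES_PER_PLOT, 0.70)
        sigma = np.full(N_TREES_PER_PLOT, 0.15)
    else:
        d1 = np.array([pool[s].d1_mean for s in species])
        h1 = np.array([pool[s].h1_mean for s in species])
        sigma = np.array([pool[s].growth_sigma for s in species])
    jitter = 0.5 * sigma  # planting stock is more uniform than grown trees
    d1 = d1 * rng.lognormal(0.0, jitter)
    h1 = h1 * rng.lognormal(0.0, jitter)

    return pd.DataFrame(
        {
            "tree_id": [f"{plot.plot_id}-T{i:03d}" for i in range(1, N_TREES_PER_PLOT + 1)],
            "plot_id": plot.plot_id,
            "species_id": species,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "D1": d1,
            "H1": h1,
            "D2": d1,
            "H2": h1,
            "alive": True,
        }
    )
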