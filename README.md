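# standweave

Quantitative tools for linking **tree species richness** to **stand
structural complexity** and **wood productivity** in planted tree-diversity
experiments — the kind of two-block design that crosses richness (1, 2, 4
species) with mycorrhizal association (AM, EM, AM+EM) over 80 small plots.

It is written for forest ecologists who want to go from a single central
terrestrial-laser-scan (TLS) point cloud per plot, plus two tree censuses,
to plot-level biodiversity-effect statistics, and to validate every step of
that chain against synthetic stands with known ground truth.

## What it computes

**Stand structural complexity index.** For a plot-clipped, soil-stripped
point cloud:

- *ENL* — the effective number of 25 cm height layers, the inverse Simpson
  diversity of filled-voxel proportions of a 5 cm occupancy grid:
  ENL = 1 / Σᵢ pᵢ², capturing vertical stratification;
- *MeanFrac* — the mean fractal dimension FRAC = 2·ln(0.25·P)/ln(A)
  (clamped to [1, 2]) of 4500 azimuthal cross-section polygons around the
  scanner, capturing the density and convolution of structural elements;
- **SSCI = MeanFrac^ln(ENL)** — 1 for a single-layer or square-section
  stand, increasing with both components.

**Productivity.** Stem volume V = π·D²·H·f with form factor f = 0.5 (a
`cylinder-quarter` convention V = π·(D²/4)·H·f is also available), and
annual wood productivity AWP = Σᵢ (V_{i,2} − V_{i,1})/(t₂ − t₁) over trees
alive at the second census, restricted to the 64 trees of the central
8 m × 8 m window to avoid edge effects. Mortality is tallied over all 140
planted trees.

**Biodiversity effects.** The net biodiversity effect (overyielding)
NBE = Σ Y_O,i − Σ RY_E,i·M_i with its additive partition into
complementarity CE = N·mean(ΔRY)·mean(M) and selection
SE = N·cov(ΔRY, M) (population covariance; NBE = CE + SE exactly); the
structural analogue **ΔSSCI** = SSCI_obs − Σᵢ p_ij·mean-monoculture-SSCIᵢ
with mortality-corrected 2021 abundances p_ij; and Hedges' g effect sizes
with pooled SD and small-sample correction.

**Community metrics.** CWM and single-trait functional dispersion (FDis)
of shade tolerance, and a ground-light interception proxy (mean of
strictly positive hourly sensor readings, four sensors per plot).

**Synthetic experiments.** `standweave.synthetic` generates the full
80-plot design (all composition and replication rules), tree growth with
an injectable overyielding effect, central-scanner point clouds whose
vertical structure is driven by shade tolerance (stratification), and
diel light series — so every estimator above can be tested for parameter
recovery with known truth.

## Worked example

```python
from standweave import compute_ssci, synthetic

pool = synthetic.default_species_pool()
design = synthetic.generate_design(pool, seed=1)
plot = next(p for p in design.plots if p.richness == 4)
census = synthetic.simulate_growth(
    synthetic.layout_plot(plot, seed=1, pool=pool), pool, seed=2)
cloud = synthetic.simulate_scan(plot, census, pool, seed=3)
result = compute_ssci(cloud)
```

prints (see `examples/02_ssci_from_point_cloud.py`):

```
plot P051: 109200 points, scanner at (5.5, 5.5, 1.3)
ENL       = 22.57   (effective 25 cm layers; vertical stratification)
MeanFrac  = 1.612  (mean polygon fractal dimension, 1 = square-like)
SSCI      = 4.430  (= MeanFrac^ln(ENL))
```

The four-species stand spreads its biomass over ~23 effective height
layers and has strongly convoluted cross-sections, giving an SSCI of 4.4.
Running the whole chain (`examples/04_full_pipeline.py`, 80 plots, scaled
to 360 sections):

```
means by richness:
           SSCI     ENL    AWP  mortality
richness
1         5.638  17.425  0.361      0.051
2         6.122  20.768  0.415      0.048
4         6.410  22.655  0.469      0.049

NBE ~ dSSCI slope over 60 mixtures: 0.030 (R^2 = 0.10)
```

— mean SSCI and AWP rise monotonically with richness, and mixtures that
are structurally more complex than their monoculture expectation
(ΔSSCI > 0) also overyield more in wood volume (positive slope).

A thin CLI mirrors the library:
`standweave run|simulate|ssci|productivity|effects|traits|light|report`
(see `standweave --help`).

## Layout

- `src/standweave/` — the library (`pointcloud`, `ssci`, `productivity`,
  `effects`, `community`, `pipeline`, `synthetic/`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — unit, property and acceptance suites
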