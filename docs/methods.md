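# Methods

This note documents the models behind `standweave`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions adopted where the underlying methods leave room.

## Stand structural complexity

### Voxel grid and ENL

A plot-clipped cloud is first stripped of its soil surface: points with
`z ≤ z_min + soil_height` are dropped, with `soil_height = 0.10 m` by
default (the vertical extent of a ground-return layer is scanner- and
terrain-dependent; the value is exposed in the config). The remainder is
discretized into a cubic occupancy grid, `voxel_size = 0.05 m`, anchored
at the cloud's minimum corner with half-open bins `[o + i·s, o + (i+1)·s)`
— the anchor and the bin convention are implementation choices made
explicit so boundary behavior is testable. A voxel is filled if it holds
at least one point, which makes occupancy (and everything downstream)
invariant to point duplication and, to first order, to scan density.

Filled voxels are grouped into horizontal layers of
`slice_thickness = 0.25 m`, stacked from the lowest filled voxel upward
(the datum is the stand itself, not an absolute height). With layer
proportions `p_i` (filled voxels in layer i over all filled voxels), the
effective number of layers is the inverse Simpson diversity
`ENL = 1 / Σ p_i²`: 1 when one layer holds everything, equal to the layer
count when layers are equally filled. Layer membership is computed from
voxel-center heights, which avoids float boundary ambiguity at the exact
5-voxels-per-layer ratio.

### Cross sections and MeanFrac

The full circle around the scanner (plot center, 1.3 m tripod height) is
divided into `n_sections = 4500` equal azimuthal sectors. Each point maps
to `(d, z)` — horizontal distance from the scanner and height relative to
it — in its sector's vertical half-plane. Sorting a sector's points by
elevation angle `atan2(z, d)` and closing the polygon through the scanner
vertex `(0, 0)` yields a star-shaped, hence simple, polygon; its area
comes from the shoelace formula and its perimeter from the closed
edge-length sum. Sectors with fewer than 3 points are flagged degenerate
and excluded rather than failing the computation.

Each valid section gets a perimeter-area fractal (shape-complexity)
dimension

    FRAC = 2 · ln(0.25 · P) / ln(A)

clamped to [1, 2]. Squares of any side attain the minimum (`0.25·P = √A`),
and increasingly convoluted outlines push the value up. Sections with
`|A − 1 m²| ≤ 1e−6` are excluded because `ln A` degenerates there. The
polygons are used raw (no rescaling or normalization before the formula);
this choice is configurable in the sense that callers can transform
sections themselves, and it is the only interpretation that keeps the
square family exactly at 1 at every scale.

`MeanFrac` is the arithmetic mean of FRAC over valid sections, and

    SSCI = MeanFrac ^ ln(ENL)

so SSCI = 1 whenever ENL = 1 (exponent zero) or MeanFrac = 1 (unit base),
and SSCI increases in ENL whenever MeanFrac > 1.

The default section count assumes a realistically dense scan: with the
default synthetic density (~110k points per plot) each section holds ~25
points. The test suite scales both knobs together (360 sections, 120
points per tree) to keep the per-section sampling density while running
20-replicate simulation studies in minutes; real single scans are one to
two orders of magnitude denser still.

## Productivity and mortality

Stem volume is `V = π·D²·H·f` with form factor `f = 0.5`, implemented
literally as printed in the source method even though a true cylinder
would be `π·(D/2)²·H`; a `cylinder-quarter` convention is provided for
users who prefer the dimensionally conventional form. The choice scales
all volumes by 4 and therefore cancels from every relative quantity (NBE
sign, ΔRY, percentage increases).

`AWP = Σ (V₂ − V₁)/(t₂ − t₁)` over trees alive at the second census
(2015–2021 by default, i.e. 6 years). Growth analyses use the 64 trees of
the centered 8 m × 8 m window — on the 12 × 12 planting grid that window
is exactly the interior 8 × 8 block — while mortality (dead/planted) uses
all 140 trees; both scopes are explicit parameters, and the same scopes
are used when monoculture baselines enter the biodiversity-effect
statistics (64-tree AWP, whole-plot SSCI).

## Biodiversity effects

The additive partition uses expected relative yields from *planted*
proportions (equal by design: 1/N), monoculture means `M_i` averaged over
each species' two monoculture plots, and the **population** (divide-by-N)
covariance in the selection effect; with the sample covariance SE would
change by N/(N−1) and NBE = CE + SE would fail. The identity holds to
machine precision by construction and is asserted at 1e−12 relative
tolerance over 10⁴ random instances.

ΔSSCI uses *realized* 2021 relative abundances (living-tree counts per
species), so mortality shifts the monoculture-weighted expectation — the
only place realized abundances enter; overyielding expectations stay on
the planted design.

Hedges' g uses pooled SD and the small-sample correction
`J = 1 − 3/(4(n₁+n₂) − 9)` (toggleable). The pipeline's summary computes g
between richness-level groups of plot values; model-predicted values
(mixed-effect machinery) are deliberately out of scope, so these are
raw-group effect sizes.

The NBE–ΔSSCI relationship is summarized by an ordinary least-squares
slope over mixture plots, sign being the quantity of scientific interest
at synthetic scale; no p-values are reported.

## The synthetic generator

The generator emulates a two-block, 80-plot design: 20 monocultures (10
species × 2, one per block), 30 two-species plots (all 10 AM pairs, all 10
EM pairs, 10 seeded-random AM×EM pairs, all compositions distinct), 30
four-species plots (all five 4-subsets of each pure type twice, plus 10
seeded-random distinct 2 AM + 2 EM quartets). Each plot is 11 m × 11 m
with 140 trees on a 12 × 12 grid at 1 m pitch minus the four corners —
the only regular 1 m layout consistent with 140 trees, an 11 m square and
a 64-tree 8 m × 8 m core. Species are assigned to positions by seeded
permutation with exact counts (140/70/35). Mixed-type compositions are
random draws because realized compositions of such designs are
experiment-specific.

**Growth.** Expected second-census sizes are scaled by
`1 + diversity_effect · log₂(S)` and drawn with lognormal dispersion
(σ = 0.15) per tree, floored at planting size. The default
`diversity_effect = 0.044` on diameter *and* height compounds through the
volume formula to ≈ (1 + 2·0.044)³ ≈ +29% AWP in four-species mixtures —
a magnitude typical of young broadleaf diversity experiments. Mortality
is i.i.d. per tree (default 5% over the interval); dead trees keep
planting size and contribute neither growth nor canopy points. Death
timing within the interval is not modeled.

**Stratification.** Shade tolerance (synthetic placeholder indices on a
0–5 scale; real trait tables can be supplied via config) drives vertical
differentiation: with `stratification = 1`, shade-intolerant species grow
up to ~17% taller with shallower crowns and tolerant species stay shorter
with deeper crowns. Mixtures of contrasting species therefore fill more
height layers than monocultures — raising ENL and hence SSCI — which is
the mechanism the ΔSSCI statistic is designed to detect. At
`stratification = 0` all species share one vertical structure, giving a
true structural null in which richness carries no SSCI signal.

**Scans.** Per living tree: stem points on a linearly tapered vertical
segment, crown points uniform in an ellipsoid hung from the tree top
(radius 0.75 m — crowns touch at the 1 m pitch), Gaussian jitter
(σ = 1 cm), plus a thin uniform ground layer (0–5 cm) so soil removal is
exercised. No occlusion, beam divergence, reflectance or registration
effects are modeled: passing recovery tests shows the estimators respond
correctly to geometry, not that they are robust to scanner artifacts.

**Light.** Four sensors in a square around the plot center log hourly
values over 31 days: a half-sine diel curve (06–18 h, peak 1000)
attenuated by `exp(−k·L)` with `k = 0.5`, where L is a leaf-area proxy
summing crown depths of trees within twice their crown radius of the
sensor (the factor 2 stands in for oblique light paths), plus clipped
Gaussian noise. Nighttime values are exactly 0, which is also how
downstream averaging identifies them.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline draws one
child-seed quadruple per plot up front, so runs are bit-reproducible and
plot results do not depend on iteration order. Reference conditions (4500
sections, 800 points per tree) process 80 plots in ~25 s; the simulation
studies in the test suite use 20 replicates per condition at the scaled
sizes above, chosen so a full validation runs in a few minutes on one
core.

## Known limitations

- The FRAC clamp to [1, 2] and the closure-through-scanner polygon rule
  are conventions; alternative closures change MeanFrac slightly but not
  the ordering of stands in our simulations.
- The generator's crown model is a geometric stand-in for allometry;
  absolute SSCI/ENL values are not comparable to field-measured stands,
  only contrasts within a synthetic experiment are meaningful.
- Mixed-effect models, SEMs and multiple-comparison procedures are out of
  scope; the summary statistics here are group means, raw effect sizes
  and OLS slopes.
- Light sensors are noise-free at night by construction; real loggers
  report small positive nighttime values that would need thresholding.
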