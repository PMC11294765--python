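# Methods

## Model and assumptions

The pipeline treats access to continuous maternal and perinatal health
care as three independent binary questions per ~1 km² grid cell: can a
woman living there walk, within a time threshold, to a facility capable of
antenatal care (ANC), of institutional delivery (ID), and of postnatal
care (PNC)? The core simplifications are:

* **Capability is package-level and binary.** A facility's 25 readiness
  flags (7 ANC, 8 ID, 10 PNC) collapse to three booleans. The default
  aggregation rule is `all` — a package is deliverable only when every one
  of its indicators is present. This is the strictest defensible rule and
  the only one consistent with package-capable counts sitting far below
  each single indicator's count in national census data; `any` and
  `at_least_k` are exposed for sensitivity analysis. Every indicator is
  treated independently (no joint requirements between, say, a partograph
  stock item and partograph monitoring). Missing flag columns are imputed
  as `False` — absence of evidence of readiness — and the imputation count
  is logged.
* **Travel is straight-line walking.** Nearest-neighbor method: each cell
  is served by its single nearest capable facility; time = distance /
  speed. No road network, terrain friction, motorized modes, or
  level-specific thresholds: these are deliberate omissions of the
  underlying method, not implementation gaps.
* **Demand is a rescaled density.** The gridded density proxy fixes the
  settlement pattern; announced regional totals T_j of women aged 15–49
  fix the mass: P_ij = T_j·G_ij/G_j. No demographic modelling or temporal
  projection is attempted.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| walking speed | 4 | km/h | standard pedestrian speed used in timely-access studies |
| timeliness threshold | 2 | h | the conventional emergency-access criterion; comparison is `<=` (a cell exactly at threshold is covered — boundary cells are measure-zero but the convention must be fixed for exact tests) |
| Earth radius | 6371 | km | spherical mean radius for the haversine metric |
| capability rule | `all` | — | see above |
| quantile weighting | population | — | times are reported *for women*, so cells are weighted by demand; `unweighted` retained for comparison |
| area weighting | uniform | — | count-based shares; `cosine` mode applies the first-order cos(latitude) correction for geographic cells |

## Numerical choices

* **Distance.** Haversine on a sphere, with the arcsine argument clamped
  to [0, 1] so antipodal rounding cannot yield NaN. A `planar` Euclidean
  mode serves projected inputs and the analytic test scenarios. Different
  GIS implementations use slightly different Earth models; absolute times
  can differ from other software around the third decimal.
* **Acceleration with an exactness contract.** Above 64 capable
  facilities a k-d tree (3-D chord embedding of the sphere, plain 2-D in
  planar mode) selects the nearest facility; the final distance is then
  always re-evaluated with the exact metric formula, so the surface is
  bit-identical to the exhaustive all-pairs minimum, which the tests
  enforce. Distance ties resolve to the lexicographically smallest
  facility id (facilities are pre-sorted by id; near-ties within 1e-9
  relative are re-resolved by a ball query).
* **Grid conventions.** Rasters are row-major from the top-left corner,
  cells are half-open intervals, centroids sit at half-cell offsets;
  nodata is NaN internally and a sentinel value on disk (ESRI ASCII grid).
  Infinite travel times (no capable facility anywhere) are encoded as
  nodata on write.
* **Cell-to-region assignment.** Centroid containment; at ~1 km
  resolution boundary error is second-order, so area-weighted splitting is
  not implemented. A centroid exactly on a shared edge goes to the
  lexicographically smallest region id (deterministic). Cells outside all
  regions, and nodata cells, are excluded from every downstream sum and
  counted in the log.
* **Redistribution edge cases.** A region with T_j > 0 but zero density
  mass raises an error naming the region (there is no shape to scale);
  T_j = 0 with positive mass yields an all-zero region with a warning.
  Per-region sums reproduce T_j to well below 1e-6 relative (floating
  point only).
* **Weighted quantiles.** Lower step function of the weighted CDF: sort
  by value, return the smallest value whose cumulative normalized weight
  reaches q. No interpolation — this makes every quantile exactly
  reproducible by weight-replication, which the tests exploit. Cells with
  infinite time are excluded from quantiles; their weighted share is
  reported as `unreachable_pct`. A weighted mean column is also emitted.
* **Rounding.** Report percentages are rounded half-up to 2 decimals at
  write time only; all internal arithmetic is unrounded. Columns of the
  zone-share table sum to exactly 100 before rounding and to 100 ± 0.05
  after.
* **Zone codes.** The (ANC, ID, PNC) truth table maps bijectively to
  types 1–8 with 1 = all three, 2 = ANC+ID, 3 = ANC+PNC, 4 = ID+PNC,
  5/6/7 = single packages, 8 = none; 0 is nodata outside the study area.

## Synthetic data: what it does and does not emulate

The generator produces, from one integer seed, a rectangular study window
tiled into regions (log-uniform totals, default 5×10⁴–5×10⁵ women per
region), a density raster of isotropic Gaussian urban clusters (default 2
per region, 5 km spread) over a uniform rural background (default 10% of
peak), and a three-level facility network sampled proportional to density
(default 60 primary / 4 secondary / 1 tertiary on a ~110 km, 100×100-cell
window — a deliberately down-scaled national system). Indicator flags are
independent Bernoulli draws whose default prevalences equal observed
national facility-census rates (e.g. 0.9131 for IPTp in pregnancy, 0.3268
for emergency obstetric care). Each generation stage draws from its own
seed substream, so adding a stage never perturbs earlier draws and
regeneration is byte-identical.

What it does *not* emulate: real coastline/province geometry, road
networks, correlated readiness between indicators (real facilities that
stock oxytocin usually also keep partographs; independent draws make the
`all` rule pessimistic relative to a real census), or level-dependent
readiness (real secondary hospitals pass delivery indicators far more
often than health posts). Passing tests therefore demonstrate that the
*computations* are correct and internally consistent under controlled
conditions, not that any particular country's coverage numbers would be
reproduced.

Analytic "known truth" scenarios use planar geometry so expected outputs
have closed forms: a single fully-capable facility at the center of a
100×100 unit-cell window covers exactly the centroids within
speed×threshold = 8 km, a count obtained by direct enumeration; degenerate
full-coverage/no-coverage worlds pin the 100% type-1 and type-8 cases; a
two-region world with all supply in one half must rank the dense region
strictly better on all three medians and on type-1 share.

## Design choices where the design was open

* The aggregation rule behind published package-capable counts is not
  derivable without survey microdata; `all` is the default and the rule is
  a first-class option rather than a constant.
* ESRI ASCII grid is the raster interchange format (text, header-complete,
  universally importable); the grid container carries an opaque CRS label
  and the pipeline refuses to mix labels rather than attempt reprojection.
* Zone shares default to count-based (uniform cell area): reproducible and
  assumption-free; the cosine mode exists because nominally 1 km
  geographic cells shrink with latitude.
* In the pipeline's end-to-end report, the national summary row pools all
  in-study cells (it is not an average of regional statistics).

## Problem sizes

Tests and the acceptance script run on grids from 10×10 to 100×100 cells
with up to ~100 facilities (10⁴ facilities for the Bernoulli-rate check);
the exhaustive-oracle comparisons use 50×50 grids × 20 random scenarios.
These sizes make every stochastic check cheap enough to run on every
commit while keeping the brute-force oracles exact. The library itself is
vectorised and k-d-tree-accelerated; national-scale inputs (~10⁶ cells,
~1.5×10³ facilities) are well within its reach.

## Known limitations

* Straight-line walking underestimates true travel time everywhere and
  most severely where road networks are sparse — the method's own stated
  limitation.
* Centroid assignment misallocates partial boundary cells; negligible at
  1 km resolution but not at coarser grids.
* `unreachable_pct` conflates "no capable facility exists nationally"
  with genuinely disconnected cells; with any capable facility the surface
  is finite everywhere, so regional unreachability only occurs when a
  package has zero capable facilities.
* The independent-Bernoulli flag model ignores indicator correlation (see
  above) and facility-level effects unless `forced` capability mode or
  custom prevalences are used.
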