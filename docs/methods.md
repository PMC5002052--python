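# Methods note

This note records the model implemented by `agbcompare`, the assumptions it
makes, the parameters it exposes, and the places where a design decision had
to be taken. It describes what the code computes; it makes no empirical
claims beyond that.

## 1. Problem and data model

The object of study is a set of two or more co-located continuous raster
maps of aboveground biomass density (AGB, Mg/ha) over the same territory.
Ancillary inputs are: a partition of the territory into mapping regions
(administrative units or ecoregions), an optional table of per-unit
reference biomass totals (Mg) emulating plot-based inventory estimates, an
optional proxy change map (Mg/ha of loss between two nominal map years),
and per-map metadata tags (sensor class, extrapolation technique, allometry
family, grain class, nominal year, forest-mask identity).

### Grid model

A raster lives on a `GridSpec`: north-west corner origin, square cells of
`cell_size` metres, rows increasing southward. Cells are half-open
intervals, so adjacent grids never double-count boundaries. Cell area in
hectares is `(cell_size / 100)^2`. A `BiomassRaster` carries a value array,
a boolean validity mask, and a nonnegativity invariant (waived for
difference rasters, which are signed by construction).

Operations:

- **Block-mean aggregation** (`aggregate_mean`, factor *f*): the mean of
  valid cells in each *f*×*f* window. A window is valid when its valid
  fraction (judged against the full *f*² even at map edges) is at least
  `min_valid_fraction` (default 0.5 — a coarse cell should summarise at
  least half its footprint, the conventional majority criterion). With full
  masks and *f* dividing both dimensions, total biomass (density × area) is
  conserved exactly up to float rounding; tests enforce a 1e−9 relative
  bound.
- **Nearest-neighbour resampling** (`resample_nearest`): each target cell
  takes the source cell whose centre is nearest to the target centre;
  distance ties break toward the smaller (row, col) index so the operation
  is deterministic.
- **Modal aggregation** (`aggregate_mode`) for categorical rasters: the
  most frequent code per window; frequency ties break to the smallest code.
- **Grid alignment** (`align_to`): when maps arrive at different grains,
  finer maps are block-mean aggregated by the rounded cell-size ratio and
  then snapped to the coarsest grid by nearest-neighbour resampling. All
  cross-map statistics are computed on the intersection of validity masks
  after alignment.

## 2. Descriptive phase

### Willmott's index of agreement

For a reference series X (truth slot) and a comparison series Y,

    d = 1 − Σ (X_i − Y_i)² / Σ (|X_i − X̄| + |Y_i − X̄|)²,   X̄ = mean(X).

Because |X_i − Y_i| ≤ |X_i − X̄| + |Y_i − X̄| termwise, d ∈ [0, 1]; the
implementation clamps to [0, 1] purely to absorb float rounding (observed
at the 1e−16 level). Degenerate convention: if the potential-error
denominator is zero (both series constant at X̄), d = 1 when the error sum
is also zero, else 0. d is translation invariant but not symmetric in its
arguments; the reference always occupies the X slot, and for map-vs-map
comparisons with no privileged truth both orderings are computed.

### Reference comparison

Each map is summed to per-unit totals over **its own** validity mask (maps
legitimately disagree about what is forest, and that disagreement is part
of the signal) and compared against reference unit totals with d, OLS
slope/intercept/r², and mean bias. Units missing from either side are
excluded and flagged; the national total is the sum over included units.

### R-mode principal component analysis

Shared valid pixels are stacked into an observations × maps table
(minimum 10 shared pixels). The PCA diagonalises the correlation matrix by
default — maps differ in scale and bias, and correlation mode asks only
about pattern; covariance mode is available when amplitude matters.
Eigenvectors come from `numpy.linalg.eigh` (the matrix is symmetric),
sorted by descending eigenvalue; each eigenvector's sign is fixed so its
largest-magnitude loading is positive, making outputs reproducible across
platforms. With strongly co-varying maps, PC1 is the consensus biomass
gradient and PC2 the dominant axis of disagreement; `outlier_map` returns
the map with the largest |correlation| with a chosen post-PC1 component.
Regional PCA repeats this per partition region, skipping regions with fewer
than `min_pixels` (default 30) shared pixels — below that, two-digit
correlations are not stable.

### Zonal statistics and the multiscale ladder

Region summaries report n_valid, mean, sd, percentiles (p5–p95 by
`numpy.percentile`, linear interpolation) and totals; statistics of empty
regions are None rather than NaN-propagated. Percentile pairs tabulate
matched region-wise percentiles for each map pair with an OLS fit per
(pair, statistic).

`multiscale_agreement` recomputes per-region d for a map pair across a
ladder of aggregation factors (default 1–4). At factor *f* both maps are
block-mean aggregated and the partition degraded modally; the minimum pixel
count scales as `max(2, min_pixels // f²)` so the criterion tracks the
shrinking region size instead of silently dropping regions at coarse
grains. Per-factor `median_d` and `range_d` summarise the ladder: rising
median_d with *f* diagnoses pixel-scale noise, a flat ladder diagnoses
region-scale structure.

## 3. Evaluative phase

Each test turns a narrative hypothesis into an explicit decision rule over
computed metrics and returns `consistent` (evidence matches the
hypothesised error source), `inconsistent` (evidence points the opposite
way), or `inconclusive`. All rules use strict inequalities, so identical
maps — zero evidence — always return `inconclusive`; this null-scenario
discipline is enforced by tests.

- **Forest mask**: Spearman rank concordance between mask area and
  national total across maps. ρ ≈ 1 (within float tolerance) →
  consistent; the smallest mask carrying the largest total → inconsistent.
- **Resolution**: region-wise medians of the interdecile range (p90 − p10);
  consistent iff every coarse-grain map's median is strictly below every
  fine-grain map's (strict group dominance), inconsistent iff the reverse
  dominance holds.
- **Sensor saturation**: among high-biomass regions (top quartile of the
  across-map mean of region medians; quantile default 75), consistent iff
  a strict majority (> 50 %) have every passive-sensor p90 below every
  active-sensor p90.
- **Extrapolation**: strict group dominance of parametric-technique maps
  below nonparametric ones in both region-median p10-complement and p90
  (two-tail compression, the mean-shrinkage signature).
- **Year effect**: OLS of the pairwise difference map on the proxy change
  map; the squared correlation is the "consistency fraction" (share of
  difference variance the proxy explains). Consistent iff slope > 0 and
  fraction ≥ 0.4 (default) — a slope of the right sign with under 40 % of
  variance explained leaves the year hypothesis open but unproven. A
  constant proxy raises `DegenerateFitError`, surfaced as inconclusive in
  the pipeline.
- **Allometry**: strict group dominance of map means (region medians)
  between allometry families.

Stratified differences over categorical layers exclude code 0 (nodata
stratum) but count it, and skip empty strata.

## 4. Synthetic scenario generator

The generator provides fully deterministic test landscapes. It emulates the
*statistical signatures* of mapping error sources, not their physics.

- **Truth field**: Gaussian random field — white noise smoothed with a
  Gaussian kernel of σ = corr_length/√2 cells, wrap mode (keeps the field
  stationary to the edge), empirically restandardised, scaled to the target
  mean/sd, clipped at 0. Defaults: 120 × 120 cells at 240 m, mean 100
  Mg/ha, sd 35, correlation length 8 cells — mid-range temperate-forest
  magnitudes with landscape-scale autocorrelation; they are package
  defaults chosen for plausibility, not fitted to any dataset.
- **Perturbations** (composable, applied in order): additive `bias`,
  multiplicative `scale`, `saturate` (hard cap, the passive-sensor
  signature), additive Gaussian `noise`, `coarsen` (block-mean then
  constant-within-block refinement), `mask_morph` (binary dilation/erosion
  of the validity mask with a disk element), `shrinkage`
  (x → x̄ + λ(x − x̄), the parametric-regression-toward-the-mean
  signature), and `disturbance` (biomass loss in random disk patches, used
  to build the proxy change map as the exact truth loss over the
  footprints).
- **Partitions** are Voronoi cells of random seeds (contiguous,
  irregular); categorical layers are quantile bins of independent random
  fields.
- **Reproducibility**: every (map, perturbation) pair draws from
  `default_rng([base_seed & 0x7FFFFFFF, map_index, pert_index])`, so adding
  a map or perturbation never shifts another's stream, and the proxy change
  map matches the disturbed map exactly.
- **Presets**: four archetypes spanning the tag space — fine-grain
  active-sensor maps with mild scale/noise error or saturation, and
  coarse-grain passive-sensor maps with bias + mask morphing or shrinkage.
  Generator defaults are the study conditions; tests and the acceptance
  script consume them as-is.

Not emulated: georeferencing error, temporal compositing artefacts,
per-species allometric structure, spatially correlated (as opposed to iid)
measurement noise, and real cloud/terrain masking geometry.

## 5. I/O, configuration, and numerics

Rasters are single-band GeoTIFFs written via `tifffile` with
ModelPixelScale/ModelTiepoint geo-tags and a GDAL nodata tag (default
−9999); rotated, multiband, or untagged files are rejected with
`FormatError`. Categorical rasters carry a `<name>.legend.csv` sidecar.
Runs are driven by a YAML `RunConfig`; output manifests embed a SHA-256
digest of the configuration for provenance. The CLI exits 0 on success,
2 on validation errors, 3 on computation errors.

Numerical choices worth recording: `eigh` rather than a general
eigensolver (symmetry, determinism); the explicit eigenvector sign
convention; the Willmott clamp; half-open grid cells; round-half-down
nearest-neighbour tie-breaking; derived seeds kept below 2³¹.

## 6. Limitations

- Verdicts are consistency checks, not causal attributions: several error
  sources can produce overlapping signatures, and a `consistent` verdict
  for one does not exclude another.
- Strict-dominance rules are conservative by design; with few maps per
  group, a single atypical map forces `inconclusive`.
- The reference comparison treats inventory totals as error-free; no
  sampling uncertainty is propagated.
- Alignment by block mean + nearest neighbour assumes near-integer
  cell-size ratios and axis-aligned grids; arbitrary reprojection is out
  of scope.
- The generator's iid noise and circular disturbance patches are stylised;
  conclusions about detector power transfer to real maps only insofar as
  real error sources share these signatures.
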