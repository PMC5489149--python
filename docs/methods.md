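# Methods

This note documents the models, the parameter choices that matter, the
numerical decisions, and what the synthetic study conditions do and do not
demonstrate.

## Grid conventions

All rasters in a run share one planar metric grid. Cells are half-open
squares `[x, x+res) × [y, y+res)` named by their lower-left corner, matching
national-grid reference semantics where a reference names a square, not a
point. Grids never get resampled: a raster is accepted only if it shares the
run's origin and nests exactly (integer resolution ratio). This is enforced
at load time because sub-cell misregistration between the occurrence grid,
the environmental stack and the fine land mask would silently corrupt every
downstream statistic. GeoTIFF interchange carries the georeferencing in the
ModelPixelScale/ModelTiepoint tags and layer metadata (kind, nodata
sentinel, CRS tag) as JSON in the image description.

Per-cell land area comes from a fine binary land mask (25 m in the field
protocol); a target cell's area is simply the count of fine land pixels
times the pixel area, so aggregating at any nesting resolution conserves
total land area exactly. The fine resolution is a parameter rather than a
constant: the synthetic scenarios use resolution/8 pixels so a 60×60-cell
landscape stays desk-sized while exercising identical code paths. The mask
is treated as given and binary; partial coastal pixels are whichever way the
mask rounded them.

## Occurrence handling

A record is a grid reference: a square of side equal to its stated
resolution (100 m, 1 km, 2 km, 10 km). Quality control keeps a record iff
its reference point lies inside the land boundary buffered by that
resolution class's distance; the default buffer equals the resolution
itself, i.e. the positional uncertainty of the reference, and is
configurable. Discards carry reason codes (`outside_buffered_boundary`,
`year_out_of_window`, `misaligned_reference`).

On a working grid, only records at least as fine as the grid are used (all
four classes at 10 km; 100 m and 1 km records at 1 km) so every kept record
has equivalent or better uncertainty — a coarser record is excluded rather
than smeared over candidate cells. Effort counts every kept row; occurrence
is effort > 0; a record's decade is `floor(year/10)·10`.

## Stage 1: the suitability ensemble

Per repetition:

1. **Pseudo-absences.** A fixed number of distinct unoccupied land cells,
   uniform without replacement (defaults 500 at 10 km, 5000 at 1 km —
   the tenfold increase tracks the typical growth in record counts).
   Occupied cells can never enter the absence set.
2. **Split.** Stratified 75/25 train/test preserving the class ratio;
   each class contributes `floor(0.25·n)` (min 1) test points.
3. **Seven models.** Profile methods use the continuous variables only
   (Bioclim, Mahalanobis) or Gower similarity over continuous + land-class
   (Domain), since percentiles and covariances are undefined on class
   codes. The GLM, random forest, SVM and the MaxEnt-style model see the
   continuous variables plus a dummy-coded land class. The GLM selects its
   predictor subset by deterministic greedy forward–backward search on
   AICc — same contract as exhaustive best-subset search (best subset by
   criterion) at a fraction of the cost, and deterministic. The
   MaxEnt-style model is a documented surrogate: an L2-penalized binomial
   model on expanded features (linear + quadratic + pairwise products of
   the standardized continuous variables) with the pseudo-absences as
   background; the ensemble accepts external scorer plug-ins for users who
   want the original feature-class machinery. SVM scores are Platt-scaled
   probabilities so all seven maps live on comparable scales when averaged.
4. **Evaluation.** Spatial sorting bias = mean nearest-neighbour distance
   (test presences → training presences) divided by the same for test
   absences. If below 1 the test absences are subsampled by greedy
   one-to-one pairwise-distance matching in random order; with fewer test
   absences than presences the full absence set is kept and the condition
   logged. AUC is the exact rank statistic. Best model by adjusted AUC;
   ties broken by a fixed priority order (maxent-like > random forest >
   SVM > GLM > Mahalanobis > Domain > Bioclim) for reproducibility.
5. **Threshold and standardization.** The maxSSS threshold is searched
   over midpoints between consecutive sorted unique pooled test scores
   plus the extremes (the objective is piecewise constant, so this set is
   exhaustive); the lowest maximiser is returned. The threshold uses the
   unadjusted test scores — the SSB matching is an AUC evaluation
   correction, whereas the threshold should reflect the full test sample.
   Map and threshold are then min–max standardized over land cells; a
   constant map is a degenerate repetition, discarded and logged.

All randomness descends from one master seed through per-repetition
substreams (`numpy` `SeedSequence.spawn`), so raising the repetition count
extends a run without perturbing earlier repetitions, and a repeated run is
bit-identical.

The ensemble records per-cell mean suitability, mean threshold, per-model
win counts and the per-cell relative standard error of the mean
(sd/√R)/mean, computed on cells with mean > 1e-6. **Caveat:** the maximum of
this RSE over cells is ill-conditioned wherever the mean approaches zero.
Different model families have different floors at unsuitable cells (logistic
probabilities ~1e-4; random-forest votes ~0.01; Platt-scaled SVM ~0.06), so
when the winning model switches between repetitions, cells with mean ~0.005
show relative errors of tens of percent even though their absolute standard
error is ~0.002 suitability units. On a generalist species whose map never
approaches zero the statistic stays small; on the default synthetic species,
which spans the full [0, 1] range, the maximum exceeds 10% for this reason
alone. The per-cell RSE raster is exposed (`EnsembleSuitability.rse_map`) so
users can see exactly where the instability lives.

## Stage 2: density bounds and the regression cascade

Survey polygons are burned at the fine-mask resolution; a fine land pixel
covered by several surveys takes the most recent one's density, with year
ties resolved toward the larger density (deterministic, conservative for the
upper bound, logged). Aggregation to the working grid produces the
bracketing pair: minimum = surveyed density mass divided by all land pixels
(unsurveyed land counted empty — right when surveys covered all used
habitat), maximum = divided by surveyed pixels only (unsurveyed land
representative — right for habitat generalists). Sea pixels never enter
either denominator, so min = surveyed_fraction × max holds cell-wise by
construction. Training rows are the surveyed cells at or above the mean
threshold; each bound is fitted as an independent cascade.

The cascade follows the gate → transform → GLM logic described in the
README. Numerical specifics:

* **Box-Cox with zeros.** Densities of zero occur; the transform uses a
  shift of half the smallest positive value when zeros are present,
  recorded in the model provenance.
* **Correlation structures.** Gaussian `exp(−(d/r)²)`, exponential
  `exp(−d/r)`, spherical `1 − 1.5h + 0.5h³` (h = d/r < 1, else 0) on cell
  centroid distances, nugget fixed at zero. The range r is profiled by
  maximum likelihood over a 12-point geometric grid from the 5th percentile
  of positive pairwise distances to twice the maximum — grid precision is
  ample for an AICc comparison and keeps the n² Cholesky count bounded.
  β and σ² are profiled out in closed form per candidate. AICc counts
  p + 2 parameters (coefficients + σ² + range) for spatial candidates.
* **Degree.** The suitability polynomial degree (1 or 2) enters the same
  criterion comparison; the candidate set is capped at 2.
* **GLM branch.** Families Gaussian (identity), gamma (log link; dropped
  when zeros are present), Poisson on the rounded response (logged),
  compared by plain AIC, degrees 1 and 2.
* **Prediction.** The mean structure predicts at every presence cell (the
  spatial correlation affects fitting, not population-level prediction);
  the inverse transform is applied, undefined fractional-power bases and
  negatives clamp to zero (warned when >1% of presence cells), and density
  × land km² gives abundance. Absence cells carry exactly zero.
  Predictions extrapolate beyond the training suitability range, with the
  clamp as the guard.
* **Subsampling.** Tables over 2000 rows: 10 independent subsets without
  replacement, full selection + prediction per subset, per-cell and total
  means, and the relative standard error of the mean total reported.

Biomass is the cell-wise sum over species of abundance × standard weight.

## The synthetic study conditions

The generator emulates the structure of the real inputs, not their
geography: smoothed standardized Gaussian noise fields for climate-like
variables, an argmax-of-fields categorical land class, a single
coastline-like landmass (thresholded smooth field, largest connected
component, ragged at the fine scale), occurrence sampled ∝ effort ×
suitability with the archive's resolution mixture (38/38/1/23% at
100 m/1 km/2 km/10 km), and rectangular surveys whose reported density is
the land-weighted true-density mean under the polygon times lognormal
reporting noise.

Defaults, chosen once: 60×60 cells at a nominal 10 km (≈2,600 land cells —
comparable to a national 10 km grid, minutes-scale runtime); 5 continuous
layers, 6 land classes, correlation length 6 cells; logistic suitability
with N(0, 1.5) coefficients; density link `0.5 + 10·s` individuals/km² —
realistic medium-mammal densities with a small vagrant-level baseline in
unsuitable habitat, so the truth is coherent with the occupancy concept the
same surface defines; survey rectangles of 0.2–1.0 cell sides (2–10 km),
matching the fact that published survey sites are small relative to a 10 km
cell; reporting noise sd 0.2 on the log scale. Named scenarios flip the link
(quadratic with negative curvature; negative slope, mirroring species whose
density falls where sightings are most likely) and the survey placement
(uniform vs suitability-biased) to exercise every cascade branch.

**What passing tests show — and don't.** The synthetic fields are smooth,
stationary and exactly the covariates the species responds to; real
environmental stacks are none of these. Survey placement is unbiased under
the default scenario, whereas published densities concentrate on high-
density populations. Two honest negative results follow from the protocol
itself and are visible in the test suite:

1. *Best-of-seven optimism.* On label-shuffled data every individual model's
   SSB-adjusted AUC is statistically indistinguishable from 0.5, but the
   AUC of the per-repetition *winner* averages ≈0.54 — the familiar
   optimism of reporting the maximum of several correlated test statistics.
   Headline best-model AUCs produced by this protocol inherit that bias.
2. *Coverage of the true total.* The upper abundance bound is an
   approximately unbiased (slightly low) estimator of the true total:
   the threshold zeroes real abundance in marginal habitat and polygon-mean
   densities dilute across suitability gradients, while nothing in the
   unbiased-survey scenario pushes the bound upward. The interval
   [total_min, total_max] therefore sits below the truth more often than
   it contains it. With suitability-biased surveys (the realistic case) the
   upper bound inflates and coverage improves — which is exactly the
   mechanism the original field application relied on.

## Problem sizes used in the automated checks

Unit and property tests run on 30×30-cell landscapes with reduced
repetition counts; the stability diagnostics use the full default scenario
(60×60, 100 repetitions, 500 pseudo-absences) and the 5000-row / 10×2000
subsampling configuration; the recovery experiment runs 20 seeds at 10
repetitions each, since the abundance interval is insensitive to the
repetition count. These sizes are the package's chosen desk-scale study
conditions.
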