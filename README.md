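# sdm2abund

Estimating **where a species occurs** and **how many individuals there are**
at a national scale, from two data sources that almost never line up:
presence-only occurrence records reported on a metric grid at mixed
resolutions, and a handful of published, geo-referenced density estimates.
`sdm2abund` implements a systematic two-stage pipeline for this problem,
aimed at ecologists and wildlife-management analysts who need transparent,
reproducible abundance bounds rather than expert guesses.

## The method

**Stage 1 — habitat suitability.** Occurrence records are quality-controlled
against a land boundary buffered by each record's own positional uncertainty
(100 m / 1 km / 2 km / 10 km), filtered so that every record on the working
grid carries equivalent uncertainty, and rasterized into effort, occurrence
and last-decade maps. For each of *R* = 100 repetitions the pipeline draws
fixed-size pseudo-absences from unoccupied land cells (500 at 10 km, 5000 at
1 km), holds out 25% of the presence/absence set, fits seven suitability
models — Bioclim, Domain, Mahalanobis distance, a binomial GLM with AICc
subset selection, random forest, an RBF support-vector machine, and a
MaxEnt-style penalized logistic model on expanded features — and scores them
by the rank AUC

> AUC = (#concordant pairs + ½·#ties) / (n₊ · n₋)

on the test set, after correcting for spatial sorting bias by
distance-matched subsampling of test absences whenever test presences sit
systematically closer to the training data. The best model per repetition is
thresholded at the value maximising sensitivity + specificity (maxSSS), and
map and threshold are min–max standardized to [0, 1]. The ensemble output is
the per-cell mean suitability s̄ᵢ, the mean threshold t̄, and the per-cell
relative standard error of the mean as a stability diagnostic.

**Stage 2 — abundance bounds.** Survey polygons are burned onto a fine
(25 m-style) land grid, most recent survey winning on overlap, then
aggregated to the working grid under two bracketing assumptions: unsurveyed
land contributes zero (minimum) or is representative of the surveyed pixels
(maximum). For cells predicted present (s̄ᵢ ≥ t̄) each bound's densities are
regressed on suitability through a cascade — Shapiro–Wilk normality gate at
α = 0.1, Box-Cox power transform λ ∈ [−2, 2] by profile likelihood if
rejected, GLM families (Gaussian / gamma / Poisson, by AIC) if rejected
again; on the normal branch, generalized least squares with spatial
correlation structure ∈ {none, Gaussian, exponential, spherical} and
suitability polynomial degree ∈ {1, 2} compared by AICc. Predicted density
times per-cell land area (from the fine land mask), summed over cells, gives
the national total for each bound. Tables larger than 2000 rows are fitted
on 10 random 2000-row subsets and averaged.

Everything runs on seeded synthetic landscapes with known truth, so the
whole pipeline is testable end to end without any restricted data.

## Worked example

```python
from sdm2abund.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(scenario="linear-uniform", seed=7,
                                 n_reps=10, out_dir="run_output"))
print(round(summary["true_total"]),
      round(summary["abundance"]["total_min"]),
      round(summary["abundance"]["total_max"]))
```

prints

```
1248956 178776 1005323
```

meaning: the generated species truly has ≈1.25 M individuals; the pipeline's
lower bound (unsurveyed land counted as empty) is ≈0.18 M and its upper
bound (surveyed densities taken as representative) ≈1.01 M. The upper bound
sits slightly below the truth because cells under the suitability threshold
are assigned zero abundance while the generating species keeps a small
density in marginal habitat — the run directory's `summary.json`,
`model_selection.csv` and GeoTIFF maps record exactly which model produced
each bound. The same pipeline is available from the shell:

```bash
sdm2abund run --scenario linear-uniform --seed 7 --out-dir run_output
```

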