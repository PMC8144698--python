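# Methods

## Problem setting and analysis windows

The pipeline quantifies how surface concentrations of NO₂, SO₂, CO and 8-h O₃
changed during a lockdown window — January 23 to March 31 of a target year —
relative to the same calendar window of the two preceding years, and converts
the NO₂ and O₃ changes into premature-mortality differences. Windows are
aligned by calendar date: the window holds 69 days in a leap target year and
68 otherwise, and Feb 29 exists only where the calendar provides it. In
weekly comparisons, days are paired on the window-relative index 1..68 and
the leap day joins the target side of the last (tenth) bin; in window means
it is simply part of the target window. Both choices are configurable.

## Satellite quality control and regridding

Retrieval pixels are discarded when cloud radiance fraction > 0.5, terrain
reflectivity > 30 %, solar zenith angle > 85°, or the pixel lies in a
row-anomaly column. All four rules are strict inequalities, so boundary
values are retained; a pixel violating several rules is counted under each
rule but removed once, and removal is idempotent. Removed pixels become NaN —
never zero, since zero is a valid retrieval.

Regridding computes, for each target cell, the overlap-area-weighted mean of
contributing non-missing pixels. Pixels are axis-aligned rectangles, so the
spherical overlap factorises into a sin(latitude) interval overlap times a
longitude interval overlap; this makes the operation exact (verified against
a polygon-intersection oracle to 1e−10) and mean-conserving under complete
coverage. Cells with no contributing area are NaN.

## Feature assembly

Each station-day becomes one row: observed concentration (target), the QC'd
satellite value of the containing cell, the eight meteorological covariates,
elevation, population density, five land-use class fractions, a 1-based
day-of-window index, and the year label (used only for fold construction,
never as a predictor). Stations map to cells by the half-open convention
[edge, edge + resolution); stations outside the grid are dropped with a
logged count. Satellite gaps left by QC are filled with the cell's window
mean over the same year's available days plus a missing-data indicator
column; filling (rather than dropping rows) keeps by-year folds balanced.

## Random-forest estimation and validation

A RandomForestRegressor (scikit-learn) maps covariate rows to concentrations.
Defaults: 500 trees, max_features = 1/3 of the predictors (the classical
regression default), unlimited depth, one CPU thread; all exposed in config.
Two training presets exist:

* **per_year** (default): one model per pollutant and year, each predicting
  its own year's grids. Regression trees shrink predictions toward the
  training-set mean, so a pooled model systematically compresses
  between-year contrasts — on the default scenario a pooled fit recovered
  −16.4 % for a −20 % injected decrement, a per-year fit −19.7 %. Per-year
  fits also match how multi-year studies of this kind report per-year skill.
* **pooled**: one model per pollutant across all years, used for pooled
  cross-validation experiments.

Skill metrics are computed on pooled held-out predictions: R² is the
coefficient of determination 1 − SS_res/SS_tot (not squared Pearson
correlation), with a zero-variance truth flagged as undefined rather than
raised; RMSE and MAE are in concentration units. Two schemes are
implemented: sample-based 10-fold cross-validation (random partition, fold
sizes differing by at most one, every row held out exactly once) and
leave-one-year-out cross-validation. Because trees cannot extrapolate beyond
the training target range, a year whose levels fall outside the other years'
range scores visibly worse by-year than 10-fold — the diagnostic the by-year
scheme exists to provide.

## Exposure change statistics

The baseline grid is the unweighted mean of the two baseline years' window
means. Percent change over a region is
100 · (mean_w(target) − mean_w(baseline)) / mean_w(baseline), where mean_w is
area-weighted by default (concentration changes) with population weighting
available for exposure-oriented sensitivity. Negative values are decreases.
A uniform scaling of the target by a factor f reports exactly 100(f−1) % for
every region and weighting. Weekly series use consecutive 7-day bins from
the window start (last bin short), the same weighted means per bin.

## Health burden

Attributable deaths per cell: M = y₀ · (d/365) · (1 − 1/exp[ER · max(C − C₀, 0)]) · Pop,
evaluated on the window-mean concentration grid per year (one burden per
period; a day-wise mode that applies the formula per day at y₀/365 and sums
is available for sensitivity). Choices worth stating:

* **Threshold truncation.** The raw formula goes negative below C₀; the
  default truncates at zero (standard attributable-burden practice), and a
  flag restores the untruncated form.
* **Window scaling.** Annual baseline rates y₀ scale by window_days/365 —
  the only construction consistent with an annual rate and a window-total
  death count.
* **Uncertainty.** Burden bounds substitute the ER interval endpoints;
  concentration and population are treated as fixed, so the interval width
  is driven entirely by the ER confidence interval. When an ER interval
  straddles zero (as for the ozone respiratory-disease and COPD coefficients
  in the shipped defaults), the burden and delta intervals straddle a sign
  change.
* **Parameters.** ER and y₀ live in an editable YAML file
  (`src/airburden/data/health_params.yaml`). The shipped values are
  illustrative defaults in the range of published Chinese time-series
  meta-analyses, declared per 10 µg/m³ and rescaled on access; they are not
  authoritative epidemiology. C₀ defaults: NO₂ 40 µg/m³, 8-h O₃ 100 µg/m³.

The lockdown delta is mean(burden 2018, burden 2019) − burden 2020, applied
to the central estimate and to each bound; positive = avoided deaths.
Region totals are sums over masked cells, hence exactly additive over
disjoint masks; burden tables never sum across causes (they overlap).

## Synthetic scenario generator

The generator emulates the study's data stack with known truth:

* **Latent truth** per pollutant: a static sum-of-Gaussian-bumps surface
  (six bumps, floored so every cell is strictly positive, normalised to the
  configured national level) times a smooth within-window trend (±15 %), a
  weekend factor (0.92) and a year level. Inside the target-year window the
  field is multiplied by (1 − decrement), exactly, so the decrement identity
  holds cell by cell. Defaults: NO₂ 30 µg/m³ with a 0.20 decrement, SO₂ 15
  with 0.26, CO 1.0 mg/m³ with 0.07, O₃ 80 µg/m³ with decrement 0 and a
  +1.3 % target-year level (the spec of an *increase* cannot be expressed as
  a decrement in [0, 1)). Year levels are otherwise neutral so the injected
  decrement is the only between-year difference.
* **Stations**: 200 sites sampled with probability proportional to
  population (uneven network), observing truth at the containing cell plus
  zero-mean Gaussian noise (10 % of the national level), floored at zero
  with floored values kept.
* **Satellite**: pixels on a 2× finer grid; value = gain·truth + offset +
  smooth daily bias + white noise (both at 5 % of level by default). QC
  metadata is drawn so a configured fraction (5 % per threshold rule)
  violates each rule, plus fixed anomaly columns; the union of injected
  violations is recorded per pixel, giving filter tests exact ground truth.
* **Meteorology**: eight variables at plausible physical scales; a
  configured subset mixes per-cell-standardised truth with smooth noise at a
  correlation knob (default 0.5), so the model has secondary signal; knob 0
  gives independence.
* **Statics**: smooth lognormal population density (~400 km⁻²), smooth
  elevation, Dirichlet-like land-use fractions; four rectangular toy regions
  plus a national mask.

All draws descend from one integer seed through a fixed
`numpy.random.SeedSequence` spawn order; regeneration is bit-identical.

What the generator does **not** emulate: orbital geometry and swath gaps,
averaging kernels, chemistry (no NO₂–O₃ anticorrelation mechanism), spatially
correlated station noise, and real regional geography. Passing recovery
tests therefore demonstrates correctness of the pipeline's accounting and
the estimator's behavior under the stated observation model, not performance
on real retrievals.

## Problem sizes and numerical choices

The default scenario is a 40×40-cell 0.25° grid with 200 stations and three
years (≈41,000 training rows per pollutant) — large enough for stable
recovery statistics while a full run completes in minutes on one CPU. Tests
and the acceptance script use this default for end-to-end recovery; repeated
cross-validation experiments run on smaller grids and fewer trees (50–150),
since CV refits 10–13 forests and tree count affects variance, not the
recovery bias under study. Tolerances: exact identities are asserted
bitwise or at 1e−12/1e−10 relative (floating-point accumulation); stochastic
recovery uses ±3 percentage points on the injected −20 % decrement and ±0.05
on R² comparisons. The concentration-response factor is evaluated literally
as 1 − 1/exp(·); ties in station-to-cell assignment follow the half-open
interval convention; degenerate inputs (zero-variance targets, empty masks,
zero-area pixels, missing QC metadata) raise or flag rather than silently
pass.

## Pipeline mechanics

Seven stages (simulate, qc, assemble, train, predict, change, health) write
artifacts under the output directory with a JSON manifest of per-stage
input/output hashes, seeds and wall times. The master seed expands to stage
seeds by a fixed SeedSequence spawn order, so stages re-run independently;
completed stages are skipped unless forced, which provides resume semantics.
NetCDF I/O uses xarray's scipy backend (NetCDF3 classic). Exit codes: 2 for
configuration errors (all violations reported at once), 3 for stage
failures, 4 for I/O errors.

## Known limitations

* Grid cells are treated as exchangeable samples; no spatial autocorrelation
  correction in CV (no buffered/spatial folds).
* The burden interval ignores concentration-model uncertainty and population
  uncertainty; it is an ER-CI interval only.
* The 8-h O₃ station metric is taken as given, not derived from hourly data.
* No meteorological normalisation of the change signal: the comparison is
  raw year against years, so weather differences between years alias into
  the "lockdown" change on real data (the synthetic meteorology is
  year-stationary, hiding this).
* Pixel geometry is restricted to axis-aligned rectangles; real swath
  footprints would need a polygon-overlap regridder.
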