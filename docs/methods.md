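# Methods

## Problem setting

The pipeline estimates relative changes in city populations from changes
in car counts detected in very-high-resolution (0.3–0.5 m GSD) satellite
imagery. It assumes that within a city the relationship between resident
population and visible cars, estimated in a baseline year, still holds in
later periods, so that a change in gridded car counts is informative
about a change in gridded population. All computation happens in a planar
metric frame (meters); real data must arrive in a metric projected CRS.

## Data model and screening

Detections are points with a confidence score and class label; only the
"small car" class enters the pipeline (other classes are dropped with a
logged count). Images carry a footprint polygon, acquisition timestamp
(UTC), GSD, off-nadir angle, sun elevation, cloud fraction and snow flag.

Screening applies, in order, with every dropped image retained in the
report with its reason:

1. **Ingest contract** — an image must cover ≥ 1% of its AOI's area.
2. **Cloud** — images with cloud fraction ≥ 0.95 are treated as fully
   obstructed and dropped; fractions in [0.5, 0.95) keep the image but
   flag it for review. This automates what is otherwise a visual
   inspection step; the thresholds are configurable.
3. **Population representativeness** — the coverage index is the percent
   of the AOI's baseline population under the footprint, with boundary
   fine cells apportioned by intersection-area fraction (unbiased under
   uniform within-cell density). Images under 50 are dropped. The index
   is kept on the 0–100 percent scale so the drop rule reads "< 50".
4. **Low counts** — kept images with fewer than 10 filtered detections
   are flagged suspicious (possible haze/obstruction), not dropped.

False-positive filtering removes every detection inside (or on the
boundary of — removal is conservative) a tagged exclusion polygon.
Exclusion layers are consumed as GeoJSON with OSM-style key/value tags
(keys among landuse, place, natural, leisure, aeroway); live map queries
are out of scope.

The confidence threshold is tuned by sweeping τ from 0 to 1 in steps of
0.05 (21 thresholds) and maximizing F_0.5 against ground-truth points.
Detections are matched to truth one-to-one, greedily by distance, within
2.5 m (about half a car length) — a deterministic, resolution-appropriate
rule chosen because box-IoU matching is unavailable for point output.
Ties on the maximal F_β resolve to the largest threshold, leaning toward
precision as the β = 0.5 choice intends. The production default
threshold is 0.45.

## Gridding and car dynamics

Analysis cells are 1 × 1 km squares snapped to multiples of 1000 m in the
world frame, so cell identities are stable across periods and runs; cells
not intersecting the AOI are excluded, and baseline people per cell come
from area-weighted aggregation of the 100 m population raster.
Detections are assigned by half-open intervals `[x0, x0+1000)` so edge
points land in exactly one cell. A cell counts as covered by an image
when ≥ 50% of its area (configurable) lies inside the footprint — sliver
coverage would otherwise bias monthly means low. Monthly cell means
average over covering images only; uncovered cell-months are absent,
never imputed as zero.

Car-density change per city is the percent change of mean monthly
density (cars per covered km²) in a target period versus the baseline
year; target months before the war cut date (default 2022-02-24) are
excluded, and quarters are calendar quarters. Oblast-level change
averages the oblast's city densities first and then takes the change.
Units lacking data on either side are reported missing with a reason.

## Estimation

Comparisons use matching months (calendar months present in both the
baseline and a comparison year; cities with none are excluded with a
reason) and matching cells (cells in the pooled baseline table that are
also covered in the comparison month). Baseline pooling averages each
cell's monthly mean cars over its available baseline months.

**Ratio estimator.** `r_z = y_z / x_z` where `x_z > 0`; zero-car cells
borrow the median of the city's defined ratios. The median is computed
per city, not across cities, because car ownership and parking structure
differ between cities; a cross-city median is a one-line configuration
change. Predictions are `r_z · x'_z`; the city level is the exact cell
sum.

**Smooth Poisson regression.** `Y_z ~ Poisson(exp(β₀ + f(x_z)))` with a
penalized cubic B-spline basis (default dimension 10, reduced when a
city has few distinct car values), fitted by penalized IRLS via
statsmodels. The pooled people response is a non-integer average; it is
fitted through the Poisson log-likelihood as a quasi-likelihood, and the
dispersion is reported. The smoothing weight is selected automatically
by minimizing AIC with a deterministic Nelder–Mead search (a stochastic
global search would make reruns non-reproducible). Numerical edge
cases: constant car counts fall back to an intercept-only fit with a
warning; an exactly interpolable (noiseless) response, which the
penalized iteration refuses as perfect separation, falls back to the
unpenalized GLM on the spline design. Spline knots span the observed car
range; predictions outside it are evaluated at the nearest boundary
(constant extrapolation) and flagged `out_of_range`, because the
unconstrained basis tail otherwise produces astronomically wrong means —
in particular, empty cells below the observed range receive the smooth's
positive boundary mean, which is the regression method's characteristic
dampening of extreme changes. Prediction intervals are normal intervals
on the link scale from the penalized coefficient covariance. Fits are
summarized by deviance explained and a squared-correlation R²; cities
below an R² of 0.6 are labelled low-confidence but never suppressed.

## Imagery-feature model

Per kept image, log(detections / imaged km²) is regressed by OLS on GSD
(categorical, 0.3 m reference), snow (reference absent), off-nadir
angle, sun elevation and cloud fraction. Zero-detection images have no
defined log density and are excluded with a reported count; zero-variance
or rank-deficient designs abort naming the offending columns (via QR
pivoting). Diagnostics report Jarque–Bera and Shapiro normality,
Breusch–Pagan heteroscedasticity (flagged below 5%), the |residual|-vs-
fitted trend slope, and the lag-1 residual autocorrelation in
acquisition-time order. The model is linear in off-nadir angle by
construction; any detectability optimum at intermediate angles is not
captured.

## Synthetic world

The generator emulates the data the pipeline consumes, not imagery
pixels. Defaults describe a modest four-city study (two oblasts):

- **Population**: 25,000 people per 4 × 4 km city on a 100 m grid —
  mid-sized regional towns, small enough that a full run stays cheap —
  as Gaussian hotspots (3 per city, SD 700 m) over a 15% uniform floor.
  Exclusion areas (a water body, a forest block per city) are
  uninhabited; people are rescaled so city totals are preserved.
- **Link**: E[cars] = 0.05 · people per fine cell (one visible car per
  20 residents — of the order of visible parked-car densities in
  European cities), Poisson count noise, optional sub-linearity via a
  power exponent.
- **Imaging**: Poisson(2.5) images per city-month over months 3–7 of
  2019, 4–5 of 2020 and 3–6 of 2022; footprints are full-AOI with
  probability 0.4, otherwise uniform sub-squares covering 30–100% of the
  AOI; GSD ∈ {0.3, 0.4, 0.5}; cloud is zero for 60% of images, Beta(1,4)
  otherwise, and fully obstructing with probability 0.05; snow occurs in
  winter months and halves detectability. Detections thin by cloud
  transparency and the snow factor; truth annotations retain undetected
  cars so precision/recall sweeps are informative.
- **Contamination**: false positives follow a Poisson process (3 per
  km²) inside exclusion polygons, placed ≥ 5 m from boundaries so
  oracle tests are unambiguous; scores are Beta(2,5) (low-skewed)
  against Beta(8,2) for true cars.
- **Scenario**: the war year multiplies city populations by 1.5, 1.3,
  0.6, 0.35 from west to east (the two western cities receive people,
  the eastern pair empties), and the COVID year by 0.95 everywhere.

One seed drives everything through spawned substreams; identical
configurations produce byte-identical exports.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: detector biases that correlate with scene
content (shadows, building occlusion beyond the linear off-nadir term),
spatially correlated detection errors, within-year population dynamics,
war-time behavioral shifts in the car–people link (packed or hidden
cars), and non-rectangular stitched footprints.

## Validation summary

The recovery study (analysis/05, 20 replicates, 500-cell cities) checks
that a uniform 40% drop is recovered by both methods from Poisson car
counts (median estimates around −38%), that the regression method is
milder than the ratio method when cells empty entirely, and that empty
cells always receive a strictly positive regression prediction. The
ratio method is exact to machine precision in noiseless proportional
worlds under arbitrary displacement fields — its defining property.

## Limitations

- Estimates are relative to the baseline gridded population; absolute
  head counts inherit any baseline bias.
- Months with partial spatial coverage conflate displacement with
  coverage; the per-month area-coverage percentage is attached to every
  estimate and should accompany any interpretation.
- The two methods bracket informally; no formal interval covers the pair.
- City-level smooth fits with few usable cells (the 10-cell minimum is
  configurable) can be wiggly even with automatic penalization.
- The quasi-likelihood treatment of pooled means reports, but does not
  model, overdispersion.
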