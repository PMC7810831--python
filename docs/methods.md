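# Methods

`resptrend` implements a complete observational trend analysis for annual
soil-respiration (Rs) records of the kind curated in community flux
databases: record filtering, climate/SOC covariate matching, weighted
interaction modelling, moving-window and robust trend estimation,
homogeneity-test breakpoint detection, and Monte Carlo upscaling of
annual global Rs from gridded climate. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic test world does and does not establish.

## Record selection

Records pass, in order: (1) an annual flux value is present; (2)
coordinates and a decimal measurement mid-year are present; (3) the
ecosystem is non-agricultural and the record carries no experimental
manipulation; (4) the flux was measured by infrared gas analyzer (IRGA)
or gas chromatography (other methods — alkali absorption, soda lime —
systematically misestimate fluxes); (5) the calendar year (integer part
of the mid-year) lies in the study period, 1987–2016 by default, because
IRGA/GC were not in wide use earlier; (6) a single-pass outlier screen
removes fluxes beyond mean ± 3 SD of the surviving population. The
outlier statistics come from the already-filtered set by default (the
analysis population); a switch allows the pre-filter population for
sensitivity checks. Filtering only changes membership, never values, and
is idempotent. Each step's removal count is logged.

A record with a missing `Manipulation` entry is treated as
unmanipulated: in SRDB-dialect tables the field is filled with "None"
when curators verified the absence of treatment, and left blank when the
source did not discuss treatments at all; both are overwhelmingly
unmanipulated sites, and treating blanks as manipulated would discard
usable natural-ecosystem records.

## Covariates

MAT and MAP are averaged over the record's measurement window: the
window spans `[mid_year − d/2, mid_year + d/2)` for duration `d` years,
discretized to `round(12 d)` months (an 18-month record gets the
18-month mean temperature); MAP is the window precipitation total
rescaled to an annual rate. Grid lookup is nearest cell centre, no
interpolation — the climate source is already a cell average.
Anomalies are deviations from the per-cell reference means,

    dMAT = MAT − mean(MAT, 1987–2016 at the cell),   likewise dMAP,

computed over all calendar years of the reference period (not only
years with records at the site; a switch is unnecessary because the
reference means are per cell, so the default is the better-sampled
estimate). SOC stock (topsoil, 0–30 cm, Mg ha⁻¹) is nearest-cell; cells
missing from the grid get the median SOC of same-ecosystem records with
an `soc_imputed` flag. Annotation never drops records.

## The weighted interaction model

The interaction model regresses Rs on year and year² plus measurement
method, latitude, altitude, developmental stage, ecosystem, SOC, biome,
and the climate covariates MAT, MAP, dMAT, dMAP, with year ×
{method, latitude, altitude, stage, ecosystem, SOC, biome} and
{MAT × MAP, dMAT × dMAP} × biome interactions; Rh/Ra variants add the
partitioning method and its year interaction. Weights are the record's
years of observation — a multi-year mean is a steadier estimate of the
site's annual flux, and the weight is the most direct measure of that
(configurable to unweighted).

The ANOVA is sequential (Type I): the weighted sum of squares is
attributed to terms in design order, so per-term SS depend on the order
while their total does not (conservation is tested). Term order follows
the degree-then-appearance convention of R-style model formulas (main
effects, then two-way, then three-way interactions), which is what an
`anova()` on a fitted linear model reports. Categorical factors are
treatment-coded with the alphabetically first level as reference; Type I
F tests are invariant to this choice, individual coefficients are not.
Year is centred at the period start before squaring — pure conditioning,
F tests unaffected. Factor levels observed fewer than `min_level_n`
times are merged into "other" with a warning (a level entering k
interaction terms needs at least k linearly independent records, and a
level whose few records share one or two sites is exactly aliased); if
the merged bucket is itself rare it is absorbed into the modal level.
Rank-deficient designs raise an error naming the aliased columns rather
than silently pseudo-inverting.

Per-period trend regressions (early/late period, biome groups, window
subsets) are plain unweighted OLS of Rs on calendar year, with the
Theil–Sen estimator — the median of all pairwise slopes, breakdown point
≈ 29% — reported alongside as the robust check.

## Moving subset windows

One-dimensional overlapping windows advance along (a) measurement year:
10-calendar-year spans stepping 1 year from the earliest record year;
(b) signed latitude: 30° spans stepping 1° from the data minimum rounded
down (the origin is data-driven, so the window count is a property of
the sample, not a constant); (c) SOC stock: 60 Mg ha⁻¹ spans stepping
10 Mg ha⁻¹ from 0 with an upper cap of 380 Mg ha⁻¹ (richer soils are too
sparsely sampled — fewer than 10 records per window — to support a
slope). Intervals are closed on both ends; a boundary record belongs to
every window covering it. Within each window the Rs-vs-year OLS slope,
p-value and Theil–Sen slope are computed; windows with fewer than
`min_n = 10` records are flagged `low_n`, and windows whose records all
share one year are flagged `degenerate` — flagged windows stay in the
output with their n.

## Breakpoint detection

Candidate breakpoint years 1996–2015 are tested by exhaustion: for each
candidate y the "first-period slope" is the OLS slope of Rs vs year over
[1987, y]. Three homogeneity tests locate the change in that candidate
series: Buishand range (rescaled range of adjusted partial sums,
R/√n with R = (max S_k − min S_k)/s), Buishand U
(U = [n(n+1)]⁻¹ Σ_{k<n} (S_k/s)²), and the Standard Normal Homogeneity
Test (T = max_k [k z̄₁² + (n−k) z̄₂²] on standardized values). All three
are invariant to shifting and scaling the series. Critical values are
not read from published tables; p-values for the standalone statistics
come from ≥10,000 simulated iid standard-normal series of the same
length, seeded.

Two measured properties shaped the detection design:

1. **The tests are applied to the year-over-year increments of the
   slope series, not to the series itself.** Partial-sum homogeneity
   tests locate level shifts. A trend breakpoint does not produce a
   level shift in the truncated-regression slope series — it produces a
   gradual bend (the slope over [1987, y] dilutes slowly as post-break
   years accumulate), and the argmax of |S_k| on such a ramp sits where
   the series crosses its mean, ~5 years late on this series class
   (measured on noise-free data). In the increment series the bend is a
   level shift, and localization is sharp. The raw-series and
   annual-mean-Rs modes remain available as switches.
2. **The split index is mapped back with a one-element correction.**
   The increment at the first post-break candidate is attenuated — a
   single off-trend year has almost no leverage in a regression over the
   whole window — so the partial-sum argmax sits *at* the corner element
   rather than before it (verified exactly on noise-free series). The
   detected split k therefore identifies `candidates[k]` as b + 1, one
   past the first late-regime year b, and the reported pair is
   `(b − 1, b)`.

P-values inside `detect_breakpoint` use a pipeline-level permutation
null rather than the iid-normal null: increments of nested-window slope
estimates are heteroscedastic (early windows are small, so early
increments are noisier) and serially correlated, and the iid null
over-rejects badly for SNHT (measured 9/20 at α = 0.05 on single-trend
data). Permuting Rs values across records destroys the year association
while preserving per-year sample sizes, so re-deriving the slope series
on permuted records reproduces the nesting covariance under H₀;
rejection rates are then near nominal (measured 1–2/20). The standalone
test functions keep the classical iid-normal simulated nulls.

The consensus breakpoint is the year pair reported by at least two of
the three tests; a three-way disagreement returns no consensus, with all
three positions reported. Calibration, measured over 100 seeded
datasets at the study scale (~2,400 records, late-heavy sampling 1:3,
per-record noise 100 g C m⁻² yr⁻¹, slope change 25 → 0 g C m⁻² yr⁻² at
year 2000): the consensus is within ±1 year of truth in 98/100 runs.
Localization degrades gracefully as the slope change shrinks relative
to the increment-series noise; with the full realistic record structure
(biome offsets, climate sensitivity, noise 250) single runs typically
land within ±2 years.

## Upscaling

The climate model regresses √Rs on MAT, MAT², MAP, MAP², MAT×MAP,
MAT×dMAT and MAP×dMAP (the square root stabilizes the variance of
strictly positive skewed fluxes; negative Rs is a domain error).
Stepwise AIC selection runs in both directions from the full model,
respecting marginality: a square or interaction may stay only while the
normals it involves stay (the anomalies enter only through interactions,
so they require just the corresponding normal). Exact zero-residual fits
make AIC degenerate (log 0); such fits are ranked equal and the tie is
broken by parsimony. Note AIC is not selection-consistent: a single
irrelevant covariate is dropped with asymptotic probability
P(χ²₁ < 2) ≈ 0.84, and the tests assert that rate, not certainty.

Monte Carlo uncertainty: each of `n_trials = 1000` trials draws every
coefficient independently from normal(mean, SE). Independent sampling
ignores coefficient covariance and therefore *overstates* predictive
variance when coefficients covary (they do, strongly, between a normal
and its square); a correlated mode drawing from the joint multivariate
normal is provided and documented as the tighter alternative, but the
independent mode is the default because it is the plainer reading of a
per-parameter mean-and-SD description.

Per trial and year, the sqrt-scale linear predictor is evaluated on
every land cell from that year's MAT/MAP and anomalies (per-cell
1987–2016 reference means, consistent with the covariate module),
clamped at zero before squaring — squaring a negative predictor would
fabricate positive flux where the model predicts none; the clamp count
is logged. Cell areas: the default mode evaluates
A = R² Δλ Δφ cos(φ_upper) at the cell's upper latitude edge (hemispheric
biases cancel in a global sum, within 0.1% of exact); the exact
spherical-band mode A = R² Δλ (sin φ_u − sin φ_l) conserves 4πR² to
machine precision. The unit chain g C m⁻² yr⁻¹ × m² × 10⁻¹⁵ = Pg C yr⁻¹
is covered by a closed-form single-cell test.

Period trends of global Rs pool all (trial, year) points into one
regression, so 12 years × 1000 trials gives residual df = 11,998. An
exactly linear zero-variance series reports an infinite t with p = 0
rather than dividing by zero.

## The synthetic world

The generators produce an SRDB-dialect record table, a monthly 2°
climate grid (latitudinal base profile, 0.18 °C/decade warming trend,
per-cell-year anomalies of 0.3 °C, seasonal cycles that sum to zero over
a calendar year so annual means follow the trend exactly), an SOC grid
increasing toward high latitudes with 4% missing cells, and a Bernoulli
land mask. Each record's flux is an exact sum of components — base 700 g
C m⁻² yr⁻¹, biome offset, piecewise-linear trend (27.66 g C m⁻² yr⁻²
before year 2000, flat after, mirroring the magnitude of the early-period
rise reported for the real record base), climate term (55 g C m⁻² yr⁻¹
per °C of annual temperature anomaly, consistent with a Q10 ≈ 2 response
at the base flux), and Gaussian noise (250 g C m⁻² yr⁻¹, truncated so
fluxes stay positive; the realized draw is stored, so components still
sum exactly). Defaults of 600 sites × 4 records ≈ 2,400 records with a
1:3 early-to-late sampling ramp mirror the scale and temporal skew of
the real filtered record base. Contamination (agricultural sites,
manipulated plots, non-IRGA/GC methods) is injected at 5% each to
exercise the filters. Biomes are assigned by absolute-latitude band
(tropical < 23.5°, subtropical 23.5–35°, temperate 35–55°, boreal
55–66.5°, Arctic ≥ 66.5°) with a Mediterranean longitude box carved from
the temperate band.

What passing tests on this world establish: the machinery — filters,
matching, estimators, detectors, upscaling — recovers known structure
exactly (noise-free) or within stated statistical tolerance. What they
do not establish: anything about real-world sampling bias (no spatial
clustering or mid-latitude over-representation beyond the temporal
ramp), measurement error structure (noise is additive Gaussian, real
flux errors are heteroscedastic and site-correlated), ecological
covariance between SOC, biome and climate, or the real breakpoint year —
the published headline numbers can only be reproduced from the real
pinned record base and climate/SOC grids, which are external downloads.

## Problem sizes

Routine runs use a 6° demonstration grid with ~2,400 records (seconds);
the calibration experiments use a 15° grid for record generation (the
climate enters only through per-cell annual anomalies) and a 2° grid for
the upscaling recovery; homogeneity-test calibration uses 10,000
simulated null series per batch; breakpoint recovery uses 100 seeded
datasets; upscaling recovery uses 200 Monte Carlo trials against the
closed-form truth integral. These sizes are the package's test
conditions, chosen so the whole suite completes in well under an hour on
one CPU while keeping every statistical assertion comfortably powered.

## Known limitations

- Nearest-cell climate matching ignores sub-cell topography; the
  altitude covariate enters the interaction model but not the climate
  lookup.
- The permutation null for the breakpoint p-values conditions on the
  observed per-year sample sizes; it does not model site-level
  clustering of records.
- Stepwise AIC explores single add/drop moves greedily; with strongly
  collinear candidates the path can stop at a local optimum.
- The upscaling applies a point-record regression to cell-mean climate
  (an aggregation approximation); no land-cover weighting is applied
  beyond the binary mask.
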