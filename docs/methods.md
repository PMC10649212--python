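# Methods

## Problem setting

Broiler chickens raised to 35 d in open-sided tropical housing experience
house temperatures and humidities that swing around the age-specific
recommendations for the breed.  Rather than summarising the environment by
daily means or extremes, this package counts *exposure hours*: for every
flock and every age window, the number of hourly records whose temperature,
relative humidity (RH) or thermal-humidity index (THI) falls outside the
recommended band for that day of age.  Exposure hours are then related to
weekly live performance (body weight BW, BW gain, feed conversion ratio FCR,
weekly and cumulative mortality) by correlation screening and simple linear
regression; farm survey attributes are analysed by per-variable clustering
plus one-way ANOVA; and early performance plus farm attributes feed three
cross-validated predictive models with matched variable-importance methods.

## Target schedule and THI

The recommended house temperature is a per-day step function built by linear
interpolation between anchor ages; the default brooding curve runs from
30 °C at day 0 to 21 °C at day 27 and is constant thereafter.  Breed-company
management tables are licensed material, so the schedule is plain data:
fully configurable, serialised as CSV, and every test pins its own anchors.
The ideal band is the recommendation ±1.5 °C (configurable half-width); RH
limits default to 50–75 %.

The THI is bilinear in temperature and RH:

    THI = 3.43 + 1.058·T − 0.293·RH + 0.0164·T·RH + 35.7

The two additive constants are kept as printed in the source equation even
though only their sum matters numerically; whether the `+35.7` is a
transcription artifact of the original index literature is left open, and
the coefficients are overridable in configuration.  Because the index is
bilinear, its extrema over the rectangle (t_rec ± halfwidth) × (rh_low,
rh_high) sit at the four corners; the per-day THI bounds are the corner
minimum and maximum, verified in tests against a dense grid search.

## Exposure accounting

Hourly records from the (typically two) sensors of a house are averaged per
house-hour; hours with one sensor pass through, hours with three or more are
averaged and counted in the output.  Records are aligned to hours of age
0–839 from placement (half-open 840-h window, floor arithmetic, 0-based
ages).  QC drops a flock when fewer than `completeness_min × 840` hours are
observed (default 0.995) or any reading is physically implausible
(temperature outside −5…45 °C, RH outside 0–100 %).

Exposure uses strict inequalities — an hour is below the band at depth d
when `t < t_rec(age) − d`, with d ∈ {1.5, 2.5, 5, 7} °C — so a reading
exactly on a boundary is in-band; the study's counting convention for
boundary ties is not documented, and strictness was fixed once here.
Counts are produced for weekly windows [0,7)…[28,35) and cumulative windows
[0,7)…[0,35), over observed hours only.  Invariants (band nestedness,
weekly-to-cumulative additivity, the in/below/above partition at d = 1.5)
and a per-hour brute-force oracle are enforced in the test suite.

## Association stage

For every response × age × band × window cell of a fixed grid (weekly and
cumulative-to-age windows), the Pearson correlation is computed with a
two-sided t-test; cells with p < α (default 0.05) get a simple OLS fit of
the response on exposure hours.  The closed-form estimators (slope =
Sxy/Sxx, rmse = √(SSE/(n−2)), adjusted R²) are implemented directly and
cross-checked against statsmodels to 1e−10 in the tests.  No
multiple-testing correction is applied by default, matching the screening
protocol the package reproduces; Benjamini–Hochberg is available as an
option.

## Farm factors

Continuous survey variables are clustered one variable at a time by
k-means.  Because the clustering is one-dimensional, the within-SS optimum
is computed exactly: optimal 1-D clusters are contiguous runs of the sorted
values, so dynamic programming over split points finds the global optimum
that multi-start Lloyd iteration only approximates (the exhaustive-partition
equivalence is property-tested).  The number of clusters is chosen with an
information-criterion surrogate for a 1-D k-means fit,

    AIC = n·ln(wss/n) + 2k,   BIC = n·ln(wss/n) + k·ln(n),

selecting the lowest BIC with ties to smaller k and reporting both.  This
surrogate is an approximation (the statistical package originally used for
this analysis does not publish its formula) and has a known limitation: for
continuous noise the likelihood term always rewards splitting, so it
discriminates mainly through feasibility and near-degenerate fits; the
`wss` is floored at 1e−12 before the logarithm.

Cluster labels (or categorical factor levels) enter a fixed-effects one-way
ANOVA on 35-d BW, FCR and cumulative mortality.  The pooled SEM uses the
harmonic mean of group sizes; CV% is 100·√MS_within over the grand mean.
Mean separation uses Tukey's HSD (studentized range, Tukey–Kramer for
unequal n) when there are more than two levels and Student's t when exactly
two — the source protocol names both without a rule, and this split is the
conventional reading.  Letters are assigned with the insert-and-absorb
compact-letter-display algorithm and renamed so 'a' marks the highest mean;
the display satisfies "share a letter ⇔ not significantly different", which
is property-tested on random instances.

## Prediction stage

Predictors are performance at 7/14/21 d, sex, and farm attributes;
responses are BW or FCR at 35 d.  Categoricals are dummy-coded against the
alphabetically first level and all columns are min-max scaled to [0, 1].
Inside k-fold cross-validation (default k = 5, folds differing by ≤1 row),
encoding, scaling and variable selection are fitted on the training folds
only and frozen for the held-out fold — a held-out value below the training
minimum scales below 0 by design.  A global normalisation would leak
held-out information into training; this deviation from a whole-table
normalisation is deliberate and tested (scrambling held-out responses does
not change held-out predictions).

* **MLR** drops the highest-VIF predictor while any VIF exceeds 10, then
  backward-eliminates by largest p ≥ 0.05.  Variable contribution is the
  partial (Type III) sum of squares over the model sum of squares in
  percent — partial rather than sequential for order invariance; the two
  coincide for orthogonal predictors.
* **RF** is a bagged regression forest; `mtry` (max features per split) is
  chosen from a small grid by CV mean RMSE.  Permutation importance is
  computed on out-of-bag rows: per variable, the column is permuted and the
  OOB MSE recomputed; the score is the percent increase in OOB MSE averaged
  over `n_reps` (default 10) permutations.  The per-tree bootstrap draws
  are reconstructed from each tree's random state and verified against the
  library's own OOB predictions.
* **ANN** is a single-hidden-layer sigmoid network trained by L-BFGS with
  weight decay (default 1e−3) and best-of-restarts initialisation; the node
  count comes from a grid by CV mean RMSE.  The response is scaled to
  [0, 1] for training and back-transformed for RMSE.  Non-convergence after
  all restarts is flagged on the model, not raised.  Importance is Olden's
  connection-weights measure: for input i, Σ_h w_ih·w_hO, signed and ranked
  by magnitude (exactly linear in the output-layer weights).

## Synthetic data generator

Real records of this kind are proprietary, so the generator emulates their
structure; its defaults are the study conditions: 80 flocks across 29
farms, 35-d cycles (840 hourly records per flock), two sensors per house.

* **Environment.**  True house temperature is the age target plus a diurnal
  sinusoid (amplitude 2 °C, peak 15:00) plus N(0, 0.5 °C) noise; RH is
  anticorrelated with temperature within the day (mean 65 %, amplitude
  12 %, noise 3 %), clipped to the observed 30.32–92 % range.  Half the
  flocks (configurable) get a cold-night depression: night hours
  (22:00–05:00) lowered by a per-flock uniform fraction of 4 °C.  Sensors
  observe truth plus independent N(0, 0.3) noise.  *Excursions* are
  controlled deviations for experiment design: a per-flock uniform number
  of eligible hours in a window is pinned exactly at target + dt (cold
  excursions at night, warm in the afternoon; RH optionally pinned), giving
  a designed spread of exposure hours across flocks.  Excursion hours omit
  ambient noise so the offset relative to the band is exactly the one
  configured.
* **Survey attributes** are region-stratified draws matching the published
  descriptive tables: categorical frequencies (technification, hatchery,
  litter type, house/floor/water-storage composition, stories) and
  truncated-normal continuous draws (altitude, litter reuse, transport
  distance in km and h, downtime, farm area) bounded by the printed
  min/max.
* **Performance** is additive and linear in exposure hours: for each
  configured (response, window, band) effect, slope × hours is added to the
  response, where the hours are computed from the generated environment *by
  the package's own exposure engine*.  This closes the loop by
  construction: with zero noise the regression stage recovers every
  configured slope exactly (tested), and with noise within sampling error.
  Default slopes are the package's reference exposure-response table
  (e.g. BW@21 −4.91 g/h below the 5 °C band; FCR@21 +0.007 per THI-below
  hour; last-week mortality +0.028 %/h above the 7 °C band; cumulative
  mortality +0.018 %/h below the 2.5 °C band over 0–28 d).  Sex enters as
  an additive per-age offset (±90 g at 35 d for BW), farms as N(0, σ)
  offsets shared by their flocks, and weekly responses get Gaussian noise
  (defaults: BW 15 g, FCR 0.02, weekly mortality 0.05 %).  BW gain is the
  between-week BW difference (40-g chick weight) and cumulative mortality
  is the running weekly sum, so records are internally consistent.
  Cumulative-mortality effects are applied once to the weekly mortality of
  the week ending at the stated age, so every later cumulative value
  carries the slope exactly once.
* **Faults.**  A configurable fraction of houses (default 5 %) either lose
  10–50 house-hours or receive an 80 °C outlier burst; a manifest records
  each injection, and QC is expected to drop exactly the faulted flocks.

Determinism: one seed-sequence root spawns independent child streams per
flock and stage, so equal configs give bit-identical CSV output.

What the generator does **not** emulate: poultry-house heat balance and
ventilation physics, weather systems, spatially correlated sensor drift,
litter/disease dynamics, or nonlinear and interacting exposure responses.
Passing recovery tests therefore show that the pipeline correctly measures
exposure and recovers linear effects under the stated noise — not that
real-house effects are linear.

## Problem sizes and numerical choices

Recovery experiments use 100–150 single-sex, fault-free flocks with
cold-night depression off, isolating one excursion mechanism per
experiment; these sizes give slope standard errors of 2–3 % of the target
effects.  A known residual: hours below the THI bound correlate negatively
(r ≈ −0.5) with noise-driven crossings of the 2.5 °C band, biasing the
single-predictor THI slope downward by about 5 % — inherent to fitting
collinear exposures one at a time, and left visible rather than corrected.
Test-suite model fits use n of 60–150 rows, forests of 50–300 trees and
node grids up to 5, sizes at which every check is stable under the fixed
seeds.  Ties in k-means selection go to smaller k; constant predictor
columns are dropped with a warning; correlation of a constant vector,
regression on a constant design, ANOVA groups with n < 2, and R² of a
constant truth all raise errors rather than returning NaN.
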