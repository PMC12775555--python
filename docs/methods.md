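# Methods

`pinkfoot` implements the computational chain used to study how an
Arctic-breeding goose population tracks spring along a migration flyway:
extracting spring-onset dates from temperature and satellite-index series,
deriving migration and nesting phenology from GPS tracks, computing
percentile timing measures from mark–resight and count data, and running
the flyway-level statistical comparisons. Every stage can be exercised on
synthetic data with known ground truth; this note records the models,
parameter choices and their limits.

## Spring onset

Three measures are computed per site (or breeding subarea) and year.

**GDD-based onset.** Six-hourly site temperatures are averaged per day and
accumulated as growing degree days, `G(d) = Σ_{k≤d} max(0, T_k − T_base)`
with `T_base = 0 °C` (configurable). The onset is the day on which `G`
accelerates fastest, operationalised as the maximum of the third discrete
difference ("jerk") of the cumulative curve inside a search window
(default 1 Feb–31 Jul, a closed interval; "spring" is otherwise
unquantified). Because third differences amplify noise badly, `G` is first
smoothed with a 7-day centred moving average. Ties break to the earliest
day; a maximum at or below 1e-6 (e.g. constant temperature, hence linear
`G`) yields `no_event`. Two numerical consequences worth knowing:

* on a noiseless kink (flat, then linear ramp), the moving average turns
  the jerk spike into a plateau of near-equal values; the earliest-day tie
  rule then lands up to `(smooth_days − 1)/2` days early. The detector is
  therefore specified to grid-and-smoothing resolution, ±3 days at the
  defaults, not to the day.
* missing days contribute zero GDD and are logged; a series with more than
  20% missing days (configurable) is rejected rather than silently
  under-accumulated.

**Snowmelt and green-up.** Per-pixel NDSI/NDVI observations (~2-day
revisit) are smoothed with a penalized cubic smoothing spline whose
penalty is chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); a fixed penalty can be
supplied for bit-reproducible runs. Pixels with fewer than 10 in-window
observations are excluded. Snowmelt is the first day the smoothed NDSI
drops below 0.42, required to follow at least one day at or above the
threshold: pixels that never reach 0.42 were never snow-covered and are
excluded from aggregation (the protocol is silent here; exclusion avoids
biasing the site median toward early dates), while pixels that never drop
below it have no melt event that season. The site value is the pixel
*median* — the day half the snow-covered area is snow-free. Green-up is
the day of the largest day-to-day increase of the smoothed NDVI (ties
earliest, within float tolerance); the site value is the pixel *mean*.
The median/mean asymmetry between the two measures is deliberate and
follows the field protocol. Breeding-area onsets average the (six)
subarea values, degrading to `insufficient_data` when fewer than half the
subareas are valid. Subarea *dates* are averaged, not subarea
temperatures; the alternative reading is left to a config switch.

Windows: temperature 1 Jan–30 Sep; stopover indices 1 Jan–30 Jun;
breeding-area indices 15 Mar–15 Sep. Day-of-year is the canonical time
unit (1 Jan = 1, leap years by calendar conversion); fractional days
appear only after aggregation.

## Track phenology

A fix is **flying** at ground speed ≥ 15 km/h; with no recorded speed the
great-circle displacement to the previous fix over the elapsed time is
used. All distances are WGS84 great-circle (haversine); coordinates are
never projected. A **stopover visit** spans the first to the last calendar
day with a non-flying fix within the site radius (default 75 km, inside
the documented 50–100 km band); separate residency bouts therefore merge
into one visit. **Breeding-area arrival** is the first day any fix lies
strictly beyond latitude 76.5640° (Svalbard) or longitude 51.4432°
(Novaya Zemlya).

**Nest detection.** Days with fewer than 8 fixes (half the nominal 16/day)
are excluded. For each remaining day the non-flying fixes are clustered:
the reference is the fix with the most neighbours within the stationarity
radius (100 m), and the day's stationary fraction is the share of the
day's fixes in that cluster. Using the densest cluster rather than the raw
component-wise median matters when nest and foraging fixes split a day
evenly — the median then falls between the clusters and detects nothing.
The candidate nest is the component-wise median of stationary fixes pooled
over "mostly sitting still" days (stationary fraction > 0.5). Daily
**attendance** is the fraction of the day's *non-flying* fixes within the
attendance radius (50 m) of the candidate; excluding flight fixes keeps
attendance invariant to commuting or fly-over fixes far from the nest. A
nest is accepted on the earliest run of ≥3 consecutive days with
attendance > 75% (a single day at or below 75% ends the run; gap tolerance
0 by default, configurable). Laying is the first run day; the nest is
successful when the run lasts 28–35 days — runs beyond 35 days are treated
as overdue incubation, not success — and hatch is the last run day of a
successful nest. One nest per goose-season is kept (the earliest);
renesting is out of scope, as is accelerometer processing — body-motion
stationarity is subsumed into the speed/displacement criteria.

Derived quantities: breeding propensity (attempting / tracked), nesting
success (successful / detected), pre-laying interval (laying − arrival),
and relative timing (event day − local spring onset; positive = after).

## Migration timing

From resightings of neckbanded individuals, each bird contributes its
first and last observation day in the season. `Arr_q` is the smallest day
by which *strictly more than* q% of the season's birds have been seen
("over q%"); `Dep_q` is the largest day on which *at least* q% are still
present. Both are exactly equal to a brute-force day-scan and are monotone
(arrival) / antitone (departure) in q. One boundary subtlety: adding a
bird strictly inside the season can legitimately move `Arr5` a day later
when the count sits exactly on the percentile boundary, because the
threshold rises by q/100 while the count below the new bird's date does
not; only the directed statement (a bird first seen at or before `Arr5`
never delays `Arr5`) holds universally.

Counts (surveys every 1–3 days) have no published percentile analogue;
the package defines one relative to the seasonal maximum after linear
interpolation to daily resolution: `Peak` is the earliest day of the
maximum, `Arr_q`/`Dep_q` the first/last day the interpolated count reaches
q% of it (inclusive on both sides, which is what a day-resolution
interpolation oracle yields on a triangular season). These measures carry
`source="counts"` so downstream users can treat them separately; sparse
survey coverage makes the tails of this definition unreliable.

## Statistics

* **Trends**: OLS of the annual value on year, per site; a constant series
  returns slope 0 with the p-value flagged undefined.
* **Detrending**: residuals of that fit (fitted even when the trend is not
  significant); residuals are orthogonal to year to numerical precision.
* **Predictability**: OLS of site-B residuals on site-A residuals over
  shared years; with a period split (default 1979–1999 vs 2000–2022,
  configurable) the model adds a period main effect and slope×period
  interaction, pooling residual variance across periods in a single model,
  and reports per-period slopes and the interaction p-value. Each period
  needs ≥3 shared years.
* **Within-year differences**: intercept-only OLS on per-year B−A,
  identical to a paired t-test. **Correlations**: Pearson, two-sided.
* **Mixed models** with crossed random intercepts of year and individual.
  Gaussian responses use REML via statsmodels `MixedLM`, the crossed
  intercepts expressed as variance components over a single trivial group.
  Degrees of freedom are a between-within style approximation
  (`n − p − Σ(levels−1)`, floored at 1) — a deliberate simplification; no
  claim is made to reproduce any particular Satterthwaite implementation.
  Binomial responses use a Laplace-approximation logistic GLMM implemented
  in `pinkfoot.stats`: random effects are reparametrised spherically
  (`u = σ b`, `b ~ N(0, I)`), the inner penalized IRLS profiles fixed
  effects and `b` jointly with step-halving, the outer Nelder–Mead
  optimises the σ's, and the marginal likelihood includes the Laplace
  log-determinant over the random-effect block only. σ = 0 is an ordinary
  point of this parametrisation, so the fit degrades smoothly to a plain
  GLM — with zero estimated variance the fixed effect matches the analytic
  2×2 log-odds to ~1e-12, and on non-degenerate data the estimates agree
  with lme4's `glmer` to ~0.03 (cross-checked in the test suite via
  Rscript). Fixed-effect standard errors are conditional (from the joint
  penalized Hessian), as in common Laplace implementations. Grouping
  factors with fewer than two levels are dropped with a logged warning;
  with none left, the model degrades to a fixed-effects fit.
  Non-convergence is reported on the result object, never swallowed.
* "Scaled" covariates are z-scored within the modelled dataset. No
  multiple-testing correction is applied; α = 0.05. Missing years drop
  listwise per pairwise analysis.

## Biometrics

Expected mass is a sex-specific OLS prediction of mass from wing length,
fitted on all captures of that sex pooled across routes and years
(per-route fits are a config option; year-specific fits are not offered).
Body condition is mass / expected mass, a dimensionless ratio with mean
≈ 1 on the fitting sample by the OLS zero-residual identity, and invariant
to rescaling all masses. Route/sex comparisons are LMMs with a random year
intercept; mass and condition include the capture day-of-year, centred at
the sample mean; condition adds a route×sex interaction. Out-of-range
biometrics (head outside 80–120 mm, wing 350–520 mm, mass 1500–4500 g) are
rejected at ingest with a row-level reason, never clipped.

## Synthetic data

The generator emulates every pipeline input with configurable truth. One
global seed expands into per-entity substreams (keyed by stage, site or
animal, and year), so adding entities never perturbs existing data.

* **Temperature**: daily mean 0 °C before the true onset day, then a
  linear ramp (0.15 °C/day, capped at 16 °C), so cumulative GDD switches
  from flat to quadratic exactly at the truth; a diurnal cycle sampled at
  the quarter phases sums to zero and leaves daily means untouched;
  Gaussian noise per 6-h value.
* **Indices**: logistic seasonal curves, chosen because they make truth
  analytic — the NDSI curve's midpoint value equals the 0.42 threshold so
  it crosses exactly at the pixel's true melt day, and the NDVI curve has
  its maximum slope at the true green-up day. Pixel truths scatter
  normally (sd 3 days) around the site truth; observations every 2 days
  with configurable noise and cloud-gap missingness, clipped to [−1, 1].
* **Tracks**: residency is a slow local wander (≤2 km scatter; speeds
  0–8 km/h) around the site centroid; migration legs are great-circle
  flights at a fixed 70 km/h, timed to land at 03:00 of the arrival day —
  unambiguously above the 15 km/h classification cut. Nest phase: exactly
  `round(p · fixes/day)` of each incubation day's fixes sit on the true
  nest coordinate, the rest forage 0.3–2 km away. The deterministic count
  is deliberate: per-fix Bernoulli sampling at p = 0.9 and 16 fixes/day
  would break a 28-day >75% attendance run with probability ≈ 0.86,
  making long incubation runs almost impossible to generate — daily
  attendance is pinned at p instead, with GPS noise (sd 15 m per axis) the
  only stochastic component. Truths (site arrival/departure, boundary
  crossing day, laying/hatch/success) are derived from the noise-free
  planned path. Successful nests have attendance runs of 28–35 days
  (incubation = run − 1); failed attempts 4–20 days.
* **Resightings** are per bird-day Bernoulli(detection) draws inside the
  true presence interval; **counts** scale the number of birds present;
  **captures** draw wing/head per sex and set mass from the sex-specific
  allometry plus an optional route effect and noise.

What the generator does *not* emulate bounds what passing tests show:
movement is not behaviourally realistic (no correlated random walk, no
accelerometer channel — stationarity lives purely in positions/speeds),
satellite data have no spatial autocorrelation or systematic cloud
seasons, and detection probability is constant over the season. Recovery
rates measured here are therefore upper bounds on field performance;
boundary conventions, identities and invariances transfer as proved.

## Reference conditions used by `scripts/acceptance.py`

Problem sizes follow the package's reference experiment set: 200
goose-years for nest-detection recovery (16 fixes/day, attendance 0.9,
GPS sd 15 m, breeding propensity 0.6), 100 pixels per index at noise sd
0.05 and 30% missingness, 1,000 random seasons for the percentile oracle,
500 simulation seeds for the period-interaction power check (generating
slopes 0 and −1, noise sd 1, 21+23 years), 90 goose-years for the
Gaussian LMM recovery (+3.5-day area effect; year sd 2, individual sd 3,
residual sd 4), and 400 captures for the condition-effect recovery
(+290 g for new-route females ≈ +0.09 condition). The worked-example
proportions are computed from their printed per-area counts (37/62,
17/28, 18/36, 9/17).
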