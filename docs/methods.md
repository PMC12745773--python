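# Methods

This note documents the statistical machinery, the synthetic data-generating
process that stands in for real mortality and weather records, the numerical
choices, and what the validation studies do and do not establish.

## Data model

The observational unit is a department-day: an all-cause death count, the
population at risk, daily mean temperature (°C), daily mean relative humidity
(%), and daily accumulated precipitation (mm). Mortality rates are expressed
as deaths per 100,000 population per day; the scale only shifts fixed-effect
levels, never slopes or contrasts. Days are keyed by `(year, day_of_year)`
with day-of-year defined on the 366-day leap calendar (Feb 29 = 60, Mar 1 =
61 in every year), so "the same calendar day" across years is integer
equality and Feb 29 climatologies draw only on leap years. Missing weather is
an error, not imputed.

## Excess mortality

Log mortality rate is fit as an additive two-way decomposition — a level per
(department, year) and a seasonal term per (department, day-of-year) — by
alternating means iterated to 1e-10, which is least squares with saturated
dummies. The decomposition's level ambiguity is fixed by constraining each
department's seasonal terms to mean zero; predictions are invariant to this
choice. Excess deaths are observed counts minus the exponentiated prediction
converted back to counts; no retransformation (smearing) correction is
applied, and the option is deliberately omitted because every downstream
comparison is a *difference* of predictions in which any multiplicative
correction largely cancels. Zero-death days have no log rate and are excluded
with a count (rare at the default population scale; a 0.5-death continuity
correction is available but off by default).

## Exposure–response regressions

The design contains, for each lag j = 0..L (L = 5 by default; 3, 10, 30
available): powers T, T², …, T^P of the day-(d−j) temperature (P = 4
default), optionally each power times the department's long-term mean
temperature T̄_i (the climate interaction, letting warm-adapted departments
respond differently), and — in the compounding variants — each power times a
transform g(·) of the *preceding* day's temperature (lag j interacts with day
d−j−1, so compounding needs L+1 lagged days). Controls (humidity,
precipitation) enter with the same lags by default; an unlagged option
exists. Temperatures enter uncentered: all reported quantities are contrasts,
which difference out the level, so centering would change nothing and is
omitted for transparency.

Three previous-day transforms: the level (default), the anomaly from the
department/calendar-day climatology (weaker collinearity with the current
day), and a natural cubic spline with one interior knot (default 11.7 °C,
roughly the median daily temperature) and boundary knots at the sample
min/max of previous-day temperature — two basis columns, C² everywhere and
linear beyond the boundaries.

Lags never cross department boundaries or gaps in the daily record; rows
missing any required lagged day are dropped and counted, never padded.

### Estimation

Both fixed-effect dimensions (department×year, department×day-of-year) are
absorbed by alternating within-group demeaning. Columns are scaled to unit
root-mean-square first — raw T⁴ columns reach ~10⁶, and an absolute
convergence tolerance is only meaningful on a common scale — and the sweeps
iterate until the largest removed group mean is below 1e-10 (cap 10,000;
near-balanced panels converge in ~5 sweeps). Slopes equal explicit
dummy-variable OLS (tested to 1e-8). Columns demeaned below 1e-12 variance
are collinear with the fixed effects and dropped with a warning; residual
rank deficiency raises an error naming the offending set via pivoted QR.

Inference is a CR1 cluster sandwich with departments as clusters:
(X′X)⁻¹(Σ_g X_g′u_g u_g′X_g)(X′X)⁻¹ scaled by G/(G−1)·(N−1)/(N−K), where K
counts the absorbed fixed effects as G₁+G₂ minus the number of connected
components of the two grouping factors (standard small-sample accounting; it
only affects the scalar). Coefficient uncertainty is propagated by n = 500
draws from MVN(β̂, V̂) via a symmetric eigenfactorization with eigenvalues
clipped at zero; intervals are 2.5th–97.5th percentiles of derived
quantities, computed per draw.

### From coefficients to deaths

Because the outcome is a log rate, the contrast of the fitted temperature
terms at two scenarios is a percent change: exp(Δ)−1 per draw (the exact
transform; Δ×100 is available behind a flag). Marginal effects move only the
focal day's terms, conditioning on the previous day through the compounding
interaction and on climate through T̄ (evaluated at the population-weighted
mean T̄ by default). The cumulative variant sums every lag's contribution
along a realized temperature path and backs daily event predictions: per
department-day, the percent change between the scenario path and the
climatological path, times the climatological mean death count for that
department and calendar day. Negative contributions (days cooler than
climatology) are retained. The two-dimensional compounding surface reports
the mean percent change per (previous °C, current °C) cell relative to two
consecutive days at 20 °C, masked to 1 °C half-open cells that contain at
least one observed consecutive-day pair; response curves flag extrapolation
outside the observed current-day range conditional on the previous-day bin.

### Attribution and projection

Counterfactual events use the region-wide delta method: one daily temperature
difference applied uniformly to every department. History days before the
window reuse the first window delta (avoiding an artificial jump entering the
lag structure; a zero-delta policy is available). Scenarios carry their
unshifted base temperatures plus the cumulative delta, so deltas that cancel
reproduce the observed scenario bit-exactly. Attributable deaths are the
*paired* per-draw difference between factual and counterfactual predictions —
never a difference of summaries — pooled over delta sources when several are
supplied (ensemble size = draws × sources); mismatched draw order is an
error. Projections apply warmed deltas with coefficient samples tagged by
estimation period, enabling pre- vs post-adaptation contrasts on the same
scenario.

## The synthetic data generator

The generator is the source of ground truth for every validation study. It
emulates:

* **Climate**: a cosine seasonal cycle (amplitude 8 °C, peak ~July 20) around
  department mean temperatures spaced 10–16 °C, with stationary AR(1) daily
  anomalies (ρ = 0.55, sd 2.6 °C). Innovations are Student-t with 4 degrees
  of freedom (clipped at ±7 innovation sd): heavy tails produce occasional
  short-lived hot spikes, so isolated very hot days occur and identify the
  response curve at high temperatures while *sustained* blocks of equally hot
  consecutive days remain unprecedented. This support geometry — single hot
  days observed, hot-after-hot combinations absent — is the defining feature
  of record-shattering heat waves and is what makes the standard additive
  model genuinely extrapolate when a sustained event arrives. With Gaussian
  AR(1) weather, every hot day lies on the persistence ridge and an additive
  model reproduces sustained events from training data alone; we verified
  this directly, and it is why the innovation distribution matters.
* **Mortality**: Poisson counts (an expected-value mode rounds the mean
  instead) with log rate = baseline (2.5/100k/day) + department-year and
  department-day-of-year effects (sd 0.03/0.02) + a distributed-lag response.
  The true response is parameterized directly on the regression's own
  columns so the estimating equations span it exactly: a quartic in raw
  temperature (J-shaped, minimum near 18–20 °C, ~+11% at 30 °C and ~+35% at
  36 °C summed over lags), lag weights (0.45, 0.25, 0.15, 0.08, 0.04, 0.03),
  a climate interaction −4.3e-9·T⁴·T̄ (warmer departments respond less), and
  a compounding interaction 3.0e-8·T⁴·T_prev — tail-concentrated, so an
  extra previous-day degree adds ≈0.024 to a 30 °C day's log rate, the order
  implied by estimates for strongly heat-sensitive populations, while
  ordinary warm spells barely compound. Small humidity/precipitation effects
  complete the controls. Every "truth" used downstream is evaluated in
  closed form from these coefficients, never by a second implementation of
  the regression.
* **Populations** are region-scale (1–3 million, ~25–75 expected deaths/day).
  This matters for calibration: least squares on log Poisson counts carries a
  −1/(2λ) retransformation bias whose variation across cells biases heat
  coefficients upward; at region-scale counts the bias is well inside
  sampling noise, at small-department counts it measurably degrades interval
  coverage. The estimation stage is thus deliberately misspecified for
  Poisson data in the same way the real analysis is, and the validation
  relies on coverage-based criteria that tolerate it.
* **Events**: a storyline heat wave replaces the window's temperatures with
  the seasonal climatology plus an uplift profile (raised-cosine or plateau);
  an additive mode that stacks the uplift on realized anomalies is also
  available. The canonical study event is a 14-day +12 °C plateau in the
  held-out final year — roughly a 4.5-sigma daily anomaly sustained for two
  weeks, i.e. far outside the consecutive-pair support. Mortality is
  re-simulated only where the expected rate changes, so the event's true
  excess is the closed-form difference in expected deaths (accumulated over
  the window plus L following days, matching what predictions accumulate).

What the generator does *not* emulate: spatial correlation of weather across
departments, demographic structure (age-specific mortality), harvesting/
displacement dynamics, air pollution co-stressors, reporting artifacts, and
long-term trends in baseline mortality beyond free year effects. Passing
validation here shows the *machinery* is correct and calibrated under the
stated conditions; it does not certify any particular real-world estimate.

## Validation studies and problem sizes

All studies live in `heatmort.studies` with fixed desk-scale sizes chosen to
give stable Monte Carlo verdicts at interactive runtimes: interval-coverage
calibration uses 200 replicates of 10 departments × 25 years (~91k rows,
84-column design); the standard-vs-compounding out-of-sample contrast uses 50
event replicates; attribution and adaptation use single replicates with 500
coefficient draws. A full-scale configuration (94 departments × 40 years) is
available through `GeneratorConfig` but is not required by any test.

Observed behavior at these sizes: 95% draw intervals for the hot-after-hot
contrast cover truth ~94–95% of the time; the standard model's event
prediction falls ~10–15% below the true excess essentially always, while the
compounding interval covers it in ~80–90% of replicates. Two small systematic
effects are worth knowing about when reading event predictions: the
climatological mean death count that converts percent changes into deaths is
inflated a few percent by hot reference-year summers (the response is convex
in temperature), and the prediction contrasts against climatology whereas the
true excess contrasts against the realized no-event weather; both push
predictions slightly above the truth and are shared by any analysis built on
climatological baselines.

## Numerical notes

* Large-panel fitting reuses preallocated workspaces and numba-compiled
  demeaning/score kernels (with numpy fallbacks); repeated fresh allocation
  of ~60 MB design matrices dominates runtime otherwise.
* `build_design(..., reuse_buffers=True)` lets Monte Carlo loops alias an
  internal buffer; the default allocates fresh storage.
* Seeds fan out from a single master seed into named substreams (weather,
  fixed effects, deaths, event redraws, coefficient draws), so every stage is
  independently reproducible and replicates are independent.
* Ties and degenerate inputs: zero-variance regressors are rejected before
  absorption; a single cluster, a single department, a single year, event
  windows within L days of the panel edge, and missing delta days all raise
  typed errors rather than degrading silently.

## Known limitations

* The log-linear OLS stage is not a count model; at small populations the
  Poisson retransformation bias is material (see above). A GLM stage is out
  of scope.
* With 10 departments the CR1 clustered covariance is itself noisy; interval
  coverage a few points below nominal is expected and is why calibration is
  judged by a band, not a point.
* The spline and anomaly compounding variants share the machinery of the
  level variant and are exercised by unit tests, but the canonical studies
  validate the level variant only.
* `absorb_fixed_effects` guarantees convergence for two non-nested groupings
  in practice; pathological grouping graphs could require many sweeps and are
  capped at 10,000 iterations with an explicit error.
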