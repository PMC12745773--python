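# heatmort

Heat-wave mortality analysis on department-day panels: distributed-lag
temperature–mortality regressions with **temporal compounding**, excess
mortality baselines, and counterfactual climate attribution of event deaths —
validated end to end on synthetic panels with known ground truth.

## Who this is for

Environmental epidemiologists and climate-impact researchers who want a
tested, reusable implementation of the workflow used to study unprecedented
extreme heat events: how much did an event raise mortality, how badly do
standard exposure–response functions extrapolate to it, how much of the toll
is attributable to warming, and how much would adaptation change a future
recurrence.

## The models

**Excess mortality.** Log daily mortality rate (deaths per 100,000/day) is
decomposed into department-specific trends and seasonality,

```
log(M_idy) = μ_iy + δ_id + ε_idy
```

for department *i*, day-of-year *d*, year *y*; excess deaths in a window are
observed deaths minus the exponentiated baseline prediction.

**Standard exposure–response.** A two-way fixed-effects panel regression with
a degree-4 polynomial in daily mean temperature at lags *j* = 0…5, a
continuous interaction with the department's long-term mean climate T̄_i, and
lagged humidity/precipitation controls:

```
log(M_idy) = Σ_j [ f(T_i(d−j)y) + f(T_i(d−j)y)·T̄_i ] + Σ_j λ_j·X_i(d−j)y + μ_iy + δ_id + ε_idy
```

**Temporal compounding.** Each lag's polynomial is additionally interacted
with the *preceding* day's temperature (so day d−2 interacts with day d−3),
letting a hot day hit harder when it follows another hot day:

```
... + Σ_j f(T_i(d−j)y) · g(T_i(d−j−1)y) ...
```

with `g` either the previous day's level (default), its anomaly, or a natural
cubic spline with a knot near the median temperature.

Estimation is OLS with both fixed-effect dimensions absorbed by alternating
demeaning; inference uses a CR1 sandwich clustered by department, and
uncertainty is propagated by 500 multivariate-normal coefficient draws
(intervals are 2.5th–97.5th percentiles). Event deaths are the
exposure–response contrast between realized (or delta-shifted counterfactual)
temperatures and the climatological temperature for each calendar day,
multiplied by the climatological mean death count. Attributable deaths are
paired per-draw differences between factual and counterfactual predictions.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(10 synthetic departments × 24 years, with a 14-day +12 °C storyline heat
wave in a held-out year) and write tables under `results/analysis/`:

```
$ python analysis/01_simulate_event_panel.py
panel written: results/analysis/panel.csv (87,660 department-days)
true event excess (window + lag tail): 18,470 deaths

$ python analysis/02_fit_response_functions.py
30 degC day after a 20 degC day vs two 20 degC days: +23% (95% CI +21 to +25%)
30 degC day after a 30 degC day vs two 20 degC days: +36% (95% CI +28 to +45%)
support: 41% of (previous, current) 1 degC cells observed

$ python analysis/03_excess_vs_predicted.py
true event excess :    18,470 deaths
estimated excess  :    17,480 deaths
standard     model :    15,428 deaths (95% 14,748 - 16,006) <- underestimates the true excess
compounding  model :    18,099 deaths (95% 15,862 - 20,451) <- interval covers the true excess

$ python analysis/04_attribution.py
standard    : 4,304 attributable deaths (95% 4,046 - 4,565), 28% of event mortality
compounding : 5,448 attributable deaths (95% 4,229 - 6,958), 30% of event mortality

$ python analysis/05_adaptation_projection.py
+1.5 degC scenario: 34,947 deaths with the pre-event response, 9,251 with the
moderated response (74% reduction; post < pre in 100% of paired draws)
```

Reading the numbers: hot days compound — a 30 °C day is markedly deadlier
after another 30 °C day (+36%) than after a mild day (+23%). A sustained
event made of exactly such sequences is under-predicted by the standard
additive model (15,428 vs a true 18,470), while the compounding model's
interval covers the truth. Cooling the event by the counterfactual delta
(−1.2 °C) removes ~30% of its mortality, and halving the response function
("post-adaptation") cuts the projected toll of a warmed recurrence by ~74%.

A `heatmort` CLI wraps the same stages behind a YAML config
(`heatmort simulate|full|report|config show ...`).

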