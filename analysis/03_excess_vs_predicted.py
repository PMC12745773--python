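#!/usr/bin/env python
"""Excess mortality during the event versus out-of-sample predictions.

Computes the seasonal-and-trend excess over the event window, then predicts
the event with both pre-event response functions (estimated without the
event year).  The standard additive model should fall short of the true
excess; the compounding model's interval should cover it.
"""

import json

from heatmort.attribution import predict_event_deaths, scenario_from_panel
from heatmort.design import ModelSpec
from heatmort.excess import excess_deaths, fit_baseline
from heatmort.panel import build_climatology, read_panel
from heatmort.studies import CANONICAL_EVENT as EV
from heatmort.studies import PRE_PERIOD, fit_and_sample

OUT = "results/analysis"
L = 5

if __name__ == "__main__":
    panel = read_panel(f"{OUT}/panel.csv").with_mean_temperature(PRE_PERIOD)
    truth = json.loads(open(f"{OUT}/truth.json").read())

    baseline = fit_baseline(panel, (panel.years[0], panel.years[-1]))
    tab, excess = excess_deaths(panel, baseline, EV.year, EV.start_doy, EV.end_doy + L)
    tab.to_csv(f"{OUT}/excess.csv", index=False)

    clim = build_climatology(panel, PRE_PERIOD)
    scen = scenario_from_panel(panel, EV.year, EV.start_doy, EV.end_doy + L, n_history=L + 1)
    print(f"true event excess : {truth['true_event_excess']:>9,.0f} deaths")
    print(f"estimated excess  : {excess:>9,.0f} deaths")
    for name, mode in (("standard", "none"), ("compounding", "previous_level")):
        s = fit_and_sample(panel, ModelSpec(compounding=mode), PRE_PERIOD, seed=12)
        pred = predict_event_deaths(s, scen, clim)
        pred.daily().to_csv(f"{OUT}/predicted_daily_{name}.csv", index=False)
        sm = pred.summary()
        tx = truth["true_event_excess"]
        if sm["lo"] <= tx <= sm["hi"]:
            flag = " <- interval covers the true excess"
        elif sm["hi"] < tx:
            flag = " <- underestimates the true excess"
        else:
            flag = " <- overestimates the true excess"
        print(
            f"{name:12s} model : {sm['mean']:>9,.0f} deaths "
            f"(95% {sm['lo']:,.0f} - {sm['hi']:,.0f}){flag}"
        )
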