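"""Scenarios, delta shifting, event prediction, attributable deaths."""

import numpy as np
import pandas as pd
import pytest

from heatmort.attribution import (
    EventPrediction,
    apply_deltas,
    attributable_deaths,
    predict_event_deaths,
    project_event,
    scenario_from_panel,
)
from heatmort.design import ModelSpec
from heatmort.errors import ConfigError, DataError
from heatmort.generator import make_delta_series
from heatmort.panel import Climatology, build_climatology
from heatmort.studies import CANONICAL_EVENT, PRE_PERIOD, event_config, fit_and_sample
from heatmort.generator import generate_panel, inject_event

L = 5


@pytest.fixture(scope="module")
def event_world():
    """One event panel with fitted compounding samples and climatology."""
    cfg = event_config()
    panel, truth = generate_panel(cfg, seed=77)
    panel2, truth2, info = inject_event(panel, truth, CANONICAL_EVENT, seed=8)
    clim = build_climatology(panel2, PRE_PERIOD)
    samples = fit_and_sample(
        panel2, ModelSpec(compounding="previous_level"), PRE_PERIOD, n_draws=200, seed=9
    )
    scen = scenario_from_panel(panel2, 2003, 214, 227, n_history=L + 1)
    return cfg, panel2, truth2, info, clim, samples, scen


class TestApplyDeltas:
    def test_zero_deltas_identity(self, event_world):
        *_, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"GMT+0.0": 0.0})
        cf = apply_deltas(scen, deltas, label="GMT+0.0")
        np.testing.assert_array_equal(cf.df["tmean_c"], scen.df["tmean_c"])

    def test_plus_minus_delta_round_trip_is_bit_exact(self, event_world):
        *_, scen = event_world
        plus = make_delta_series(scen.window_dates, {"x": 0.7})
        minus = make_delta_series(scen.window_dates, {"x": -0.7})
        back = apply_deltas(apply_deltas(scen, plus, "up"), minus, "back")
        np.testing.assert_array_equal(back.df["tmean_c"], scen.df["tmean_c"])

    def test_uniform_cooling_shifts_every_window_day(self, event_world):
        *_, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"GMT+0.0": -1.2})
        cf = apply_deltas(scen, deltas, label="GMT+0.0")
        win = scen.df["date"] >= scen.window_start
        np.testing.assert_allclose(
            scen.df.loc[win, "tmean_c"] - cf.df.loc[win, "tmean_c"], 1.2
        )

    def test_history_policy(self, event_world):
        *_, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"x": -1.2})
        hist = scen.df["date"] < scen.window_start
        first = apply_deltas(scen, deltas, "a", history_delta="first")
        zero = apply_deltas(scen, deltas, "b", history_delta="zero")
        np.testing.assert_allclose(
            scen.df.loc[hist, "tmean_c"] - first.df.loc[hist, "tmean_c"], 1.2
        )
        np.testing.assert_array_equal(
            zero.df.loc[hist, "tmean_c"], scen.df.loc[hist, "tmean_c"]
        )

    def test_missing_window_day_rejected(self, event_world):
        *_, scen = event_world
        short = make_delta_series(scen.window_dates[:-2], {"x": -1.0})
        with pytest.raises(DataError, match="missing"):
            apply_deltas(scen, short, "x")


class TestPredictEventDeaths:
    def test_climatological_scenario_predicts_zero(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        df = scen.df.copy()
        from heatmort.calendar import day_of_year_366

        for dept, sub in df.groupby("department_id"):
            doys = day_of_year_366(pd.DatetimeIndex(sub["date"]))
            df.loc[sub.index, "tmean_c"] = clim.temperature(dept, doys)
        clim_scen = type(scen)(label="clim", df=df, window_start=scen.window_start)
        pred = predict_event_deaths(samples, clim_scen, clim)
        np.testing.assert_allclose(pred.deaths, 0.0, atol=1e-9)

    def test_doubling_baseline_deaths_doubles_predictions(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        doubled = Climatology(
            clim.df.assign(deaths_clim=clim.df["deaths_clim"] * 2), clim.period
        )
        p1 = predict_event_deaths(samples, scen, clim)
        p2 = predict_event_deaths(samples, scen, doubled)
        np.testing.assert_allclose(p2.deaths, 2 * p1.deaths, rtol=1e-12)

    def test_insufficient_history_rejected(self, event_world):
        cfg, panel2, truth2, info, clim, samples, _ = event_world
        short = scenario_from_panel(panel2, 2003, 214, 227, n_history=2)
        with pytest.raises(DataError, match="history"):
            predict_event_deaths(samples, short, clim)


class TestAttributableDeaths:
    def test_identical_scenarios_zero_with_zero_width(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        pred = predict_event_deaths(samples, scen, clim)
        att = attributable_deaths(pred, pred)
        s = att.summary()
        assert s["attributable_deaths_mean"] == 0.0
        assert s["attributable_deaths_lo"] == 0.0 == s["attributable_deaths_hi"]

    def test_cooling_counterfactual_positive_in_every_draw(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"GMT+0.0": -1.2})
        cf = apply_deltas(scen, deltas, "GMT+0.0")
        att = attributable_deaths(
            predict_event_deaths(samples, scen, clim),
            predict_event_deaths(samples, cf, clim),
        )
        assert np.all(att.att_totals > 0)

    def test_fraction_identity_per_draw(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"GMT+0.0": -1.2})
        cf = apply_deltas(scen, deltas, "GMT+0.0")
        obs = predict_event_deaths(samples, scen, clim)
        att = attributable_deaths(obs, predict_event_deaths(samples, cf, clim))
        np.testing.assert_allclose(
            att.att_fractions * obs.totals_by_draw(), att.att_totals, rtol=1e-12
        )

    def test_shuffled_draw_order_rejected(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        pred = predict_event_deaths(samples, scen, clim)
        shuffled = EventPrediction(
            deaths=pred.deaths[::-1],
            cells=pred.cells,
            label="shuffled",
            draw_ids=pred.draw_ids[::-1],
            period=pred.period,
        )
        with pytest.raises(DataError, match="draw order"):
            attributable_deaths(pred, shuffled)

    def test_pooling_over_delta_sources(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        obs = predict_event_deaths(samples, scen, clim)
        cfs = []
        for k, d in enumerate([-1.0, -1.4]):
            deltas = make_delta_series(scen.window_dates, {"GMT+0.0": d}, source_id=f"m{k}")
            cfs.append(
                predict_event_deaths(samples, apply_deltas(scen, deltas, "GMT+0.0"), clim)
            )
        att = attributable_deaths(obs, cfs)
        assert len(att.att_totals) == samples.n_samples * 2


class TestProjectEvent:
    def test_zero_deltas_reproduce_baseline_prediction(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        deltas = make_delta_series(scen.window_dates, {"GMT+0.0": 0.0})
        warmed = apply_deltas(scen, deltas, "GMT+0.0")
        base = predict_event_deaths(samples, scen, clim)
        proj = project_event(samples, warmed, clim)
        np.testing.assert_array_equal(base.deaths, proj.deaths)

    def test_missing_period_tag_rejected(self, event_world):
        cfg, panel2, truth2, info, clim, samples, scen = event_world
        unperioded = fit_and_sample(
            panel2, ModelSpec(compounding="none"), PRE_PERIOD, n_draws=10, seed=1
        )
        unperioded.fitted.period = None
        with pytest.raises(ConfigError, match="period"):
            project_event(unperioded, scen, clim)

    def test_monotone_in_uniform_warming_for_increasing_response(self, event_world):
        from test_response import handmade_samples

        cfg, panel2, truth2, info, clim, samples, scen = event_world
        spec = ModelSpec(polynomial_order=1, n_lags=5, compounding="none",
                         climate_interaction=False, controls=())
        inc = handmade_samples(spec, {f"t_l{j}_p1": 0.01 for j in range(6)}, n_draws=20)
        d15 = make_delta_series(scen.window_dates, {"w": 1.5})
        d20 = make_delta_series(scen.window_dates, {"w": 2.0})
        p15 = project_event(inc, apply_deltas(scen, d15, "GMT+1.5"), clim)
        p20 = project_event(inc, apply_deltas(scen, d20, "GMT+2.0"), clim)
        assert np.all(p20.totals_by_draw() >= p15.totals_by_draw())
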