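"""Synthetic panel generator: determinism, weather process, truth oracles."""

import numpy as np
import pandas as pd
import pytest

from heatmort.errors import ConfigError, DataError
from heatmort.generator import (
    EventSpec,
    GeneratorConfig,
    generate_panel,
    inject_event,
    make_delta_series,
    true_lag0_contrast,
    true_log_response,
)


class TestConfig:
    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(rho=1.0)

    def test_population_length_checked(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_departments=3, populations=(1e5,))

    def test_dict_round_trip(self):
        cfg = GeneratorConfig(n_departments=4, rho=0.3)
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestGeneratePanel:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_departments=2, year_start=2000, year_end=2002)
        p1, _ = generate_panel(cfg, seed=11)
        p2, _ = generate_panel(cfg, seed=11)
        pd.testing.assert_frame_equal(p1.df, p2.df)
        p3, _ = generate_panel(cfg, seed=12)
        assert not p1.df["deaths"].equals(p3.df["deaths"])

    def test_null_model_is_flat_baseline(self):
        """All effects off in expected_value mode: every department-day has
        the same rate, equal to the baseline."""
        cfg = GeneratorConfig(
            n_departments=2, year_start=2000, year_end=2001,
            fe_year_sd=0.0, fe_doy_sd=0.0,
            lag_weights=(0.0,), climate_coeff=0.0, compound_coeff=0.0,
            rh_coeff=0.0, precip_coeff=0.0,
            noise="expected_value", burn_in_days=10,
        )
        panel, truth = generate_panel(cfg, seed=0)
        rate = np.exp(cfg.baseline_log_rate)
        expected = np.round(rate / 1e5 * panel.df["population"].to_numpy())
        np.testing.assert_array_equal(panel.df["deaths"].to_numpy(), expected)

    def test_ar1_autocorrelation_recovered(self):
        """Gaussian AR(1), rho=0.7, 50 years, one department, no seasonality:
        the sample lag-1 autocorrelation matches the configured coefficient."""
        cfg = GeneratorConfig(
            n_departments=1, year_start=1960, year_end=2009,
            seasonal_amplitude=0.0, rho=0.7, innovation_df=None,
            noise="expected_value",
        )
        panel, truth = generate_panel(cfg, seed=21)
        anom = truth.temps_full[0] - truth.tbar[0]
        r = np.corrcoef(anom[1:], anom[:-1])[0, 1]
        assert r == pytest.approx(0.7, abs=0.03)

    def test_heavy_tail_innovations_make_isolated_spikes(self):
        """Student-t innovations: marginal extremes exceed the hottest
        consecutive-pair diagonal, the support geometry the studies rely on."""
        cfg = GeneratorConfig(n_departments=2, year_start=1980, year_end=2009)
        panel, truth = generate_panel(cfg, seed=5)
        anom = truth.temps_full[0] - (
            truth.temps_full[0] * 0 + truth.tbar[0]
        )
        # seasonal cycle removed by differencing against the other department
        a = truth.temps_full[0] - truth.tbar[0]
        b = truth.temps_full[1] - truth.tbar[1]
        season_proxy = (a + b) / 2
        dev = a - season_proxy  # idiosyncratic part only (half-difference)
        hottest = np.max(dev)
        hottest_pair = np.max(np.minimum(dev[1:], dev[:-1]))
        assert hottest > hottest_pair + 1.0


class TestTruthOracles:
    def test_reference_normalization_is_zero(self):
        cfg = GeneratorConfig()
        ref = np.full(cfg.n_lags + 1, 20.0)
        assert true_log_response(cfg, ref, ref, tbar=13.0, reference=20.0) == pytest.approx(0.0)

    def test_zero_compounding_removes_previous_day_dependence(self):
        cfg = GeneratorConfig(compound_coeff=0.0)
        cur = np.full(cfg.n_lags + 1, 25.0)
        a = true_log_response(cfg, cur, np.full(6, 10.0), tbar=13.0)
        b = true_log_response(cfg, cur, np.full(6, 30.0), tbar=13.0)
        assert a == pytest.approx(b)

    def test_matches_internal_rate_to_machine_precision(self, default_panel_and_truth):
        cfg, panel, truth = default_panel_and_truth
        r = truth.log_rate()
        T = truth.temps_full
        rng = np.random.default_rng(0)
        for _ in range(20):
            di = rng.integers(0, cfg.n_departments)
            t = rng.integers(cfg.n_lags + 1, truth.n_panel_days)
            i = truth.burn + t
            cur = T[di, i - cfg.n_lags : i + 1][::-1]
            prev = T[di, i - cfg.n_lags - 1 : i][::-1]
            temp_part = true_log_response(cfg, cur, prev, truth.tbar[di])
            rest = (
                cfg.baseline_log_rate
                + truth.fe_year[di, truth.year_idx[t]]
                + truth.fe_doy[di, truth.doy366[t] - 1]
                + cfg.rh_coeff * (truth.rh[di, t] - 75.0)
                + cfg.precip_coeff * truth.precip[di, t]
            )
            assert r[di, t] == pytest.approx(temp_part + rest, abs=1e-12)

    def test_lag0_contrast_sign_structure(self):
        cfg = GeneratorConfig()
        hot_after_hot = true_lag0_contrast(cfg, (30, 30), (20, 20), 13.0)
        hot_after_mild = true_lag0_contrast(cfg, (20, 30), (20, 20), 13.0)
        assert hot_after_hot > hot_after_mild > 0


@pytest.fixture(scope="module")
def small():
    cfg = GeneratorConfig(n_departments=3, year_start=1996, year_end=2003)
    return cfg, *generate_panel(cfg, seed=31)


class TestInjectEvent:
    def test_zero_uplift_add_mode_is_identity(self, small):
        cfg, panel, truth = small
        ev = EventSpec(2003, 214, 227, 0.0, mode="add")
        panel2, truth2, info = inject_event(panel, truth, ev, seed=1)
        pd.testing.assert_frame_equal(panel.df, panel2.df)
        assert info.true_excess_total == pytest.approx(0.0)

    def test_positive_uplift_raises_expected_deaths(self, small):
        cfg, panel, truth = small
        ev = EventSpec(2003, 214, 227, 8.0, mode="add")
        _, truth2, info = inject_event(panel, truth, ev, seed=1)
        assert info.true_excess_total > 0
        assert np.all(info.true_excess_by_day.iloc[:14] > 0)

    def test_poisson_excess_within_3sd_of_closed_form(self, small):
        cfg, panel, truth = small
        ev = EventSpec(2003, 214, 227, 8.0, mode="add")
        panel2, truth2, info = inject_event(panel, truth, ev, seed=2)
        diff = panel2.df["deaths"].to_numpy() - panel.df["deaths"].to_numpy()
        realized = diff.sum()
        lam1, lam2 = truth.expected_deaths(), truth2.expected_deaths()
        changed = lam1 != lam2
        sd = np.sqrt(lam1[changed].sum() + lam2[changed].sum())
        assert abs(realized - info.true_excess_total) < 3 * sd

    def test_event_near_panel_edge_rejected(self, small):
        cfg, panel, truth = small
        ev = EventSpec(2003, 360, 364, 8.0)
        with pytest.raises(DataError, match="edge"):
            inject_event(panel, truth, ev, seed=1)

    def test_event_spec_validation(self):
        with pytest.raises(ConfigError):
            EventSpec(2003, 250, 240, 8.0)
        with pytest.raises(ConfigError):
            EventSpec(2003, 214, 227, float("inf"))


class TestDeltaSeries:
    def test_constant_delta_event_mean(self):
        dates = pd.date_range("2003-08-01", periods=14)
        d = make_delta_series(dates, {"GMT+0.0": -1.2})
        assert d["delta_c"].mean() == pytest.approx(-1.2)
        assert set(d["scenario_label"]) == {"GMT+0.0"}

    def test_mixed_sign_mean_is_arithmetic_mean(self):
        dates = pd.date_range("2003-08-01", periods=4)
        vals = np.array([-1.0, 0.5, 2.0, -0.3])
        d = make_delta_series(dates, {"x": vals})
        assert d["delta_c"].mean() == pytest.approx(vals.mean())

    def test_duplicate_dates_rejected(self):
        dates = pd.DatetimeIndex(["2003-08-01", "2003-08-01"])
        with pytest.raises(DataError):
            make_delta_series(dates, {"x": np.array([1.0, 2.0])})
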