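"""Response curves, marginal effects, and the compounding surface."""

import numpy as np
import pandas as pd
import pytest

from heatmort.design import DesignInfo, ModelSpec, support_mask
from heatmort.fitting import CoefficientSamples, FittedModel
from heatmort.response import (
    compounding_surface,
    cumulative_effect,
    marginal_effect,
    response_curve,
)


def handmade_samples(spec: ModelSpec, coef: dict, n_draws: int = 10, tbar_pw: float = 13.0):
    """CoefficientSamples with a fixed, hand-chosen coefficient vector."""
    names = spec.column_names()
    beta = pd.Series(0.0, index=names)
    for k, v in coef.items():
        beta[k] = v
    tbar = pd.Series(tbar_pw, index=[f"D{i:02d}" for i in range(1, 21)])
    info = DesignInfo(
        spec=spec, columns=names, tbar=tbar, tbar_pw=tbar_pw,
        spline_boundary=None, climatology=None, period=(1980, 2002),
    )
    fitted = FittedModel(
        params=beta,
        vcov=pd.DataFrame(0.0, index=names, columns=names),
        vcov_classical=pd.DataFrame(0.0, index=names, columns=names),
        n_obs=1000, n_clusters=10, fe_sizes=(10, 10), n_components=2,
        dof_k=len(names), dropped_columns=[], info=info, period=(1980, 2002),
        n_absorb_iter=1, resid=np.zeros(1),
    )
    draws = pd.DataFrame(
        np.tile(beta.to_numpy(), (n_draws, 1)), columns=names, index=pd.RangeIndex(n_draws)
    )
    return CoefficientSamples(draws=draws, seed=0, fitted=fitted)


LIN_SPEC = ModelSpec(polynomial_order=1, n_lags=2, compounding="none",
                     climate_interaction=False, controls=())


class TestMarginalEffect:
    def test_null_contrast_is_exact_zero_with_zero_width(self, compounding_samples):
        eff = marginal_effect(compounding_samples, (25.0, 28.0), (25.0, 28.0))
        assert eff.mean == 0.0 and eff.lo == 0.0 and eff.hi == 0.0

    def test_closed_form_linear_coefficient(self):
        s = handmade_samples(LIN_SPEC, {"t_l0_p1": 0.01})
        eff = marginal_effect(s, (20.0, 30.0), (20.0, 20.0))
        assert eff.mean == pytest.approx((np.exp(0.1) - 1) * 100, rel=1e-12)

    def test_approximate_scale_option(self):
        s = handmade_samples(LIN_SPEC, {"t_l0_p1": 0.01})
        eff = marginal_effect(s, (20.0, 30.0), (20.0, 20.0), exact=False)
        assert eff.mean == pytest.approx(10.0, rel=1e-12)

    def test_zero_compounding_draws_are_separable(self):
        spec = ModelSpec(polynomial_order=2, n_lags=1, compounding="previous_level",
                         climate_interaction=False, controls=())
        s = handmade_samples(spec, {"t_l0_p1": 0.005, "t_l0_p2": 1e-4})
        a = marginal_effect(s, (20.0, 30.0), (20.0, 20.0))
        b = marginal_effect(s, (30.0, 30.0), (20.0, 20.0))
        assert a.mean == pytest.approx(b.mean)

    def test_bands_are_nested(self, compounding_samples):
        eff = marginal_effect(compounding_samples, (30.0, 30.0), (20.0, 20.0))
        assert eff.lo <= eff.median <= eff.hi


class TestCumulativeEffect:
    def test_identical_paths_zero(self, compounding_samples):
        path = np.full(7, 22.0)
        eff = cumulative_effect(compounding_samples, path, path)
        assert eff.mean == 0.0 and eff.hi == 0.0

    def test_single_day_perturbation_touches_L_plus_one_focal_days(self):
        spec = LIN_SPEC  # L = 2, linear, additive
        s = handmade_samples(spec, {"t_l0_p1": 0.01, "t_l1_p1": 0.02, "t_l2_p1": 0.03})
        base = np.full(12, 20.0)
        bumped = base.copy()
        bumped[6] += 1.0
        affected = []
        for focal in range(3, 12):
            eff = cumulative_effect(s, bumped[: focal + 1], base[: focal + 1])
            if abs(eff.mean) > 1e-12:
                affected.append(focal)
        assert affected == [6, 7, 8]  # the day itself plus L following days

    def test_disjoint_perturbations_add_on_log_scale(self):
        s = handmade_samples(LIN_SPEC, {"t_l0_p1": 0.01, "t_l2_p1": 0.005})
        base = np.full(9, 20.0)
        p1 = base.copy(); p1[-1] += 2.0
        p2 = base.copy(); p2[-3] += 3.0
        both = base.copy(); both[-1] += 2.0; both[-3] += 3.0
        d1 = np.log1p(cumulative_effect(s, p1, base).mean / 100)
        d2 = np.log1p(cumulative_effect(s, p2, base).mean / 100)
        d12 = np.log1p(cumulative_effect(s, both, base).mean / 100)
        assert d12 == pytest.approx(d1 + d2, abs=1e-12)

    def test_short_path_rejected(self, compounding_samples):
        from heatmort.errors import DataError

        with pytest.raises(DataError):
            cumulative_effect(compounding_samples, np.full(3, 20.0), np.full(3, 20.0))


class TestCompoundingSurface:
    def test_reference_cell_zero_and_monotone_in_previous(self, compounding_samples):
        grid = np.arange(16.0, 33.0, 1.0)
        surf = compounding_surface(compounding_samples, grid, grid)
        ref_i = np.where(grid == 20.0)[0][0]
        assert surf.mean_pct[ref_i, ref_i] == pytest.approx(0.0, abs=1e-9)
        cur_i = np.where(grid == 30.0)[0][0]
        hot_prev = np.where(grid == 30.0)[0][0]
        mild_prev = np.where(grid == 20.0)[0][0]
        assert surf.mean_pct[hot_prev, cur_i] > surf.mean_pct[mild_prev, cur_i]

    def test_unsupported_cells_are_nan(self, default_panel_and_truth, compounding_samples):
        cfg, panel, truth = default_panel_and_truth
        mask = support_mask(panel)
        grid = np.arange(-10.0, 40.0, 1.0)
        surf = compounding_surface(compounding_samples, grid, grid, mask=mask)
        assert np.isnan(surf.mean_pct[~surf.supported]).all()
        assert np.isfinite(surf.mean_pct[surf.supported]).all()
        # extreme corner (very cold previous, very hot current) cannot occur
        assert not surf.supported[0, -1]

    def test_supported_cells_contain_observed_pairs(self, default_panel_and_truth):
        """Every cell reported as supported holds at least one consecutive-day
        pair, and every observed pair lands in a supported cell."""
        cfg, panel, truth = default_panel_and_truth
        mask = support_mask(panel)
        df = panel.df
        pairs = []
        for dept, sub in df.groupby("department_id"):
            t = sub["tmean_c"].to_numpy()
            ords = sub["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
            ok = np.diff(ords) == 1
            pairs.append(np.column_stack([t[:-1][ok], t[1:][ok]]))
        pairs = np.vstack(pairs)
        lo = mask.prev_edges[0]
        w = mask.bin_width
        counts = np.zeros_like(mask.grid, dtype=int)
        pi = ((pairs[:, 0] - lo) / w).astype(int)
        ci = ((pairs[:, 1] - lo) / w).astype(int)
        np.add.at(counts, (pi, ci), 1)
        np.testing.assert_array_equal(counts > 0, mask.grid)

    def test_reference_outside_grid_rejected(self, compounding_samples):
        from heatmort.errors import ConfigError

        with pytest.raises(ConfigError):
            compounding_surface(compounding_samples, np.arange(25.0, 35.0), np.arange(25.0, 35.0))


class TestResponseCurve:
    def test_band_zero_at_reference_and_extrapolation_flags(
        self, default_panel_and_truth, compounding_samples
    ):
        cfg, panel, truth = default_panel_and_truth
        mask = support_mask(panel)
        grid = np.arange(-10.0, 45.0, 1.0)
        curve = response_curve(compounding_samples, grid, previous=20.0, mask=mask)
        tab = curve.table
        ref = tab[tab["current_c"] == 20.0].iloc[0]
        assert ref["mean_pct"] == pytest.approx(0.0, abs=1e-9)
        assert ref["lo_pct"] == pytest.approx(ref["hi_pct"], abs=1e-9)
        assert (tab["lo_pct"] <= tab["hi_pct"]).all()
        # far outside any observed current-day range given a 20 degC previous day
        assert tab[tab["current_c"] == 44.0]["extrapolated"].iloc[0]
        assert not tab[tab["current_c"] == 21.0]["extrapolated"].iloc[0]
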