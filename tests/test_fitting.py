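"""Estimation: FE absorption vs dummy OLS, CR1 sandwich, MVN sampling."""

import numpy as np
import pandas as pd
import pytest

from heatmort.design import DesignMatrix, ModelSpec, build_design
from heatmort.errors import NumericalError
from heatmort.fitting import (
    absorb_fixed_effects,
    cluster_robust_vcov,
    fit,
    sample_coefficients,
)


def dummy_ols(design):
    """Explicit dummy-variable least squares (the estimator oracle)."""
    D1 = pd.get_dummies(design.fe_codes[0]).to_numpy(float)
    D2 = pd.get_dummies(design.fe_codes[1]).to_numpy(float)
    X = np.hstack([design.X, D1, D2])
    beta, *_ = np.linalg.lstsq(X, design.y, rcond=None)
    return beta[: design.X.shape[1]]


class TestAbsorption:
    def test_slopes_equal_dummy_ols(self, toy_design, toy_fit):
        np.testing.assert_allclose(
            toy_fit.params.to_numpy(), dummy_ols(toy_design), atol=1e-8
        )

    def test_single_fe_demeaning_is_idempotent(self, toy_design):
        one = DesignMatrix(**{**toy_design.__dict__, "fe_codes": (toy_design.fe_codes[0], toy_design.fe_codes[0])})
        d1 = absorb_fixed_effects(one)
        d2 = absorb_fixed_effects(d1)
        np.testing.assert_allclose(d1.X, d2.X, atol=1e-9)
        np.testing.assert_allclose(d1.y, d2.y, atol=1e-9)

    def test_fe_collinear_column_dropped_with_warning(self, toy_panel):
        spec = ModelSpec(n_lags=1, polynomial_order=1, controls=(), climate_interaction=True)
        # T^1 x Tbar is not collinear, but a department-constant regressor is;
        # emulate by overwriting a control with the department mean temperature
        d = build_design(toy_panel, spec)
        pops = toy_panel.df.groupby("department_id")["population"].first()
        const_col = pops.loc[d.index["department_id"]].to_numpy()
        d.X = np.column_stack([d.X, const_col])
        d.columns = d.columns + ["dept_constant"]
        with pytest.warns(UserWarning, match="dept_constant"):
            f = fit(d)
        assert "dept_constant" in f.dropped_columns

    def test_rank_deficiency_names_collinear_columns(self, toy_design):
        d = toy_design
        bad = DesignMatrix(**{**d.__dict__})
        bad.X = np.column_stack([d.X, d.X[:, 0] * 2.0])
        bad.columns = d.columns + ["dup_of_first"]
        with pytest.raises(NumericalError, match="collinear"):
            fit(bad)


class TestFit:
    def test_exact_linear_recovery(self, toy_design):
        d = DesignMatrix(**{**toy_design.__dict__})
        rng = np.random.default_rng(0)
        beta = rng.normal(size=d.X.shape[1])
        d.y = d.X @ beta  # no noise, no FE component
        f = fit(d)
        np.testing.assert_allclose(f.params.to_numpy(), beta, atol=1e-7)
        assert np.abs(f.resid).max() < 1e-8

    def test_permutation_invariance(self, toy_design, toy_fit):
        rng = np.random.default_rng(1)
        perm = rng.permutation(toy_design.n_obs)
        d = DesignMatrix(**{**toy_design.__dict__})
        d.X = toy_design.X[perm]
        d.y = toy_design.y[perm]
        d.fe_codes = (toy_design.fe_codes[0][perm], toy_design.fe_codes[1][perm])
        d.clusters = toy_design.clusters[perm]
        d.index = toy_design.index.iloc[perm].reset_index(drop=True)
        f = fit(d)
        np.testing.assert_allclose(f.params.to_numpy(), toy_fit.params.to_numpy(), atol=1e-8)

    def test_recovers_generator_truth_under_small_noise(self, default_panel_and_truth):
        """Estimates on a Poisson panel sit within a few SEs of the generator's
        coefficients for the well-identified low-order terms."""
        cfg, panel, truth = default_panel_and_truth
        d = build_design(panel, ModelSpec(compounding="previous_level"))
        f = fit(d)
        se = f.se()
        w0 = cfg.lag_weights[0]
        true_comp = w0 * cfg.compound_coeff
        est = f.params["t_l0_p4_x_prev0"]
        assert abs(est - true_comp) < 4 * se["t_l0_p4_x_prev0"]


class TestClusterVcov:
    def test_zero_residuals_give_zero_matrix(self, toy_design):
        X = toy_design.X[:, :2]
        V = cluster_robust_vcov(X, np.zeros(len(X)), toy_design.clusters, dof_k=5)
        np.testing.assert_allclose(V, 0.0)

    def test_matches_brute_force_sandwich(self, toy_design, toy_fit):
        dd = absorb_fixed_effects(toy_design)
        Xd = dd.X
        beta = np.linalg.lstsq(Xd, dd.y, rcond=None)[0]
        u = dd.y - Xd @ beta
        K = Xd.shape[1] + toy_fit.fe_sizes[0] + toy_fit.fe_sizes[1] - toy_fit.n_components
        G = len(np.unique(dd.clusters))
        N = len(u)
        bread = np.linalg.inv(Xd.T @ Xd)
        meat = np.zeros((Xd.shape[1],) * 2)
        for g in np.unique(dd.clusters):
            h = Xd[dd.clusters == g].T @ u[dd.clusters == g]
            meat += np.outer(h, h)
        V = (G / (G - 1)) * ((N - 1) / (N - K)) * bread @ meat @ bread
        np.testing.assert_allclose(V, toy_fit.vcov.to_numpy(), atol=1e-10)

    def test_matches_statsmodels_cluster_covariance(self, toy_design, toy_fit):
        """Independent route: statsmodels OLS on the absorbed design with
        clustered covariance, rescaled to our absorbed-dof convention."""
        sm = pytest.importorskip("statsmodels.api")
        dd = absorb_fixed_effects(toy_design)
        res = sm.OLS(dd.y, dd.X).fit(
            cov_type="cluster", cov_kwds={"groups": dd.clusters, "use_correction": True}
        )
        N, k = dd.X.shape
        K_ours = k + toy_fit.fe_sizes[0] + toy_fit.fe_sizes[1] - toy_fit.n_components
        rescale = (N - k) / (N - K_ours)
        np.testing.assert_allclose(
            res.cov_params() * rescale, toy_fit.vcov.to_numpy(), rtol=1e-8
        )

    def test_variances_nonnegative_across_random_problems(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, k, G = 60, 3, 5
            X = rng.normal(size=(n, k))
            u = rng.normal(size=n)
            cl = rng.integers(0, G, size=n)
            V = cluster_robust_vcov(X, u, cl, dof_k=k)
            assert np.all(np.diag(V) >= 0)

    def test_clustered_exceeds_classical_under_within_cluster_correlation(self):
        """With a common shock per cluster, clustered SEs exceed classical
        i.i.d. SEs in aggregate."""
        rng = np.random.default_rng(4)
        n_per, G = 200, 10
        cl = np.repeat(np.arange(G), n_per)
        x = rng.normal(size=G * n_per) + np.repeat(rng.normal(size=G), n_per)
        u = 0.5 * rng.normal(size=G * n_per) + np.repeat(rng.normal(size=G), n_per)
        X = x[:, None] - x.mean()
        V_cl = cluster_robust_vcov(X, u, cl, dof_k=1)
        sigma2 = u @ u / (len(u) - 1)
        V_iid = sigma2 * np.linalg.inv(X.T @ X)
        assert V_cl[0, 0] > V_iid[0, 0]

    def test_single_cluster_rejected(self, toy_design):
        with pytest.raises(NumericalError):
            cluster_robust_vcov(toy_design.X[:, :2], toy_design.y, np.zeros(toy_design.n_obs, dtype=int), 3)


class TestCoefficientSamples:
    def test_default_draw_count(self, toy_fit):
        assert sample_coefficients(toy_fit, seed=0).n_samples == 500

    def test_degenerate_covariance_returns_point_mass(self, toy_fit):
        f = toy_fit
        zero = f.vcov * 0.0
        frozen = type(f)(**{**f.__dict__, "vcov": zero})
        s = sample_coefficients(frozen, n=50, seed=1)
        np.testing.assert_allclose(
            s.draws.to_numpy(), np.tile(f.params.to_numpy(), (50, 1))
        )

    def test_empirical_covariance_converges(self, toy_fit):
        s = sample_coefficients(toy_fit, n=100_000, seed=2)
        emp = np.cov(s.draws.to_numpy().T)
        V = toy_fit.vcov.to_numpy()
        rel = np.linalg.norm(emp - V) / np.linalg.norm(V)
        assert rel < 0.05

    def test_seed_reproducibility(self, toy_fit):
        a = sample_coefficients(toy_fit, n=10, seed=9).draws
        b = sample_coefficients(toy_fit, n=10, seed=9).draws
        pd.testing.assert_frame_equal(a, b)

    def test_nonfinite_covariance_rejected(self, toy_fit):
        bad = toy_fit.vcov.copy()
        bad.iloc[0, 0] = np.nan
        broken = type(toy_fit)(**{**toy_fit.__dict__, "vcov": bad})
        with pytest.raises(NumericalError):
            sample_coefficients(broken)
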