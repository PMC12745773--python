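"""Shared fixtures: small synthetic panels and fitted models.

Expensive objects (a default-scale panel, a fitted compounding model) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pandas as pd
import pytest

from heatmort.design import ModelSpec, build_design
from heatmort.fitting import fit, sample_coefficients
from heatmort.generator import GeneratorConfig, generate_panel
from heatmort.panel import PanelDataset


@pytest.fixture(scope="session")
def toy_config():
    """3 departments x 2 years, January-February only (via doy filter)."""
    return GeneratorConfig(n_departments=3, year_start=2000, year_end=2001)


@pytest.fixture(scope="session")
def toy_panel(toy_config):
    """3 departments x 2 years x 30 days: small enough for dummy-variable OLS."""
    panel, _ = generate_panel(toy_config, seed=5)
    df = panel.df[panel.df["day_of_year"] <= 30].copy()
    return PanelDataset(df, panel.dept_mean_temp, validate=False)


@pytest.fixture(scope="session")
def toy_design(toy_panel):
    spec = ModelSpec(n_lags=2, polynomial_order=2, controls=(), climate_interaction=False)
    return build_design(toy_panel, spec)


@pytest.fixture(scope="session")
def toy_fit(toy_design):
    return fit(toy_design)


@pytest.fixture(scope="session")
def default_panel_and_truth():
    """One default-conditions Poisson panel (10 departments x 25 years)."""
    cfg = GeneratorConfig()
    return cfg, *generate_panel(cfg, seed=123)


@pytest.fixture(scope="session")
def compounding_samples(default_panel_and_truth):
    """500 coefficient draws from the compounding model on the default panel."""
    cfg, panel, truth = default_panel_and_truth
    design = build_design(panel, ModelSpec(compounding="previous_level"))
    fitted = fit(design)
    return sample_coefficients(fitted, n=500, seed=7)


def tiny_manual_panel(rows):
    """Build a validated panel from (dept, date, deaths, pop, t, rh, pr) rows."""
    df = pd.DataFrame(
        rows,
        columns=["department_id", "date", "deaths", "population", "tmean_c", "rh_pct", "precip_mm"],
    )
    return PanelDataset(df)
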