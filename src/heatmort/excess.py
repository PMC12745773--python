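"""Excess mortality against a department-specific seasonal-and-trend baseline.

The baseline models log mortality rate as an additive two-way decomposition,
log(M_idy) = mu_iy + delta_id: each department gets its own long-term trend
(one level per year) and its own seasonal cycle (one level per calendar day).
Excess deaths in a window are observed deaths minus the exponentiated
baseline prediction converted back to counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import RATE_SCALE, PanelDataset


@dataclass
class BaselineModel:
    """Fitted two-way additive baseline for log mortality rates.

    The additive decomposition is identified by constraining each
    department's seasonal terms to mean zero across its observed calendar
    days; predictions are invariant to this choice.
    """

    mu: pd.Series  # (department_id, year) -> level
    delta: pd.Series  # (department_id, day_of_year) -> seasonal term
    period: tuple[int, int]
    n_obs: int
    n_dropped_zero_deaths: int

    def predict_log_rate(self, df: pd.DataFrame) -> np.ndarray:
        """Baseline log rate for rows with department_id, year, day_of_year."""
        mu = self.mu.reindex(
            pd.MultiIndex.from_frame(df[["department_id", "year"]])
        ).to_numpy()
        de = self.delta.reindex(
            pd.MultiIndex.from_frame(df[["department_id", "day_of_year"]])
        ).to_numpy()
        out = mu + de
        if np.isnan(out).any():
            i = int(np.flatnonzero(np.isnan(out))[0])
            row = df.iloc[i]
            raise DataError(
                "baseline has no term for "
                f"({row['department_id']}, {row['year']}, {row['day_of_year']})"
            )
        return out


def fit_baseline(
    panel: PanelDataset,
    period: tuple[int, int],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> BaselineModel:
    """Least-squares fit of log(M) = mu_iy + delta_id by alternating means.

    Equivalent to OLS with saturated department-by-year and
    department-by-day-of-year dummies; iterated to ``tol`` on the largest
    update.  Zero-death days carry an undefined log rate and are excluded
    (counted); a (department, day_of_year) cell with no usable observation at
    all is an error.
    """
    y0, y1 = period
    if y1 - y0 + 1 < 2:
        raise DataError("baseline period must span at least 2 years")
    sub = panel.subset_years(y0, y1).df
    usable = sub[sub["deaths"] > 0].copy()
    n_dropped = len(sub) - len(usable)

    all_cells = sub.groupby(["department_id", "day_of_year"]).size()
    good_cells = usable.groupby(["department_id", "day_of_year"]).size()
    empty = all_cells.index.difference(good_cells.index)
    if len(empty) > 0:
        raise DataError(
            f"(department, day_of_year) cells with no usable observations: "
            f"{list(empty[:3])}..."
        )

    y = np.log(usable["deaths"] / usable["population"] * RATE_SCALE)
    g_my = pd.MultiIndex.from_frame(usable[["department_id", "year"]])
    g_dd = pd.MultiIndex.from_frame(usable[["department_id", "day_of_year"]])
    mu = pd.Series(0.0, index=g_my.unique().sort_values())
    delta = pd.Series(0.0, index=g_dd.unique().sort_values())

    for _ in range(max_iter):
        resid = y.to_numpy() - delta.reindex(g_dd).to_numpy()
        mu_new = pd.Series(resid, index=g_my).groupby(level=[0, 1]).mean()
        resid = y.to_numpy() - mu_new.reindex(g_my).to_numpy()
        delta_new = pd.Series(resid, index=g_dd).groupby(level=[0, 1]).mean()
        change = max(
            float((mu_new - mu.reindex(mu_new.index)).abs().max()),
            float((delta_new - delta.reindex(delta_new.index)).abs().max()),
        )
        mu, delta = mu_new, delta_new
        if change < tol:
            break
    else:
        raise DataError(f"baseline fit did not converge (last change {change:.2e})")

    # identification: seasonal terms mean-zero within each department
    dept_means = delta.groupby(level=0).mean()
    delta = delta - dept_means.reindex(delta.index.get_level_values(0)).to_numpy()
    mu = mu + dept_means.reindex(mu.index.get_level_values(0)).to_numpy()

    return BaselineModel(
        mu=mu,
        delta=delta,
        period=period,
        n_obs=len(usable),
        n_dropped_zero_deaths=n_dropped,
    )


def excess_deaths(
    panel: PanelDataset,
    baseline: BaselineModel,
    year: int,
    doy_start: int,
    doy_end: int,
    departments: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Observed minus baseline-expected deaths over a window.

    Returns the per-cell table (department_id, date, observed_deaths,
    expected_deaths, excess_deaths) and the aggregate sum.  Expected counts
    are exp(predicted log rate) x population / 100,000 (count scale; no
    retransformation correction is applied).
    """
    df = panel.df
    m = (
        (df["year"] == year)
        & (df["day_of_year"] >= doy_start)
        & (df["day_of_year"] <= doy_end)
    )
    if departments is not None:
        m &= df["department_id"].isin(departments)
    win = df[m].copy()
    if win.empty:
        raise DataError(f"window {year}:{doy_start}-{doy_end} matches no panel rows")
    n_days_expected = doy_end - doy_start + 1
    per_dept = win.groupby("department_id").size()
    short = per_dept[per_dept < n_days_expected - 1]  # tolerate a missing Feb 29
    if len(short) > 0:
        raise DataError(f"window cells missing from panel for: {list(short.index)}")

    pred = baseline.predict_log_rate(win)
    expected = np.exp(pred) * win["population"].to_numpy() / RATE_SCALE
    out = pd.DataFrame(
        {
            "department_id": win["department_id"].to_numpy(),
            "date": win["date"].to_numpy(),
            "observed_deaths": win["deaths"].to_numpy(),
            "expected_deaths": expected,
            "excess_deaths": win["deaths"].to_numpy() - expected,
        }
    )
    return out, float(out["excess_deaths"].sum())
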