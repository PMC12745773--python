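"""Counterfactual temperature scenarios and attributable event mortality.

A counterfactual event is built by the region-wide delta method: one daily
temperature difference (factual minus counterfactual prediction for the same
meteorology at a different annual global-mean-temperature level) applied
uniformly to every department.  Event mortality under a scenario is the
exposure-response contrast between the scenario's temperature path and the
climatological path, converted to deaths by multiplying the per-draw percent
change with the climatological mean death count for that department and
calendar day.  Attributable deaths are the *paired* per-draw difference
between the factual and counterfactual predictions; intervals are percentiles
over the pooled draw-by-delta-source ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendar import day_of_year_366
from .errors import ConfigError, DataError
from .fitting import CoefficientSamples
from .panel import Climatology, PanelDataset
from .response import path_design

OBSERVED_LABEL = "observed"


@dataclass
class TemperatureScenario:
    """Daily temperatures per department over an event window plus the lag
    history needed to predict the first window day."""

    label: str
    df: pd.DataFrame  # department_id, date, tmean_c, population
    window_start: pd.Timestamp
    provenance: str = "observed"  # or "delta"
    source_id: str | None = None
    #: unshifted temperatures and the cumulative per-row delta; kept so that
    #: stacked delta applications reconstruct temperatures as base + total
    #: (a +d then -d round trip is then bit-exact)
    base_tmean: np.ndarray | None = None
    delta_total: np.ndarray | None = None

    def __post_init__(self) -> None:
        need = {"department_id", "date", "tmean_c", "population"}
        if not need.issubset(self.df.columns):
            raise DataError(f"scenario frame needs columns {sorted(need)}")
        self.df = self.df.sort_values(["department_id", "date"]).reset_index(drop=True)
        if self.base_tmean is None:
            self.base_tmean = self.df["tmean_c"].to_numpy().copy()
        if self.delta_total is None:
            self.delta_total = np.zeros(len(self.df))

    @property
    def departments(self) -> list[str]:
        return list(self.df["department_id"].unique())

    @property
    def window_dates(self) -> pd.DatetimeIndex:
        d = self.df[self.df["date"] >= self.window_start]["date"].unique()
        return pd.DatetimeIndex(sorted(d))

    def n_history(self) -> int:
        dept = self.departments[0]
        sub = self.df[self.df["department_id"] == dept]
        return int((sub["date"] < self.window_start).sum())


def scenario_from_panel(
    panel: PanelDataset,
    year: int,
    doy_start: int,
    doy_end: int,
    n_history: int,
    label: str = OBSERVED_LABEL,
) -> TemperatureScenario:
    """Extract the observed temperatures for an event window plus history."""
    df = panel.df
    win = df[(df["year"] == year) & (df["day_of_year"] >= doy_start) & (df["day_of_year"] <= doy_end)]
    if win.empty:
        raise DataError(f"window {year}:{doy_start}-{doy_end} not in panel")
    start = win["date"].min()
    lo = start - pd.Timedelta(days=n_history)
    sel = df[(df["date"] >= lo) & (df["date"] <= win["date"].max())]
    counts = sel.groupby("department_id")["date"].count()
    if counts.nunique() != 1:
        raise DataError("scenario window/history incomplete for some departments")
    return TemperatureScenario(
        label=label,
        df=sel[["department_id", "date", "tmean_c", "population"]].copy(),
        window_start=start,
        provenance="observed",
    )


def apply_deltas(
    observed: TemperatureScenario,
    deltas: pd.DataFrame,
    label: str,
    source_id: str | None = None,
    history_delta: str = "first",
) -> TemperatureScenario:
    """Shift every department's temperature on day d by the region-wide
    delta_d.

    Deltas must cover every window day.  History days before the window reuse
    the first window day's delta by default (``history_delta='first'``) so the
    lag structure sees no artificial jump; ``'zero'`` leaves history unshifted.
    """
    need = {"date", "delta_c"}
    if not need.issubset(deltas.columns):
        raise DataError(f"delta table needs columns {sorted(need)}")
    if source_id is not None and "source_id" in deltas.columns:
        deltas = deltas[deltas["source_id"] == source_id]
    if deltas.duplicated(subset=["date"]).any():
        raise DataError("duplicate dates in delta series (filter by source_id/label first)")
    dmap = pd.Series(
        deltas["delta_c"].to_numpy(dtype=float), index=pd.DatetimeIndex(deltas["date"])
    )
    window = observed.window_dates
    missing = window.difference(dmap.index)
    if len(missing) > 0:
        raise DataError(f"delta series missing window day(s): {list(missing[:3])}")

    df = observed.df.copy()
    shift = dmap.reindex(pd.DatetimeIndex(df["date"])).to_numpy()
    if history_delta == "first":
        fill = float(dmap.loc[window[0]])
    elif history_delta == "zero":
        fill = 0.0
    else:
        raise ConfigError(f"unknown history_delta policy {history_delta!r}")
    shift = np.where(np.isnan(shift), fill, shift)
    total = observed.delta_total + shift
    # reconstruct from the unshifted base so deltas that cancel leave the
    # temperatures bit-identical to the observed scenario
    df["tmean_c"] = np.where(total == 0.0, observed.base_tmean,
                             observed.base_tmean + total)
    return TemperatureScenario(
        label=label,
        df=df,
        window_start=observed.window_start,
        provenance="delta",
        source_id=source_id,
        base_tmean=observed.base_tmean.copy(),
        delta_total=total,
    )


# -----------------------------------------------------------------------------


@dataclass
class EventPrediction:
    """Per-draw heat-related deaths for each department-day of an event."""

    deaths: np.ndarray  # (n_draws, n_cells)
    cells: pd.DataFrame  # department_id, date, day_of_year, clim_deaths, population
    label: str
    draw_ids: np.ndarray
    period: tuple[int, int] | None

    @property
    def n_draws(self) -> int:
        return self.deaths.shape[0]

    def totals_by_draw(self) -> np.ndarray:
        return self.deaths.sum(axis=1)

    def summary(self) -> dict:
        t = self.totals_by_draw()
        return {
            "label": self.label,
            "mean": float(t.mean()),
            "lo": float(np.percentile(t, 2.5)),
            "hi": float(np.percentile(t, 97.5)),
        }

    def daily(self) -> pd.DataFrame:
        """Mean and 95% band of national deaths per day (percentiles of the
        daily series, not of totals)."""
        out = []
        for date, idx in self.cells.groupby("date").groups.items():
            d = self.deaths[:, np.asarray(idx)].sum(axis=1)
            out.append(
                {
                    "date": date,
                    "mean": d.mean(),
                    "lo": np.percentile(d, 2.5),
                    "hi": np.percentile(d, 97.5),
                }
            )
        return pd.DataFrame(out)


def predict_event_deaths(
    samples: CoefficientSamples,
    scenario: TemperatureScenario,
    climatology: Climatology,
) -> EventPrediction:
    """Heat-related deaths per draw and department-day.

    For each department-day, the percent change between the scenario
    temperature path and the climatological path for the same calendar days
    (summing all lag contributions) is multiplied by the climatological mean
    death count for that department and calendar day.  Negative values (days
    cooler than climatology) are retained.
    """
    spec, info = samples.spec, samples.info
    H = spec.n_lags + (1 if spec.compounding != "none" else 0)
    if scenario.n_history() < H:
        raise DataError(
            f"scenario carries {scenario.n_history()} history days; {H} required"
        )
    draws = samples.draws.to_numpy()
    kept = samples.draws.columns

    frames, contrasts, clim_deaths_all = [], [], []
    for dept, sub in scenario.df.groupby("department_id", sort=True):
        sub = sub.sort_values("date")
        temps = sub["tmean_c"].to_numpy(dtype=float)
        dates = pd.DatetimeIndex(sub["date"])
        doys = day_of_year_366(dates)
        clim_t = climatology.temperature(dept, doys)
        win = np.flatnonzero(dates >= scenario.window_start)
        n_days = len(win)
        # sliding paths: rows end on each window day
        paths = np.stack([temps[i - H : i + 1] for i in win])
        clim_paths = np.stack([clim_t[i - H : i + 1] for i in win])
        tb = float(info.tbar.loc[dept])
        anom = spec.compounding == "previous_anomaly"
        r_obs = path_design(spec, info, paths, tb, clims=clim_paths if anom else None)
        r_clim = path_design(spec, info, clim_paths, tb, clims=clim_paths if anom else None)
        con = (r_obs - r_clim).reindex(columns=kept, fill_value=0.0)
        dropped_nonzero = set(r_obs.columns) - set(kept)
        if dropped_nonzero and np.any((r_obs - r_clim)[list(dropped_nonzero)].to_numpy() != 0):
            raise DataError(f"scenario contrast needs dropped columns: {sorted(dropped_nonzero)}")
        contrasts.append(con.to_numpy())
        cd = climatology.deaths(dept, doys[win])
        clim_deaths_all.append(cd)
        frames.append(
            pd.DataFrame(
                {
                    "department_id": dept,
                    "date": dates[win],
                    "day_of_year": doys[win],
                    "clim_deaths": cd,
                    "population": sub["population"].to_numpy()[win],
                }
            )
        )
    C = np.vstack(contrasts)  # (n_cells, K)
    clim_deaths = np.concatenate(clim_deaths_all)
    delta = draws @ C.T  # (n_draws, n_cells)
    pct = np.exp(delta) - 1.0
    deaths = pct * clim_deaths[None, :]
    return EventPrediction(
        deaths=deaths,
        cells=pd.concat(frames, ignore_index=True),
        label=scenario.label,
        draw_ids=samples.draw_ids.copy(),
        period=samples.period,
    )


# -----------------------------------------------------------------------------


@dataclass
class AttributionResult:
    """Attributable deaths (factual minus counterfactual, paired per draw)."""

    att_totals: np.ndarray  # pooled ensemble of attributable totals
    att_fractions: np.ndarray  # per-draw attributable fraction
    per_day: pd.DataFrame
    per_department: pd.DataFrame
    observed_label: str
    counterfactual_labels: list[str]
    n_draws: int
    n_sources: int

    def summary(self) -> dict:
        t, f = self.att_totals, self.att_fractions
        return {
            "observed": self.observed_label,
            "counterfactual": self.counterfactual_labels,
            "attributable_deaths_mean": float(t.mean()),
            "attributable_deaths_lo": float(np.percentile(t, 2.5)),
            "attributable_deaths_hi": float(np.percentile(t, 97.5)),
            "attributable_fraction_mean": float(f.mean()),
            "attributable_fraction_lo": float(np.percentile(f, 2.5)),
            "attributable_fraction_hi": float(np.percentile(f, 97.5)),
            "ensemble_size": int(len(t)),
        }


def attributable_deaths(
    observed: EventPrediction,
    counterfactual: EventPrediction | list[EventPrediction],
) -> AttributionResult:
    """Paired per-draw differences, pooled over counterfactual delta sources.

    Every counterfactual must share the observed prediction's cells and draw
    order (the difference is taken draw by draw, never between summaries);
    unpaired ensembles are an error.
    """
    cfs = counterfactual if isinstance(counterfactual, list) else [counterfactual]
    obs_tot = observed.totals_by_draw()
    diffs, frac = [], []
    day_diffs, dept_diffs = [], []
    for cf in cfs:
        if cf.deaths.shape != observed.deaths.shape:
            raise DataError("unpaired ensembles: prediction shapes differ")
        if not np.array_equal(cf.draw_ids, observed.draw_ids):
            raise DataError("unpaired ensembles: draw order differs between inputs")
        if not cf.cells[["department_id", "date"]].equals(
            observed.cells[["department_id", "date"]]
        ):
            raise DataError("unpaired ensembles: cell layout differs")
        d = observed.deaths - cf.deaths  # (n_draws, n_cells)
        diffs.append(d.sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            frac.append(np.where(obs_tot != 0, d.sum(axis=1) / obs_tot, 0.0))
        day_diffs.append(d)
        dept_diffs.append(d)

    att_totals = np.concatenate(diffs)
    att_fractions = np.concatenate(frac)
    pooled = np.vstack(day_diffs)  # (n_draws * n_sources, n_cells)

    cells = observed.cells
    per_day = []
    for date, idx in cells.groupby("date").groups.items():
        d = pooled[:, np.asarray(idx)].sum(axis=1)
        per_day.append(
            {"date": date, "mean": d.mean(), "lo": np.percentile(d, 2.5), "hi": np.percentile(d, 97.5)}
        )
    per_dept = []
    for dept, idx in cells.groupby("department_id").groups.items():
        idx = np.asarray(idx)
        d = pooled[:, idx].sum(axis=1)
        pop = float(cells.loc[idx, "population"].mean())
        per_dept.append(
            {
                "department_id": dept,
                "mean": d.mean(),
                "lo": np.percentile(d, 2.5),
                "hi": np.percentile(d, 97.5),
                "rate_per_100k": d.mean() / pop * 1e5,
            }
        )
    return AttributionResult(
        att_totals=att_totals,
        att_fractions=att_fractions,
        per_day=pd.DataFrame(per_day),
        per_department=pd.DataFrame(per_dept),
        observed_label=observed.label,
        counterfactual_labels=[cf.label for cf in cfs],
        n_draws=observed.n_draws,
        n_sources=len(cfs),
    )


def project_event(
    samples: CoefficientSamples,
    scenario: TemperatureScenario,
    climatology: Climatology,
) -> EventPrediction:
    """Event prediction under a (typically warmed) scenario using coefficient
    samples from a tagged estimation period, for adaptation contrasts."""
    if samples.period is None:
        raise ConfigError(
            "project_event requires coefficient samples tagged with an estimation period"
        )
    return predict_event_deaths(samples, scenario, climatology)
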