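"""Department-day panel data model.

The observational unit is a department-day: an all-cause death count, the
population at risk, and daily weather (mean temperature, mean relative
humidity, accumulated precipitation).  Mortality rates are expressed as deaths
per 100,000 population per day throughout the package.

A :class:`PanelDataset` wraps a validated :class:`pandas.DataFrame` with one
row per (department, year, day_of_year) and optionally carries each
department's long-term mean temperature ``T̄_i`` used for the climate
interaction in the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import day_of_year_366
from .errors import DataError, IntegrityError, SchemaError

RATE_SCALE = 100_000.0  # deaths per this many persons per day

PANEL_COLUMNS = [
    "department_id",
    "date",
    "deaths",
    "population",
    "tmean_c",
    "rh_pct",
    "precip_mm",
]

_NUMERIC = ["deaths", "population", "tmean_c", "rh_pct", "precip_mm"]


@dataclass
class PanelDataset:
    """Validated department-day panel.

    Attributes
    ----------
    df
        One row per department-day, sorted by (department_id, date), with
        derived integer columns ``year`` and ``day_of_year`` (leap-calendar
        indexing, Feb 29 = 60).
    dept_mean_temp
        Optional per-department long-term mean temperature (°C), constant
        within a department.
    """

    df: pd.DataFrame
    dept_mean_temp: pd.Series | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            self.df = _validate(self.df)
        elif "year" not in self.df.columns or "day_of_year" not in self.df.columns:
            self.df = self.df.copy()
            self.df["year"] = self.df["date"].dt.year.astype(int)
            self.df["day_of_year"] = day_of_year_366(self.df["date"])
        # derived subsets/copies of an already-validated frame stay trusted
        self.validate = False
        if self.dept_mean_temp is not None:
            missing = set(self.departments) - set(self.dept_mean_temp.index)
            if missing:
                raise DataError(f"dept_mean_temp missing departments: {sorted(missing)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def departments(self) -> list[str]:
        return list(self.df["department_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def subset_years(self, year_start: int, year_end: int) -> "PanelDataset":
        sub = self.df[(self.df["year"] >= year_start) & (self.df["year"] <= year_end)]
        if sub.empty:
            raise DataError(f"no records in years {year_start}-{year_end}")
        return replace(self, df=sub.copy())

    def subset_departments(self, include: list[str]) -> "PanelDataset":
        sub = self.df[self.df["department_id"].isin(include)]
        if sub.empty:
            raise DataError("department include-list matches no records")
        return replace(self, df=sub.copy())

    def mortality_rate(self) -> pd.Series:
        """Deaths per 100,000 per day."""
        return self.df["deaths"] / self.df["population"] * RATE_SCALE

    def with_mean_temperature(self, period: tuple[int, int] | None = None) -> "PanelDataset":
        tbar = department_mean_temperature(self, period)
        return replace(self, dept_mean_temp=tbar)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel is missing required column(s): {missing}")
    df = df.copy()
    df["department_id"] = df["department_id"].astype(str)
    if not np.issubdtype(df["date"].dtype, np.datetime64):
        try:
            df["date"] = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparseable date column: {exc}") from None
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            idx = int(np.flatnonzero(vals.isna())[0])
            raise SchemaError(f"non-numeric or missing value in '{col}' at row {idx}")
        df[col] = vals.astype(float)

    df["year"] = df["date"].dt.year.astype(int)
    df["day_of_year"] = day_of_year_366(df["date"])

    dup = df.duplicated(subset=["department_id", "date"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["department_id", "date"]]
        raise IntegrityError(
            f"duplicate department-day key: ({first['department_id']}, "
            f"{first['date'].date()})"
        )
    if (df["population"] <= 0).any():
        raise IntegrityError("population must be strictly positive for every record")
    if (df["deaths"] < 0).any():
        raise IntegrityError("deaths must be non-negative")
    if not np.allclose(df["deaths"], np.round(df["deaths"])):
        raise IntegrityError("deaths must be integral counts")
    df["deaths"] = np.round(df["deaths"]).astype(float)

    df = df.sort_values(["department_id", "date"], kind="mergesort").reset_index(drop=True)
    return df


# -- I/O ----------------------------------------------------------------------

def read_panel(path: str | Path, include_departments: list[str] | None = None) -> PanelDataset:
    """Read a panel CSV (columns: department_id, date, deaths, population,
    tmean_c, rh_pct, precip_mm; ISO-8601 dates, UTF-8, header required)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel file not found: {path}")
    df = pd.read_csv(path, dtype={"department_id": str})
    panel = PanelDataset(df[[c for c in df.columns if c in PANEL_COLUMNS]])
    if include_departments is not None:
        panel = panel.subset_departments(include_departments)
    return panel


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    out = panel.df[PANEL_COLUMNS].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out["deaths"] = out["deaths"].astype(int)
    out.to_csv(path, index=False)


# -- derived summaries --------------------------------------------------------

def department_mean_temperature(
    panel: PanelDataset, period: tuple[int, int] | None = None
) -> pd.Series:
    """Unweighted mean of daily temperature per department over ``period``.

    This is the long-term mean climate ``T̄_i`` interacted with the temperature
    polynomial to let the response vary across space.
    """
    df = panel.df
    if period is not None:
        y0, y1 = period
        df = df[(df["year"] >= y0) & (df["year"] <= y1)]
        if df.empty:
            raise DataError(f"period {period} does not overlap panel years")
    tbar = df.groupby("department_id")["tmean_c"].mean()
    absent = set(panel.departments) - set(tbar.index)
    if absent:
        raise DataError(
            f"department(s) with no records in period {period}: {sorted(absent)}"
        )
    tbar.name = "tbar_c"
    return tbar


def population_weighted_average(
    panel: PanelDataset,
    variable: str = "tmean_c",
    selector: pd.Series | None = None,
) -> pd.Series:
    """Population-weighted cross-department average of ``variable`` per day.

    Σ_i pop_i · x_i / Σ_i pop_i for each date; invariant to rescaling all
    populations by a positive constant.
    """
    df = panel.df if selector is None else panel.df[np.asarray(selector, dtype=bool)]
    if df.empty:
        raise DataError("empty selection for population-weighted average")
    w = df["population"]
    num = (df[variable] * w).groupby(df["date"]).sum()
    den = w.groupby(df["date"]).sum()
    out = num / den
    out.name = variable
    return out


def population_weighted_mean_climate(panel: PanelDataset) -> float:
    """Single evaluation climate: population-weighted average of T̄_i."""
    if panel.dept_mean_temp is None:
        raise DataError("panel has no department mean temperatures; call with_mean_temperature")
    pop = panel.df.groupby("department_id")["population"].mean()
    tbar = panel.dept_mean_temp.reindex(pop.index)
    return float((tbar * pop).sum() / pop.sum())


# -- climatology --------------------------------------------------------------

@dataclass
class Climatology:
    """Per (department, day_of_year) reference-period means.

    ``tmean_clim_c`` is the mean temperature and ``deaths_clim`` the mean daily
    death count over the reference years.  These are the baselines against
    which event temperatures are contrasted and by which percent changes in
    mortality are converted to death counts.
    """

    df: pd.DataFrame  # columns: department_id, day_of_year, tmean_clim_c, deaths_clim
    period: tuple[int, int]
    _idx: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        need = {"department_id", "day_of_year", "tmean_clim_c", "deaths_clim"}
        if not need.issubset(self.df.columns):
            raise SchemaError(f"climatology needs columns {sorted(need)}")
        self._idx = self.df.set_index(["department_id", "day_of_year"]).sort_index()

    def _lookup(self, column: str, dept: str, doys: np.ndarray) -> np.ndarray:
        keys = [(dept, int(d)) for d in np.atleast_1d(doys)]
        try:
            return self._idx.loc[keys, column].to_numpy(dtype=float)
        except KeyError:
            have = self._idx.index
            bad = [k for k in keys if k not in have]
            raise DataError(f"climatology has no entry for {bad[:3]}...") from None

    def temperature(self, dept: str, doys: np.ndarray) -> np.ndarray:
        return self._lookup("tmean_clim_c", dept, doys)

    def deaths(self, dept: str, doys: np.ndarray) -> np.ndarray:
        return self._lookup("deaths_clim", dept, doys)

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out["ref_start"], out["ref_end"] = self.period
        out.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "Climatology":
        df = pd.read_csv(path, dtype={"department_id": str})
        period = (int(df["ref_start"].iloc[0]), int(df["ref_end"].iloc[0]))
        return cls(df.drop(columns=["ref_start", "ref_end"]), period)


def build_climatology(panel: PanelDataset, period: tuple[int, int]) -> Climatology:
    """Reference-period mean temperature and deaths per calendar day.

    ``period`` must lie fully inside the panel's year range.
    """
    y0, y1 = period
    years = panel.years
    if y0 < years[0] or y1 > years[-1]:
        raise DataError(
            f"reference period {period} not inside panel years {years[0]}-{years[-1]}"
        )
    sub = panel.df[(panel.df["year"] >= y0) & (panel.df["year"] <= y1)]
    clim = (
        sub.groupby(["department_id", "day_of_year"])
        .agg(tmean_clim_c=("tmean_c", "mean"), deaths_clim=("deaths", "mean"))
        .reset_index()
    )
    return Climatology(clim, period)
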