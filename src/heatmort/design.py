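"""Turn a panel plus a declarative model specification into a regression design.

The estimating equation regresses log mortality rate on, for each lag
j = 0..L, a degree-P polynomial in the day-(d-j) temperature, optionally
interacted with the department's long-term mean climate and with a transform
of the *preceding* day's temperature (the temporal-compounding interaction:
lag j is interacted with day d-j-1, so day d-2 is interacted with day d-3),
plus lagged weather controls and two sets of fixed-effect labels
(department-by-year and department-by-day-of-year).

Temperatures enter the polynomial uncentered; all contrasts downstream
difference out the level, so centering would be a mathematical no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .panel import RATE_SCALE, Climatology, PanelDataset, department_mean_temperature

COMPOUNDING_MODES = ("none", "previous_level", "previous_anomaly", "previous_spline")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the exposure-response regression.

    Defaults reproduce the main specification: fourth-order polynomial, five
    lags, climate interaction on, humidity and precipitation controls entered
    with the same lags as temperature.
    """

    polynomial_order: int = 4
    n_lags: int = 5
    compounding: Literal["none", "previous_level", "previous_anomaly", "previous_spline"] = "none"
    climate_interaction: bool = True
    controls: tuple[str, ...] = ("rh_pct", "precip_mm")
    lag_controls: bool = True
    temperature_variable: str = "tmean_c"
    spline_knot: float = 11.7  # interior knot (degC) for the spline variant

    def __post_init__(self) -> None:
        if self.polynomial_order < 1:
            raise ConfigError("polynomial_order must be >= 1")
        if self.n_lags < 0:
            raise ConfigError("n_lags must be >= 0")
        if self.compounding not in COMPOUNDING_MODES:
            raise ConfigError(f"unknown compounding mode {self.compounding!r}")
        if self.compounding == "previous_spline" and not np.isfinite(self.spline_knot):
            raise ConfigError("spline_knot must be finite in previous_spline mode")
        bad = set(self.controls) - {"rh_pct", "precip_mm"}
        if bad:
            raise ConfigError(f"unknown control(s): {sorted(bad)}")

    @property
    def n_prev_basis(self) -> int:
        return {"none": 0, "previous_level": 1, "previous_anomaly": 1, "previous_spline": 2}[
            self.compounding
        ]

    @property
    def max_lag_needed(self) -> int:
        return self.n_lags + (1 if self.compounding != "none" else 0)

    def column_names(self) -> list[str]:
        names: list[str] = []
        P, L = self.polynomial_order, self.n_lags
        for j in range(L + 1):
            for p in range(1, P + 1):
                names.append(f"t_l{j}_p{p}")
            if self.climate_interaction:
                for p in range(1, P + 1):
                    names.append(f"t_l{j}_p{p}_x_tbar")
            for b in range(self.n_prev_basis):
                for p in range(1, P + 1):
                    names.append(f"t_l{j}_p{p}_x_prev{b}")
        for ctrl in self.controls:
            lags = range(L + 1) if self.lag_controls else range(1)
            for j in lags:
                names.append(f"{ctrl}_l{j}")
        return names

    def temperature_column_names(self) -> list[str]:
        return [c for c in self.column_names() if c.startswith("t_l")]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["controls"] = list(self.controls)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kw = dict(d)
        kw["controls"] = tuple(kw.get("controls", ("rh_pct", "precip_mm")))
        return cls(**kw)


# -- previous-day transform ---------------------------------------------------


def natural_spline_basis(
    x: np.ndarray, knot: float, boundary: tuple[float, float]
) -> np.ndarray:
    """Natural cubic spline basis with one interior knot (two columns).

    Knot set (a, k, b) with boundary knots a < b; the basis is {x, N(x)} with
    N built from truncated cubics so that the function is linear beyond the
    boundary knots and C2 everywhere, including at the interior knot.
    """
    a, b = boundary
    if not (a < knot < b):
        raise ConfigError(f"interior knot {knot} must lie inside boundary {boundary}")
    x = np.asarray(x, dtype=float)

    def d(xi: float) -> np.ndarray:
        return (np.clip(x - xi, 0, None) ** 3 - np.clip(x - b, 0, None) ** 3) / (b - xi)

    return np.column_stack([x, d(a) - d(knot)])


def previous_day_transform(
    prev: np.ndarray,
    mode: str,
    clim: np.ndarray | None = None,
    knot: float | None = None,
    boundary: tuple[float, float] | None = None,
) -> np.ndarray:
    """Transform g(.) of the previous day's temperature, as (n, n_basis).

    previous_level: identity; previous_anomaly: deviation from the
    climatological mean for that department/calendar day; previous_spline:
    natural cubic spline basis around ``knot``.
    """
    prev = np.asarray(prev, dtype=float)
    if mode == "previous_level":
        return prev[:, None]
    if mode == "previous_anomaly":
        if clim is None:
            raise ConfigError("previous_anomaly mode requires climatological means")
        return (prev - np.asarray(clim, dtype=float))[:, None]
    if mode == "previous_spline":
        if knot is None or boundary is None:
            raise ConfigError("previous_spline mode requires knot and boundary knots")
        return natural_spline_basis(prev, knot, boundary)
    raise ConfigError(f"no previous-day transform for mode {mode!r}")


# -- design matrix ------------------------------------------------------------


@dataclass
class DesignInfo:
    """Evaluation context needed to reuse a fitted design out of sample."""

    spec: ModelSpec
    columns: list[str]
    tbar: pd.Series  # per-department long-term mean temperature
    tbar_pw: float  # population-weighted mean of tbar (default evaluation climate)
    spline_boundary: tuple[float, float] | None
    climatology: Climatology | None  # for previous_anomaly evaluation
    period: tuple[int, int] | None


@dataclass
class DesignMatrix:
    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    fe_codes: tuple[np.ndarray, np.ndarray]  # (department-year, department-doy)
    fe_sizes: tuple[int, int]
    clusters: np.ndarray  # department code per row
    cluster_ids: list[str]
    index: pd.DataFrame  # department_id, date, year, day_of_year per row
    n_dropped_missing_lags: int
    n_dropped_zero_deaths: int
    info: DesignInfo

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        out = self.index.copy()
        out["log_rate"] = self.y
        for k, c in enumerate(self.columns):
            out[c] = self.X[:, k]
        return out


def _lagged(arr: np.ndarray, k: int, valid: np.ndarray) -> np.ndarray:
    """Shift ``arr`` down by k rows; entries flagged invalid become NaN."""
    out = np.full(arr.shape, np.nan)
    if k == 0:
        out[:] = arr
    else:
        out[k:] = arr[:-k]
    out[~valid] = np.nan
    return out


def _lag_validity(dept_codes: np.ndarray, ordinals: np.ndarray, k: int) -> np.ndarray:
    """Rows whose day-(d-k) record exists k rows earlier, same department,
    exactly k calendar days back (lags never cross department boundaries or
    gaps in the record)."""
    n = len(dept_codes)
    valid = np.zeros(n, dtype=bool)
    if k == 0:
        return np.ones(n, dtype=bool)
    if k < n:
        valid[k:] = (dept_codes[k:] == dept_codes[:-k]) & (ordinals[k:] - ordinals[:-k] == k)
    return valid


def build_design(
    panel: PanelDataset,
    spec: ModelSpec,
    period: tuple[int, int] | None = None,
    climatology: Climatology | None = None,
    zero_death: Literal["drop", "half"] = "drop",
    reuse_buffers: bool = False,
) -> DesignMatrix:
    """Numeric realization of the exposure-response regression.

    Rows lacking any required lagged day are excluded (and counted); so are
    zero-death days unless ``zero_death='half'`` adds a 0.5-death continuity
    correction.  Requires at least two departments and two years.

    ``reuse_buffers=True`` lets the returned matrix alias an internal
    workspace (for Monte Carlo loops that build, fit, and discard designs
    sequentially); the default allocates fresh storage.
    """
    from ._kernels import pooled

    sub = panel.subset_years(*period) if period is not None else panel
    df = sub.df
    if df["department_id"].nunique() < 2 or df["year"].nunique() < 2:
        raise DataError("design needs >= 2 departments and >= 2 years")
    if spec.compounding == "previous_anomaly" and climatology is None:
        raise ConfigError("previous_anomaly compounding requires a climatology")

    tbar = (
        panel.dept_mean_temp
        if panel.dept_mean_temp is not None
        else department_mean_temperature(sub)
    )

    dept_codes, dept_ids = pd.factorize(df["department_id"], sort=True)
    ordinals = (df["date"].to_numpy().astype("datetime64[D]")).astype(np.int64)
    T = df[spec.temperature_variable].to_numpy(dtype=float)
    doy = df["day_of_year"].to_numpy()
    years = df["year"].to_numpy()
    deaths = df["deaths"].to_numpy(dtype=float)
    pop_all = df["population"].to_numpy(dtype=float)

    Lmax = spec.max_lag_needed
    rows_ok = np.ones(len(df), dtype=bool)
    for k in range(1, Lmax + 1):
        rows_ok &= _lag_validity(dept_codes, ordinals, k)
    n_dropped_lags = int((~rows_ok).sum())
    if not rows_ok.any():
        raise DataError(
            f"no rows have the required {Lmax} lagged days; "
            "panel too short or fragmented for this specification"
        )

    zero = deaths <= 0
    if zero_death == "half":
        deaths = np.where(zero, 0.5, deaths)
        n_dropped_zero = 0
    else:
        n_dropped_zero = int((zero & rows_ok).sum())
        rows_ok &= ~zero

    idx = np.flatnonzero(rows_ok)
    n = len(idx)
    names = spec.column_names()
    K = len(names)

    # lagged temperatures at valid rows: row idx-k holds day d-k by validity
    Tl = pooled("design_lags", (Lmax + 1, n)) if reuse_buffers else np.empty((Lmax + 1, n))
    for k in range(Lmax + 1):
        np.take(T, idx - k, out=Tl[k])

    spline_boundary = None
    gbases: dict[int, np.ndarray] = {}
    if spec.compounding != "none":
        if spec.compounding == "previous_spline":
            spline_boundary = (float(Tl[1].min()), float(Tl[1].max()))
        clim_lookup = None
        if spec.compounding == "previous_anomaly":
            clim_lookup = _climatology_lookup(climatology, dept_ids)
        dept_sel = dept_codes[idx]
        for j in range(spec.n_lags + 1):
            clim_j = None
            if clim_lookup is not None:
                doy_prev = doy[idx - (j + 1)]
                clim_j = clim_lookup[dept_sel, doy_prev]
                if np.isnan(clim_j).any():
                    raise DataError("climatology missing days needed for anomaly mode")
            gbases[j] = previous_day_transform(
                Tl[j + 1],
                spec.compounding,
                clim=clim_j,
                knot=spec.spline_knot,
                boundary=spline_boundary,
            )

    tbar_by_code = tbar.reindex(dept_ids).to_numpy(dtype=float)
    tbar_row = tbar_by_code[dept_codes[idx]]

    X = pooled("design_X", (n, K), order="F") if reuse_buffers else np.empty((n, K), order="F")
    P = spec.polynomial_order
    pw = np.empty((P, n))
    col = 0
    for j in range(spec.n_lags + 1):
        np.copyto(pw[0], Tl[j])
        for p in range(1, P):
            np.multiply(pw[p - 1], Tl[j], out=pw[p])
        for p in range(P):
            X[:, col] = pw[p]
            col += 1
        if spec.climate_interaction:
            for p in range(P):
                np.multiply(pw[p], tbar_row, out=X[:, col])
                col += 1
        if spec.compounding != "none":
            g = gbases[j]
            for b in range(spec.n_prev_basis):
                for p in range(P):
                    np.multiply(pw[p], g[:, b], out=X[:, col])
                    col += 1
    for ctrl in spec.controls:
        c = df[ctrl].to_numpy(dtype=float)
        lags = range(spec.n_lags + 1) if spec.lag_controls else range(1)
        for k in lags:
            np.take(c, idx - k, out=X[:, col])
            col += 1
    assert col == K

    y = np.log(deaths[idx] / pop_all[idx] * RATE_SCALE)

    dept_sel = dept_codes[idx]
    y0 = int(years.min())
    yspan = int(years.max()) - y0 + 1
    _, fe1_codes = np.unique(dept_sel * yspan + (years[idx] - y0), return_inverse=True)
    _, fe2_codes = np.unique(dept_sel * 367 + doy[idx], return_inverse=True)
    fe1_ids = np.unique(fe1_codes)
    fe2_ids = np.unique(fe2_codes)
    if len(fe1_ids) < 2 or len(fe2_ids) < 2:
        raise DataError("fewer than 2 fixed-effect groups in a dimension")

    pop_mean = df.groupby("department_id")["population"].mean()
    tbar_al = tbar.reindex(pop_mean.index)
    tbar_pw = float((tbar_al * pop_mean).sum() / pop_mean.sum())
    sel = pd.DataFrame(
        {
            "department_id": np.asarray(dept_ids)[dept_sel],
            "date": df["date"].to_numpy()[idx],
            "year": years[idx],
            "day_of_year": doy[idx],
        }
    )

    info = DesignInfo(
        spec=spec,
        columns=names,
        tbar=tbar,
        tbar_pw=tbar_pw,
        spline_boundary=spline_boundary,
        climatology=climatology,
        period=period,
    )
    return DesignMatrix(
        X=X,
        y=y,
        columns=names,
        fe_codes=(fe1_codes, fe2_codes),
        fe_sizes=(len(fe1_ids), len(fe2_ids)),
        clusters=dept_sel,
        cluster_ids=list(dept_ids),
        index=sel,
        n_dropped_missing_lags=n_dropped_lags,
        n_dropped_zero_deaths=n_dropped_zero,
        info=info,
    )


def _climatology_lookup(clim: Climatology, dept_ids) -> np.ndarray:
    """(n_dept, 367) array of climatological mean temperature by doy."""
    table = np.full((len(dept_ids), 367), np.nan)
    sub = clim.df[clim.df["department_id"].isin(dept_ids)]
    pos = {d: i for i, d in enumerate(dept_ids)}
    table[
        sub["department_id"].map(pos).to_numpy(),
        sub["day_of_year"].to_numpy(dtype=int),
    ] = sub["tmean_clim_c"].to_numpy(dtype=float)
    return table


# -- support mask -------------------------------------------------------------


@dataclass
class SupportMask:
    """Which (previous-day, current-day) temperature bins occur in the data.

    Bins are half-open [a, a+w) cells; a cell is supported iff at least one
    consecutive-day pair in the estimation sample falls in it.  Also records,
    per previous-day bin, the min/max observed current-day temperature for
    flagging extrapolation.
    """

    prev_edges: np.ndarray
    cur_edges: np.ndarray
    grid: np.ndarray  # bool, (n_prev_bins, n_cur_bins)
    cur_range_by_prev: np.ndarray  # (n_prev_bins, 2) min/max current, NaN if empty
    bin_width: float

    def supported(self, prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
        pi = np.floor((np.asarray(prev, float) - self.prev_edges[0]) / self.bin_width)
        ci = np.floor((np.asarray(cur, float) - self.cur_edges[0]) / self.bin_width)
        pi, ci = pi.astype(int), ci.astype(int)
        ok = (
            (pi >= 0) & (pi < self.grid.shape[0]) & (ci >= 0) & (ci < self.grid.shape[1])
        )
        out = np.zeros(np.shape(pi), dtype=bool)
        out[ok] = self.grid[pi[ok], ci[ok]]
        return out

    def in_observed_range(self, prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
        """Whether the current-day value lies within the min/max observed for
        its previous-day bin (the shading convention for response curves)."""
        pi = np.floor((np.asarray(prev, float) - self.prev_edges[0]) / self.bin_width).astype(int)
        cur = np.asarray(cur, float)
        ok = (pi >= 0) & (pi < self.grid.shape[0])
        out = np.zeros(np.shape(pi), dtype=bool)
        rng = self.cur_range_by_prev
        out[ok] = (cur[ok] >= rng[pi[ok], 0]) & (cur[ok] <= rng[pi[ok], 1])
        return out


def support_mask(
    panel: PanelDataset,
    bin_width: float = 1.0,
    period: tuple[int, int] | None = None,
    temperature_variable: str = "tmean_c",
) -> SupportMask:
    if bin_width <= 0:
        raise ConfigError("bin width must be positive")
    sub = panel.subset_years(*period) if period is not None else panel
    df = sub.df
    if df.empty:
        raise DataError("empty panel for support mask")
    dept_codes, _ = pd.factorize(df["department_id"], sort=True)
    ordinals = df["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    T = df[temperature_variable].to_numpy(dtype=float)
    v1 = _lag_validity(dept_codes, ordinals, 1)
    cur = T[v1]
    prev = _lagged(T, 1, v1)[v1]

    lo = np.floor(min(prev.min(), cur.min()) / bin_width) * bin_width
    # last bin is half-open like the rest: extend one bin past the maximum
    hi = np.floor(max(prev.max(), cur.max()) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _, _ = np.histogram2d(prev, cur, bins=(edges, edges))
    grid = counts > 0

    nb = len(edges) - 1
    rng = np.full((nb, 2), np.nan)
    pi = np.clip(np.floor((prev - lo) / bin_width).astype(int), 0, nb - 1)
    for b in np.unique(pi):
        vals = cur[pi == b]
        rng[b] = (vals.min(), vals.max())
    return SupportMask(edges, edges, grid, rng, bin_width)
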