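"""Exposure-response curves, marginal effects, and the compounding surface.

Because the regression outcome is a log rate, contrasting the fitted
temperature terms at two scenarios yields percent changes in mortality:
pct = exp(delta) - 1 per coefficient draw, summarized by the mean and the
2.5th/97.5th percentiles.  Marginal effects move only the focal day's (lag-0)
terms, conditioning on the previous day through the compounding interaction
and on the department's mean climate through the climate interaction; the
cumulative variant sums all lag contributions along a realized temperature
path and backs daily event predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignInfo, ModelSpec, SupportMask, previous_day_transform
from .errors import ConfigError, DataError, NumericalError
from .fitting import CoefficientSamples


def _g_basis(spec: ModelSpec, info: DesignInfo, prev: np.ndarray,
             prev_clim: np.ndarray | None) -> np.ndarray:
    if spec.compounding == "previous_anomaly" and prev_clim is None:
        raise ConfigError(
            "previous_anomaly evaluation needs climatological means for the previous days"
        )
    return previous_day_transform(
        prev,
        spec.compounding,
        clim=prev_clim,
        knot=spec.spline_knot,
        boundary=info.spline_boundary,
    )


def lag0_design(
    spec: ModelSpec,
    info: DesignInfo,
    current: np.ndarray,
    previous: np.ndarray,
    tbar: np.ndarray,
    prev_clim: np.ndarray | None = None,
) -> pd.DataFrame:
    """Focal-day (lag-0) temperature terms for an array of scenarios; all
    other lags' columns are zero, so dotting with a coefficient vector gives
    the lag-0 contribution only."""
    current = np.atleast_1d(np.asarray(current, dtype=float))
    previous = np.atleast_1d(np.asarray(previous, dtype=float))
    tbar = np.broadcast_to(np.asarray(tbar, dtype=float), current.shape)
    names = spec.temperature_column_names()
    out = pd.DataFrame(0.0, index=np.arange(len(current)), columns=names)
    powers = [current]
    for _ in range(spec.polynomial_order - 1):
        powers.append(powers[-1] * current)
    for p, col in enumerate(powers, start=1):
        out[f"t_l0_p{p}"] = col
        if spec.climate_interaction:
            out[f"t_l0_p{p}_x_tbar"] = col * tbar
    if spec.compounding != "none":
        g = _g_basis(spec, info, previous, prev_clim)
        for b in range(spec.n_prev_basis):
            for p, col in enumerate(powers, start=1):
                out[f"t_l0_p{p}_x_prev{b}"] = col * g[:, b]
    return out


def path_design(
    spec: ModelSpec,
    info: DesignInfo,
    paths: np.ndarray,
    tbar: np.ndarray,
    clims: np.ndarray | None = None,
) -> pd.DataFrame:
    """All-lag temperature terms for focal days with realized histories.

    ``paths[i]`` is a temperature series ending on cell i's focal day; it must
    be at least L+1 days long (one more under compounding).  ``clims`` is an
    aligned array of climatological means (previous_anomaly mode only).
    """
    paths = np.atleast_2d(np.asarray(paths, dtype=float))
    need = spec.n_lags + 1 + (1 if spec.compounding != "none" else 0)
    if paths.shape[1] < need:
        raise DataError(
            f"temperature path has {paths.shape[1]} days; {need} required"
        )
    tbar = np.broadcast_to(np.asarray(tbar, dtype=float), (paths.shape[0],))
    names = spec.temperature_column_names()
    out = pd.DataFrame(0.0, index=np.arange(paths.shape[0]), columns=names)
    for j in range(spec.n_lags + 1):
        cur = paths[:, paths.shape[1] - 1 - j]
        powers = [cur]
        for _ in range(spec.polynomial_order - 1):
            powers.append(powers[-1] * cur)
        for p, col in enumerate(powers, start=1):
            out[f"t_l{j}_p{p}"] = col
            if spec.climate_interaction:
                out[f"t_l{j}_p{p}_x_tbar"] = col * tbar
        if spec.compounding != "none":
            prev = paths[:, paths.shape[1] - 2 - j]
            pc = None
            if clims is not None:
                clims = np.atleast_2d(np.asarray(clims, dtype=float))
                pc = clims[:, clims.shape[1] - 2 - j]
            g = _g_basis(spec, info, prev, pc)
            for b in range(spec.n_prev_basis):
                for p, col in enumerate(powers, start=1):
                    out[f"t_l{j}_p{p}_x_prev{b}"] = col * g[:, b]
    return out


def _align_contrast(samples: CoefficientSamples, contrast: pd.DataFrame) -> np.ndarray:
    """Map a contrast over the full temperature-column set onto the fitted
    (kept) columns; a nonzero contrast on a dropped column is an error."""
    kept = samples.draws.columns
    missing = [c for c in contrast.columns if c not in kept]
    if missing:
        bad = contrast[missing].to_numpy()
        if np.any(bad != 0):
            raise NumericalError(
                f"contrast needs coefficient(s) dropped in fitting: {missing}"
            )
    aligned = pd.DataFrame(0.0, index=contrast.index, columns=kept)
    common = [c for c in contrast.columns if c in kept]
    aligned[common] = contrast[common]
    return aligned.to_numpy()


@dataclass
class EffectDistribution:
    """Percent-change distribution across coefficient draws."""

    draws_pct: np.ndarray  # (n_draws,) or (n_draws, n_cells)

    @property
    def mean(self):
        return self.draws_pct.mean(axis=0)

    @property
    def lo(self):
        return np.percentile(self.draws_pct, 2.5, axis=0)

    @property
    def median(self):
        return np.percentile(self.draws_pct, 50.0, axis=0)

    @property
    def hi(self):
        return np.percentile(self.draws_pct, 97.5, axis=0)


def marginal_effect(
    samples: CoefficientSamples,
    scenario: tuple[float, float],
    reference: tuple[float, float] = (20.0, 20.0),
    tbar: float | None = None,
    prev_clim: float | None = None,
    ref_prev_clim: float | None = None,
    exact: bool = True,
) -> EffectDistribution:
    """Percent change in mortality for a (previous, current) temperature pair
    relative to a reference pair, from the focal day's terms only.

    Scenario and reference are (previous_c, current_c).  ``tbar`` defaults to
    the population-weighted mean department climate of the estimation sample.
    ``exact=False`` uses the delta*100 approximation instead of exp(delta)-1.
    """
    spec, info = samples.spec, samples.info
    tb = info.tbar_pw if tbar is None else float(tbar)
    p_s, c_s = scenario
    p_r, c_r = reference
    pc = None if prev_clim is None else np.array([prev_clim, ref_prev_clim if ref_prev_clim is not None else prev_clim])
    rows = lag0_design(
        spec, info,
        np.array([c_s, c_r]), np.array([p_s, p_r]), np.array([tb, tb]),
        prev_clim=pc,
    )
    v = _align_contrast(samples, rows)
    delta = samples.draws.to_numpy() @ (v[0] - v[1])
    pct = (np.exp(delta) - 1.0 if exact else delta) * 100.0
    return EffectDistribution(pct)


def cumulative_effect(
    samples: CoefficientSamples,
    path: np.ndarray,
    ref_path: np.ndarray,
    tbar: float | None = None,
    clims: np.ndarray | None = None,
    ref_clims: np.ndarray | None = None,
) -> EffectDistribution:
    """Percent change on the focal (last) day of ``path`` relative to
    ``ref_path``, summing every lag's contribution given its realized
    history."""
    spec, info = samples.spec, samples.info
    tb = info.tbar_pw if tbar is None else float(tbar)
    path, ref_path = np.asarray(path, float), np.asarray(ref_path, float)
    if path.shape != ref_path.shape:
        raise DataError("scenario and reference paths must have equal length")
    rows = path_design(
        spec, info, np.vstack([path, ref_path]), np.array([tb, tb]),
        clims=None if clims is None else np.vstack([clims, ref_clims if ref_clims is not None else clims]),
    )
    v = _align_contrast(samples, rows)
    delta = samples.draws.to_numpy() @ (v[0] - v[1])
    return EffectDistribution((np.exp(delta) - 1.0) * 100.0)


@dataclass
class ResponseCurve:
    """Exposure-response curve with uncertainty bands and range flags."""

    table: pd.DataFrame  # current_c, previous_c, tbar_c, mean_pct, lo_pct, med_pct, hi_pct, extrapolated

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def response_curve(
    samples: CoefficientSamples,
    current_grid: np.ndarray,
    previous: float = 20.0,
    reference: tuple[float, float] = (20.0, 20.0),
    tbar: float | None = None,
    mask: SupportMask | None = None,
) -> ResponseCurve:
    """Percent-change curve over current-day temperatures at a fixed
    previous-day temperature, relative to the reference pair.

    The band at the reference point is exactly zero-width; points outside the
    observed current-day range conditional on the previous-day bin are
    flagged extrapolated when a support mask is supplied.
    """
    spec, info = samples.spec, samples.info
    tb = info.tbar_pw if tbar is None else float(tbar)
    grid = np.asarray(current_grid, dtype=float)
    p_r, c_r = reference
    rows_grid = lag0_design(
        spec, info, grid, np.full(len(grid), previous), np.full(len(grid), tb)
    )
    ref_row = lag0_design(spec, info, np.array([c_r]), np.array([p_r]), np.array([tb]))
    rows = pd.concat([rows_grid, ref_row], ignore_index=True)
    v = _align_contrast(samples, rows)
    delta = samples.draws.to_numpy() @ (v[:-1] - v[-1]).T
    pct = (np.exp(delta) - 1.0) * 100.0
    eff = EffectDistribution(pct)
    extrap = (
        ~mask.in_observed_range(np.full(len(grid), previous), grid)
        if mask is not None
        else np.zeros(len(grid), dtype=bool)
    )
    table = pd.DataFrame(
        {
            "current_c": grid,
            "previous_c": previous,
            "tbar_c": tb,
            "mean_pct": eff.mean,
            "lo_pct": eff.lo,
            "med_pct": eff.median,
            "hi_pct": eff.hi,
            "extrapolated": extrap,
        }
    )
    return ResponseCurve(table)


@dataclass
class CompoundingSurface:
    """Mean percent change over (previous, current) temperature pairs.

    Unsupported cells (pairs never observed in the estimation sample) carry
    NaN; the reference cell is exactly zero.
    """

    prev_grid: np.ndarray
    cur_grid: np.ndarray
    mean_pct: np.ndarray  # (n_prev, n_cur), NaN where unsupported
    supported: np.ndarray
    reference: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        pv, cv = np.meshgrid(self.prev_grid, self.cur_grid, indexing="ij")
        return pd.DataFrame(
            {
                "previous_c": pv.ravel(),
                "current_c": cv.ravel(),
                "mean_pct": self.mean_pct.ravel(),
                "supported": self.supported.ravel(),
            }
        )


def compounding_surface(
    samples: CoefficientSamples,
    prev_grid: np.ndarray,
    cur_grid: np.ndarray,
    tbar: float | None = None,
    reference: tuple[float, float] = (20.0, 20.0),
    mask: SupportMask | None = None,
) -> CompoundingSurface:
    """Two-dimensional marginal-effect surface vs the reference pair
    (default: two consecutive days at 20 degC)."""
    spec, info = samples.spec, samples.info
    tb = info.tbar_pw if tbar is None else float(tbar)
    prev_grid = np.asarray(prev_grid, dtype=float)
    cur_grid = np.asarray(cur_grid, dtype=float)
    p_r, c_r = reference
    if not (prev_grid.min() <= p_r <= prev_grid.max()) or not (
        cur_grid.min() <= c_r <= cur_grid.max()
    ):
        raise ConfigError(f"reference pair {reference} outside the evaluation grid")
    pv, cv = np.meshgrid(prev_grid, cur_grid, indexing="ij")
    rows = lag0_design(
        spec, info,
        np.concatenate([cv.ravel(), [c_r]]),
        np.concatenate([pv.ravel(), [p_r]]),
        np.full(pv.size + 1, tb),
    )
    v = _align_contrast(samples, rows)
    delta = samples.draws.to_numpy() @ (v[:-1] - v[-1]).T
    mean_pct = (np.exp(delta) - 1.0).mean(axis=0).reshape(pv.shape) * 100.0
    if mask is not None:
        supported = mask.supported(pv.ravel(), cv.ravel()).reshape(pv.shape)
    else:
        supported = np.ones(pv.shape, dtype=bool)
    mean_pct = np.where(supported, mean_pct, np.nan)
    return CompoundingSurface(prev_grid, cur_grid, mean_pct, supported, reference)
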