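"""Synthetic department-day panels with a known temperature-mortality response.

The generator emulates the statistical structure the analysis assumes:

* per-department seasonal temperature cycles (cosine, peak in late July) with
  stationary AR(1) anomalies;
* a spatial gradient in mean climate across departments;
* Poisson death counts whose log expected rate is a distributed-lag polynomial
  in temperature, with a temporal-compounding interaction (today's polynomial
  terms times yesterday's temperature), a climate interaction (times the
  department's long-term mean temperature), weather controls, and
  department-by-year / department-by-day-of-year fixed effects.

The true response is parameterized directly on the regression's own columns
(powers of raw temperature and their interactions), so the estimating
equations span the truth exactly and every downstream "truth" in tests can be
evaluated in closed form through :func:`true_log_response` - never through a
second implementation of the fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .calendar import day_of_year_366, seasonal_position
from .errors import ConfigError, DataError
from .panel import RATE_SCALE, PanelDataset

# Anchor points for the total (summed over lags) polynomial response f(T):
# a J-shape with elevated mortality at cold, a flat minimum near 16-22 degC,
# and a steep heat tail.  Magnitudes are log-rate changes relative to the
# minimum and sit in the range reported by multi-country temperature-mortality
# studies for an unadapted population.
_F_TARGET_T = np.array([-8.0, -4.0, 0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0])
_F_TARGET_Y = np.array([0.16, 0.11, 0.07, 0.045, 0.025, 0.012, 0.003, 0.0, 0.012, 0.055, 0.16, 0.35])

#: compounding slope: the true interaction is c * T^4 * T_prev, concentrating
#: the previous-day amplification in the heat tail (sustained extreme heat
#: compounds; ordinary warm spells barely do).  The default gives
#: H(30 degC) = c*30^4 ~= 0.024 per degC of previous-day temperature, i.e. a
#: 30 degC day after a 30 degC day adds ~0.24 to the log rate relative to
#: following a 20 degC day - the order estimated for strongly heat-sensitive
#: populations before modern heat adaptation.
_DEFAULT_COMPOUND = 3.0e-8
#: climate interaction: warmer departments respond less to heat.
_DEFAULT_CLIMATE = -4.3e-9


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic panel.

    Defaults are a desk-scale analog of a national daily-mortality panel:
    10 departments spanning 10-16 degC mean climate, 25 years of daily
    records, region-scale populations of one to three million, and a baseline
    all-cause mortality rate of 2.5 deaths per 100,000 per day.
    """

    n_departments: int = 10
    year_start: int = 1980
    year_end: int = 2004
    tbar_range: tuple[float, float] = (10.0, 16.0)
    seasonal_amplitude: float = 8.0
    peak_doy: float = 201.0  # seasonal maximum around July 20
    rho: float = 0.55  # AR(1) coefficient of daily temperature anomalies
    anomaly_sd: float = 2.6  # stationary anomaly standard deviation, degC
    #: degrees of freedom of the Student-t AR(1) innovations (None = Gaussian).
    #: Heavy tails emulate short-lived advective heat spikes: isolated very hot
    #: days occur (supporting the response curve at high temperatures) while
    #: *sustained* blocks of equally hot consecutive days remain unprecedented,
    #: the support geometry characteristic of record-breaking heat waves.
    innovation_df: float | None = 4.0
    baseline_log_rate: float = float(np.log(2.5))  # log deaths per 100k per day
    fe_year_sd: float = 0.03
    fe_doy_sd: float = 0.02
    populations: tuple[float, ...] | None = None  # default: geomspace 1M-3M
    lag_weights: tuple[float, ...] = (0.45, 0.25, 0.15, 0.08, 0.04, 0.03)
    climate_coeff: float = _DEFAULT_CLIMATE  # on T^4 x Tbar, all lags (weighted)
    compound_coeff: float = _DEFAULT_COMPOUND  # on T^p x T_prev, all lags (weighted)
    compound_power: int = 4  # power p in the compounding term
    rh_coeff: float = 0.0015  # per % relative humidity (centered at 75)
    precip_coeff: float = -0.0005  # per mm precipitation
    response_scale: float = 1.0  # multiplies the whole temperature response
    noise: Literal["poisson", "expected_value"] = "poisson"
    burn_in_days: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if self.seasonal_amplitude < 0:
            raise ConfigError("seasonal_amplitude must be >= 0")
        if self.populations is not None:
            if len(self.populations) != self.n_departments:
                raise ConfigError("populations length must equal n_departments")
            if any(p <= 0 for p in self.populations):
                raise ConfigError("populations must be positive")
        if self.noise not in ("poisson", "expected_value"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if self.burn_in_days < self.n_lags + 2:
            raise ConfigError(
                f"burn_in_days={self.burn_in_days} too short for {self.n_lags} lags"
            )

    @property
    def n_lags(self) -> int:
        return len(self.lag_weights) - 1

    def department_ids(self) -> list[str]:
        return [f"D{i:02d}" for i in range(1, self.n_departments + 1)]

    def department_tbar(self) -> np.ndarray:
        lo, hi = self.tbar_range
        if self.n_departments == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, self.n_departments)

    def department_populations(self) -> np.ndarray:
        if self.populations is not None:
            return np.asarray(self.populations, dtype=float)
        return np.round(np.geomspace(1e6, 3e6, self.n_departments))

    def f_poly(self) -> np.ndarray:
        """Raw-temperature coefficients (highest power first) of the total
        lag-summed polynomial response, least-squares fitted to the anchors."""
        return np.polyfit(_F_TARGET_T, _F_TARGET_Y, 4)

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kw = dict(d)
        for k in ("tbar_range", "lag_weights", "populations"):
            if kw.get(k) is not None:
                kw[k] = tuple(kw[k])
        return cls(**kw)

    def with_response_scale(self, scale: float) -> "GeneratorConfig":
        return replace(self, response_scale=scale)


@dataclass(frozen=True)
class EventSpec:
    """A heat-wave-like temperature uplift injected into one year.

    The temporal profile emulates a multi-day event that ramps to a peak and
    decays (raised-cosine by default, as in the canonical two-week August
    pattern); the spatial pattern is uniform unless per-department weights are
    given.
    """

    year: int
    start_doy: int
    end_doy: int
    peak_uplift_c: float
    profile: Literal["hann", "plateau"] = "hann"
    spatial_weights: tuple[float, ...] | None = None
    #: "replace" prescribes the window trajectory as seasonal climatology plus
    #: the uplift profile (a storyline event with the weather noise overridden);
    #: "add" stacks the uplift on top of the realized anomalies.
    mode: Literal["replace", "add"] = "replace"

    def __post_init__(self) -> None:
        if self.start_doy > self.end_doy:
            raise ConfigError("event start_doy must be <= end_doy")
        if not np.isfinite(self.peak_uplift_c):
            raise ConfigError("event uplift must be finite")

    @property
    def n_days(self) -> int:
        return self.end_doy - self.start_doy + 1

    def shape(self) -> np.ndarray:
        n = self.n_days
        if self.profile == "plateau":
            return np.ones(n)
        return np.sin(np.pi * (np.arange(n) + 0.5) / n) ** 2


# -----------------------------------------------------------------------------


@dataclass
class GeneratorTruth:
    """Everything needed to evaluate the generator's exact response.

    Holds the full simulated weather (including burn-in days before the panel
    starts, so lagged terms are defined from the first panel day), the fixed
    effect draws, and the true coefficients; exposes closed-form expected
    deaths for arbitrary temperature series.
    """

    config: GeneratorConfig
    dates_full: pd.DatetimeIndex  # burn-in + panel days
    burn: int
    temps_full: np.ndarray  # (n_dept, n_total)
    rh: np.ndarray  # (n_dept, n_panel)
    precip: np.ndarray  # (n_dept, n_panel)
    fe_year: np.ndarray  # (n_dept, n_years)
    fe_doy: np.ndarray  # (n_dept, 366)
    tbar: np.ndarray  # (n_dept,)
    populations: np.ndarray  # (n_dept,)
    year_idx: np.ndarray = field(init=False)  # (n_panel,) index into fe_year
    doy366: np.ndarray = field(init=False)  # (n_panel,)

    def __post_init__(self) -> None:
        panel_dates = self.dates_full[self.burn:]
        self.year_idx = panel_dates.year.to_numpy() - self.config.year_start
        self.doy366 = day_of_year_366(panel_dates)

    @property
    def n_panel_days(self) -> int:
        return len(self.dates_full) - self.burn

    def log_rate(self, temps_full: np.ndarray | None = None) -> np.ndarray:
        """Log mortality rate (per 100k/day) for every panel department-day."""
        cfg = self.config
        T = self.temps_full if temps_full is None else np.asarray(temps_full, dtype=float)
        n_total = T.shape[1]
        r = np.full((cfg.n_departments, self.n_panel_days), cfg.baseline_log_rate)
        r += self.fe_year[:, self.year_idx]
        r += self.fe_doy[:, self.doy366 - 1]
        r += cfg.rh_coeff * (self.rh - 75.0) + cfg.precip_coeff * self.precip
        f = cfg.f_poly()
        for j, w in enumerate(cfg.lag_weights):
            Tj = T[:, self.burn - j : n_total - j]
            Tp = T[:, self.burn - j - 1 : n_total - j - 1]
            Tj4 = Tj**4
            r += cfg.response_scale * w * (
                np.polyval(f, Tj)
                + cfg.climate_coeff * Tj4 * self.tbar[:, None]
                + cfg.compound_coeff * Tj**cfg.compound_power * Tp
            )
        return r

    def expected_deaths(self, temps_full: np.ndarray | None = None) -> np.ndarray:
        lam = np.exp(self.log_rate(temps_full)) / RATE_SCALE
        return lam * self.populations[:, None]


def true_log_response(
    config: GeneratorConfig,
    current_lags: np.ndarray,
    previous: np.ndarray,
    tbar: float,
    reference: float | None = None,
) -> float:
    """Exact temperature contribution to the log rate for one focal day.

    ``current_lags[j]`` is the temperature on day d-j (j = 0..L) and
    ``previous[j]`` the temperature on day d-j-1.  With ``reference`` set, the
    same response evaluated with every temperature at the reference value is
    subtracted, which removes the polynomial's arbitrary level.
    """
    cur = np.asarray(current_lags, dtype=float)
    prev = np.asarray(previous, dtype=float)
    if cur.shape[-1] != config.n_lags + 1 or prev.shape[-1] != config.n_lags + 1:
        raise ConfigError(
            f"need {config.n_lags + 1} current and previous temperatures"
        )
    f = config.f_poly()
    w = np.asarray(config.lag_weights)
    c4 = cur**4
    val = np.sum(
        w * (np.polyval(f, cur) + config.climate_coeff * c4 * tbar
             + config.compound_coeff * cur**config.compound_power * prev),
        axis=-1,
    ) * config.response_scale
    if reference is not None:
        ref = np.full(config.n_lags + 1, float(reference))
        val = val - true_log_response(config, ref, ref, tbar, None)
    return float(val) if np.ndim(val) == 0 else val


def true_lag0_contrast(
    config: GeneratorConfig,
    scenario: tuple[float, float],
    reference: tuple[float, float],
    tbar: float,
) -> float:
    """True lag-0 (previous, current) contrast on the log scale.

    The oracle for the marginal-effect stage: only the focal day's terms move,
    conditioning on the previous day through the compounding interaction.
    """
    w0 = config.lag_weights[0]
    f = config.f_poly()

    def lag0(cur: float, prev: float) -> float:
        return w0 * (
            np.polyval(f, cur)
            + config.climate_coeff * cur**4 * tbar
            + config.compound_coeff * cur**config.compound_power * prev
        )

    (p_s, c_s), (p_r, c_r) = scenario, reference
    return config.response_scale * float(lag0(c_s, p_s) - lag0(c_r, p_r))


# -----------------------------------------------------------------------------


def _simulate_weather(config: GeneratorConfig, rng: np.random.Generator):
    dates_full = pd.date_range(
        pd.Timestamp(config.year_start, 1, 1) - pd.Timedelta(days=config.burn_in_days),
        pd.Timestamp(config.year_end, 12, 31),
        freq="D",
    )
    n_total = len(dates_full)
    n_dept = config.n_departments
    s = seasonal_position(day_of_year_366(dates_full))
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (s - config.peak_doy) / 365.0
    )
    innov_sd = config.anomaly_sd * np.sqrt(1.0 - config.rho**2)
    if config.innovation_df is None:
        eps = rng.normal(0.0, innov_sd, size=(n_dept, n_total))
    else:
        df = config.innovation_df
        if df <= 2:
            raise ConfigError("innovation_df must be > 2 (finite variance) or None")
        unit = rng.standard_t(df, size=(n_dept, n_total)) / np.sqrt(df / (df - 2.0))
        # physical bound on single-day jumps (~5 innovation sd)
        eps = innov_sd * np.clip(unit, -7.0, 7.0)
    eps[:, 0] = rng.normal(0.0, config.anomaly_sd, size=n_dept)  # stationary start
    anom = lfilter([1.0], [1.0, -config.rho], eps, axis=1)
    tbar = config.department_tbar()
    temps = tbar[:, None] + seasonal[None, :] + anom
    return dates_full, temps, anom


def generate_panel(
    config: GeneratorConfig, seed: int | None = 0
) -> tuple[PanelDataset, GeneratorTruth]:
    """Simulate a department-day panel and return it with its ground truth.

    Reproducible: identical config and seed give a byte-identical panel.
    Randomness fans out from the seed into named substreams (weather, fixed
    effects, deaths) so stages can be varied independently.
    """
    ss = np.random.SeedSequence(seed)
    rng_weather, rng_fe, rng_deaths = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    dates_full, temps, anom = _simulate_weather(config, rng_weather)
    burn = config.burn_in_days
    n_dept = config.n_departments
    n_panel = len(dates_full) - burn
    n_years = config.year_end - config.year_start + 1

    rh = np.clip(
        75.0 - 1.0 * anom[:, burn:] + rng_weather.normal(0, 6.0, (n_dept, n_panel)),
        20.0,
        100.0,
    )
    wet = rng_weather.random((n_dept, n_panel)) < 0.4
    precip = np.where(wet, rng_weather.exponential(3.0, (n_dept, n_panel)), 0.0)

    truth = GeneratorTruth(
        config=config,
        dates_full=dates_full,
        burn=burn,
        temps_full=temps,
        rh=rh,
        precip=precip,
        fe_year=rng_fe.normal(0, config.fe_year_sd, (n_dept, n_years)),
        fe_doy=rng_fe.normal(0, config.fe_doy_sd, (n_dept, 366)),
        tbar=config.department_tbar(),
        populations=config.department_populations(),
    )
    lam = truth.expected_deaths()
    deaths = _draw_deaths(lam, config.noise, rng_deaths)
    panel = _assemble_panel(config, truth, deaths)
    return panel, truth


def _draw_deaths(lam: np.ndarray, noise: str, rng: np.random.Generator) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(lam).astype(float)
    return np.round(lam)


def _assemble_panel(
    config: GeneratorConfig, truth: GeneratorTruth, deaths: np.ndarray
) -> PanelDataset:
    dates = truth.dates_full[truth.burn:]
    n_dept, n_panel = deaths.shape
    df = pd.DataFrame(
        {
            "department_id": np.repeat(config.department_ids(), n_panel),
            "date": np.tile(dates.to_numpy(), n_dept),
            "deaths": deaths.ravel(),
            "population": np.repeat(truth.populations, n_panel),
            "tmean_c": truth.temps_full[:, truth.burn:].ravel(),
            "rh_pct": truth.rh.ravel(),
            "precip_mm": truth.precip.ravel(),
            "year": np.tile(dates.year.to_numpy().astype(np.int64), n_dept),
            "day_of_year": np.tile(day_of_year_366(dates), n_dept),
        }
    )
    tbar = pd.Series(
        truth.tbar, index=pd.Index(config.department_ids(), name="department_id"),
        name="tbar_c",
    )
    # valid by construction (sorted, unique keys, integral counts)
    return PanelDataset(df, dept_mean_temp=tbar, validate=False)


# -----------------------------------------------------------------------------


@dataclass
class EventInfo:
    """Bookkeeping for an injected event, including its closed-form excess."""

    event: EventSpec
    window_dates: pd.DatetimeIndex
    uplift: np.ndarray  # (n_dept, n_window)
    true_excess_by_day: pd.Series  # indexed by date, window + lag tail
    true_excess_total: float  # summed over window + n_lags following days


def inject_event(
    panel: PanelDataset,
    truth: GeneratorTruth,
    event: EventSpec,
    seed: int | None = 1,
) -> tuple[PanelDataset, GeneratorTruth, EventInfo]:
    """Raise temperatures in the event window and re-simulate mortality there.

    Deaths are redrawn only where the expected rate changes (the window plus
    the following ``n_lags`` days); all other department-days keep their
    original draws, so the event's true excess is the closed-form difference
    in expected deaths between the two temperature series.
    """
    cfg = truth.config
    L = cfg.n_lags
    panel_dates = truth.dates_full[truth.burn:]
    in_year = panel_dates.year == event.year
    doys = day_of_year_366(panel_dates)
    win_mask_panel = in_year & (doys >= event.start_doy) & (doys <= event.end_doy)
    if win_mask_panel.sum() != event.n_days:
        raise DataError("event window not fully inside the panel")
    win_idx_panel = np.flatnonzero(win_mask_panel)
    if win_idx_panel[-1] + L >= len(panel_dates):
        raise DataError(
            f"event window ends within {L} days of the panel edge; lags would truncate"
        )

    weights = (
        np.ones(cfg.n_departments)
        if event.spatial_weights is None
        else np.asarray(event.spatial_weights, dtype=float)
    )
    uplift = weights[:, None] * (event.peak_uplift_c * event.shape())[None, :]

    temps2 = truth.temps_full.copy()
    if event.mode == "add":
        temps2[:, truth.burn + win_idx_panel] += uplift
    else:  # replace: deterministic trajectory on top of the seasonal cycle
        from .calendar import seasonal_position

        s = seasonal_position(doys[win_idx_panel])
        seasonal = cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (s - cfg.peak_doy) / 365.0
        )
        temps2[:, truth.burn + win_idx_panel] = (
            truth.tbar[:, None] + seasonal[None, :] + uplift
        )

    lam1 = truth.expected_deaths()
    lam2 = truth.expected_deaths(temps2)
    affected = lam2 != lam1

    deaths2 = _panel_deaths_matrix(panel, cfg)
    if cfg.noise == "poisson":
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        deaths2[affected] = rng.poisson(lam2[affected]).astype(float)
    else:
        deaths2[affected] = np.round(lam2[affected])

    tail = np.arange(win_idx_panel[0], win_idx_panel[-1] + L + 1)
    diff = (lam2 - lam1)[:, tail].sum(axis=0)
    info = EventInfo(
        event=event,
        window_dates=panel_dates[win_idx_panel],
        uplift=uplift,
        true_excess_by_day=pd.Series(diff, index=panel_dates[tail]),
        true_excess_total=float(diff.sum()),
    )
    truth2 = replace(truth, temps_full=temps2)
    panel2 = _assemble_panel(cfg, truth2, deaths2)
    return panel2, truth2, info


def _panel_deaths_matrix(panel: PanelDataset, cfg: GeneratorConfig) -> np.ndarray:
    wide = panel.df.pivot(index="department_id", columns="date", values="deaths")
    wide = wide.loc[cfg.department_ids()]
    return wide.to_numpy(dtype=float).copy()


def inject_deaths(
    panel: PanelDataset,
    truth: GeneratorTruth,
    department_id: str,
    year: int,
    start_doy: int,
    end_doy: int,
    extra: float = 10.0,
    seed: int | None = 2,
) -> tuple[PanelDataset, float]:
    """Add ``extra`` expected deaths/day in a window of one department.

    In expected_value mode the counts increase by exactly ``extra``; in
    Poisson mode the window is redrawn at the raised rate.  Returns the new
    panel and the closed-form standard deviation of the realized excess
    difference (0 in expected_value mode).
    """
    cfg = truth.config
    df = panel.df.copy()
    m = (
        (df["department_id"] == department_id)
        & (df["year"] == year)
        & (df["day_of_year"] >= start_doy)
        & (df["day_of_year"] <= end_doy)
    )
    if not m.any():
        raise DataError("injection window matches no panel rows")
    if cfg.noise == "expected_value":
        df.loc[m, "deaths"] += extra
        sd = 0.0
    else:
        d_i = cfg.department_ids().index(department_id)
        panel_dates = truth.dates_full[truth.burn:]
        lam = truth.expected_deaths()[d_i]
        date_pos = panel_dates.get_indexer(pd.DatetimeIndex(df.loc[m, "date"]))
        lam_w = lam[date_pos]
        rng = np.random.default_rng(seed)
        df.loc[m, "deaths"] = rng.poisson(lam_w + extra).astype(float)
        # realized-minus-original excess variance: two independent Poisson sums
        sd = float(np.sqrt(np.sum(lam_w + extra) + np.sum(lam_w)))
    return PanelDataset(df, dept_mean_temp=panel.dept_mean_temp, validate=False), sd


# -----------------------------------------------------------------------------


def make_delta_series(
    dates: pd.DatetimeIndex,
    deltas_by_label: dict[str, float | np.ndarray],
    source_id: str = "synthetic",
) -> pd.DataFrame:
    """Region-wide daily temperature deltas per counterfactual scenario label.

    Labels follow the annual-GMT-anomaly convention, e.g. ``GMT+0.0`` for a
    no-warming counterfactual or ``GMT+1.5``/``GMT+2.0`` for warmed scenarios.
    """
    frames = []
    for label, delta in deltas_by_label.items():
        arr = np.broadcast_to(np.asarray(delta, dtype=float), (len(dates),))
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "scenario_label": label,
                    "source_id": source_id,
                    "delta_c": arr,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if out.duplicated(subset=["date", "scenario_label", "source_id"]).any():
        raise DataError("duplicate (date, scenario_label, source_id) in delta series")
    return out
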