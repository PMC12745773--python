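"""Canonical synthetic studies: the experiments the package is validated on.

Each study generates department-day panels from the default study conditions
(:class:`~heatmort.generator.GeneratorConfig`), runs the estimation and
prediction machinery end to end, and compares the result with the generator's
closed-form ground truth.  The studies are used by the test suite, the
acceptance script, and the analysis drivers, so their problem sizes are fixed
here in one place.

The canonical event is a two-week storyline heat wave: the first half of
August of a held-out year is replaced by the seasonal climatology plus a
sustained +12 degC plateau, a block-like event whose *consecutive-day*
temperature combinations never occur in the estimation years even though
isolated days of comparable heat do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attribution import (
    apply_deltas,
    attributable_deaths,
    predict_event_deaths,
    project_event,
    scenario_from_panel,
)
from .design import ModelSpec, build_design
from .excess import excess_deaths, fit_baseline
from .fitting import CoefficientSamples, fit, sample_coefficients
from .generator import (
    EventSpec,
    GeneratorConfig,
    generate_panel,
    inject_deaths,
    inject_event,
    make_delta_series,
    true_lag0_contrast,
)
from .panel import build_climatology

#: estimation years for the "pre-event" response (the event year is held out)
PRE_PERIOD = (1980, 2002)
EVENT_YEAR = 2003
#: Aug 1 - Aug 14 in leap-calendar day-of-year indexing
EVENT_DOYS = (214, 227)
CANONICAL_EVENT = EventSpec(
    year=EVENT_YEAR,
    start_doy=EVENT_DOYS[0],
    end_doy=EVENT_DOYS[1],
    peak_uplift_c=12.0,
    profile="plateau",
    mode="replace",
)

STANDARD_SPEC = ModelSpec(compounding="none")
COMPOUNDING_SPEC = ModelSpec(compounding="previous_level")


def event_config(**overrides) -> GeneratorConfig:
    """Default study conditions for event experiments (panel ends in the
    event year so the estimation period excludes it)."""
    kw = dict(year_start=PRE_PERIOD[0], year_end=EVENT_YEAR)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def fit_and_sample(
    panel,
    spec: ModelSpec,
    period: tuple[int, int],
    n_draws: int = 500,
    seed: int | None = None,
    climatology=None,
) -> CoefficientSamples:
    design = build_design(panel, spec, period=period, climatology=climatology, reuse_buffers=True)
    fitted = fit(design)
    return sample_coefficients(fitted, n=n_draws, seed=seed)


# -- parameter recovery / interval coverage -----------------------------------


@dataclass
class CoverageResult:
    n_reps: int
    n_covered: int
    estimates: np.ndarray
    truths: np.ndarray

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_reps


def coverage_study(
    n_reps: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    spec: ModelSpec = COMPOUNDING_SPEC,
    scenario: tuple[float, float] = (30.0, 30.0),
    reference: tuple[float, float] = (20.0, 20.0),
    n_draws: int = 500,
) -> CoverageResult:
    """Do 95% coefficient-draw intervals cover the true marginal contrast?

    Each replicate simulates a fresh Poisson panel (default 10 departments x
    25 years), fits the compounding regression, draws coefficients, and checks
    whether the percentile interval for the (previous, current) contrast
    contains the generator's closed-form value.
    """
    from .response import marginal_effect

    cfg = config or GeneratorConfig()
    seeds = _child_seeds(seed, 2 * n_reps)
    covered = 0
    ests, trus = [], []
    for rep in range(n_reps):
        panel, _ = generate_panel(cfg, seed=seeds[2 * rep])
        samples = fit_and_sample(panel, spec, (cfg.year_start, cfg.year_end),
                                 n_draws=n_draws, seed=seeds[2 * rep + 1])
        eff = marginal_effect(samples, scenario, reference)
        truth = (
            np.exp(true_lag0_contrast(cfg, scenario, reference, samples.info.tbar_pw)) - 1
        ) * 100.0
        covered += bool(eff.lo <= truth <= eff.hi)
        ests.append(eff.mean)
        trus.append(truth)
    return CoverageResult(n_reps, covered, np.array(ests), np.array(trus))


# -- excess-mortality injection ------------------------------------------------


@dataclass
class InjectionResult:
    recovered: float
    expected: float
    poisson_sd: float


def excess_injection_study(
    seed: int = 0,
    noise: str = "expected_value",
    extra: float = 10.0,
    n_days: int = 14,
) -> InjectionResult:
    """Inject a known death surplus and recover it via the excess pipeline.

    Adds ``extra`` expected deaths/day for ``n_days`` in one department of a
    synthetic panel, fits the seasonal-and-trend baseline on the unmodified
    panel years, and differences the window excess between the injected and
    original panels.  The baseline prediction cancels exactly, so in
    expected_value mode the recovery is exact; in Poisson mode the realized
    difference has the closed-form standard deviation returned alongside.
    """
    s_gen, s_inj = _child_seeds(seed, 2)
    cfg = GeneratorConfig(noise=noise, year_start=1990, year_end=2001)
    panel, truth = generate_panel(cfg, seed=s_gen)
    dept = cfg.department_ids()[3]
    year, d0 = 2000, 200
    panel2, sd = inject_deaths(
        panel, truth, dept, year, d0, d0 + n_days - 1, extra=extra, seed=s_inj
    )
    # one baseline, fit on the unmodified panel, applied to both versions:
    # its prediction cancels exactly in the excess difference
    baseline = fit_baseline(panel, (1990, 2001))
    _, total1 = excess_deaths(panel, baseline, year, d0, d0 + n_days - 1)
    _, total2 = excess_deaths(panel2, baseline, year, d0, d0 + n_days - 1)
    return InjectionResult(total2 - total1, extra * n_days, sd)


# -- out-of-sample event prediction: standard vs compounding -------------------


@dataclass
class EventRep:
    truth: float
    std_mean: float
    cmp_mean: float
    cmp_lo: float
    cmp_hi: float


def _event_panel(cfg: GeneratorConfig, event: EventSpec, seed_gen: int, seed_ev: int):
    panel, truth = generate_panel(cfg, seed=seed_gen)
    return inject_event(panel, truth, event, seed=seed_ev)


def _event_scenario(panel, spec: ModelSpec, event: EventSpec, extra_days: int):
    # predict over the event window plus the following lags so carry-over is
    # accumulated on both the prediction and the truth side
    return scenario_from_panel(
        panel,
        event.year,
        event.start_doy,
        event.end_doy + extra_days,
        n_history=spec.max_lag_needed,
    )


def event_prediction_study(
    n_reps: int = 50,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    event: EventSpec = CANONICAL_EVENT,
    n_draws: int = 500,
) -> list[EventRep]:
    """Out-of-sample event death tolls: standard vs compounding regression.

    Per replicate: simulate a panel whose final year carries the canonical
    storyline heat wave, fit both regressions on the pre-event years, predict
    the event against climatology, and record the generator's true excess
    (event-window plus lag tail)."""
    cfg = config or event_config()
    L = STANDARD_SPEC.n_lags
    seeds = _child_seeds(seed, 4 * n_reps)
    out = []
    for rep in range(n_reps):
        panel2, truth2, info = _event_panel(cfg, event, seeds[4 * rep], seeds[4 * rep + 1])
        clim = build_climatology(panel2, PRE_PERIOD)
        scen = _event_scenario(panel2, COMPOUNDING_SPEC, event, extra_days=L)
        s_std = fit_and_sample(panel2, STANDARD_SPEC, PRE_PERIOD, n_draws, seeds[4 * rep + 2])
        s_cmp = fit_and_sample(panel2, COMPOUNDING_SPEC, PRE_PERIOD, n_draws, seeds[4 * rep + 3])
        t_std = predict_event_deaths(s_std, scen, clim).totals_by_draw()
        t_cmp = predict_event_deaths(s_cmp, scen, clim).totals_by_draw()
        out.append(
            EventRep(
                truth=info.true_excess_total,
                std_mean=float(t_std.mean()),
                cmp_mean=float(t_cmp.mean()),
                cmp_lo=float(np.percentile(t_cmp, 2.5)),
                cmp_hi=float(np.percentile(t_cmp, 97.5)),
            )
        )
    return out


# -- attribution ---------------------------------------------------------------


@dataclass
class AttributionStudyResult:
    summary: dict
    true_attributable: float
    excess_total: float
    std_summary: dict


def attribution_study(
    seed: int = 0,
    delta_c: float = -1.2,
    n_draws: int = 500,
    config: GeneratorConfig | None = None,
    event: EventSpec = CANONICAL_EVENT,
) -> AttributionStudyResult:
    """Attribute event deaths to a uniform warming delta.

    The counterfactual cools every department-day of the event window by
    ``|delta_c|``; attributable deaths are the paired per-draw difference
    between the factual and counterfactual predictions.  The generator's
    closed-form attributable total (difference in expected deaths between the
    two temperature series over the same cells) is returned for comparison.
    """
    cfg = config or event_config()
    L = STANDARD_SPEC.n_lags
    seeds = _child_seeds(seed, 4)
    panel2, truth2, info = _event_panel(cfg, event, seeds[0], seeds[1])
    clim = build_climatology(panel2, PRE_PERIOD)
    scen = _event_scenario(panel2, COMPOUNDING_SPEC, event, extra_days=L)
    s_cmp = fit_and_sample(panel2, COMPOUNDING_SPEC, PRE_PERIOD, n_draws, seeds[2])
    s_std = fit_and_sample(panel2, STANDARD_SPEC, PRE_PERIOD, n_draws, seeds[3])

    deltas = make_delta_series(scen.window_dates, {"GMT+0.0": delta_c})
    cf = apply_deltas(scen, deltas[deltas["scenario_label"] == "GMT+0.0"], label="GMT+0.0")

    att = attributable_deaths(
        predict_event_deaths(s_cmp, scen, clim),
        predict_event_deaths(s_cmp, cf, clim),
    )
    att_std = attributable_deaths(
        predict_event_deaths(s_std, scen, clim),
        predict_event_deaths(s_std, cf, clim),
    )

    # closed-form truth over the same cells: expected deaths at event
    # temperatures minus at uniformly shifted temperatures
    dates_panel = truth2.dates_full[truth2.burn:]
    window = scen.window_dates
    hist = scen.df[scen.df["date"] < scen.window_start]["date"].unique()
    shifted_dates = set(window) | set(hist)
    shift_mask = np.array([d in shifted_dates for d in dates_panel])
    temps_cf = truth2.temps_full.copy()
    temps_cf[:, truth2.burn:][:, shift_mask] += delta_c
    lam_obs = truth2.expected_deaths()
    lam_cf = truth2.expected_deaths(temps_cf)
    cell_mask = np.array([d in set(window) for d in dates_panel])
    true_att = float((lam_obs - lam_cf)[:, cell_mask].sum())

    baseline = fit_baseline(panel2, (cfg.year_start, cfg.year_end))
    _, excess_total = excess_deaths(
        panel2, baseline, event.year, event.start_doy, event.end_doy
    )
    return AttributionStudyResult(att.summary(), true_att, excess_total, att_std.summary())


# -- adaptation contrast -------------------------------------------------------


@dataclass
class AdaptationResult:
    pre_totals: np.ndarray
    post_totals: np.ndarray

    @property
    def frac_post_below_pre(self) -> float:
        return float(np.mean(self.post_totals < self.pre_totals))


def adaptation_study(
    seed: int = 0,
    warming_delta: float = 1.5,
    response_scale_post: float = 0.5,
    n_draws: int = 500,
    event: EventSpec = CANONICAL_EVENT,
) -> AdaptationResult:
    """Project a warmed event with pre- and post-adaptation responses.

    The post-adaptation world halves every temperature coefficient (the
    moderation observed after severe events); both response functions are fit
    on their own synthetic panels and applied to the same warmed scenario."""
    seeds = _child_seeds(seed, 6)
    cfg_pre = event_config()
    cfg_post = cfg_pre.with_response_scale(response_scale_post)
    panel_pre, truth_pre, _ = _event_panel(cfg_pre, event, seeds[0], seeds[1])
    panel_post, _ = generate_panel(cfg_post, seed=seeds[2])
    clim = build_climatology(panel_pre, PRE_PERIOD)
    L = STANDARD_SPEC.n_lags
    scen = _event_scenario(panel_pre, COMPOUNDING_SPEC, event, extra_days=L)
    deltas = make_delta_series(scen.window_dates, {"warmed": warming_delta})
    warmed = apply_deltas(scen, deltas, label=f"GMT+{warming_delta}")

    s_pre = fit_and_sample(panel_pre, COMPOUNDING_SPEC, PRE_PERIOD, n_draws, seeds[3])
    s_post = fit_and_sample(panel_post, COMPOUNDING_SPEC, PRE_PERIOD, n_draws, seeds[4])
    p_pre = project_event(s_pre, warmed, clim)
    p_post = project_event(s_post, warmed, clim)
    return AdaptationResult(p_pre.totals_by_draw(), p_post.totals_by_draw())
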