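"""Orchestration: configuration file, staged runs, and reproducibility manifests.

A single master seed fans out into named substreams (generation, event
injection, coefficient sampling) so each stage is independently reproducible;
every artifact lands in the configured output directory and is content-hashed
into ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    apply_deltas,
    attributable_deaths,
    predict_event_deaths,
    project_event,
    scenario_from_panel,
)
from .design import ModelSpec, build_design, support_mask
from .errors import ConfigError, DataError
from .excess import excess_deaths, fit_baseline
from .fitting import fit, sample_coefficients
from .generator import EventSpec, GeneratorConfig, generate_panel, inject_event, make_delta_series
from .panel import PanelDataset, build_climatology, read_panel, write_panel
from .response import compounding_surface, response_curve

_SUBSTREAMS = {"generate": 0, "event": 1, "samples_pre": 2, "samples_post": 3}


def substream(master_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the master seed."""
    child = np.random.SeedSequence(master_seed).spawn(len(_SUBSTREAMS))[_SUBSTREAMS[name]]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    panel_path: str | None = None
    deltas_path: str | None = None
    generator: GeneratorConfig | None = None
    event: dict | None = None  # year, start_doy, end_doy, peak_uplift_c
    deltas_by_label: dict[str, float] = field(
        default_factory=lambda: {"GMT+0.0": -1.2, "GMT+1.5": 0.9, "GMT+2.0": 1.55}
    )
    counterfactual_label: str = "GMT+0.0"
    projection_labels: tuple[str, ...] = ("GMT+1.5", "GMT+2.0")
    pre_period: tuple[int, int] = (1980, 2002)
    post_period: tuple[int, int] | None = None
    climatology_period: tuple[int, int] | None = None
    model: ModelSpec = field(default_factory=lambda: ModelSpec(compounding="previous_level"))
    n_samples: int = 500
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.event is not None:
            y = int(self.event["year"])
            for name, period in (("pre", self.pre_period), ("post", self.post_period)):
                if period is not None and period[0] <= y <= period[1]:
                    raise ConfigError(
                        f"{name}_period {period} overlaps the event year {y}; "
                        "out-of-sample prediction requires disjoint periods"
                    )

    @property
    def clim_period(self) -> tuple[int, int]:
        return self.climatology_period or self.pre_period

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if kw.get("generator") is not None:
            kw["generator"] = GeneratorConfig.from_dict(kw["generator"])
        if kw.get("model") is not None:
            kw["model"] = ModelSpec.from_dict(kw["model"])
        for k in ("pre_period", "post_period", "projection_labels"):
            if kw.get(k) is not None:
                kw[k] = tuple(kw[k])
        if kw.get("climatology_period") is not None:
            kw["climatology_period"] = tuple(kw["climatology_period"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["generator"] = self.generator.to_dict() if self.generator else None
        d["model"] = self.model.to_dict()
        for k in ("pre_period", "post_period", "projection_labels", "climatology_period"):
            if d.get(k) is not None:
                d[k] = list(d[k])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, cfg: PipelineConfig, artifacts: list[Path]) -> Path:
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _prepare_out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.overwrite:
        raise ConfigError(
            f"output directory {out} is not empty; pass overwrite: true to reuse it"
        )
    out.mkdir(parents=True, exist_ok=True)
    return out


# -- stages -------------------------------------------------------------------


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate a panel (and optional event), write panel/delta CSVs and a
    ground-truth manifest for downstream checks."""
    if cfg.generator is None:
        raise ConfigError("simulate requires a generator section in the config")
    out = _prepare_out(cfg)
    panel, truth = generate_panel(cfg.generator, seed=substream(cfg.seed, "generate"))
    truth_info: dict = {
        "f_poly": list(cfg.generator.f_poly()),
        "lag_weights": list(cfg.generator.lag_weights),
        "climate_coeff": cfg.generator.climate_coeff,
        "compound_coeff": cfg.generator.compound_coeff,
        "response_scale": cfg.generator.response_scale,
    }
    if cfg.event is not None:
        ev = EventSpec(
            year=int(cfg.event["year"]),
            start_doy=int(cfg.event["start_doy"]),
            end_doy=int(cfg.event["end_doy"]),
            peak_uplift_c=float(cfg.event.get("peak_uplift_c", 8.0)),
            profile=cfg.event.get("profile", "hann"),
            mode=cfg.event.get("mode", "replace"),
        )
        panel, truth, info = inject_event(panel, truth, ev, seed=substream(cfg.seed, "event"))
        truth_info["true_event_excess"] = info.true_excess_total
        window = info.window_dates
    else:
        window = panel.df["date"].iloc[:0]

    panel_path = out / "panel.csv"
    write_panel(panel, panel_path)
    artifacts = [panel_path]
    if len(window) > 0:
        # cover the lag tail after the event so predictions that accumulate
        # carry-over days can be delta-shifted too
        full_window = pd.date_range(window[0], window[-1] + pd.Timedelta(days=cfg.model.n_lags))
        deltas = make_delta_series(full_window, cfg.deltas_by_label)
        deltas_path = out / "deltas.csv"
        deltas.to_csv(deltas_path, index=False)
        artifacts.append(deltas_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_info, indent=2))
    artifacts.append(truth_path)
    artifacts.append(_write_manifest(out, cfg, artifacts))
    return {"panel": str(panel_path), "n_records": panel.n_records, **truth_info}


def _load_panel(cfg: PipelineConfig) -> PanelDataset:
    path = cfg.panel_path or str(Path(cfg.out_dir) / "panel.csv")
    return read_panel(path).with_mean_temperature(cfg.pre_period)


def _event_window(cfg: PipelineConfig) -> tuple[int, int, int]:
    if cfg.event is None:
        raise ConfigError("this stage requires an event section in the config")
    return int(cfg.event["year"]), int(cfg.event["start_doy"]), int(cfg.event["end_doy"])


def _fit_samples(cfg: PipelineConfig, panel, spec, period, seed_name):
    clim = build_climatology(panel, cfg.clim_period) if spec.compounding == "previous_anomaly" else None
    design = build_design(panel, spec, period=period, climatology=clim)
    fitted = fit(design)
    return sample_coefficients(fitted, n=cfg.n_samples, seed=substream(cfg.seed, seed_name))


def run_full(cfg: PipelineConfig) -> dict:
    """The end-to-end sequence: fit the standard and compounding response
    functions on the pre period, predict the event out of sample, compare to
    excess mortality, attribute deaths against the counterfactual deltas,
    optionally refit on the post period, and project the event under warmed
    scenarios with each period's response."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    panel = _load_panel(cfg)
    year, d0, d1 = _event_window(cfg)
    clim = build_climatology(panel, cfg.clim_period)

    standard = ModelSpec(**{**cfg.model.to_dict(), "compounding": "none"})
    compounding = cfg.model if cfg.model.compounding != "none" else ModelSpec(
        **{**cfg.model.to_dict(), "compounding": "previous_level"}
    )

    samples_std = _fit_samples(cfg, panel, standard, cfg.pre_period, "samples_pre")
    samples_cmp = _fit_samples(cfg, panel, compounding, cfg.pre_period, "samples_pre")

    # excess mortality over the event window
    baseline = fit_baseline(panel, (panel.years[0], panel.years[-1]))
    excess_tab, excess_total = excess_deaths(panel, baseline, year, d0, d1)
    p = out / "excess.csv"
    excess_tab.to_csv(p, index=False)
    artifacts.append(p)

    # response curves and surface
    mask = support_mask(panel, period=cfg.pre_period)
    grid = np.arange(-5.0, 36.0, 1.0)
    for name, smp in (("standard", samples_std), ("compounding", samples_cmp)):
        curve = response_curve(smp, grid, previous=20.0, mask=mask)
        p = out / f"curve_{name}.csv"
        curve.to_csv(p)
        artifacts.append(p)
    surf = compounding_surface(samples_cmp, grid, grid, mask=mask)
    p = out / "surface.csv"
    surf.to_frame().to_csv(p, index=False)
    artifacts.append(p)

    # out-of-sample event prediction + attribution
    H = compounding.n_lags + 1
    observed = scenario_from_panel(panel, year, d0, d1, n_history=H)
    deltas = pd.read_csv(
        cfg.deltas_path or Path(cfg.out_dir) / "deltas.csv", parse_dates=["date"]
    )
    preds = {}
    for name, smp in (("standard", samples_std), ("compounding", samples_cmp)):
        preds[name] = predict_event_deaths(smp, observed, clim)
    cf_lab = cfg.counterfactual_label
    cf_scenario = apply_deltas(
        observed, deltas[deltas["scenario_label"] == cf_lab], label=cf_lab
    )
    att = attributable_deaths(
        preds["compounding"], predict_event_deaths(samples_cmp, cf_scenario, clim)
    )
    att_std = attributable_deaths(
        preds["standard"], predict_event_deaths(samples_std, cf_scenario, clim)
    )

    # adaptation: refit on the post period if configured, project warmed events
    projections: dict = {}
    samples_post = None
    if cfg.post_period is not None:
        samples_post = _fit_samples(cfg, panel, compounding, cfg.post_period, "samples_post")
    for lab in cfg.projection_labels:
        sub = deltas[deltas["scenario_label"] == lab]
        if sub.empty:
            continue
        warmed = apply_deltas(observed, sub, label=lab)
        projections[f"pre::{lab}"] = project_event(samples_cmp, warmed, clim).summary()
        if samples_post is not None:
            projections[f"post::{lab}"] = project_event(samples_post, warmed, clim).summary()

    summary = {
        "event": {"year": year, "start_doy": d0, "end_doy": d1},
        "excess_deaths": excess_total,
        "predicted_deaths": {k: v.summary() for k, v in preds.items()},
        "attribution_compounding": att.summary(),
        "attribution_standard": att_std.summary(),
        "projections": projections,
        "n_obs_pre": samples_cmp.fitted.n_obs,
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, default=str))
    artifacts.append(p)
    artifacts.append(_write_manifest(out, cfg, artifacts))
    return summary
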