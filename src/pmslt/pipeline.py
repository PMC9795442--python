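"""Configuration-driven end-to-end pipeline.

One YAML config drives: synthetic input generation (or loading user CSVs),
trajectory construction, the BAU / counterfactual / TMREL runs, attributable
and prevented burden tables, the yearly trend series, and optional Monte
Carlo and sensitivity stages. All outputs are CSV/JSON; a manifest records
the seed, a hash of the config and the package version, which together
fully determine every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .distributions import PointExposure, UniformExposure
from .engine import EngineConfig, MSLTModel, attributable_burden, prevented_burden
from .montecarlo import ParameterDistributions, run_monte_carlo
from .reporting import aggregate_results, run_sensitivity
from .scenarios import SCENARIO_NAMES, ScenarioSpec, apply_scenario, project_bau
from .synth import default_inputs
from .types import ModelInputs

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": {"source": "synthetic", "total_population": 155_000_000},
    "scenario": {"horizon_years": 10, "reduction_fraction": 0.067},
    "lags": {"noncancer_years": 5, "cancer_years": 10, "noncancer_form": "ramp"},
    "tmrel": {"kind": "uniform", "low": 20.0, "high": 25.0},
    "engine": {"entrant_growth": 1.01, "anchor": 22.5, "floor_rr_at_one": False},
    "mc": {"enabled": False, "draws": 5000, "exposure_mean_se": 0.1, "rate_cv": 0.05},
    "sensitivity": {"enabled": False},
    "output": {"dir": "pmslt_out"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ValueError(f"unknown config key {k!r}")
        out[k] = _merge(base[k], v) if isinstance(base[k], dict) and isinstance(v, dict) else v
    return out


def load_config(config_path: str | Path | None) -> dict:
    if config_path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    text = Path(config_path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a YAML mapping")
    return _merge(DEFAULT_CONFIG, user)


def _engine_config(cfg: dict) -> EngineConfig:
    tm = cfg["tmrel"]
    if tm["kind"] == "uniform":
        tmrel = UniformExposure(float(tm.get("low", 20.0)), float(tm.get("high", 25.0)))
    elif tm["kind"] == "point":
        tmrel = PointExposure(float(tm.get("at", 22.5)))
    else:
        raise ValueError("tmrel.kind must be 'uniform' or 'point'")
    return EngineConfig(
        horizon=int(cfg["scenario"]["horizon_years"]),
        entrant_growth=float(cfg["engine"]["entrant_growth"]),
        anchor=float(cfg["engine"]["anchor"]),
        tmrel=tmrel,
        floor_rr_at_one=bool(cfg["engine"]["floor_rr_at_one"]),
    )


def build_inputs(cfg: dict) -> ModelInputs:
    src = cfg["inputs"]["source"]
    if src == "synthetic":
        return default_inputs(seed=int(cfg["seed"]),
                              total_population=float(cfg["inputs"]["total_population"]))
    return pio.read_inputs(Path(src))


def _apply_lag_config(inputs: ModelInputs, cfg: dict) -> ModelInputs:
    from dataclasses import replace as dc_replace
    lags = cfg["lags"]
    out = inputs.copy()
    new_rates = []
    for rs in out.disease_rates:
        d = rs.definition
        if d.group == "cancer":
            d = dc_replace(d, lag_years=float(lags["cancer_years"]), lag_form="step")
        else:
            d = dc_replace(d, lag_years=float(lags["noncancer_years"]),
                           lag_form=str(lags["noncancer_form"]))
        rs.definition = d
        new_rates.append(rs)
    out.disease_rates = new_rates
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config_path: str | Path | None, out_dir: str | Path | None = None) -> Path:
    """Execute the whole pipeline; returns the artifact directory.

    Stages: inputs -> trajectories -> runs (BAU, S1-S3, TMREL) ->
    attributable & prevented burden tables and trend series -> optional
    Monte Carlo and sensitivity -> manifest. Any stage failure aborts the
    pipeline with the stage name; partial outputs are written to a temporary
    directory that is only renamed into place on success.
    """
    try:
        cfg = load_config(config_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'config': {exc}") from exc
    out = Path(out_dir or cfg["output"]["dir"])
    tmp = out.with_name(out.name + ".partial")
    if tmp.exists():
        import shutil
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        inputs = _apply_lag_config(build_inputs(cfg), cfg)
        pio.write_inputs(inputs, tmp / "inputs")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "trajectories"
        t0 = time.perf_counter()
        horizon = int(cfg["scenario"]["horizon_years"])
        bau = project_bau(inputs.bmi_baseline, inputs.annual_mean_delta, horizon)
        trajectories = {"BAU": bau}
        for name in SCENARIO_NAMES[1:]:
            spec = ScenarioSpec(name, reduction_fraction=float(cfg["scenario"]["reduction_fraction"]),
                                horizon_years=horizon)
            trajectories[name] = apply_scenario(bau, spec)
        _write_csv(pd.concat([t.to_frame() for t in trajectories.values()], ignore_index=True),
                   tmp / "trajectories.csv")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "runs"
        t0 = time.perf_counter()
        config = _engine_config(cfg)
        model = MSLTModel(inputs, config)
        runs = {name: model.run(traj) for name, traj in trajectories.items()}
        runs["TMREL"] = model.run("tmrel")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "burden"
        t0 = time.perf_counter()
        attrib = attributable_burden(runs["BAU"], runs["TMREL"])
        _write_csv(attrib.to_frame(), tmp / "attributable_burden.csv")
        for metric in ("cases", "deaths"):
            tab = aggregate_results(attrib, metric=metric)
            tab.rounded.rename_axis("group").reset_index().pipe(
                _write_csv, tmp / f"table_attributable_{metric}.csv")

        prevented = {}
        trend_recs = []
        for name in SCENARIO_NAMES[1:]:
            p = prevented_burden(runs["BAU"], runs[name])
            prevented[name] = p
            _write_csv(p.to_frame(), tmp / f"prevented_{name}.csv")
        for metric in ("cases", "deaths"):
            recs = []
            for name in SCENARIO_NAMES[1:]:
                tab = aggregate_results(prevented[name], metric=metric)
                row = tab.rounded.loc["Total"]
                recs.append((name, row["Men"], row["Women"], row["Total"]))
            _write_csv(pd.DataFrame(recs, columns=["scenario", "men", "women", "total"]),
                       tmp / f"table_prevented_{metric}.csv")
        # yearly attributable trend per scenario (the figure-style series)
        for name in SCENARIO_NAMES:
            a = attributable_burden(runs[name], runs["TMREL"])
            for y in range(horizon):
                trend_recs.append((name, y + 1,
                                   float(a.yearly_totals("cases")[y]),
                                   float(a.yearly_totals("deaths")[y])))
        _write_csv(pd.DataFrame(trend_recs, columns=["scenario", "year", "cases", "deaths"]),
                   tmp / "trend.csv")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        if cfg["mc"]["enabled"]:
            stage = "monte_carlo"
            t0 = time.perf_counter()
            dists = ParameterDistributions(
                exposure_mean_se=float(cfg["mc"]["exposure_mean_se"]),
                rate_cv=float(cfg["mc"]["rate_cv"]),
                n_draws=int(cfg["mc"]["draws"]), seed=int(cfg["seed"]))
            ui = run_monte_carlo(inputs, ("bau", "tmrel"), dists, config)
            _write_csv(ui.to_frame(), tmp / "ui.csv")
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        if cfg["sensitivity"]["enabled"]:
            stage = "sensitivity"
            t0 = time.perf_counter()
            rep = run_sensitivity(inputs, config)
            _write_csv(rep.table.rename_axis("variant").reset_index(), tmp / "sensitivity.csv")
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "manifest"
        cfg_text = json.dumps(cfg, sort_keys=True)
        manifest = {
            "seed": cfg["seed"],
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "config": cfg,
            "package_version": __import__("pmslt").__version__,
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        import shutil
        shutil.rmtree(tmp, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if out.exists():
        import shutil
        shutil.rmtree(out)
    tmp.rename(out)
    return out
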