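"""End-to-end pipeline orchestration.

``run_pipeline`` executes the seven stages

    simulate -> qc -> assemble -> train -> predict -> change -> health

writing every intermediate artifact under the output directory and a JSON
manifest recording, per stage, the inputs hash, outputs hash, stage seed and
wall time. The master seed expands into per-stage seeds through a fixed
``numpy.random.SeedSequence`` spawn order, so individual stages can be re-run
in isolation and a full re-run with the same configuration and seed
reproduces every artifact. Stages whose outputs already exist are skipped
unless ``force`` is set, which lets a run resume after downstream outputs are
deleted.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import exposure, features, health, rf_model, satellite_qc
from .synthetic import (LatentScenario, ScenarioConfig, generate_scenario,
                        synthesize_meteorology, synthesize_satellite)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "assemble", "train", "predict", "change", "health")

# exit/error codes per failure class
ERR_CONFIG = 2
ERR_STAGE = 3
ERR_IO = 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, code: int = ERR_STAGE):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.code = code


def default_health_params_path() -> Path:
    return Path(importlib.resources.files("airburden") / "data" / "health_params.yaml")


class RunConfig(BaseModel):
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    pollutants: list[str] | None = None      # default: all in the scenario
    rf_n_estimators: int = 500
    rf_max_features: float = 1.0 / 3.0
    # "per_year": one model per (pollutant, year), each predicting its own
    # year, which preserves between-year level contrasts; "pooled": one model
    # per pollutant across all years.
    training_preset: str = "per_year"
    cv_schemes: list[str] = Field(default_factory=lambda: ["tenfold_sample", "by_year"])
    health_params_path: str | None = None    # default: packaged parameter file
    outdir: str = "runs/default"
    master_seed: int = 0

    def active_pollutants(self) -> list[str]:
        if self.pollutants is None:
            return sorted(self.scenario.pollutants)
        return sorted(self.pollutants)

    def hyperparams(self) -> rf_model.RFHyperparams:
        return rf_model.RFHyperparams(n_estimators=self.rf_n_estimators,
                                      max_features=self.rf_max_features)

    def resolved_health_params(self) -> Path:
        if self.health_params_path is None:
            return default_health_params_path()
        return Path(self.health_params_path)

    @field_validator("training_preset")
    @classmethod
    def _preset(cls, v: str) -> str:
        if v not in ("per_year", "pooled"):
            raise ValueError("training_preset must be 'per_year' or 'pooled'")
        return v


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML run configuration, reporting all violations."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    except OSError as err:
        return None, [f"unreadable config file: {err}"]
    except yaml.YAMLError as err:
        return None, [f"malformed YAML: {err}"]
    errors: list[str] = []
    cfg: RunConfig | None = None
    try:
        cfg = RunConfig.model_validate(doc)
    except ValidationError as err:
        errors.extend(f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                      for e in err.errors())
        return None, errors
    bad = set(cfg.active_pollutants()) - set(cfg.scenario.pollutants)
    if bad:
        errors.append(f"pollutants: {sorted(bad)} not configured in the scenario")
    hp_path = cfg.resolved_health_params()
    if not hp_path.exists():
        errors.append(f"health_params_path: file not found: {hp_path}")
    return (cfg if not errors else None), errors


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(STAGES, children)}


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


@dataclass
class _Context:
    cfg: RunConfig
    outdir: Path
    seeds: dict[str, int]
    scenario: LatentScenario | None = None


def _load_scenario(ctx: _Context) -> LatentScenario:
    """Regenerate the in-memory scenario (deterministic given the stage seeds)."""
    if ctx.scenario is None:
        scen = generate_scenario(ctx.cfg.scenario, ctx.seeds["simulate"])
        synthesize_meteorology(scen, ctx.seeds["simulate"] + 1)
        synthesize_satellite(scen, seed=ctx.seeds["simulate"] + 2,
                             pollutants=ctx.cfg.active_pollutants())
        ctx.scenario = scen
    return ctx.scenario


def _stage_simulate(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    scen.export(stage_dir)
    np.save(stage_dir / "population.npy", scen.population)
    return sorted(stage_dir.iterdir())


def _stage_qc(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    outputs = []
    report_rows = []
    for pol in ctx.cfg.active_pollutants():
        series = scen.satellite[pol]
        cubes = []
        counts: dict[str, int] = {}
        for i in range(len(series)):
            res = satellite_qc.filter_retrievals(series.field(i))
            for rule, n in res.removed_per_rule.items():
                counts[rule] = counts.get(rule, 0) + n
            cubes.append(satellite_qc.regrid_area_weighted(res.field, scen.grid))
        da = xr.DataArray(np.stack(cubes),
                          coords={"time": series.time, "lat": scen.grid.lat_centers,
                                  "lon": scen.grid.lon_centers},
                          dims=("time", "lat", "lon"), name="satellite")
        path = stage_dir / f"satellite_{pol}.nc"
        da.to_dataset(name="satellite").to_netcdf(path, engine="scipy")
        outputs.append(path)
        report_rows.extend({"pollutant": pol, "rule": r, "pixels_removed": n}
                           for r, n in sorted(counts.items()))
    report = stage_dir / "qc_report.csv"
    pd.DataFrame(report_rows).to_csv(report, index=False)
    outputs.append(report)
    return outputs


def _stage_assemble(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    static = scen.static_covariates()
    outputs = []
    for pol in ctx.cfg.active_pollutants():
        sat = xr.open_dataset(ctx.outdir / "qc" / f"satellite_{pol}.nc",
                              engine="scipy")["satellite"]
        table = features.build_table(scen.observations, sat, scen.meteorology,
                                     static, scen.grid, pol,
                                     window_start=ctx.cfg.scenario.window_start)
        path = stage_dir / f"features_{pol}.csv"
        features.to_csv(table, path)
        outputs.append(path)
    return outputs


def _stage_train(ctx: _Context, stage_dir: Path) -> list[Path]:
    outputs = []
    hp = ctx.cfg.hyperparams()
    for k, pol in enumerate(ctx.cfg.active_pollutants()):
        table = features.from_csv(ctx.outdir / "assemble" / f"features_{pol}.csv")
        if ctx.cfg.training_preset == "per_year":
            for j, year in enumerate(sorted(table["year"].unique())):
                model = rf_model.fit(table[table["year"] == year], hp,
                                     seed=ctx.seeds["train"] + 10 * k + j,
                                     pollutant=pol)
                path = stage_dir / f"model_{pol}_{year}.joblib"
                joblib.dump(model, path)
                outputs.append(path)
        else:
            model = rf_model.fit(table, hp, seed=ctx.seeds["train"] + 10 * k,
                                 pollutant=pol)
            path = stage_dir / f"model_{pol}.joblib"
            joblib.dump(model, path)
            outputs.append(path)
    return outputs


def _stage_predict(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    static = scen.static_covariates()
    outputs = []
    for pol in ctx.cfg.active_pollutants():
        sat = xr.open_dataset(ctx.outdir / "qc" / f"satellite_{pol}.nc",
                              engine="scipy")["satellite"]
        if ctx.cfg.training_preset == "per_year":
            parts = []
            for year in np.unique(sat.time.dt.year.values):
                model: rf_model.FittedModel = joblib.load(
                    ctx.outdir / "train" / f"model_{pol}_{year}.joblib")
                sel = sat.time.dt.year == year
                parts.append(rf_model.predict_grid_series(
                    model, sat.sel(time=sel),
                    scen.meteorology.sel(time=scen.meteorology.time.dt.year == year),
                    static, scen.grid, window_start=ctx.cfg.scenario.window_start))
            pred = xr.concat(parts, dim="time")
        else:
            model = joblib.load(ctx.outdir / "train" / f"model_{pol}.joblib")
            pred = rf_model.predict_grid_series(
                model, sat, scen.meteorology, static, scen.grid,
                window_start=ctx.cfg.scenario.window_start)
        path = stage_dir / f"predicted_{pol}.nc"
        pred.to_dataset(name="concentration").to_netcdf(path, engine="scipy")
        outputs.append(path)
    return outputs


def _predicted_by_year(ctx: _Context, pol: str) -> dict[int, xr.DataArray]:
    da = xr.open_dataset(ctx.outdir / "predict" / f"predicted_{pol}.nc",
                         engine="scipy")["concentration"]
    return {int(y): da.sel(time=da.time.dt.year == y)
            for y in np.unique(da.time.dt.year.values)}


def _stage_change(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    outputs = []
    regional_frames, weekly_frames = [], []
    for pol in ctx.cfg.active_pollutants():
        preds = _predicted_by_year(ctx, pol)
        summary = exposure.summarize(pol, preds, scen.target_year, scen.grid,
                                     scen.region_masks, scen.population)
        path = stage_dir / f"change_{pol}.nc"
        summary.to_dataset(scen.grid).to_netcdf(path, engine="scipy")
        outputs.append(path)
        regional_frames.append(summary.regional)
        weekly_frames.append(summary.weekly)
    regional = stage_dir / "regional_changes.csv"
    pd.concat(regional_frames, ignore_index=True).to_csv(
        regional, index=False, float_format="%.10g")
    weekly = stage_dir / "weekly_changes.csv"
    pd.concat(weekly_frames, ignore_index=True).to_csv(
        weekly, index=False, float_format="%.10g")
    outputs.extend([regional, weekly])
    return outputs


def _stage_health(ctx: _Context, stage_dir: Path) -> list[Path]:
    scen = _load_scenario(ctx)
    params = health.load_health_params(ctx.cfg.resolved_health_params())
    params = [p for p in params if p.pollutant in ctx.cfg.active_pollutants()]
    if not params:
        logger.warning("no health parameters match the active pollutants; "
                       "writing empty burden tables")
    per_year_frames, delta_frames = [], []
    for pol in sorted({p.pollutant for p in params}):
        preds = _predicted_by_year(ctx, pol)
        year_means = {y: exposure.window_mean(da) for y, da in preds.items()}
        window_days = {y: int(preds[y].sizes["time"]) for y in preds}
        per_year, deltas = health.assess(
            year_means, scen.target_year,
            [p for p in params if p.pollutant == pol],
            scen.population, window_days, scen.region_masks)
        per_year_frames.append(per_year)
        delta_frames.append(deltas)
    per_year_path = stage_dir / "burden_per_year.csv"
    delta_path = stage_dir / "burden_delta.csv"
    (pd.concat(per_year_frames, ignore_index=True) if per_year_frames
     else health.burden_table([])).to_csv(per_year_path, index=False,
                                          float_format="%.10g")
    (pd.concat(delta_frames, ignore_index=True) if delta_frames
     else health.burden_table([])).to_csv(delta_path, index=False,
                                          float_format="%.10g")
    return [per_year_path, delta_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assemble": _stage_assemble,
    "train": _stage_train,
    "predict": _stage_predict,
    "change": _stage_change,
    "health": _stage_health,
}

_STAGE_INPUTS = {
    "simulate": (),
    "qc": ("simulate",),
    "assemble": ("simulate", "qc"),
    "train": ("assemble",),
    "predict": ("qc", "train"),
    "change": ("predict",),
    "health": ("predict",),
}


def run_stage(ctx: _Context, stage: str, force: bool = False) -> dict:
    stage_dir = ctx.outdir / stage
    manifest_entry = ctx.outdir / stage / ".outputs.json"
    if manifest_entry.exists() and not force:
        entry = json.loads(manifest_entry.read_text())
        paths = [Path(p) for p in entry["outputs"]]
        if all(p.exists() for p in paths):
            logger.info("stage %s: outputs exist, skipping (use force to re-run)", stage)
            entry["skipped"] = True
            return entry
    stage_dir.mkdir(parents=True, exist_ok=True)
    upstream = []
    for dep in _STAGE_INPUTS[stage]:
        dep_entry = ctx.outdir / dep / ".outputs.json"
        if not dep_entry.exists():
            raise PipelineError(stage, f"missing upstream stage '{dep}'")
        upstream.extend(Path(p) for p in json.loads(dep_entry.read_text())["outputs"])
    t0 = time.time()
    try:
        outputs = _STAGE_FUNCS[stage](ctx, stage_dir)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    entry = {
        "stage": stage,
        "seed": ctx.seeds[stage],
        "inputs_hash": _hash_files(upstream) if upstream else None,
        "outputs_hash": _hash_files(outputs),
        "outputs": [str(p) for p in outputs],
        "wall_time_s": round(time.time() - t0, 3),
        "skipped": False,
    }
    manifest_entry.write_text(json.dumps(entry, indent=1))
    return entry


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Run all seven stages in order; return and write the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(cfg=cfg, outdir=outdir, seeds=stage_seeds(cfg.master_seed))
    entries = []
    for stage in STAGES:
        logger.info("running stage %s", stage)
        entries.append(run_stage(ctx, stage, force=force))
    manifest = {"master_seed": cfg.master_seed,
                "pollutants": cfg.active_pollutants(),
                "stages": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_cv(cfg: RunConfig, pollutant: str,
           hyperparams: rf_model.RFHyperparams | None = None) -> dict[str, rf_model.CVResult]:
    """Run the configured cross-validation schemes on an assembled table."""
    table = features.from_csv(Path(cfg.outdir) / "assemble" / f"features_{pollutant}.csv")
    seeds = stage_seeds(cfg.master_seed)
    hp = hyperparams or cfg.hyperparams()
    out = {}
    if "tenfold_sample" in cfg.cv_schemes:
        out["tenfold_sample"] = rf_model.cross_validate_10fold(
            table, hp, seed=seeds["train"] + 101)
    if "by_year" in cfg.cv_schemes:
        out["by_year"] = rf_model.cross_validate_by_year(
            table, hp, seed=seeds["train"] + 202)
    return out
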