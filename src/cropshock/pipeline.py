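"""End-to-end orchestration: config parsing, staging, manifests.

A pipeline run is driven by a single YAML config holding either a
synthetic-landscape section or a path to an on-disk cell table (never
both), plus optional preprocessing, model and scenario overrides.  All
randomness flows from the config's seeds; rerunning the same config
produces bit-identical CSV outputs and an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cells import read_cell_table, write_cell_table
from .glm import DEFAULT_SPLIT_SEED, CropYieldResults, ModelSpec, fit_gamma_glm, split_sample
from .preprocess import CleaningReport, compute_gvif, preprocess
from .scenario import ScenarioParams, build_phase_inputs
from .summarize import predict_phases, plot_reduction_by_crop, summarize
from .synthetic import SyntheticConfig, default_config, generate_landscape

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "parse_config", "run_pipeline"]

_SCHEMA: dict[str, set] = {
    "": {"input_table", "synthetic", "crops", "preprocess", "model", "scenario",
         "baseline_mode", "seed"},
    "synthetic": {f.name for f in dataclasses.fields(SyntheticConfig)},
    "preprocess": {"min_area_ha", "trim", "n_total_percentile"},
    "model": {"split_fraction", "split_seed"},
    "scenario": {f.name for f in dataclasses.fields(ScenarioParams)},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    input_table: str | None = None
    synthetic: dict = field(default_factory=dict)
    use_synthetic: bool = True
    crops: list[str] | None = None
    min_area_ha: float = 100.0
    trim: dict | None = None
    n_total_percentile: float = 99.9
    split_fraction: float = 0.8
    split_seed: int = DEFAULT_SPLIT_SEED
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    baseline_mode: str = "observed"
    raw: dict = field(default_factory=dict)

    def synthetic_config(self) -> SyntheticConfig:
        over = dict(self.synthetic)
        over.setdefault("seed", self.seed)
        if self.crops and "crops" not in over:
            over["crops"] = tuple(self.crops)
        return default_config(**over)


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            where = f"section {section!r}" if section else "top level"
            msg = f"unknown config key {key!r} at {where}"
            if hint:
                msg += f"; did you mean {hint[0]!r}?"
            raise ValueError(msg)


def parse_config(path_or_mapping) -> PipelineConfig:
    """Parse and validate a pipeline config (YAML path or mapping).

    Unknown keys are rejected with a nearest-key suggestion; scenario
    constants default to the published global figures.  Exactly one of
    ``input_table`` / ``synthetic`` selects the data source (an empty
    config runs the default synthetic landscape).
    """
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})
    _check_keys("", raw)
    for sec in ("synthetic", "preprocess", "model", "scenario"):
        if raw.get(sec):
            _check_keys(sec, raw[sec])
    if raw.get("input_table") and raw.get("synthetic"):
        raise ValueError("config must provide input_table OR synthetic, not both")

    pre = raw.get("preprocess") or {}
    mod = raw.get("model") or {}
    scen_kwargs = raw.get("scenario") or {}
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        input_table=raw.get("input_table"),
        synthetic=raw.get("synthetic") or {},
        use_synthetic=not raw.get("input_table"),
        crops=list(raw["crops"]) if raw.get("crops") else None,
        min_area_ha=float(pre.get("min_area_ha", 100.0)),
        trim=pre.get("trim"),
        n_total_percentile=float(pre.get("n_total_percentile", 99.9)),
        split_fraction=float(mod.get("split_fraction", 0.8)),
        split_seed=int(mod.get("split_seed", DEFAULT_SPLIT_SEED)),
        scenario=ScenarioParams(**scen_kwargs),
        baseline_mode=raw.get("baseline_mode", "observed"),
        raw=raw,
    )
    return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: pd.DataFrame
    preprocessed: pd.DataFrame
    cleaning_report: CleaningReport
    gvif: pd.DataFrame
    fits: dict[str, CropYieldResults]
    validations: pd.DataFrame
    factor_effects: pd.DataFrame
    phase_inputs: dict
    predictions: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir=None, *, plot: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write the artifact bundle."""
    if config.use_synthetic:
        landscape = generate_landscape(config.synthetic_config())
    else:
        landscape = read_cell_table(config.input_table)
    if config.crops:
        landscape = landscape[landscape["crop"].isin(config.crops)].reset_index(drop=True)
    log.info("landscape: %d rows, %d crops", len(landscape), landscape["crop"].nunique())

    table, report = preprocess(
        landscape,
        min_area_ha=config.min_area_ha,
        trim_spec=config.trim,
        n_total_percentile=config.n_total_percentile,
    )
    log.info("preprocessed: %d rows (%d removed)", len(table), report.total_removed)

    spec = ModelSpec()
    gvif_frames = []
    fits: dict[str, CropYieldResults] = {}
    validations = []
    effects = []
    crop_names = sorted(table["crop"].unique())
    crop_seeds = {
        crop: int(child.generate_state(1)[0] % (2**31))
        for crop, child in zip(
            crop_names, np.random.SeedSequence(config.split_seed).spawn(len(crop_names))
        )
    }
    for crop, group in table.groupby("crop", sort=True):
        gv = compute_gvif(group, spec.predictors)
        gv = gv.assign(crop=crop)
        gvif_frames.append(gv)
        crop_seed = crop_seeds[crop]
        cal, val = split_sample(group, config.split_fraction, crop_seed)
        fit = fit_gamma_glm(cal, spec)
        fits[crop] = fit
        v = fit.mcfadden_rho2(val)
        validations.append(
            {"crop": crop, "rho2": v.rho2, "n_calibration": len(cal),
             "n_validation": v.n_validation, "split_seed": crop_seed,
             "dispersion": fit.dispersion, "shape": fit.shape_}
        )
        for factor in (*spec.continuous, *spec.binary):
            fe = fit.factor_effect(group, factor)
            effects.append(
                {"crop": crop, "factor": factor, "x_min": fe.x_min, "x_max": fe.x_max,
                 "percent_change": fe.percent_change}
            )

    phases = {p: build_phase_inputs(table, config.scenario, p) for p in (1, 2)}
    predictions = predict_phases(
        fits, table, phases, baseline_mode=config.baseline_mode
    )
    summary = summarize(predictions)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "split_seed": config.split_seed,
        "n_landscape_rows": len(landscape),
        "n_preprocessed_rows": len(table),
        "crops": sorted(fits),
        "baseline_mode": config.baseline_mode,
        "scenario": dataclasses.asdict(config.scenario),
        "n_unsupported_cells": predictions.attrs.get("n_unsupported", 0),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    result = PipelineResult(
        config=config,
        landscape=landscape,
        preprocessed=table,
        cleaning_report=report,
        gvif=pd.concat(gvif_frames),
        fits=fits,
        validations=pd.DataFrame(validations),
        factor_effects=pd.DataFrame(effects),
        phase_inputs=phases,
        predictions=predictions,
        summary=summary,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir), plot=plot)
    return result


def _write_bundle(result: PipelineResult, outdir: Path, *, plot: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_cell_table(result.landscape, outdir / "landscape.csv")
    write_cell_table(result.preprocessed, outdir / "preprocessed.csv")
    result.cleaning_report.to_frame().to_csv(outdir / "cleaning_report.csv", index=False)
    (outdir / "cleaning_report.txt").write_text(result.cleaning_report.to_text() + "\n")
    result.gvif.to_csv(outdir / "gvif.csv")
    for crop, fit in result.fits.items():
        fit.coef_table().to_csv(outdir / f"model_results_{crop}.csv")
    result.validations.to_csv(outdir / "validation.csv", index=False)
    result.factor_effects.to_csv(outdir / "factor_effects.csv", index=False)
    for phase, inputs in result.phase_inputs.items():
        write_cell_table(inputs.table, outdir / f"phase_inputs_{phase}.csv")
    result.predictions.to_csv(outdir / "predictions.csv", index=False)
    result.summary.to_csv(outdir / "summary.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    if plot:
        plot_reduction_by_crop(result.summary, outdir / "reduction_by_crop.png")
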