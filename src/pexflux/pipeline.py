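"""Stage orchestration: run configured pipeline stages and write a manifest.

A pipeline config is a nested mapping with optional stage blocks
(``synthetic``, ``segment``, ``quantify``, ``fit``, ``simulate``), a
mandatory ``seed`` whenever a stochastic stage (synthetic, simulate) is
requested, and an ``output_dir``.  Stages execute in dependency order;
every run writes ``manifest.json`` recording inputs, outputs, the seed,
and a hash of the parameters so any run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, kinetics, quantitation, segmentation, simulation, synthetic

__all__ = ["ConfigError", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_ORDER = ["synthetic", "segment", "quantify", "fit", "simulate"]
_STOCHASTIC = {"synthetic", "simulate"}


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the failing field."""


def _params_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _kinetic_params(block: dict) -> kinetics.KineticParams:
    return kinetics.KineticParams(**block)


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the configured stages; returns the manifest.

    Raises :class:`ConfigError` naming the first invalid field.  Artifacts
    and ``manifest.json`` are written under ``output_dir`` (or
    ``config["output_dir"]``).
    """
    unknown = set(config) - set(_STAGE_ORDER) - {"seed", "output_dir", "log_level"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in config]
    if not stages:
        raise ConfigError("config contains no stage blocks")
    seed = config.get("seed")
    if any(s in _STOCHASTIC for s in stages) and seed is None:
        raise ConfigError("seed: required when a stochastic stage (synthetic/simulate) is configured")

    outdir = Path(output_dir or config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    if "log_level" in config:
        logging.getLogger("pexflux").setLevel(config["log_level"])

    manifest: dict = {
        "seed": seed,
        "params_hash": _params_hash(config),
        "stages": stages,
        "outputs": {},
        "inputs": {},
    }
    artifacts: dict = {}

    try:
        if "synthetic" in config:
            _stage_synthetic(config["synthetic"], seed, outdir, manifest, artifacts)
        if "segment" in config:
            _stage_segment(config["segment"], outdir, manifest, artifacts)
        if "quantify" in config:
            _stage_quantify(config["quantify"], outdir, manifest, artifacts)
        if "fit" in config:
            _stage_fit(config["fit"], outdir, manifest, artifacts)
        if "simulate" in config:
            _stage_simulate(config["simulate"], seed, outdir, manifest, artifacts)
    finally:
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage_synthetic(block, seed, outdir, manifest, artifacts) -> None:
    geo = dict(block.get("geometry", {}))
    geo.setdefault("seed", seed)
    if "shape" in geo:
        geo["shape"] = tuple(geo["shape"])
    if "peroxisome_radius" in geo:
        geo["peroxisome_radius"] = tuple(geo["peroxisome_radius"])
    spec = synthetic.GeometrySpec(**geo)
    noise = synthetic.NoiseModel(**block.get("noise", {}))
    truth = synthetic.generate_geometry(spec, noise)
    channels = block.get(
        "channels", {"marker": "peroxisome:marker", "substrate": "peroxisome:substrate"}
    )
    stacks = synthetic.render_stack(truth, noise, channels, seed=seed + 1)
    outputs = {}
    for name, stack in stacks.items():
        path = outdir / f"stack_{name}.tif"
        io.write_stack(
            io.ImageStack(np.asarray(stack.data, dtype=np.float32), channel=name), path
        )
        outputs[name] = str(path)
    for organelle in ("peroxisome", "mitochondrion"):
        lab = truth.labels_for(organelle)
        if lab.max(initial=0) > 0:
            path = outdir / f"truth_labels_{organelle}.tif"
            io.write_labels(lab, path)
            outputs[f"labels_{organelle}"] = str(path)
    table_path = outdir / "truth_objects.csv"
    io.write_table(truth.objects, table_path)
    outputs["objects"] = str(table_path)
    manifest["outputs"]["synthetic"] = outputs
    artifacts["truth"] = truth
    artifacts["stacks"] = stacks
    artifacts["noise"] = noise


def _stage_segment(block, outdir, manifest, artifacts) -> None:
    params = segmentation.SegmentationParams(**block.get("params", {}))
    if "stack" in block:
        stack = io.read_stack(block["stack"])
        manifest["inputs"]["segment"] = block["stack"]
    elif "stacks" in artifacts:
        name = block.get("channel", "marker")
        stack = artifacts["stacks"][name]
    else:
        raise ConfigError("segment.stack: no stack file given and no synthetic stage upstream")
    background = block.get("camera_background")
    if background is None and "noise" in artifacts:
        background = artifacts["noise"].background_mean
    other = None
    if "exclude_overlap" in block:
        other = segmentation.LabelMap(io.read_labels(block["exclude_overlap"]))
    labels = segmentation.segment_organelles(
        stack, params, camera_background=background or 0.0, other=other
    )
    path = outdir / f"labels_{params.mode}.tif"
    io.write_labels(labels.labels, path)
    manifest["outputs"]["segment"] = {"labels": str(path), "n_objects": labels.n_objects}
    artifacts["labels"] = labels


def _stage_quantify(block, outdir, manifest, artifacts) -> None:
    if "labels" in block:
        labels = segmentation.LabelMap(io.read_labels(block["labels"]))
    elif "labels" in artifacts:
        labels = artifacts["labels"]
    else:
        raise ConfigError("quantify.labels: no label map given and no segment stage upstream")
    if "stack" in block:
        stack = io.read_stack(block["stack"])
    elif "stacks" in artifacts:
        stack = artifacts["stacks"][block.get("channel", "substrate")]
    else:
        raise ConfigError("quantify.stack: no stack given and no synthetic stage upstream")
    meas = quantitation.measure_objects(labels, stack)
    background = block.get("background", 0.0)
    if "background_from" in block:
        background = quantitation.estimate_background(io.read_table(block["background_from"]))
    elif background == "noise_model" and "noise" in artifacts:
        background = artifacts["noise"].background_mean
    meas = quantitation.subtract_background(meas, float(background))
    path = outdir / "measurements.csv"
    io.write_table(meas, path)
    manifest["outputs"]["quantify"] = {"measurements": str(path), "n_objects": len(meas)}
    artifacts["measurements"] = meas


def _stage_fit(block, outdir, manifest, artifacts) -> None:
    if "summary" in block:
        df = io.read_table(block["summary"])
        tc = kinetics.NormalizedTimeCourse.from_raw(
            df["time_hr"].to_numpy(),
            df["mean_density"].to_numpy(),
            df["sem"].to_numpy() if "sem" in df.columns else None,
        )
    elif "timecourse" in artifacts:
        tc = artifacts["timecourse"]
    else:
        raise ConfigError("fit.summary: no summary CSV given and no time course upstream")
    one = kinetics.fit_one_state(tc)
    two = kinetics.fit_two_state(
        tc,
        fix_f0=block.get("fix_f0"),
        n_starts=block.get("n_starts", 10),
        seed=block.get("seed", 0),
    )
    area = kinetics.area_between_fits(one, two, (tc.time_hr[0], tc.time_hr[-1]))
    report = {
        "one_state": {
            "k_decay": one.params.k_decay,
            "stderr": one.stderr,
            "rss_log": one.rss_log,
            "half_life_min": kinetics.half_life_minutes(one.params.k_decay)
            if one.params.k_decay > 0
            else None,
        },
        "two_state": {
            "k_mat": two.params.k_mat,
            "k_decay1": two.params.k_decay1,
            "k_decay2": two.params.k_decay2,
            "f0": two.params.f0,
            "stderr": two.stderr,
            "rss_log": two.rss_log,
        },
        "area_between_fits_per_hr": area,
    }
    path = outdir / "fit_report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    manifest["outputs"]["fit"] = {"report": str(path)}
    artifacts["fit_report"] = report


def _stage_simulate(block, seed, outdir, manifest, artifacts) -> None:
    cfg_kwargs = dict(block)
    cfg_kwargs.setdefault("seed", seed)
    perturbed = cfg_kwargs.pop("perturbed", True)
    cfg = simulation.SimConfig(**cfg_kwargs)
    trajs = simulation.run_ensemble(cfg, perturbed=perturbed)
    mean_raw = simulation.ensemble_summarize(trajs, normalize=False)
    mean_norm = mean_raw.normalized()
    df = pd.DataFrame(
        {
            "minute": mean_raw.minutes,
            "mean_abundance": mean_raw.abundance,
            "mean_age_min": mean_raw.mean_age_min,
            "sfyfp": mean_raw.sfyfp,
            "mcherry": mean_raw.mcherry,
            "tft_ratio": mean_raw.tft_ratio,
            "norm_abundance": mean_norm.abundance,
            "norm_mean_age": mean_norm.mean_age_min,
            "norm_tft_ratio": mean_norm.tft_ratio,
        }
    )
    path = outdir / "simulation_ensemble.csv"
    io.write_table(df, path)
    rep_path = outdir / "simulation_replicates.csv"
    reps = pd.concat(
        [
            pd.DataFrame(
                {
                    "replicate": i,
                    "minute": tr.minutes,
                    "abundance": tr.abundance,
                    "mean_age_min": tr.mean_age_min,
                    "tft_ratio": tr.tft_ratio,
                }
            )
            for i, tr in enumerate(trajs)
        ],
        ignore_index=True,
    )
    io.write_table(reps, rep_path)
    manifest["outputs"]["simulate"] = {
        "ensemble": str(path),
        "replicates": str(rep_path),
        "config": dataclasses.asdict(cfg),
    }
    artifacts["ensemble"] = mean_raw
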