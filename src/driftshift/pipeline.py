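"""End-to-end orchestration: simulate -> filter -> centroids -> classify -> fit -> report.

A run is a pure function of (config, seed) up to MCMC Monte-Carlo noise —
and since the sampler itself is seeded, artifacts are byte-reproducible in
practice.  Every stage records its inputs and outputs with content hashes in
``manifest.json`` so a run's provenance can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .ece import build_design, classify_severe_february, make_year_labels
from .filtering import filter_checklists, nonzero_observations
from .geometry import compute_shifts
from .io import read_anomaly, read_ebd, read_flyways, write_ebd
from .model import ModelSpec, check_convergence, fit_shift_model, marginal_medians
from .simulate import DEFAULT_ECE_YEARS, CountModel, Eq1Effects, GpsConfig, SimConfig, write_bundle

STAGES = ("simulate", "filter", "centroids", "classify", "fit", "report")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sim_config_from_dict(cfg: dict) -> SimConfig:
    """Build a :class:`SimConfig` from the ``simulate`` section of a run config."""
    sim = dict(cfg.get("simulate", {}))
    kwargs: dict = {"seed": int(cfg.get("seed", 0))}
    for key in ("observers_per_cell", "dispersion_km", "presence_only_rate",
                "violation_rates", "records_per_cell"):
        if key in sim:
            kwargs[key] = sim[key]
    if "years" in sim:
        kwargs["years"] = tuple(int(y) for y in sim["years"])
    if "species" in sim:
        kwargs["species"] = tuple(sim["species"])
    if "count_model" in sim:
        kwargs["count_model"] = CountModel(**sim["count_model"])
    if "eq1_effects" in sim:
        kwargs["eq1_effects"] = Eq1Effects(**sim["eq1_effects"])
    if "gps" in sim:
        kwargs["gps"] = GpsConfig(**sim["gps"])
    return SimConfig(**kwargs)


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Run all six stages from a config mapping; return the manifest.

    Config keys: ``seed``, ``outdir``, ``analysis`` ("ece2021" or
    "severe_feb"), ``scope`` ("continental" or "flyway"), optional
    ``lat_band`` [lo, hi], a ``simulate`` section (generator settings), and a
    ``model`` section (chains/iterations/warmup).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir or cfg.get("outdir", "driftshift_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    analysis = cfg.get("analysis", "ece2021")
    scope = cfg.get("scope", "continental")
    lat_band = tuple(cfg["lat_band"]) if cfg.get("lat_band") else None
    manifest = {"version": __version__, "seed": seed, "config": cfg, "stages": []}

    def record(stage, inputs, outputs):
        manifest["stages"].append({
            "stage": stage,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
        })

    # -- simulate ----------------------------------------------------------
    try:
        simcfg = sim_config_from_dict(cfg)
        paths = write_bundle(simcfg, outdir)
    except Exception as e:  # noqa: BLE001 - every stage converts to PipelineError
        raise PipelineError("simulate", e) from e
    record("simulate", [], paths.values())

    # -- filter ------------------------------------------------------------
    try:
        obs = read_ebd(paths["ebd"])
        filtered, report = filter_checklists(obs)
        filtered_path = outdir / "filtered.tsv"
        write_ebd(filtered, filtered_path)
        report_path = outdir / "filter_report.json"
        report.to_json(report_path)
    except Exception as e:
        raise PipelineError("filter", e) from e
    record("filter", [paths["ebd"]], [filtered_path, report_path])

    # -- centroids ---------------------------------------------------------
    try:
        flyways_path = Path(cfg.get("flyways") or paths["flyways"])
        if not flyways_path.exists():
            raise FileNotFoundError(f"flyway file not found: {flyways_path}")
        flyways = read_flyways(flyways_path)
        pos = nonzero_observations(filtered)
        shifts = compute_shifts(pos, flyways, scope="continental", lat_band=lat_band)
        if scope == "flyway":
            shifts = pd.concat(
                [shifts, compute_shifts(pos, flyways, scope="flyway", lat_band=lat_band)],
                ignore_index=True)
        shifts_path = outdir / "shifts.csv"
        shifts.to_csv(shifts_path, index=False)
    except Exception as e:
        raise PipelineError("centroids", e) from e
    record("centroids", [filtered_path, flyways_path], [shifts_path])

    # -- classify ----------------------------------------------------------
    try:
        severe = {}
        grid_paths = []
        for year in simcfg.years:
            p = paths[f"anomaly_{year}"]
            grid_paths.append(p)
            severe[int(year)] = classify_severe_february(read_anomaly(p))
        labels = make_year_labels(severe)
        labels_path = outdir / "labels.json"
        with open(labels_path, "w") as fh:
            json.dump({str(y): dataclasses.asdict(l) for y, l in sorted(labels.items())}, fh, indent=2)
    except Exception as e:
        raise PipelineError("classify", e) from e
    record("classify", grid_paths, [labels_path])

    # -- fit ---------------------------------------------------------------
    try:
        design = build_design(shifts, labels, analysis)
        model_cfg = dict(cfg.get("model", {}))
        spec = ModelSpec(seed=seed, **{k: model_cfg[k] for k in
                                       ("chains", "iterations", "warmup", "thin", "prior_scale")
                                       if k in model_cfg})
        draws = fit_shift_model(design, spec)
        conv = check_convergence(draws)
        posterior_path = outdir / "posterior.json"
        with open(posterior_path, "w") as fh:
            json.dump({"draws": draws.to_dict(), "rhat": conv.rhat,
                       "max_rhat": conv.max_rhat, "converged": conv.passed,
                       "seed": seed, "analysis": analysis}, fh)
    except Exception as e:
        raise PipelineError("fit", e) from e
    record("fit", [shifts_path, labels_path], [posterior_path])

    # -- report ------------------------------------------------------------
    try:
        cells = marginal_medians(draws)
        cells_path = outdir / "cells.csv"
        cells.to_csv(cells_path, index=False)
    except Exception as e:
        raise PipelineError("report", e) from e
    record("report", [posterior_path], [cells_path])

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
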