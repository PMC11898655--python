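"""End-to-end pipeline: simulate -> profiles -> landmarks -> asymmetry
(-> phasor) -> group statistics, with a deterministic run manifest.

The config is a plain mapping (YAML/JSON file or dict).  Required keys:

.. code-block:: yaml

    seed: 7
    pixel_size_um: 0.105
    simulate:
      groups:
        control: {preset: control, n: 40}
        knockout: {preset: delta_fhaA, n: 40}
    profiles: {width_px: 10, resample_points: 101}   # optional
    landmarks: {calibrate_on: control}                # optional
    compare: {metrics: [length_um, septum_rel_pos], alpha: 0.05}  # optional
    phasor: {groups: {control: control_like, mutant: shifted}, n_cells: 3}  # optional

The manifest records the resolved config, seed, per-stage cell accounting
(cells in = analyzed + excluded, one reason per exclusion) and a SHA-256
checksum of every output file; it contains no timestamps, so identical
config + seed reproduces identical manifests.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import asymmetry as asy
from . import io_utils as io
from . import landmarks as lmk
from . import phasor as phs
from . import popstats
from . import synthgen
from . import workflow
from .errors import ConfigurationError, PipelineError

__all__ = ["load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_COMPARE_METRICS = [
    "length_um", "foci_count", "septum_rel_pos", "pole_septum_ratio",
    "slope_new", "slope_old", "mean_interfoci_distance",
]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return validate_config(path_or_dict)
    text = Path(path_or_dict).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must contain a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Check the schema, naming the offending field in every error."""
    for key in ("seed", "pixel_size_um", "simulate"):
        if key not in cfg:
            raise ConfigurationError(f"config missing required field {key!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigurationError("field 'seed' must be an integer")
    if not (isinstance(cfg["pixel_size_um"], (int, float))
            and cfg["pixel_size_um"] > 0):
        raise ConfigurationError("field 'pixel_size_um' must be a positive number")
    sim = cfg["simulate"]
    if not isinstance(sim, dict) or not sim.get("groups"):
        raise ConfigurationError("field 'simulate.groups' must be a non-empty mapping")
    for gname, gcfg in sim["groups"].items():
        if "preset" not in gcfg:
            raise ConfigurationError(f"field 'simulate.groups.{gname}.preset' missing")
        if "n" not in gcfg or int(gcfg["n"]) < 1:
            raise ConfigurationError(
                f"field 'simulate.groups.{gname}.n' must be a positive integer")
    return cfg


def _stage(name):
    logger.info("stage: %s", name)
    return name


def run_pipeline(config, out_dir=None) -> Path:
    """Run the full synthetic analysis pipeline; returns the output directory."""
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out", "poleprof_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    px = float(cfg["pixel_size_um"])
    prof_cfg = cfg.get("profiles", {})
    width_px = int(prof_cfg.get("width_px", 10))
    resample = int(prof_cfg.get("resample_points", 101))
    lm_cfg = cfg.get("landmarks", {})
    min_sep = float(lm_cfg.get("min_separation", lmk.DEFAULT_MIN_SEPARATION))

    manifest = {"config": cfg, "package_version": __version__, "seed": seed,
                "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    stage = _stage("simulate")
    try:
        groups: dict[str, tuple[list, synthgen.GroundTruth]] = {}
        for g_idx, (gname, gcfg) in enumerate(sorted(cfg["simulate"]["groups"].items())):
            scenes, gt = synthgen.generate_population(
                gcfg["preset"], int(gcfg["n"]), pixel_size_um=px,
                seed=seed + 1000 * g_idx, overrides=gcfg.get("overrides"),
            )
            groups[gname] = (scenes, gt)
            gdir = out / "scenes" / gname
            for i, scene in enumerate(scenes):
                outputs += io.write_scene(scene, gdir, f"scene_{i:04d}")
            io.write_ground_truth(gt, out / f"ground_truth_{gname}.csv",
                                  out / f"params_{gname}.json")
            outputs += [out / f"ground_truth_{gname}.csv", out / f"params_{gname}.json"]
            manifest["stages"].setdefault("simulate", {})[gname] = {
                "n_cells": int(gcfg["n"]), "n_scenes": len(scenes)}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("profiles")
    try:
        pops: dict[str, workflow.PopulationProfiles] = {}
        ch2_pops: dict[str, workflow.PopulationProfiles] = {}
        for gname, (scenes, gt) in groups.items():
            pop = workflow.extract_population_profiles(
                scenes, "hada", ground_truth=gt, width_px=width_px,
                resample_points=resample)
            pops[gname] = pop
            io.write_profiles_csv(list(pop.profiles.values()),
                                  out / f"profiles_{gname}.csv")
            outputs.append(out / f"profiles_{gname}.csv")
            if all("mscarlet" in s.channels for s in scenes):
                ch2_pops[gname] = workflow.extract_population_profiles(
                    scenes, "mscarlet", ground_truth=gt, width_px=width_px,
                    resample_points=resample)
            manifest["stages"].setdefault("profiles", {})[gname] = {
                "cells_in": pop.n_in,
                "cells_analyzed": len(pop.profiles),
                "cells_excluded": len(pop.excluded),
                "exclusion_reasons": dict(sorted(pop.excluded.items())),
            }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("landmarks")
    try:
        if "prominence" in lm_cfg:  # fixed threshold supplied by the user
            prominence = float(lm_cfg["prominence"])
            cal_info = {"prominence": prominence, "calibrated_on": None}
        else:
            cal_group = lm_cfg.get("calibrate_on") or sorted(pops)[0]
            if cal_group not in pops:
                raise ConfigurationError(
                    f"landmarks.calibrate_on: unknown group {cal_group!r}")
            cal_pop = pops[cal_group]
            _, cal_gt = groups[cal_group]
            flags = [cal_gt[cid].septate for cid in cal_pop.profiles]
            prominence, diag = lmk.calibrate_prominence(
                list(cal_pop.profiles.values()), flags, min_separation=min_sep)
            cal_info = {"prominence": prominence, "calibrated_on": cal_group,
                        "diagnostics": diag}
        io.write_json(out / "calibration.json", cal_info)
        outputs.append(out / "calibration.json")
        manifest["stages"]["landmarks"] = {
            "prominence": prominence,
            "calibrated_on": cal_info.get("calibrated_on")}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("asymmetry")
    try:
        tables = {}
        for gname, pop in pops.items():
            _, gt = groups[gname]
            septate_by_cell = {rec.spec.cell_id: rec.septate for rec in gt.records}
            lms, foci, df, excl = workflow.analyze_population(
                pop, prominence, min_separation=min_sep,
                septate_by_cell=septate_by_cell, ch2=ch2_pops.get(gname))
            tables[gname] = df
            df.to_csv(out / f"metrics_{gname}.csv", index=False)
            outputs.append(out / f"metrics_{gname}.csv")
            eligible = [(pop.profiles[cid], lms[cid]) for cid in lms
                        if lms[cid].new_pole in ("pole1", "pole2")
                        and cid in pop.profiles]
            if eligible:
                aligned = asy.aligned_mean_profile([p for p, _ in eligible],
                                                   [l for _, l in eligible])
                io.write_mean_profile_csv(aligned.profile,
                                          out / f"aligned_profile_{gname}.csv")
                outputs.append(out / f"aligned_profile_{gname}.csv")
            manifest["stages"].setdefault("asymmetry", {})[gname] = {
                "cells_in": len(pop.profiles),
                "cells_analyzed": len(df),
                "cells_excluded": len(excl),
                "exclusion_reasons": dict(sorted(excl.items())),
            }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    if cfg.get("phasor"):
        stage = _stage("phasor")
        try:
            ph_cfg = cfg["phasor"]
            rows = []
            for g_idx, (gname, preset) in enumerate(sorted(ph_cfg["groups"].items())):
                scene, sgt = synthgen.generate_spectral_population(
                    preset, int(ph_cfg.get("n_cells", 3)), seed=seed + 77 * (g_idx + 1))
                outputs += io.write_spectral_scene(scene, out / "spectral", gname)
                f = phs.spectral_phasor(scene)
                summ = phs.phasor_summary(f)[0]
                summ["group"] = gname
                rows.append(summ)
            pd.DataFrame(rows).to_csv(out / "phasor_summary.csv", index=False)
            outputs.append(out / "phasor_summary.csv")
            manifest["stages"]["phasor"] = {"groups": sorted(ph_cfg["groups"])}
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    stage = _stage("stats")
    try:
        table = workflow.metrics_table(tables)
        table.to_csv(out / "metrics_all.csv", index=False)
        outputs.append(out / "metrics_all.csv")
        summary = popstats.population_summary(table)
        summary.to_csv(out / "summary.csv", index=False)
        outputs.append(out / "summary.csv")
        cmp_cfg = cfg.get("compare", {})
        alpha = float(cmp_cfg.get("alpha", 0.05))
        metrics = cmp_cfg.get("metrics", DEFAULT_COMPARE_METRICS)
        comp_rows = []
        if len(tables) >= 2:
            for metric in metrics:
                by_group = {g: df[metric].dropna().to_numpy()
                            for g, df in tables.items()
                            if metric in df.columns and df[metric].notna().sum() >= 3}
                if len(by_group) < 2:
                    continue
                res = popstats.compare_groups(by_group, alpha=alpha, metric=metric)
                comp_rows.append({
                    "metric": metric, "test": res.test_used,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "significant": res.significant,
                    **{f"n_{g}": n for g, n in res.n_per_group.items()},
                })
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
        outputs.append(out / "comparisons.csv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    for path in outputs:
        manifest["outputs"][str(Path(path).relative_to(out))] = io.sha256_of(path)
    io.write_json(out / "manifest.json", manifest)
    return out
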