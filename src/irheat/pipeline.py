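"""Stage orchestration: simulate -> calibrate -> map -> fit -> plan.

Each stage reads artifacts written by upstream stages into the configured
output directory, so stages can be re-run individually.  A run manifest
records package and library versions, the full parameter set and SHA-256
digests of every artifact; identical config and seed reproduce identical
digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .heat_model import ThermalProfile, fit_power_slope, fit_spatial_profile
from .io import (
    disk_mask,
    load_calibration,
    load_image_stack,
    load_profile,
    rect_mask,
    save_calibration,
    save_image_stack,
    save_profile,
    save_plan,
    save_temperature_map,
    save_yaml,
)
from .planner import plan_induction
from .synthetic import SceneSpec, gen_calibration_series, gen_cell_measurements, gen_onoff_pair, sheet_scene
from .thermometry import bin_by_distance, fit_sensitivity, quantify_cell_fluorescence, temperature_map

__all__ = ["run_pipeline", "DependencyError", "STAGES"]

STAGES = ("simulate", "calibrate", "map", "fit", "plan")

_DEPENDENCIES = {
    "simulate": (),
    "calibrate": ("simulate",),
    "map": ("simulate", "calibrate"),
    "fit": ("simulate",),
    "plan": ("fit",),
}

_STAGE_ARTIFACTS = {
    "simulate": ("calibration_series.tif", "pair_on.tif", "pair_off.tif", "measurements.csv"),
    "calibrate": ("calibration.yaml",),
    "map": ("temperature_map.tif",),
    "fit": ("profile.yaml",),
    "plan": ("plan.yaml",),
}


class DependencyError(RuntimeError):
    """A requested stage is missing a required upstream stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _profile_from_config(config: PipelineConfig) -> ThermalProfile:
    hm = config.heat_model
    return ThermalProfile(hm.slope_c_per_mw, hm.half_distance_um, hm.ambient_c, hm.tau_ms)


def _calibration_scene(config: PipelineConfig, seed: int) -> SceneSpec:
    sc = config.generator.scene
    cx = sc.image_shape[1] * sc.pixel_size_um / 2.0
    cy = sc.image_shape[0] * sc.pixel_size_um / 2.0
    return SceneSpec(
        image_shape=tuple(sc.image_shape),
        pixel_size_um=sc.pixel_size_um,
        cell_centers_um=((cx, cy),),
        cell_radius_um=min(sc.cell_radius_um, 3.0),
        base_fluorescence=sc.base_fluorescence,
        background_level=sc.background_level,
        read_noise_sd=sc.read_noise_sd,
        shot_noise=sc.shot_noise,
        seed=seed,
    )


def _stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    gen = config.generator
    profile = _profile_from_config(config)
    px = gen.scene.pixel_size_um

    cal_scene = _calibration_scene(config, seed=config.seed)
    cal_stack, cal_truth = gen_calibration_series(
        cal_scene, gen.sensitivity_per_c, gen.calibration_temps_c, config.calibration.ref_temp_c
    )
    save_image_stack(outdir / "calibration_series.tif", cal_stack, px)

    sheet = sheet_scene(
        image_shape=tuple(gen.scene.image_shape),
        pixel_size_um=px,
        cell_radius_um=gen.scene.cell_radius_um,
        base_fluorescence=gen.scene.base_fluorescence,
        background_level=gen.scene.background_level,
        read_noise_sd=gen.scene.read_noise_sd,
        shot_noise=gen.scene.shot_noise,
        seed=config.seed + 1,
    )
    w = gen.scene.image_shape[1] * px
    h = gen.scene.image_shape[0] * px
    focus = (w / 2.0, h / 2.0)
    on, off, _ = gen_onoff_pair(sheet, profile, focus, gen.map_power_mw, gen.sensitivity_per_c)
    save_image_stack(outdir / "pair_on.tif", on, px)
    save_image_stack(outdir / "pair_off.tif", off, px)

    rng = np.random.default_rng(config.seed + 2)
    distances = rng.uniform(0.0, gen.max_distance_um, size=gen.n_cells_per_power)
    table, _ = gen_cell_measurements(
        profile,
        gen.measurement_powers_mw,
        distances,
        gen.measurement_noise_sd_c,
        seed=config.seed + 3,
    )
    table.to_csv(outdir / "measurements.csv", index=False)

    save_yaml(
        {
            "generator": config.generator.model_dump(mode="json"),
            "heat_model": config.heat_model.model_dump(mode="json"),
            "seed": config.seed,
            "focus_um": list(focus),
        },
        outdir / "generator_params.yaml",
    )
    return {"n_calibration_images": cal_stack.shape[0], "focus_um": focus}


def _stage_calibrate(config: PipelineConfig, outdir: Path) -> dict:
    stack, _ = load_image_stack(
        outdir / "calibration_series.tif", config.generator.scene.pixel_size_um
    )
    shape = stack.shape[-2:]
    sc = config.generator.scene
    radius_px = min(sc.cell_radius_um, 3.0) / sc.pixel_size_um
    cell = disk_mask(shape, (shape[0] / 2.0 - 0.5, shape[1] / 2.0 - 0.5), radius_px + 4)
    bg = rect_mask(shape, 2, 2, max(shape[0] // 8, 4), max(shape[1] // 8, 4))
    totals = [quantify_cell_fluorescence(img, cell, bg) for img in stack]
    calib = fit_sensitivity(
        config.generator.calibration_temps_c,
        totals,
        config.calibration.ref_temp_c,
        config.calibration.valid_range_c,
    )
    save_calibration(calib, outdir / "calibration.yaml")
    return {"sensitivity_per_c": calib.sensitivity_per_c, "r_squared": calib.fit_r_squared}


def _stage_map(config: PipelineConfig, outdir: Path) -> dict:
    px = config.generator.scene.pixel_size_um
    on, _ = load_image_stack(outdir / "pair_on.tif", px)
    off, _ = load_image_stack(outdir / "pair_off.tif", px)
    calib = load_calibration(outdir / "calibration.yaml")
    bg = rect_mask(on.shape, 2, 2, max(on.shape[0] // 16, 4), max(on.shape[1] // 16, 4))
    tmap = temperature_map(
        on,
        off,
        calib,
        base_temp_c=config.heat_model.ambient_c,
        downsample_factor=config.calibration.downsample_factor,
        pixel_size_um=px,
        background_mask=bg,
    )
    save_temperature_map(tmap, outdir / "temperature_map.tif", outdir / "temperature_map.csv")
    return {"max_delta_t_c": float(np.nanmax(tmap.delta_t_c[tmap.valid]))}


def _stage_fit(config: PipelineConfig, outdir: Path) -> dict:
    table = pd.read_csv(outdir / "measurements.csv")
    binned = bin_by_distance(table, bin_width_um=2.0)
    spatial = fit_spatial_profile(binned)
    powers = sorted(spatial.amplitudes_c)
    slope_fit = fit_power_slope(
        powers,
        [config.heat_model.ambient_c + spatial.amplitudes_c[p] for p in powers],
        ambient_c=config.heat_model.ambient_c,
    )
    profile = ThermalProfile(
        slope_c_per_mw=slope_fit.slope_c_per_mw,
        half_distance_um=spatial.half_distance_um,
        ambient_c=config.heat_model.ambient_c,
        tau_ms=config.heat_model.tau_ms,
        fit_diagnostics={
            "slope_stderr": slope_fit.stderr,
            "half_distance_stderr_um": spatial.stderr_half_distance_um,
            "collapse_residual": spatial.collapse_residual,
        },
    )
    save_profile(profile, outdir / "profile.yaml")
    return {
        "slope_c_per_mw": profile.slope_c_per_mw,
        "half_distance_um": profile.half_distance_um,
    }


def _stage_plan(config: PipelineConfig, outdir: Path) -> dict:
    profile = load_profile(outdir / "profile.yaml")
    plan = plan_induction(
        profile,
        threshold_band_c=config.planner.threshold_band_c,
        neighbor_distance_um=config.planner.neighbor_distance_um,
        ambient_c=config.heat_model.ambient_c,
    )
    save_plan(plan, outdir / "plan.yaml")
    return {
        "power_mw": plan.power_mw,
        "feasible": plan.feasible,
        "predicted_focal_c": plan.predicted_focal_c,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "map": _stage_map,
    "fit": _stage_fit,
    "plan": _stage_plan,
}


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order and write a run manifest.

    Raises :class:`DependencyError` when a stage's upstream artifacts are
    neither scheduled earlier in ``stages`` nor already present on disk.
    """
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    scheduled = []
    for stage in STAGES:
        if stage not in stages:
            continue
        for dep in _DEPENDENCIES[stage]:
            artifacts_exist = all((outdir / f).exists() for f in _STAGE_ARTIFACTS[dep])
            if dep not in scheduled and not artifacts_exist:
                raise DependencyError(
                    f"stage '{stage}' requires upstream stage '{dep}' "
                    "(schedule it first or provide its artifacts)"
                )
        scheduled.append(stage)

    results = {}
    for stage in scheduled:
        results[stage] = _STAGE_FUNCS[stage](config, outdir)

    digests = {
        f: _sha256(outdir / f)
        for stage in scheduled
        for f in _STAGE_ARTIFACTS[stage]
        if (outdir / f).exists()
    }
    manifest = {
        "irheat_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stages": list(scheduled),
        "parameters": config.model_dump(mode="json"),
        "results": results,
        "artifact_sha256": dict(sorted(digests.items())),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"results": results, "manifest": manifest}
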