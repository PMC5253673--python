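"""File formats: TIFF stacks with pixel-size metadata, CSV tables, YAML records.

Images travel as (multi-page) TIFF with an ImageJ-style micrometre pixel
size; tables as CSV with a header row; profiles, plans, calibrations and
generator sidecars as YAML with units embedded in the field names
(``slope_c_per_mw``, ``ambient_c``, ...) to prevent unit drift.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .heat_model import PulseSchedule, ThermalProfile
from .morphometrics import NeuriteTrack, TrackPoint
from .planner import InductionPlan
from .thermometry import CalibrationCurve, TemperatureMap

__all__ = [
    "load_image_stack",
    "save_image_stack",
    "save_temperature_map",
    "save_yaml",
    "load_yaml",
    "save_profile",
    "load_profile",
    "save_calibration",
    "load_calibration",
    "save_plan",
    "load_plan",
    "read_tracks",
    "write_tracks",
    "disk_mask",
    "rect_mask",
    "load_roi_masks",
]


def save_image_stack(path, data, pixel_size_um: float) -> None:
    """Write a 2-D image or 3-D stack as float32 TIFF with pixel-size metadata."""
    arr = np.asarray(data, dtype=np.float32)
    tifffile.imwrite(
        path,
        arr,
        imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={"unit": "um"},
    )


def load_image_stack(path, default_pixel_size_um: float | None = None):
    """Read a single- or multi-page TIFF, returning (array, pixel_size_um).

    When the file carries no resolution metadata, ``default_pixel_size_um``
    is used with a warning; with no default either, the error is raised.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            page = tif.pages[0]
            pixel_size = None
            # a resolution is meaningful only with a unit: ImageJ metadata
            # carries it as 'unit'; plain TIFFs use the ResolutionUnit tag
            has_unit = bool(tif.imagej_metadata and tif.imagej_metadata.get("unit"))
            res_unit = page.tags.get("ResolutionUnit")
            has_unit = has_unit or (res_unit is not None and int(res_unit.value) > 1)
            if has_unit and "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                if num:
                    pixel_size = den / num
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if pixel_size is None:
        if default_pixel_size_um is None:
            raise ValueError(f"{path} has no pixel-size metadata and no default was given")
        warnings.warn(
            f"{path} has no pixel-size metadata; using default {default_pixel_size_um} um/px"
        )
        pixel_size = default_pixel_size_um
    return np.asarray(arr, dtype=float), float(pixel_size)


def save_temperature_map(tmap: TemperatureMap, tiff_path, csv_path=None) -> None:
    """Write the elevation grid as float TIFF plus an optional CSV summary."""
    save_image_stack(tiff_path, np.nan_to_num(tmap.delta_t_c, nan=np.nan), tmap.pixel_size_um)
    if csv_path is not None:
        valid = tmap.delta_t_c[tmap.valid]
        pd.DataFrame(
            [
                {
                    "max_delta_t_c": float(np.nanmax(valid)) if valid.size else float("nan"),
                    "mean_delta_t_c": float(np.nanmean(valid)) if valid.size else float("nan"),
                    "n_valid": int(tmap.valid.sum()),
                    "pixel_size_um": tmap.pixel_size_um,
                    "downsample_factor": tmap.downsample_factor,
                    "base_temp_c": tmap.base_temp_c,
                }
            ]
        ).to_csv(csv_path, index=False)


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_profile(profile: ThermalProfile, path) -> None:
    save_yaml({"thermal_profile": asdict(profile)}, path)


def load_profile(path) -> ThermalProfile:
    data = load_yaml(path)["thermal_profile"]
    return ThermalProfile(**data)


def save_calibration(calib: CalibrationCurve, path) -> None:
    d = asdict(calib)
    d["valid_range_c"] = list(d["valid_range_c"])
    save_yaml({"calibration": d}, path)


def load_calibration(path) -> CalibrationCurve:
    d = load_yaml(path)["calibration"]
    d["valid_range_c"] = tuple(d["valid_range_c"])
    return CalibrationCurve(**d)


def save_plan(plan: InductionPlan, path) -> None:
    d = asdict(plan)
    d["threshold_band_c"] = list(d["threshold_band_c"])
    if d.get("power_range_mw") is not None:
        d["power_range_mw"] = [
            x if np.isfinite(x) else None for x in d["power_range_mw"]
        ]
    save_yaml({"plan": d}, path)


def load_plan(path) -> InductionPlan:
    d = load_yaml(path)["plan"]
    d["threshold_band_c"] = tuple(d["threshold_band_c"])
    if d.get("power_range_mw") is not None:
        d["power_range_mw"] = tuple(
            float("inf") if x is None else x for x in d["power_range_mw"]
        )
    if d.get("schedule") is not None:
        d["schedule"] = PulseSchedule(**d["schedule"])
    return InductionPlan(**d)


TRACK_COLUMNS = ["embryo_id", "time", "point_index", "x", "y", "z", "label", "stage"]


def write_tracks(tracks: dict, path) -> None:
    """Write ``{embryo_id: NeuriteTrack}`` as a long-format CSV."""
    rows = []
    for embryo_id, track in tracks.items():
        for tp in track.timepoints:
            for i, (x, y, z) in enumerate(tp.points):
                rows.append(
                    {
                        "embryo_id": embryo_id,
                        "time": tp.time,
                        "point_index": i,
                        "x": x,
                        "y": y,
                        "z": z,
                        "label": "neurite",
                        "stage": tp.stage if tp.stage is not None else "",
                    }
                )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> dict:
    """Read a long-format track CSV back into ``{embryo_id: NeuriteTrack}``."""
    df = pd.read_csv(path)
    tracks = {}
    for embryo_id, edf in df.groupby("embryo_id", sort=False):
        timepoints = []
        for time, tdf in edf.groupby("time", sort=True):
            tdf = tdf.sort_values("point_index")
            stage = tdf["stage"].iloc[0]
            stage = None if pd.isna(stage) else float(stage)
            timepoints.append(
                TrackPoint(
                    time=float(time),
                    points=tdf[["x", "y", "z"]].to_numpy(dtype=float),
                    stage=stage,
                )
            )
        tracks[str(embryo_id)] = NeuriteTrack(timepoints=timepoints)
    return tracks


def disk_mask(shape, center_px, radius_px) -> np.ndarray:
    """Boolean disc ROI; ``center_px`` is (row, col) at pixel centres."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center_px
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2


def rect_mask(shape, top, left, height, width) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[top : top + height, left : left + width] = True
    return mask


def load_roi_masks(path, shape) -> dict:
    """Build named boolean masks from a CSV ROI specification.

    Columns: ``name,type,p1,p2,p3,p4`` where type ``disk`` uses
    (row, col, radius) and type ``rect`` uses (top, left, height, width),
    all in pixels.
    """
    df = pd.read_csv(path)
    masks = {}
    for _, row in df.iterrows():
        kind = str(row["type"]).strip().lower()
        if kind == "disk":
            masks[row["name"]] = disk_mask(shape, (row["p1"], row["p2"]), row["p3"])
        elif kind == "rect":
            masks[row["name"]] = rect_mask(
                shape, int(row["p1"]), int(row["p2"]), int(row["p3"]), int(row["p4"])
            )
        else:
            raise ValueError(f"unknown ROI type {row['type']!r}")
    return masks
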