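"""Ratiometric fluorescence thermometry with a temperature-dependent reporter.

A red fluorescent reporter whose signal decreases linearly with temperature
acts as an in-vivo thermometer:

    F(T) = F_ref * (1 - s * (T - T_ref))

where ``s`` is the fractional decrease per °C and ``T_ref`` the temperature
at which the calibration is normalized.  Dividing an image acquired with the
heating laser ON by one acquired with it OFF (both background-subtracted)
gives a per-pixel ratio R that is inverted to a temperature elevation.

Anchored at the ambient (laser-off) temperature ``T_b`` the exact inversion is

    dT = (1 - R) * (1 - s * (T_b - T_ref)) / s

which reduces to the common approximation ``dT = (1 - R) / s`` when the
ambient equals the normalization anchor.  Both forms are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CALIBRATION_RANGE_C, REF_TEMP_C

__all__ = [
    "CalibrationCurve",
    "TemperatureMap",
    "CellTempMeasurement",
    "fit_sensitivity",
    "quantify_cell_fluorescence",
    "invert_ratio",
    "temperature_map",
    "cell_delta_t",
    "bin_by_distance",
    "block_downsample",
    "estimate_background",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted fluorescence-temperature sensitivity of a reporter."""

    sensitivity_per_c: float  # fractional fluorescence decrease per °C
    ref_temp_c: float
    valid_range_c: tuple
    fit_r_squared: float
    n_points: int

    def __post_init__(self):
        lo, hi = self.valid_range_c
        if not lo < hi:
            raise ValueError("valid_range_c lower bound must be below upper")
        if not 0.0 <= self.fit_r_squared <= 1.0:
            raise ValueError("fit_r_squared must lie in [0, 1]")

    def fluorescence_factor(self, temp_c):
        """Relative fluorescence at ``temp_c`` (1 at the reference temperature)."""
        return 1.0 - self.sensitivity_per_c * (np.asarray(temp_c, dtype=float) - self.ref_temp_c)


@dataclass
class TemperatureMap:
    """Gridded temperature elevation derived from a laser ON/OFF image pair.

    ``delta_t_c`` is NaN wherever the OFF signal fell below the validity
    floor; ``valid`` is the complementary boolean mask.
    """

    delta_t_c: np.ndarray
    valid: np.ndarray
    pixel_size_um: float  # post-downsampling
    downsample_factor: int
    base_temp_c: float
    focus_px: tuple | None = None


@dataclass
class CellTempMeasurement:
    """Per-cell ON/OFF fluorescence pair and its derived elevation."""

    cell_id: str
    position_um: tuple
    distance_to_focus_um: float
    f_on: float
    f_off: float
    delta_t_c: float = field(default=float("nan"))

    def __post_init__(self):
        if self.f_off <= 0:
            raise ValueError("f_off must be > 0")
        if self.distance_to_focus_um < 0:
            raise ValueError("distance_to_focus_um must be >= 0")


def fit_sensitivity(
    temps_c,
    fluorescence,
    ref_temp_c: float = REF_TEMP_C,
    valid_range_c: tuple = CALIBRATION_RANGE_C,
) -> CalibrationCurve:
    """Fit the reporter's fractional fluorescence decrease per °C.

    Fluorescence values are normalized to the value measured at (or linearly
    interpolated at) ``ref_temp_c``, then an ordinary least-squares line is
    fitted; the sensitivity is the negated slope of normalized fluorescence
    per °C.  Invariant to uniform rescaling of all fluorescence values.
    """
    t = np.asarray(temps_c, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("temperatures and fluorescence must be 1-D, equal length")
    if np.any(f <= 0):
        raise ValueError("fluorescence values must be positive")
    lo, hi = valid_range_c
    if np.any((t < lo) | (t > hi)):
        raise ValueError(f"temperatures outside calibration validity window {valid_range_c}")
    n_distinct = np.unique(t).size
    if n_distinct < 2:
        raise ValueError("all temperatures identical: degenerate fit")
    if n_distinct < 3:
        warnings.warn("fewer than 3 distinct temperatures; slope is a two-point estimate")
    if not t.min() <= ref_temp_c <= t.max():
        raise ValueError("ref_temp_c outside the measured temperature range")

    # mean fluorescence per distinct temperature, interpolated at the anchor
    order = np.argsort(t)
    ts, fs = t[order], f[order]
    uniq, inv = np.unique(ts, return_inverse=True)
    means = np.bincount(inv, weights=fs) / np.bincount(inv)
    f_ref = float(np.interp(ref_temp_c, uniq, means))
    norm = f / f_ref

    slope, intercept = np.polyfit(t, norm, 1)
    resid = norm - (slope * t + intercept)
    ss_tot = float(((norm - norm.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        sensitivity_per_c=float(-slope),
        ref_temp_c=ref_temp_c,
        valid_range_c=(float(t.min()), float(t.max())),
        fit_r_squared=max(0.0, min(1.0, r2)),
        n_points=t.size,
    )


def quantify_cell_fluorescence(image, cell_mask, background_mask) -> float:
    """Background-subtracted total fluorescence of a cell ROI.

    Returns ``sum(cell pixels) - mean(background pixels) * n_cell_pixels``.
    A warning is issued when the result is not positive (signal at or below
    background).
    """
    img = np.asarray(image, dtype=float)
    cell = np.asarray(cell_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if not cell.any():
        raise ValueError("cell ROI is empty")
    if not bg.any():
        raise ValueError("background ROI is empty")
    if (cell & bg).any():
        raise ValueError("cell and background ROIs overlap")
    total = float(img[cell].sum() - img[bg].mean() * cell.sum())
    if total <= 0:
        warnings.warn("cell fluorescence at or below background level")
    return total


def invert_ratio(
    ratio,
    calibration: CalibrationCurve,
    base_temp_c: float,
    naive: bool = False,
):
    """Convert an ON/OFF fluorescence ratio to a temperature elevation (°C).

    The exact inversion of the linear fluorescence law anchored at
    ``base_temp_c``; with ``naive=True`` the approximation ``(1-R)/s`` is
    used instead (identical when ``base_temp_c == ref_temp_c``).
    """
    r = np.asarray(ratio, dtype=float)
    s = calibration.sensitivity_per_c
    if naive:
        out = (1.0 - r) / s
    else:
        anchor = 1.0 - s * (base_temp_c - calibration.ref_temp_c)
        out = (1.0 - r) * anchor / s
    return float(out) if out.ndim == 0 else out


def block_downsample(image, factor: int):
    """Non-overlapping block mean over factor x factor pixels.

    Remainder rows/columns that do not fill a block are dropped.
    """
    img = np.asarray(image, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return img.copy()
    h, w = (img.shape[0] // factor) * factor, (img.shape[1] // factor) * factor
    return img[:h, :w].reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def estimate_background(image, background_mask=None) -> tuple:
    """Background level and spread of an image.

    With a background ROI, the ROI mean and standard deviation.  Without
    one, the mode of a 256-bin intensity histogram and a robust spread
    (1.4826 x median absolute deviation about the mode).
    """
    img = np.asarray(image, dtype=float)
    if background_mask is not None:
        px = img[np.asarray(background_mask, dtype=bool)]
        if px.size == 0:
            raise ValueError("background ROI is empty")
        return float(px.mean()), float(px.std(ddof=1)) if px.size > 1 else 0.0
    counts, edges = np.histogram(img.ravel(), bins=256)
    i = int(np.argmax(counts))
    mode = 0.5 * (edges[i] + edges[i + 1])
    mad = float(np.median(np.abs(img - mode)))
    return float(mode), 1.4826 * mad


def temperature_map(
    on_image,
    off_image,
    calibration: CalibrationCurve,
    base_temp_c: float,
    downsample_factor: int = 3,
    pixel_size_um: float = 1.0,
    background_mask=None,
    naive: bool = False,
) -> TemperatureMap:
    """Convert a laser ON/OFF image pair into a gridded temperature elevation.

    Both images are downsampled by block mean (default 3x) to reduce noise
    and background subtracted; the ratio ON/OFF is then inverted through the
    calibrated linear fluorescence law anchored at ``base_temp_c``.  Grid
    cells whose OFF signal after background subtraction falls below a
    validity floor (5x the background spread of a block mean) are masked.
    """
    on = np.asarray(on_image, dtype=float)
    off = np.asarray(off_image, dtype=float)
    if on.shape != off.shape:
        raise ValueError(f"ON/OFF shape mismatch: {on.shape} vs {off.shape}")
    lo, hi = calibration.valid_range_c
    if not lo <= base_temp_c <= hi:
        raise ValueError(f"base_temp_c {base_temp_c} outside calibration range {(lo, hi)}")

    bg_on, _ = estimate_background(on, background_mask)
    bg_off, bg_off_sd = estimate_background(off, background_mask)

    on_ds = block_downsample(on, downsample_factor) - bg_on
    off_ds = block_downsample(off, downsample_factor) - bg_off

    # a block mean of k^2 background pixels has spread bg_sd / k
    floor = 5.0 * bg_off_sd / downsample_factor
    floor = max(floor, 1e-9 * max(float(off_ds.max()), 1.0))
    valid = off_ds > floor

    delta = np.full(off_ds.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, on_ds / np.where(valid, off_ds, 1.0), np.nan)
    delta[valid] = invert_ratio(ratio[valid], calibration, base_temp_c, naive=naive)
    return TemperatureMap(
        delta_t_c=delta,
        valid=valid,
        pixel_size_um=pixel_size_um * downsample_factor,
        downsample_factor=downsample_factor,
        base_temp_c=base_temp_c,
    )


def cell_delta_t(
    measurement: CellTempMeasurement,
    calibration: CalibrationCurve,
    base_temp_c: float,
    naive: bool = False,
    cooling_tolerance_c: float = 0.5,
) -> float:
    """Temperature elevation of one cell from its ON/OFF fluorescence pair.

    Apparent cooling (ON brighter than OFF) beyond ``cooling_tolerance_c``
    is returned as a negative elevation with a warning, not an error, since
    moderate negative values are expected from noise.
    """
    ratio = measurement.f_on / measurement.f_off
    dt = float(invert_ratio(ratio, calibration, base_temp_c, naive=naive))
    if dt < -cooling_tolerance_c:
        warnings.warn(
            f"cell {measurement.cell_id}: apparent cooling of {-dt:.2f} C "
            "exceeds noise tolerance"
        )
    measurement.delta_t_c = dt
    return dt


def bin_by_distance(measurements, bin_width_um: float = 2.0) -> pd.DataFrame:
    """Average independent cell measurements within distance bins.

    Measurements are grouped into half-open bins ``[k*w, (k+1)*w)``; within
    each bin (and each power level, when a ``power_mw`` column is present)
    the mean, standard deviation and count are reported.  A single-member
    bin reports sd 0.

    Accepts a DataFrame with columns ``distance_um`` and ``delta_t_c``
    (optionally ``power_mw``), or a list of :class:`CellTempMeasurement`.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        rows = [
            {"distance_um": m.distance_to_focus_um, "delta_t_c": m.delta_t_c}
            for m in measurements
        ]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no measurements to bin")
    df["_bin"] = np.floor(df["distance_um"] / bin_width_um).astype(int)
    keys = (["power_mw"] if "power_mw" in df.columns else []) + ["_bin"]
    grouped = df.groupby(keys)
    out = (
        grouped["delta_t_c"]
        .agg(mean_delta_t_c="mean", sd_delta_t_c=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    # representative distance: mean member distance, not the bin centre
    out["distance_um"] = grouped["distance_um"].mean().to_numpy()
    cols = (["power_mw"] if "power_mw" in df.columns else []) + [
        "distance_um",
        "mean_delta_t_c",
        "sd_delta_t_c",
        "n",
    ]
    return out[cols]
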