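"""Synthetic microscopy data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes so the whole pipeline is testable
without real acquisitions:

* calibration image series of a reporter-expressing cell whose fluorescence
  decreases linearly with temperature;
* laser ON/OFF image pairs of a thin sheet of cells heated by a point source
  with base-2 exponential spatial decay and linear power scaling;
* noisy per-cell temperature measurement tables;
* elongating neurite tracks and paired left/right division-timing records.

Cells are rendered as uniform-intensity discs with 1-pixel Gaussian edge
softening; noise is Poisson shot noise plus Gaussian read noise.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .constants import CALIBRATION_RANGE_C, REF_TEMP_C
from .heat_model import ThermalProfile, predict_profile
from .morphometrics import NeuriteTrack, TrackPoint

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "default_scene",
    "sheet_scene",
    "gen_calibration_series",
    "gen_onoff_pair",
    "gen_cell_measurements",
    "gen_neurite_tracks",
    "gen_division_timings",
]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, photometry and noise of a synthetic imaging scene."""

    image_shape: tuple = (160, 160)  # pixels (rows, cols)
    pixel_size_um: float = 0.25
    cell_centers_um: tuple = ((20.0, 20.0),)  # (x, y) positions
    cell_radius_um: float = 3.0
    base_fluorescence: float = 2000.0  # counts/pixel at the reference temperature
    background_level: float = 100.0  # counts/pixel
    read_noise_sd: float = 3.0  # counts
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.base_fluorescence <= self.background_level:
            raise ValueError("base_fluorescence must exceed background_level")


@dataclass
class GroundTruth:
    """Generative parameters and hidden state behind a synthetic data set."""

    true_sensitivity_per_c: float | None = None
    true_slope_c_per_mw: float | None = None
    true_half_distance_um: float | None = None
    true_ambient_c: float | None = None
    temperatures_c: list = field(default_factory=list)
    delta_t_map_c: np.ndarray | None = None  # full-resolution, °C
    per_cell_delta_t_c: list = field(default_factory=list)
    neurite_lengths_um: list = field(default_factory=list)
    mean_division_delay_min: float | None = None

    def __post_init__(self):
        if self.true_half_distance_um is not None and self.true_half_distance_um <= 0:
            raise ValueError("true_half_distance_um must be > 0")
        for dt in self.per_cell_delta_t_c:
            if dt < 0:
                raise ValueError("temperature elevations must be >= 0")


def default_scene(**overrides) -> SceneSpec:
    """A single centred cell, convenient for calibration series."""
    spec = SceneSpec()
    cx = spec.image_shape[1] * spec.pixel_size_um / 2.0
    cy = spec.image_shape[0] * spec.pixel_size_um / 2.0
    base = dict(cell_centers_um=((cx, cy),))
    base.update(overrides)
    return SceneSpec(**base)


def sheet_scene(
    image_shape=(160, 160),
    pixel_size_um: float = 0.25,
    cell_radius_um: float = 6.0,
    spacing_um: float = 8.0,
    margin_um: float = 4.0,
    **overrides,
) -> SceneSpec:
    """A confluent sheet of overlapping cells leaving a background margin.

    Emulates a thin sheet of reporter-expressing cells covering the field
    interior, as used for in-vivo temperature mapping.
    """
    w = image_shape[1] * pixel_size_um
    h = image_shape[0] * pixel_size_um
    xs = np.arange(margin_um + cell_radius_um / 2, w - margin_um, spacing_um)
    ys = np.arange(margin_um + cell_radius_um / 2, h - margin_um, spacing_um)
    centers = tuple((float(x), float(y)) for y in ys for x in xs)
    return SceneSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        cell_centers_um=centers,
        cell_radius_um=cell_radius_um,
        **overrides,
    )


def _cell_mask(spec: SceneSpec) -> np.ndarray:
    """Softened union indicator of all cell discs (values in [0, 1])."""
    ny, nx = spec.image_shape
    y = (np.arange(ny) + 0.5) * spec.pixel_size_um
    x = (np.arange(nx) + 0.5) * spec.pixel_size_um
    xx, yy = np.meshgrid(x, y)
    inside = np.zeros(spec.image_shape, dtype=bool)
    for cx, cy in spec.cell_centers_um:
        inside |= (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.cell_radius_um**2
    return gaussian_filter(inside.astype(float), sigma=1.0)


def _apply_noise(expected: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = rng.poisson(expected).astype(float) if spec.shot_noise else expected.copy()
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _render(
    spec: SceneSpec,
    temp_field_c,
    sensitivity_per_c: float,
    ref_temp_c: float,
    mask: np.ndarray,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Expected image: background + cell signal scaled by the linear law.

    ``temp_field_c`` may be a scalar or a per-pixel array.  Background is
    unaffected by temperature.
    """
    factor = 1.0 - sensitivity_per_c * (np.asarray(temp_field_c, dtype=float) - ref_temp_c)
    if np.any(factor < 0):
        raise ValueError("sensitivity x temperature range drives fluorescence negative")
    expected = spec.background_level + spec.base_fluorescence * mask * factor
    if rng is None:
        return expected
    return _apply_noise(expected, spec, rng)


def gen_calibration_series(
    spec: SceneSpec,
    sensitivity_per_c: float,
    temperatures_c: Sequence[float],
    ref_temp_c: float = REF_TEMP_C,
    validity_window_c: tuple = CALIBRATION_RANGE_C,
) -> tuple[np.ndarray, GroundTruth]:
    """Image series of a reporter cell imaged at a ladder of bath temperatures.

    Cell pixels scale as ``base * (1 - s * (T - ref))``; background does not
    depend on temperature.  Returns a (n_temps, H, W) stack plus the truth.
    """
    if not 0.0 <= sensitivity_per_c < 0.1:
        raise ValueError("sensitivity_per_c must lie in [0, 0.1)")
    temps = np.asarray(temperatures_c, dtype=float)
    lo, hi = validity_window_c
    if np.any((temps < lo) | (temps > hi)):
        raise ValueError(f"temperatures outside validity window {validity_window_c}")
    rng = np.random.default_rng(spec.seed)
    mask = _cell_mask(spec)
    stack = np.stack(
        [_render(spec, t, sensitivity_per_c, ref_temp_c, mask, rng) for t in temps]
    )
    truth = GroundTruth(
        true_sensitivity_per_c=sensitivity_per_c, temperatures_c=list(map(float, temps))
    )
    return stack, truth


def gen_onoff_pair(
    spec: SceneSpec,
    profile: ThermalProfile,
    focus_um: tuple,
    power_mw: float,
    sensitivity_per_c: float,
    ref_temp_c: float | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Laser ON / laser OFF image pair over a heated cell sheet.

    The OFF image is rendered at the ambient temperature; the ON image adds
    the heat field's per-pixel elevation around ``focus_um``.  The truth
    elevation map is stored at full resolution.  ``ref_temp_c`` defaults to
    the profile's ambient so the OFF image sits at the reference brightness.
    """
    if power_mw < 0:
        raise ValueError("power_mw must be >= 0")
    fx, fy = focus_um
    w = spec.image_shape[1] * spec.pixel_size_um
    h = spec.image_shape[0] * spec.pixel_size_um
    if not (0 <= fx <= w and 0 <= fy <= h):
        raise ValueError(f"focus {focus_um} outside image bounds ({w} x {h} um)")
    if ref_temp_c is None:
        ref_temp_c = profile.ambient_c

    ny, nx = spec.image_shape
    y = (np.arange(ny) + 0.5) * spec.pixel_size_um
    x = (np.arange(nx) + 0.5) * spec.pixel_size_um
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx - fx, yy - fy)
    delta_t = predict_profile(power_mw, r, profile) if power_mw > 0 else np.zeros_like(r)

    rng = np.random.default_rng(spec.seed)
    mask = _cell_mask(spec)
    on = _render(spec, profile.ambient_c + delta_t, sensitivity_per_c, ref_temp_c, mask, rng)
    off = _render(spec, profile.ambient_c, sensitivity_per_c, ref_temp_c, mask, rng)
    truth = GroundTruth(
        true_sensitivity_per_c=sensitivity_per_c,
        true_slope_c_per_mw=profile.slope_c_per_mw,
        true_half_distance_um=profile.half_distance_um,
        true_ambient_c=profile.ambient_c,
        delta_t_map_c=delta_t,
    )
    return on, off, truth


def gen_cell_measurements(
    profile: ThermalProfile,
    powers_mw: Sequence[float],
    cell_distances_um: Sequence[float],
    noise_sd_c: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noisy per-cell temperature elevations at given distances and powers.

    Each row carries the applied power, the cell's distance to the focus,
    the true elevation from the heat field, and a Gaussian-noised
    measurement.  The default noise scale (0.3 °C per cell) matches the
    visible scatter of per-cell in-vivo measurements.
    """
    if noise_sd_c < 0:
        raise ValueError("noise_sd_c must be >= 0")
    distances = np.asarray(cell_distances_um, dtype=float)
    if distances.size == 0:
        raise ValueError("cell_distances_um must not be empty")
    rng = np.random.default_rng(seed)
    rows = []
    for p in powers_mw:
        truth_dt = predict_profile(float(p), distances, profile)
        noisy = truth_dt + rng.normal(0.0, noise_sd_c, size=distances.shape)
        for d, t_true, t_obs in zip(distances, np.atleast_1d(truth_dt), np.atleast_1d(noisy)):
            rows.append(
                {
                    "power_mw": float(p),
                    "distance_um": float(d),
                    "delta_t_true_c": float(t_true),
                    "delta_t_c": float(t_obs),
                }
            )
    df = pd.DataFrame(rows)
    truth = GroundTruth(
        true_slope_c_per_mw=profile.slope_c_per_mw,
        true_half_distance_um=profile.half_distance_um,
        true_ambient_c=profile.ambient_c,
        per_cell_delta_t_c=df["delta_t_true_c"].tolist(),
    )
    return df, truth


def gen_neurite_tracks(
    stages: Sequence[float],
    growth_onset_stage: float,
    rate_um_per_stage: float,
    seed: int = 0,
    n_tracks: int = 1,
    jitter_sd_um: float = 0.0,
    soma_um: tuple = (0.0, 0.0, 0.0),
    step_um: float = 1.0,
) -> list[NeuriteTrack]:
    """Straight elongating neurite tracks following a staged growth schedule.

    Length is 0 before the onset stage and increases linearly at
    ``rate_um_per_stage`` thereafter, with optional Gaussian length jitter
    (off by default).  Point lists are constructed so the summed 3-D
    segment length equals the scheduled length exactly.
    """
    st = np.asarray(stages, dtype=float)
    if np.any(np.diff(st) < 0) or np.any((st < 0) | (st > 1)):
        raise ValueError("stages must be ascending and within [0, 1]")
    rng = np.random.default_rng(seed)
    tracks = []
    for k in range(n_tracks):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        timepoints = []
        for i, stage in enumerate(st):
            length = max(0.0, rate_um_per_stage * (stage - growth_onset_stage))
            if jitter_sd_um > 0 and length > 0:
                length = max(0.0, length + rng.normal(0.0, jitter_sd_um))
            if length == 0.0:
                pts = np.array([soma_um], dtype=float)
            else:
                n_seg = max(1, int(np.ceil(length / step_um)))
                frac = np.linspace(0.0, length, n_seg + 1)
                pts = np.asarray(soma_um, dtype=float) + frac[:, None] * direction
            timepoints.append(TrackPoint(time=float(i), points=pts, stage=float(stage)))
        tracks.append(NeuriteTrack(timepoints=timepoints))
    return tracks


def gen_division_timings(
    n_embryos: int,
    mean_delay_min: float,
    natural_sd_min: float,
    seed: int = 0,
    base_time_min: float = 250.0,
    between_embryo_sd_min: float = 8.0,
) -> pd.DataFrame:
    """Paired division times of heated cells and contralateral homologues.

    The control-side time varies between embryos; the heated-side time is
    the control time plus ``mean_delay_min`` plus natural left-right noise
    of scale ``natural_sd_min``.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    if natural_sd_min < 0:
        raise ValueError("natural_sd_min must be >= 0")
    rng = np.random.default_rng(seed)
    control = base_time_min + (
        rng.normal(0.0, between_embryo_sd_min, size=n_embryos)
        if between_embryo_sd_min > 0
        else np.zeros(n_embryos)
    )
    delay = mean_delay_min + (
        rng.normal(0.0, natural_sd_min, size=n_embryos)
        if natural_sd_min > 0
        else np.zeros(n_embryos)
    )
    return pd.DataFrame(
        {
            "embryo_id": [f"e{i:03d}" for i in range(n_embryos)],
            "treated_time_min": control + delay,
            "control_time_min": control,
        }
    )
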