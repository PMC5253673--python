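"""Phenomenological model of the infrared laser heat field.

The field has three calibrated properties:

* the focal temperature elevation is linear in laser power
  (``ambient + slope * power``);
* the in-plane spatial profile is a base-2 exponential decay,
  ``dT(r) = slope * power * 2**(-r / half_distance)``, so profiles at
  different powers collapse onto one curve when divided by power;
* switching transients follow first-order kinetics with time constant tau.

Fitting routines recover the slope from (power, focal temperature) tables
and the shared half-distance from binned per-cell elevation profiles across
several powers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import DEFAULT_TAU_MS

__all__ = [
    "ThermalProfile",
    "PulseSchedule",
    "PulsedExposure",
    "PowerSlopeFit",
    "SpatialProfileFit",
    "FitError",
    "predict_focal_temp",
    "predict_profile",
    "fit_power_slope",
    "fit_spatial_profile",
    "step_response",
    "pulsed_exposure",
]


class FitError(RuntimeError):
    """A model fit failed to converge; carries the attempted start point."""

    def __init__(self, message: str, initial_guess=None, residuals=None):
        super().__init__(message)
        self.initial_guess = initial_guess
        self.residuals = residuals


@dataclass(frozen=True)
class ThermalProfile:
    """Calibrated description of the laser heat field.

    Parameters
    ----------
    slope_c_per_mw : float
        Focal temperature elevation per mW of applied power (°C/mW).
    half_distance_um : float
        In-plane distance at which the elevation falls to half its focal
        value (μm).
    ambient_c : float
        Sample (bath) temperature with the laser off (°C).
    tau_ms : float
        First-order response time constant (ms).
    fit_diagnostics : dict
        Optional per-parameter standard errors and fit residuals.
    """

    slope_c_per_mw: float
    half_distance_um: float
    ambient_c: float
    tau_ms: float = DEFAULT_TAU_MS
    fit_diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.slope_c_per_mw <= 0:
            raise ValueError("slope_c_per_mw must be > 0")
        if self.half_distance_um <= 0:
            raise ValueError("half_distance_um must be > 0")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0")

    @property
    def decay_length_um(self) -> float:
        """e-folding length of the exponential decay (= half_distance/ln 2)."""
        return self.half_distance_um / math.log(2.0)


@dataclass(frozen=True)
class PulseSchedule:
    """Laser duty schedule: continuous, or pulsed at fixed frequency/width."""

    frequency_hz: float
    pulse_width_ms: float
    peak_power_mw: float
    total_duration_s: float
    mode: Literal["continuous", "pulsed"] = "pulsed"

    def __post_init__(self):
        for name in ("frequency_hz", "pulse_width_ms", "peak_power_mw", "total_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.duty_cycle > 1.0 + 1e-12:
            raise ValueError(
                f"duty cycle {self.duty_cycle:.3f} exceeds 1 "
                f"({self.frequency_hz} Hz x {self.pulse_width_ms} ms)"
            )

    @property
    def duty_cycle(self) -> float:
        if self.mode == "continuous":
            return 1.0
        return self.frequency_hz * self.pulse_width_ms / 1000.0


@dataclass(frozen=True)
class PulsedExposure:
    """Thermal summary of a pulse schedule under a given heat field."""

    peak_focal_c: float
    duty_cycle: float
    averaged_power_mw: float


@dataclass(frozen=True)
class PowerSlopeFit:
    slope_c_per_mw: float
    stderr: float
    intercept_c: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class SpatialProfileFit:
    """Joint exponential-decay fit across powers with a shared half-distance."""

    half_distance_um: float
    amplitudes_c: dict  # power (mW) -> fitted focal elevation (°C)
    collapse_residual: float  # relative RMS departure of amplitudes from A ∝ P
    stderr_half_distance_um: float
    n_points: int


def predict_focal_temp(power_mw: float, profile: ThermalProfile) -> float:
    """Absolute temperature at the laser focus: ambient + slope * power."""
    if power_mw < 0:
        raise ValueError("power_mw must be >= 0")
    return profile.ambient_c + profile.slope_c_per_mw * power_mw


def predict_profile(power_mw, r_um, profile: ThermalProfile):
    """Temperature elevation (°C above ambient) at in-plane distance r.

    Vectorized over ``r_um`` and ``power_mw``.
    """
    power = np.asarray(power_mw, dtype=float)
    r = np.asarray(r_um, dtype=float)
    if np.any(power < 0):
        raise ValueError("power_mw must be >= 0")
    if np.any(r < 0):
        raise ValueError("r_um must be >= 0")
    out = profile.slope_c_per_mw * power * np.exp2(-r / profile.half_distance_um)
    return float(out) if out.ndim == 0 else out


def fit_power_slope(
    powers_mw,
    temps_c,
    ambient_c: float,
    fix_intercept: bool = True,
) -> PowerSlopeFit:
    """Least-squares slope of focal temperature elevation on laser power.

    By default the intercept is fixed at zero: the elevation must vanish at
    zero power.  A free intercept is available as a diagnostic.
    """
    p = np.asarray(powers_mw, dtype=float)
    y = np.asarray(temps_c, dtype=float) - ambient_c
    if p.ndim != 1 or p.shape != y.shape:
        raise ValueError("powers and temperatures must be 1-D and equal length")
    if np.unique(p).size < 2:
        raise FitError("need >= 2 distinct power levels for a slope fit")
    if fix_intercept:
        slope = float(p @ y / (p @ p))
        intercept = 0.0
        resid = y - slope * p
        dof = max(p.size - 1, 1)
        stderr = float(np.sqrt(resid @ resid / dof / (p @ p)))
    else:
        (slope, intercept), cov = np.polyfit(p, y, 1, cov=True)
        resid = y - (slope * p + intercept)
        stderr = float(np.sqrt(cov[0, 0]))
        slope, intercept = float(slope), float(intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return PowerSlopeFit(slope, stderr, intercept, r2, p.size)


def _spatial_initial_guess(df: pd.DataFrame) -> tuple[float, dict]:
    amplitudes = {}
    scaled = []
    for power, grp in df.groupby("power_mw"):
        grp = grp.sort_values("distance_um")
        a0 = float(grp["delta_t_c"].iloc[0])
        amplitudes[float(power)] = a0 if a0 > 0 else float(grp["delta_t_c"].max())
        if amplitudes[float(power)] > 0:
            scaled.append(
                np.column_stack(
                    [grp["distance_um"].to_numpy(), grp["delta_t_c"].to_numpy() / amplitudes[float(power)]]
                )
            )
    pooled = np.concatenate(scaled)
    pooled = pooled[np.argsort(pooled[:, 0])]
    below = pooled[pooled[:, 1] < 0.5]  # first crossing of the half level
    r_half0 = float(below[0, 0]) if below.size else float(pooled[-1, 0]) / 2.0
    if r_half0 <= 0:
        r_half0 = max(float(pooled[-1, 0]) / 2.0, 1.0)
    return r_half0, amplitudes


def fit_spatial_profile(binned: pd.DataFrame, ambient_c: float | None = None) -> SpatialProfileFit:
    """Jointly fit ``A_p * 2**(-r/r_half)`` across powers, plateau fixed at zero.

    Parameters
    ----------
    binned : DataFrame
        Columns ``power_mw``, ``distance_um`` and either ``delta_t_c``
        (elevation above ambient) or ``temp_c`` (absolute; requires
        ``ambient_c``).  Each power level needs at least 4 distance bins.
    ambient_c : float, optional
        Subtracted from ``temp_c`` when elevations are not given directly.

    Returns
    -------
    SpatialProfileFit
        Shared half-distance, per-power amplitudes, and a collapse
        diagnostic measuring how far the amplitudes depart from strict
        proportionality to power.
    """
    df = binned.copy()
    if "delta_t_c" not in df.columns and "mean_delta_t_c" in df.columns:
        df = df.rename(columns={"mean_delta_t_c": "delta_t_c"})
    if "delta_t_c" not in df.columns:
        if "temp_c" not in df.columns or ambient_c is None:
            raise ValueError("need delta_t_c column, or temp_c plus ambient_c")
        df["delta_t_c"] = df["temp_c"] - ambient_c
    counts = df.groupby("power_mw")["distance_um"].nunique()
    if (counts < 4).any():
        bad = counts[counts < 4].index.tolist()
        raise ValueError(f"each power needs >= 4 distance bins; too few at {bad}")

    powers = sorted(float(p) for p in df["power_mw"].unique())
    r_half0, amp0 = _spatial_initial_guess(df)
    x0 = np.array([r_half0] + [amp0[p] for p in powers])

    r = df["distance_um"].to_numpy(dtype=float)
    y = df["delta_t_c"].to_numpy(dtype=float)
    power_idx = df["power_mw"].map({p: i for i, p in enumerate(powers)}).to_numpy()

    def residuals(x):
        r_half, amps = x[0], x[1:]
        return amps[power_idx] * np.exp2(-r / r_half) - y

    sol = least_squares(residuals, x0, bounds=(1e-6, np.inf))
    if not sol.success:
        raise FitError(
            f"spatial profile fit did not converge: {sol.message}",
            initial_guess=x0,
            residuals=sol.fun,
        )
    r_half = float(sol.x[0])
    amplitudes = {p: float(a) for p, a in zip(powers, sol.x[1:])}

    # collapse diagnostic: least-squares c for A_p = c * P, relative RMS residual
    pw = np.array(powers)
    am = sol.x[1:]
    c = float(pw @ am / (pw @ pw))
    collapse = float(np.sqrt(np.mean((am - c * pw) ** 2)) / np.mean(am))

    # half-distance standard error from the Jacobian at the solution
    try:
        jac = sol.jac
        dof = max(y.size - sol.x.size, 1)
        s2 = float(sol.fun @ sol.fun) / dof
        cov = s2 * np.linalg.inv(jac.T @ jac)
        stderr = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        stderr = float("nan")
    return SpatialProfileFit(r_half, amplitudes, collapse, stderr, y.size)


def step_response(
    t_ms,
    steady_elevation_c: float,
    tau_ms: float = DEFAULT_TAU_MS,
    phase: Literal["heating", "cooling"] = "heating",
):
    """Temperature elevation during a switching transient.

    Heating: ``steady * (1 - exp(-t/tau))``; cooling after switch-off decays
    symmetrically as ``steady * exp(-t/tau)``.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be >= 0")
    if tau_ms <= 0:
        raise ValueError("tau_ms must be > 0")
    if phase == "heating":
        out = steady_elevation_c * (1.0 - np.exp(-t / tau_ms))
    else:
        out = steady_elevation_c * np.exp(-t / tau_ms)
    return float(out) if out.ndim == 0 else out


def pulsed_exposure(schedule: PulseSchedule, profile: ThermalProfile) -> PulsedExposure:
    """Peak focal temperature, duty cycle and time-averaged power of a schedule.

    When pulses are short relative to the thermal response (width < 3 tau) the
    field does not reach steady state within a pulse, so the attained peak is
    scaled by the step response at the pulse width.
    """
    duty = schedule.duty_cycle
    averaged = schedule.peak_power_mw * duty
    steady = profile.slope_c_per_mw * schedule.peak_power_mw
    if schedule.mode == "pulsed" and schedule.pulse_width_ms < 3.0 * profile.tau_ms:
        elevation = step_response(schedule.pulse_width_ms, steady, profile.tau_ms)
    else:
        elevation = steady
    return PulsedExposure(profile.ambient_c + elevation, duty, averaged)
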