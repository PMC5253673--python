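"""Choose laser and ambient-temperature parameters for targeted heating.

Induction mode: put the focal cell inside the heat-shock band (default
32-34 °C) while the nearest neighbour stays below the band's lower edge.
Because focal elevation is ``slope * power`` and neighbours sit on the
exponential tail, lowering the ambient temperature and raising laser power
sharpens the spatial selectivity.

Ablation mode: drive the focal cell to a lethal temperature while pulsing
the laser at low duty cycle so that time-averaged heating at neighbouring
cells remains below the induction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .constants import (
    ABLATION_DURATION_S,
    ABLATION_FREQUENCY_HZ,
    ABLATION_PEAK_POWER_MW,
    ABLATION_PULSE_WIDTH_MS,
    DEFAULT_LETHAL_TEMP_C,
    HEAT_SHOCK_BAND_C,
    INDUCTION_DURATION_MIN,
)
from .heat_model import (
    PulseSchedule,
    ThermalProfile,
    predict_focal_temp,
    predict_profile,
    pulsed_exposure,
)

__all__ = ["InductionPlan", "plan_induction", "plan_ablation", "classify_cells"]


@dataclass
class InductionPlan:
    """A laser/ambient parameter choice with its predicted temperatures."""

    mode: Literal["induction", "ablation"]
    power_mw: float
    ambient_c: float
    threshold_band_c: tuple
    predicted_focal_c: float
    predicted_at_neighbor_c: float
    neighbor_distance_um: float
    feasible: bool
    duration_min: float | None = None
    schedule: PulseSchedule | None = None
    power_range_mw: tuple | None = None
    diagnostic: str = ""

    def __post_init__(self):
        lo, hi = self.threshold_band_c
        if not lo < hi:
            raise ValueError("threshold band lower bound must be below upper")


def plan_induction(
    profile: ThermalProfile,
    threshold_band_c: tuple = HEAT_SHOCK_BAND_C,
    neighbor_distance_um: float = None,
    ambient_c: float | None = None,
    edge: Literal["low", "mid", "high"] = "mid",
    duration_min: float = INDUCTION_DURATION_MIN,
) -> InductionPlan:
    """Plan continuous-wave irradiation that heat-shocks only the focal cell.

    The feasible power interval is ``[(T_low - ambient)/slope,
    (T_high - ambient)/slope]``; the plan takes its midpoint by default
    (``edge='low'`` reproduces the band-lower-edge choice).  The plan is
    feasible iff the predicted absolute temperature at the nearest
    neighbour stays below the band's lower bound.

    ``neighbor_distance_um`` must be supplied: it is the geometry of the
    particular embryo, not a calibration constant.
    """
    if neighbor_distance_um is None:
        raise ValueError("neighbor_distance_um must be supplied")
    if ambient_c is None:
        ambient_c = profile.ambient_c
    t_low, t_high = threshold_band_c

    def infeasible(power, reason):
        return InductionPlan(
            mode="induction",
            power_mw=power,
            ambient_c=ambient_c,
            threshold_band_c=threshold_band_c,
            predicted_focal_c=ambient_c + profile.slope_c_per_mw * power,
            predicted_at_neighbor_c=ambient_c
            + predict_profile(power, neighbor_distance_um, profile),
            neighbor_distance_um=neighbor_distance_um,
            feasible=False,
            duration_min=duration_min,
            diagnostic=reason,
        )

    if ambient_c >= t_low:
        return infeasible(0.0, f"ambient {ambient_c} C already at/above band lower edge {t_low} C")

    p_low = (t_low - ambient_c) / profile.slope_c_per_mw
    p_high = (t_high - ambient_c) / profile.slope_c_per_mw
    power = {"low": p_low, "mid": 0.5 * (p_low + p_high), "high": p_high}[edge]

    working = profile if profile.ambient_c == ambient_c else ThermalProfile(
        profile.slope_c_per_mw, profile.half_distance_um, ambient_c, profile.tau_ms
    )
    focal = predict_focal_temp(power, working)
    neighbor = ambient_c + predict_profile(power, neighbor_distance_um, profile)
    if neighbor >= t_low:
        plan = infeasible(power, f"neighbour at {neighbor_distance_um} um reaches {neighbor:.1f} C")
        plan.power_range_mw = (p_low, p_high)
        return plan
    return InductionPlan(
        mode="induction",
        power_mw=power,
        ambient_c=ambient_c,
        threshold_band_c=threshold_band_c,
        predicted_focal_c=focal,
        predicted_at_neighbor_c=neighbor,
        neighbor_distance_um=neighbor_distance_um,
        feasible=True,
        duration_min=duration_min,
        power_range_mw=(p_low, p_high),
    )


def plan_ablation(
    profile: ThermalProfile,
    lethal_temp_c: float = DEFAULT_LETHAL_TEMP_C,
    induction_band_c: tuple = HEAT_SHOCK_BAND_C,
    neighbor_distance_um: float = None,
    ambient_c: float | None = None,
    schedule: PulseSchedule | None = None,
) -> InductionPlan:
    """Plan pulsed irradiation that kills the focal cell without off-target
    induction.

    The peak power must reach ``(lethal - ambient)/slope``; the default
    schedule pulses at 6 Hz with 8.3 ms pulses at 13 mW for 10 s.
    Feasibility requires the time-averaged elevation at the neighbour
    (duty-cycled power through the spatial decay) to stay below the
    induction band's lower edge.
    """
    if neighbor_distance_um is None:
        raise ValueError("neighbor_distance_um must be supplied")
    if ambient_c is None:
        ambient_c = profile.ambient_c
    if lethal_temp_c <= induction_band_c[1]:
        raise ValueError("lethal_temp_c must exceed the induction band upper edge")
    if schedule is None:
        schedule = PulseSchedule(
            frequency_hz=ABLATION_FREQUENCY_HZ,
            pulse_width_ms=ABLATION_PULSE_WIDTH_MS,
            peak_power_mw=ABLATION_PEAK_POWER_MW,
            total_duration_s=ABLATION_DURATION_S,
            mode="pulsed",
        )
    min_peak = (lethal_temp_c - ambient_c) / profile.slope_c_per_mw
    working = ThermalProfile(
        profile.slope_c_per_mw, profile.half_distance_um, ambient_c, profile.tau_ms
    )
    exposure = pulsed_exposure(schedule, working)
    focal = ambient_c + profile.slope_c_per_mw * schedule.peak_power_mw
    avg_neighbor = ambient_c + predict_profile(
        exposure.averaged_power_mw, neighbor_distance_um, profile
    )
    feasible = schedule.peak_power_mw >= min_peak and avg_neighbor < induction_band_c[0]
    diagnostic = ""
    if schedule.peak_power_mw < min_peak:
        diagnostic = f"peak power below lethal minimum {min_peak:.2f} mW"
    elif not feasible:
        diagnostic = f"time-averaged neighbour temperature {avg_neighbor:.1f} C reaches induction band"
    return InductionPlan(
        mode="ablation",
        power_mw=schedule.peak_power_mw,
        ambient_c=ambient_c,
        threshold_band_c=induction_band_c,
        predicted_focal_c=focal,
        predicted_at_neighbor_c=avg_neighbor,
        neighbor_distance_um=neighbor_distance_um,
        feasible=feasible,
        schedule=schedule,
        power_range_mw=(min_peak, float("inf")),
        diagnostic=diagnostic,
    )


def classify_cells(
    plan: InductionPlan,
    profile: ThermalProfile,
    cell_positions_um: Sequence,
    focus_um,
) -> list[str]:
    """Label each cell 'induced' or 'sub-threshold' under a feasible plan.

    A cell is induced iff its predicted absolute temperature (ambient plus
    the heat field elevation at its distance from the focus) reaches the
    band's lower bound.  Monotone: cells closer to the focus than an
    induced cell are also induced.
    """
    if not plan.feasible:
        raise ValueError("cannot classify cells under an infeasible plan")
    focus = np.asarray(focus_um, dtype=float)
    positions = np.atleast_2d(np.asarray(cell_positions_um, dtype=float))
    dists = np.linalg.norm(positions - focus, axis=1)
    temps = plan.ambient_c + predict_profile(plan.power_mw, dists, profile)
    t_low = plan.threshold_band_c[0]
    return ["induced" if t >= t_low else "sub-threshold" for t in temps]
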