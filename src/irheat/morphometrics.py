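"""Neurite outgrowth, developmental staging and division-timing analyses.

Neurite length is the summed 3-D Euclidean distance between consecutive
annotated points.  Developmental stage is expressed as a unitless clock
mapping the tail-to-head distance linearly from 0 at the comma stage to 1
at the 2-fold stage, so growth curves from different embryos are
comparable.  Division-timing comparisons are paired between a treated cell
and its contralateral homologue; the no-treatment control uses absolute
left-right differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackPoint",
    "NeuriteTrack",
    "StageCalibration",
    "DivisionRecord",
    "GrowthComparison",
    "DivisionDelayStats",
    "polyline_length",
    "stage_ratio",
    "growth_curve",
    "compare_outgrowth",
    "division_delay_stats",
    "kinetics_curve",
]


@dataclass
class TrackPoint:
    """One timepoint of a neurite annotation: ordered 3-D points plus stage."""

    time: float
    points: np.ndarray  # (n, 3) μm
    stage: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 1:
            raise ValueError("points must be an (n >= 1, 3) array")
        if self.stage is not None and not 0.0 <= self.stage <= 1.0:
            raise ValueError("stage must lie in [0, 1] when present")


@dataclass
class NeuriteTrack:
    timepoints: list

    def __post_init__(self):
        if not self.timepoints:
            raise ValueError("track must have at least one timepoint")


@dataclass(frozen=True)
class StageCalibration:
    """Tail-to-head distances anchoring the developmental clock."""

    comma_metric_um: float
    twofold_metric_um: float

    def __post_init__(self):
        if self.comma_metric_um <= 0 or self.twofold_metric_um <= 0:
            raise ValueError("calibration metrics must be positive")
        if self.comma_metric_um == self.twofold_metric_um:
            raise ValueError("comma and 2-fold metrics must differ")


@dataclass
class DivisionRecord:
    """Division times (min) of a treated cell and its contralateral control."""

    embryo_id: str
    treated_time_min: float
    control_time_min: float
    treated_cycle_min: float | None = None
    control_cycle_min: float | None = None

    def __post_init__(self):
        if self.treated_time_min < 0 or self.control_time_min < 0:
            raise ValueError("division times must be >= 0")


@dataclass
class GrowthComparison:
    onset_difference: float
    onset_ci: tuple
    rate_difference: float
    rate_ci: tuple
    onsets_a: np.ndarray
    onsets_b: np.ndarray
    rates_a: np.ndarray
    rates_b: np.ndarray


@dataclass
class DivisionDelayStats:
    mean_delay_min: float
    sd_min: float
    differences_min: np.ndarray
    n: int
    percent_cycle_increase: float | None = None


def polyline_length(points) -> float:
    """Summed Euclidean length of consecutive 3-D segments; one point -> 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise ValueError("points must be an (n >= 1, 3) array")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinate in point list")
    if pts.shape[0] == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def stage_ratio(tail_to_head_um: float, calib: StageCalibration) -> float:
    """Developmental-clock value: 0 at the comma anchor, 1 at the 2-fold anchor.

    Linear between anchors; values outside [0, 1] (pre-comma or post-2-fold
    embryos) are clamped with a warning.
    """
    value = (tail_to_head_um - calib.comma_metric_um) / (
        calib.twofold_metric_um - calib.comma_metric_um
    )
    if value < 0.0 or value > 1.0:
        warnings.warn(f"stage ratio {value:.3f} outside [0, 1]; clamped")
        value = min(1.0, max(0.0, value))
    return float(value)


def growth_curve(track: NeuriteTrack) -> pd.DataFrame:
    """Per-timepoint (stage, length) pairs for a staged neurite track.

    Timepoints without a stage (e.g. the neurite was not visible) are
    omitted without interpolation.
    """
    staged = [tp for tp in track.timepoints if tp.stage is not None]
    if not staged:
        raise ValueError("track has no staged timepoints")
    stages = [tp.stage for tp in staged]
    if any(b < a for a, b in zip(stages, stages[1:])):
        raise ValueError("stages must be non-decreasing along the track")
    return pd.DataFrame(
        {"stage": stages, "length_um": [polyline_length(tp.points) for tp in staged]}
    )


def _onset_and_rate(curve: pd.DataFrame, threshold_um: float):
    grown = curve[curve["length_um"] > threshold_um]
    if grown.empty:
        return None, None
    onset = float(grown["stage"].iloc[0])
    if len(grown) >= 2 and grown["stage"].nunique() >= 2:
        rate = float(np.polyfit(grown["stage"], grown["length_um"], 1)[0])
    else:
        rate = None
    return onset, rate


def compare_outgrowth(
    group_a,
    group_b,
    onset_threshold_um: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> GrowthComparison:
    """Difference in outgrowth onset stage and growth rate between two groups.

    Onset per curve is the first stage at which length exceeds a small
    threshold (default 1 μm); rate is the slope of length on stage beyond
    onset.  Differences are group B minus group A with seeded percentile
    bootstrap confidence intervals (curves resampled within groups).
    Curves that never exceed the threshold are excluded with a warning.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 growth curves")

    def extract(group, label):
        onsets, rates = [], []
        for i, curve in enumerate(group):
            onset, rate = _onset_and_rate(curve, onset_threshold_um)
            if onset is None:
                warnings.warn(f"curve {i} in group {label} never exceeds threshold; excluded")
                continue
            onsets.append(onset)
            if rate is not None:
                rates.append(rate)
        return np.array(onsets), np.array(rates)

    onsets_a, rates_a = extract(group_a, "A")
    onsets_b, rates_b = extract(group_b, "B")
    if onsets_a.size < 2 or onsets_b.size < 2:
        raise ValueError("fewer than 2 usable curves in a group after exclusion")

    rng = np.random.default_rng(seed)

    def boot_ci(a, b):
        if a.size == 0 or b.size == 0:
            return (float("nan"), float("nan"))
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            diffs[i] = rng.choice(b, b.size).mean() - rng.choice(a, a.size).mean()
        return (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))

    return GrowthComparison(
        onset_difference=float(onsets_b.mean() - onsets_a.mean()),
        onset_ci=boot_ci(onsets_a, onsets_b),
        rate_difference=(
            float(rates_b.mean() - rates_a.mean()) if rates_a.size and rates_b.size else float("nan")
        ),
        rate_ci=boot_ci(rates_a, rates_b),
        onsets_a=onsets_a,
        onsets_b=onsets_b,
        rates_a=rates_a,
        rates_b=rates_b,
    )


def division_delay_stats(records, paired: bool = True) -> DivisionDelayStats:
    """Division-timing delay of treated cells relative to contralateral controls.

    Paired mode reports mean(treated - control).  Control mode (``paired=False``,
    for untreated embryos) reports the mean absolute left-right difference,
    the natural asymmetry benchmark.  When both cycle lengths are present on
    every record the mean per-embryo percent cycle increase is included.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need >= 1 division record")
    diffs = np.array([r.treated_time_min - r.control_time_min for r in recs])
    if not paired:
        diffs = np.abs(diffs)
    pct = None
    has_cycles = [r.treated_cycle_min is not None and r.control_cycle_min is not None for r in recs]
    if all(has_cycles):
        pct = float(
            np.mean(
                [
                    (r.treated_cycle_min - r.control_cycle_min) / r.control_cycle_min
                    for r in recs
                ]
            )
            * 100.0
        )
    return DivisionDelayStats(
        mean_delay_min=float(diffs.mean()),
        sd_min=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        differences_min=diffs,
        n=diffs.size,
        percent_cycle_increase=pct,
    )


def percent_cycle_increase(records) -> float:
    """Mean per-embryo percent increase in cell-cycle time; errors if absent."""
    recs = list(records)
    if any(r.treated_cycle_min is None or r.control_cycle_min is None for r in recs):
        raise ValueError("cycle fields missing on some records")
    return division_delay_stats(recs).percent_cycle_increase


def kinetics_curve(
    series,
    laser_power_uw: float,
    time_tolerance_h: float = 1e-6,
) -> pd.DataFrame:
    """Power-normalized mean reporter-induction kinetics across embryos.

    Each embryo's intensity series is divided by the imaging laser power so
    curves acquired at different powers compare on protein level alone, then
    averaged per timepoint.  Series on mismatched time grids are aligned to
    the first embryo's grid by nearest timepoint within ``time_tolerance_h``;
    larger mismatches are an error.
    """
    if laser_power_uw <= 0:
        raise ValueError("laser_power_uw must be > 0")
    frames = [pd.DataFrame(s, columns=["time_h", "fluorescence"]) for s in series]
    if not frames:
        raise ValueError("need >= 1 embryo series")
    ref_t = frames[0]["time_h"].to_numpy(dtype=float)
    aligned = []
    for k, df in enumerate(frames):
        t = df["time_h"].to_numpy(dtype=float)
        idx = np.abs(t[None, :] - ref_t[:, None]).argmin(axis=1)
        if np.any(np.abs(t[idx] - ref_t) > time_tolerance_h):
            raise ValueError(f"series {k} time grid differs beyond tolerance")
        aligned.append(df["fluorescence"].to_numpy(dtype=float)[idx] / laser_power_uw)
    return pd.DataFrame(
        {"time_h": ref_t, "normalized_intensity": np.mean(aligned, axis=0)}
    )
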