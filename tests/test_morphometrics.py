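"""Neurite length, staging, growth comparison and division-timing stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from irheat.morphometrics import (
    DivisionRecord,
    NeuriteTrack,
    StageCalibration,
    TrackPoint,
    compare_outgrowth,
    division_delay_stats,
    growth_curve,
    kinetics_curve,
    percent_cycle_increase,
    polyline_length,
    stage_ratio,
)
from irheat.synthetic import gen_neurite_tracks


def brute_force_length(points):
    """Independent oracle: explicit per-segment square root and sum."""
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        total += (
            (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2
        ) ** 0.5
    return total


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestPolylineLength:
    def test_three_four_five_triangle(self):
        assert polyline_length([(0, 0, 0), (3, 4, 0)]) == pytest.approx(5.0)

    def test_collinear_segments(self):
        pts = [(0, 0, 0), (1, 1, 1), (2, 2, 2)]
        assert polyline_length(pts) == pytest.approx(2 * np.sqrt(3))

    def test_single_point_zero(self):
        assert polyline_length([(1.0, 2.0, 3.0)]) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            polyline_length([(0, 0, 0), (np.nan, 0, 0)])

    def test_matches_brute_force_and_rigid_invariance(self, rng):
        for _ in range(200):
            pts = rng.normal(scale=10.0, size=(rng.integers(2, 12), 3))
            length = polyline_length(pts)
            assert length == pytest.approx(brute_force_length(pts), rel=1e-12)
            moved = pts @ random_rotation(rng).T + rng.normal(size=3)
            assert polyline_length(moved) == pytest.approx(length, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        pts=arrays(
            float,
            st.tuples(st.integers(2, 8), st.just(3)),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_at_least_endpoint_distance(self, pts):
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        assert polyline_length(pts) >= chord - 1e-9


class TestStageRatio:
    calib = StageCalibration(comma_metric_um=100.0, twofold_metric_um=180.0)

    def test_comma_anchor_is_zero(self):
        assert stage_ratio(100.0, self.calib) == 0.0

    def test_twofold_anchor_is_one(self):
        assert stage_ratio(180.0, self.calib) == 1.0

    def test_midpoint_is_half(self):
        assert stage_ratio(140.0, self.calib) == pytest.approx(0.5)

    def test_strictly_monotone_between_anchors(self):
        metrics = np.linspace(100.0, 180.0, 20)
        values = [stage_ratio(float(m), self.calib) for m in metrics]
        assert np.all(np.diff(values) > 0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert stage_ratio(90.0, self.calib) == 0.0
        with pytest.warns(UserWarning, match="clamped"):
            assert stage_ratio(200.0, self.calib) == 1.0

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            StageCalibration(100.0, 100.0)


class TestGrowthCurve:
    def test_generator_round_trip(self):
        stages = [0.1, 0.2, 0.4, 0.6, 0.8]
        (track,) = gen_neurite_tracks(stages, growth_onset_stage=0.3, rate_um_per_stage=20.0)
        curve = growth_curve(track)
        below = curve[curve["stage"] < 0.3]["length_um"]
        assert np.allclose(below, 0.0)
        grown = curve[curve["length_um"] > 0]
        slope = np.polyfit(grown["stage"], grown["length_um"], 1)[0]
        assert slope == pytest.approx(20.0, rel=1e-9)

    def test_single_timepoint(self):
        track = NeuriteTrack([TrackPoint(0.0, [(0, 0, 0)], stage=0.5)])
        curve = growth_curve(track)
        assert len(curve) == 1

    def test_unstaged_timepoints_omitted_not_interpolated(self):
        track = NeuriteTrack(
            [
                TrackPoint(0.0, [(0, 0, 0)], stage=0.2),
                TrackPoint(1.0, [(0, 0, 0), (5, 0, 0)], stage=None),
                TrackPoint(2.0, [(0, 0, 0), (9, 0, 0)], stage=0.6),
            ]
        )
        curve = growth_curve(track)
        assert list(curve["stage"]) == [0.2, 0.6]

    def test_no_staged_timepoints_rejected(self):
        track = NeuriteTrack([TrackPoint(0.0, [(0, 0, 0)], stage=None)])
        with pytest.raises(ValueError, match="staged"):
            growth_curve(track)


def _curves(onsets, rate, seed):
    curves = []
    for i, onset in enumerate(onsets):
        (track,) = gen_neurite_tracks(
            list(np.linspace(0.1, 0.9, 9)), float(onset), rate, seed=seed + i
        )
        curves.append(growth_curve(track))
    return curves


class TestCompareOutgrowth:
    def test_identical_groups_difference_zero(self):
        a = _curves([0.3, 0.3, 0.3, 0.3], 20.0, seed=0)
        res = compare_outgrowth(a, a, seed=0)
        assert res.onset_difference == 0.0
        assert res.onset_ci[0] <= 0.0 <= res.onset_ci[1]

    def test_onset_shift_recovered(self):
        a = _curves([0.30] * 5, 20.0, seed=0)
        b = _curves([0.40] * 5, 20.0, seed=100)
        res = compare_outgrowth(a, b, seed=1)
        # stage grid is 0.1-wide, so the detected shift is quantized
        assert res.onset_difference == pytest.approx(0.10, abs=0.11)
        assert res.onset_difference > 0

    def test_single_curve_group_rejected(self):
        a = _curves([0.3, 0.3], 20.0, seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            compare_outgrowth(a[:1], a)

    def test_flat_curve_excluded_with_warning(self):
        a = _curves([0.3, 0.3, 0.3], 20.0, seed=0)
        flat = growth_curve(gen_neurite_tracks([0.1, 0.2], 0.9, 20.0)[0])
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_outgrowth(a + [flat], a, seed=0)
        assert res.onsets_a.size == 3

    def test_ci_covers_zero_under_null(self):
        """Nominal coverage at reduced repetitions: >=90% of seeded runs."""
        rng = np.random.default_rng(7)
        covered = 0
        reps = 20
        for rep in range(reps):
            onsets_a = np.clip(rng.normal(0.3, 0.05, 4), 0.05, 0.85)
            onsets_b = np.clip(rng.normal(0.3, 0.05, 4), 0.05, 0.85)
            a = _curves(onsets_a, 20.0, seed=1000 + 10 * rep)
            b = _curves(onsets_b, 20.0, seed=2000 + 10 * rep)
            res = compare_outgrowth(a, b, n_boot=300, seed=rep)
            if res.onset_ci[0] <= 0.0 <= res.onset_ci[1]:
                covered += 1
        assert covered / reps >= 0.9


class TestDivisionDelayStats:
    def test_no_delay(self):
        recs = [DivisionRecord("e1", 100.0, 100.0), DivisionRecord("e2", 90.0, 90.0)]
        assert division_delay_stats(recs).mean_delay_min == 0.0

    def test_injected_delay_recovered(self):
        from irheat.synthetic import gen_division_timings

        df = gen_division_timings(50, 17.0, 5.0, seed=21)
        recs = [
            DivisionRecord(r.embryo_id, r.treated_time_min, r.control_time_min)
            for r in df.itertuples()
        ]
        stats = division_delay_stats(recs)
        assert stats.mean_delay_min == pytest.approx(17.0, abs=2.0)
        assert stats.n == 50

    def test_control_mode_absolute_differences(self):
        recs = [DivisionRecord("l", 97.0, 100.0), DivisionRecord("r", 103.0, 100.0)]
        stats = division_delay_stats(recs, paired=False)
        assert stats.mean_delay_min == pytest.approx(3.0)

    def test_bias_shrinks_with_sample_size(self):
        from irheat.synthetic import gen_division_timings

        df = gen_division_timings(200, 17.0, 5.0, seed=5)
        recs = [
            DivisionRecord(r.embryo_id, r.treated_time_min, r.control_time_min)
            for r in df.itertuples()
        ]
        assert division_delay_stats(recs).mean_delay_min == pytest.approx(17.0, abs=1.0)

    def test_percent_cycle_increase(self):
        recs = [
            DivisionRecord("e1", 100.0, 83.0, treated_cycle_min=63.5, control_cycle_min=50.0),
            DivisionRecord("e2", 100.0, 83.0, treated_cycle_min=63.5, control_cycle_min=50.0),
        ]
        assert division_delay_stats(recs).percent_cycle_increase == pytest.approx(27.0)

    def test_percent_without_cycles_rejected(self):
        recs = [DivisionRecord("e1", 100.0, 83.0)]
        with pytest.raises(ValueError, match="cycle"):
            percent_cycle_increase(recs)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            division_delay_stats([])


class TestKineticsCurve:
    def test_single_embryo_unit_power_identity(self):
        s = pd.DataFrame({"time_h": [0, 1, 2], "fluorescence": [0.0, 5.0, 9.0]})
        out = kinetics_curve([s], laser_power_uw=1.0)
        assert np.allclose(out["normalized_intensity"], [0.0, 5.0, 9.0])

    def test_mean_across_embryos(self):
        t = [0, 1, 2]
        s1 = pd.DataFrame({"time_h": t, "fluorescence": [1.0, 2.0, 3.0]})
        s2 = pd.DataFrame({"time_h": t, "fluorescence": [3.0, 6.0, 9.0]})
        out = kinetics_curve([s1, s2], laser_power_uw=1.0)
        assert np.allclose(out["normalized_intensity"], [2.0, 4.0, 6.0])

    def test_power_normalization_five_fold(self):
        s = pd.DataFrame({"time_h": [0, 1], "fluorescence": [10.0, 20.0]})
        low = kinetics_curve([s], laser_power_uw=20.0)
        high = kinetics_curve([s], laser_power_uw=100.0)
        assert np.allclose(low["normalized_intensity"], 5.0 * high["normalized_intensity"])

    def test_mismatched_grid_rejected(self):
        s1 = pd.DataFrame({"time_h": [0.0, 1.0], "fluorescence": [1.0, 2.0]})
        s2 = pd.DataFrame({"time_h": [0.0, 1.5], "fluorescence": [1.0, 2.0]})
        with pytest.raises(ValueError, match="time grid"):
            kinetics_curve([s1, s2], laser_power_uw=1.0)

    def test_nearest_alignment_within_tolerance(self):
        s1 = pd.DataFrame({"time_h": [0.0, 1.0], "fluorescence": [1.0, 2.0]})
        s2 = pd.DataFrame({"time_h": [0.001, 0.999], "fluorescence": [3.0, 4.0]})
        out = kinetics_curve([s1, s2], laser_power_uw=1.0, time_tolerance_h=0.01)
        assert np.allclose(out["normalized_intensity"], [2.0, 3.0])
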