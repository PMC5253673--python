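"""Sensitivity fitting, ROI quantification, ratio inversion and mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irheat.heat_model import ThermalProfile
from irheat.io import disk_mask, rect_mask
from irheat.synthetic import default_scene, gen_calibration_series, gen_onoff_pair, sheet_scene
from irheat.thermometry import (
    CalibrationCurve,
    CellTempMeasurement,
    bin_by_distance,
    block_downsample,
    cell_delta_t,
    fit_sensitivity,
    invert_ratio,
    quantify_cell_fluorescence,
    temperature_map,
)


class TestFitSensitivity:
    def test_generator_round_trip_noiseless(self):
        """A noiseless series generated at 1.7%/C fits back to 1.7%/C."""
        scene = default_scene(shot_noise=False, read_noise_sd=0.0)
        temps = np.arange(15.0, 40.1, 2.5)
        stack, _ = gen_calibration_series(scene, 0.017, temps)
        cell = disk_mask(stack.shape[1:], (79.5, 79.5), 20)
        bg = rect_mask(stack.shape[1:], 2, 2, 20, 20)
        totals = [quantify_cell_fluorescence(img, cell, bg) for img in stack]
        calib = fit_sensitivity(temps, totals, 20.0)
        assert calib.sensitivity_per_c == pytest.approx(0.017, abs=1e-9)
        assert calib.fit_r_squared == pytest.approx(1.0)

    def test_constant_fluorescence_zero_sensitivity(self):
        temps = [15.0, 20.0, 25.0, 30.0]
        calib = fit_sensitivity(temps, [500.0] * 4, 20.0)
        assert calib.sensitivity_per_c == pytest.approx(0.0, abs=1e-12)

    def test_two_point_slope(self):
        # hand formula: s = (1 - F40/F20) / (40 - 20) with F normalized at 20
        f20, f40 = 1000.0, 1000.0 * (1 - 0.04 * 20)
        with pytest.warns(UserWarning, match="two-point"):
            calib = fit_sensitivity([20.0, 40.0], [f20, f40], 20.0)
        assert calib.sensitivity_per_c == pytest.approx(0.04, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(1e-3, 1e6))
    def test_invariant_to_uniform_rescaling(self, scale):
        temps = np.array([15.0, 20.0, 25.0, 30.0, 35.0])
        f = 800.0 * (1 - 0.02 * (temps - 20.0))
        s1 = fit_sensitivity(temps, f, 20.0).sensitivity_per_c
        s2 = fit_sensitivity(temps, f * scale, 20.0).sensitivity_per_c
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_identical_temperatures_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            fit_sensitivity([20.0, 20.0, 20.0], [1.0, 1.0, 1.0], 20.0)

    def test_nonpositive_fluorescence_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_sensitivity([15.0, 20.0, 25.0], [1.0, 0.0, -1.0], 20.0)

    def test_temperature_outside_window_rejected(self):
        with pytest.raises(ValueError, match="validity window"):
            fit_sensitivity([10.0, 20.0, 30.0], [1.0, 1.0, 1.0], 20.0)


class TestQuantifyCellFluorescence:
    def test_uniform_image_zero_signal(self):
        img = np.full((10, 10), 10.0)
        cell = rect_mask(img.shape, 0, 0, 3, 3)
        bg = rect_mask(img.shape, 6, 6, 3, 3)
        with pytest.warns(UserWarning, match="background"):
            assert quantify_cell_fluorescence(img, cell, bg) == pytest.approx(0.0)

    def test_known_total(self):
        img = np.full((20, 20), 10.0)
        cell = rect_mask(img.shape, 0, 0, 5, 5)  # 25 pixels
        img[cell] = 100.0
        bg = rect_mask(img.shape, 10, 10, 5, 5)
        assert quantify_cell_fluorescence(img, cell, bg) == pytest.approx((100 - 10) * 25)

    def test_empty_background_roi(self):
        img = np.ones((5, 5))
        with pytest.raises(ValueError, match="background ROI is empty"):
            quantify_cell_fluorescence(img, np.ones_like(img, bool), np.zeros_like(img, bool))

    def test_overlapping_rois_rejected(self):
        img = np.ones((5, 5))
        m = rect_mask(img.shape, 0, 0, 3, 3)
        with pytest.raises(ValueError, match="overlap"):
            quantify_cell_fluorescence(img, m, m)


class TestRatioInversion:
    def test_unity_ratio_zero_elevation(self, calibration):
        m = CellTempMeasurement("c", (0, 0), 0.0, f_on=500.0, f_off=500.0)
        assert cell_delta_t(m, calibration, 20.0) == pytest.approx(0.0)

    def test_known_ratio_five_degrees(self, calibration):
        # (1 - 0.915) / 0.017 = 5.0 at the anchor
        m = CellTempMeasurement("c", (0, 0), 0.0, f_on=915.0, f_off=1000.0)
        assert cell_delta_t(m, calibration, 20.0) == pytest.approx(5.0, abs=1e-12)

    def test_apparent_cooling_flagged_not_raised(self, calibration):
        m = CellTempMeasurement("c", (0, 0), 0.0, f_on=1017.0, f_off=1000.0)
        with pytest.warns(UserWarning, match="cooling"):
            dt = cell_delta_t(m, calibration, 20.0)
        assert dt == pytest.approx(-1.0, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(
        delta_t=st.floats(0.0, 25.0),
        s=st.floats(0.005, 0.05),
        base=st.floats(15.0, 30.0),
    )
    def test_forward_inverse_round_trip(self, delta_t, s, base):
        """Forward ratio generation then inversion recovers dT exactly."""
        calib = CalibrationCurve(s, 20.0, (10.0, 60.0), 1.0, 5)
        f = lambda t: 1.0 - s * (t - 20.0)
        if f(base + delta_t) <= 0:
            return
        ratio = f(base + delta_t) / f(base)
        assert invert_ratio(ratio, calib, base) == pytest.approx(delta_t, abs=1e-9)

    def test_naive_matches_anchored_at_reference(self, calibration):
        assert invert_ratio(0.9, calibration, 20.0, naive=True) == pytest.approx(
            invert_ratio(0.9, calibration, 20.0)
        )

    def test_monotone_larger_decrease_larger_elevation(self, calibration):
        ratios = np.linspace(0.99, 0.70, 30)
        dts = invert_ratio(ratios, calibration, 20.0)
        assert np.all(np.diff(dts) > 0)


class TestTemperatureMap:
    def test_identical_images_all_zero(self, calibration):
        rng = np.random.default_rng(0)
        img = 100.0 + 900.0 * (rng.random((60, 60)) > 0.2)
        bg = rect_mask(img.shape, 0, 0, 10, 10)
        img[bg] = 100.0
        tmap = temperature_map(img, img, calibration, 20.0, background_mask=bg)
        assert np.allclose(tmap.delta_t_c[tmap.valid], 0.0)

    def test_uniform_ratio_ten_degrees(self, calibration):
        off = np.full((30, 30), 1000.0)
        on = np.full((30, 30), 830.0)
        bg = rect_mask(off.shape, 0, 0, 3, 3)
        on[bg] = off[bg] = 0.0
        tmap = temperature_map(on, off, calibration, 20.0, background_mask=bg)
        assert np.nanmax(np.abs(tmap.delta_t_c[tmap.valid] - 10.0)) < 1e-9

    def test_noiseless_pair_peak_near_focus(self, profile, calibration):
        scene = sheet_scene(shot_noise=False, read_noise_sd=0.0)
        on, off, truth = gen_onoff_pair(scene, profile, (20.0, 20.0), 3.5, 0.017)
        bg = rect_mask(on.shape, 0, 0, 8, 8)
        tmap = temperature_map(
            on, off, calibration, 20.0, pixel_size_um=scene.pixel_size_um, background_mask=bg
        )
        assert np.nanmax(tmap.delta_t_c[tmap.valid]) == pytest.approx(14.0, abs=0.3)

    def test_shape_mismatch_rejected(self, calibration):
        with pytest.raises(ValueError, match="shape"):
            temperature_map(np.ones((4, 4)), np.ones((5, 5)), calibration, 20.0)

    def test_base_temp_outside_range_rejected(self, calibration):
        with pytest.raises(ValueError, match="outside calibration range"):
            temperature_map(np.ones((6, 6)), np.ones((6, 6)), calibration, 50.0)

    def test_block_downsample_drops_remainder(self):
        img = np.arange(49, dtype=float).reshape(7, 7)
        out = block_downsample(img, 3)
        assert out.shape == (2, 2)
        assert out[0, 0] == pytest.approx(img[:3, :3].mean())


class TestBinByDistance:
    def test_single_measurement(self):
        import pandas as pd

        df = pd.DataFrame({"distance_um": [1.5], "delta_t_c": [5.0]})
        out = bin_by_distance(df)
        assert len(out) == 1
        assert out["sd_delta_t_c"].iloc[0] == 0.0
        assert out["n"].iloc[0] == 1

    def test_same_bin_averaged(self):
        import pandas as pd

        df = pd.DataFrame({"distance_um": [1.0, 1.9], "delta_t_c": [4.0, 6.0]})
        out = bin_by_distance(df, 2.0)
        assert len(out) == 1
        assert out["mean_delta_t_c"].iloc[0] == pytest.approx(5.0)

    def test_half_open_boundary(self):
        import pandas as pd

        df = pd.DataFrame({"distance_um": [1.9, 2.0], "delta_t_c": [4.0, 6.0]})
        out = bin_by_distance(df, 2.0)
        assert len(out) == 2
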