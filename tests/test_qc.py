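"""Quality-control procedures: radial profiling, temporal consistency,
band sensitivity, intensity adjustment and FWHM estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ledmsi as L
from ledmsi.qc import ADJUST_SAFETY

from conftest import (SIZE, brute_radial_profile, brute_roi_mean, flat_device,
                      get_band)


def _img(array):
    return L.BandImage(np.asarray(array, dtype=np.uint8), "test")


class TestRadialProfile:
    def test_uniform_image_constant_mgv_zero_sd(self):
        profile = L.radial_profile(np.full((64, 64), 200, dtype=np.uint8),
                                   (31.5, 31.5), step_mm=0.5, max_radius_mm=7.0,
                                   pixel_pitch_mm=0.25)
        valid = ~np.isnan(profile.mgv)
        assert np.allclose(profile.mgv[valid], 200.0)
        assert np.allclose(profile.sd[valid], 0.0)

    def test_default_profile_ends_at_70_mm(self):
        img = np.full((64, 64), 10, dtype=np.uint8)
        profile = L.radial_profile(img, (31.5, 31.5), pixel_pitch_mm=0.25)
        assert profile.radii_mm[-1] == pytest.approx(70.0)
        assert profile.radii_mm[0] == pytest.approx(0.1)
        assert len(profile.radii_mm) == 700

    def test_central_bright_pixel_mgv_decreases(self):
        img = np.zeros((33, 33), dtype=np.uint8)
        img[16, 16] = 255
        profile = L.radial_profile(img, (16.0, 16.0), step_mm=0.25,
                                   max_radius_mm=3.0, pixel_pitch_mm=0.25)
        mgv = profile.mgv[~np.isnan(profile.mgv)]
        assert np.all(np.diff(mgv) <= 0) and mgv[0] > mgv[-1]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_pixel_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        center = (float(rng.uniform(4, 27)), float(rng.uniform(4, 27)))
        profile = L.radial_profile(img, center, step_mm=0.33,
                                   max_radius_mm=5.0, pixel_pitch_mm=0.4)
        radii, mgv, sd = brute_radial_profile(img, center, 0.33, 5.0, 0.4)
        np.testing.assert_allclose(profile.radii_mm, radii)
        np.testing.assert_allclose(profile.mgv, mgv, atol=1e-9)
        np.testing.assert_allclose(profile.sd, sd, atol=1e-8)

    def test_sub_pixel_max_radius_rejected(self):
        with pytest.raises(ValueError, match="smaller than one pixel"):
            L.radial_profile(np.zeros((8, 8), dtype=np.uint8), (4, 4),
                             max_radius_mm=0.1, pixel_pitch_mm=0.25)


class TestConsistencyStats:
    ROI = L.CircularROI((15.5, 15.5), 10.0)

    def test_identical_frames_have_zero_relative_sd(self):
        frames = [_img(np.full((32, 32), 80))] * 100
        stats = L.consistency_stats(frames, self.ROI)
        assert stats.sd_pct == 0.0 and stats.n_frames == 100

    def test_two_frame_hand_computation(self):
        frames = [_img(np.full((32, 32), 100)), _img(np.full((32, 32), 102))]
        stats = L.consistency_stats(frames, self.ROI)
        assert stats.mean_mgv == pytest.approx(101.0)
        assert stats.sd_mgv == pytest.approx(math.sqrt(2.0))
        assert stats.sd_pct == pytest.approx(100.0 * math.sqrt(2.0) / 101.0)

    def test_invariant_to_frame_order(self):
        rng = np.random.default_rng(0)
        frames = [_img(rng.integers(50, 90, (32, 32))) for _ in range(8)]
        a = L.consistency_stats(frames, self.ROI)
        b = L.consistency_stats(frames[::-1], self.ROI)
        assert (a.mean_mgv, a.sd_mgv) == (b.mean_mgv, b.sd_mgv)

    def test_zero_mean_rejected(self):
        frames = [_img(np.zeros((32, 32)))] * 3
        with pytest.raises(ValueError, match="relative SD undefined"):
            L.consistency_stats(frames, self.ROI)

    def test_simulated_pink_disk_run_stays_below_half_percent(self):
        scene = L.make_fixture("pink_disk", size_px=SIZE)
        device = L.SimulatedDevice(scene)
        frames = [L.capture_band(device, get_band("525"), seed=s)
                  for s in range(100)]
        roi = L.CircularROI((79.5, 79.5), 60.0)
        stats = L.consistency_stats(frames, roi)
        assert stats.sd_pct <= L.CONSISTENCY_SD_PCT_BOUND
        assert stats.within_bound


class TestBandSensitivity:
    ROI = L.CircularROI((79.5, 79.5), 60.0)

    def test_curve_bounded_and_flags_saturation(self, crs_device):
        bands = [get_band(n) for n in ("632", "950")]
        curve = L.band_sensitivity(crs_device, bands, self.ROI, seed=0)
        by_name = {e.band_name: e for e in curve.entries}
        assert all(0 <= e.mgv <= 255 for e in curve.entries)
        assert by_name["632"].saturated      # high gain x high sensitivity
        assert not by_name["950"].saturated  # NIR roll-off

    def test_forced_double_full_scale_reads_255(self):
        device = flat_device(510.0)
        device.sensor.dark_offset = 0.0
        curve = L.band_sensitivity(device, [get_band("632")], self.ROI, seed=0)
        assert curve.entries[0].saturated
        assert curve.entries[0].mgv == 255.0

    def test_zero_duty_reads_near_zero(self, crs_device):
        band = get_band("632").with_duty(0.0)
        curve = L.band_sensitivity(crs_device, [band], self.ROI, seed=0)
        assert not curve.entries[0].saturated
        assert curve.entries[0].mgv < 1.0

    def test_empty_band_list_rejected(self, crs_device):
        with pytest.raises(ValueError):
            L.band_sensitivity(crs_device, [], self.ROI)


class TestAdjustIntensity:
    ROI = L.CircularROI((79.5, 79.5), 60.0)

    def test_band_already_below_target_unchanged(self):
        device = flat_device(180.0)
        result = L.adjust_intensity(device, get_band("632"), self.ROI)
        assert result.duty == 1.0
        assert result.iterations == 1
        assert result.mgv == pytest.approx(180.0)

    def test_saturated_band_converges_below_240(self, crs_device):
        band = get_band("632")  # saturates the CRS at duty 1
        result = L.adjust_intensity(crs_device, band, self.ROI, seed=4)
        assert result.mgv < 240.0
        assert result.iterations <= 8
        assert result.duty < 1.0

    def test_duty_monotonically_decreases(self, crs_device):
        result = L.adjust_intensity(crs_device, get_band("632"), self.ROI,
                                    seed=4)
        duties = [d for d, _ in result.history]
        assert all(d1 >= d2 for d1, d2 in zip(duties, duties[1:]))

    def test_linear_noiseless_one_step_closed_form(self):
        """After the first unsaturated measurement m the rule lands on
        duty * 0.98 * 240 / m, which a linear sensor maps below target."""
        device = flat_device(250.0)  # unsaturated but above target
        result = L.adjust_intensity(device, get_band("632"), self.ROI)
        assert result.iterations == 2
        expected_duty = 1.0 * ADJUST_SAFETY * 240.0 / 250.0
        assert result.duty == pytest.approx(expected_duty)
        assert result.mgv == pytest.approx(round(250.0 * expected_duty), abs=0.5)
        assert result.mgv < 240.0

    def test_deeply_saturated_band_raises_calibration_error(self):
        # ~40x full scale stays saturated through 3 back-off steps.
        device = flat_device(10000.0)
        with pytest.raises(L.CalibrationError) as err:
            L.adjust_intensity(device, get_band("632"), self.ROI, max_iter=3)
        assert err.value.iterations == 3

    def test_bad_target_rejected(self, crs_device):
        with pytest.raises(ValueError):
            L.adjust_intensity(crs_device, get_band("632"), self.ROI,
                               target_mgv=300.0)


class TestEstimateFwhm:
    def test_gaussian_recovers_configured_width(self):
        band = L.SpectralBand("632", 632.0, 10.0)
        grid = np.arange(550.0, 700.05, 0.1)
        width = L.estimate_fwhm(grid, L.led_emission_spectrum(band, grid))
        assert width == pytest.approx(10.0, abs=0.1)

    def test_rectangular_pulse_width(self):
        grid = np.arange(0.0, 100.5, 0.5)
        y = ((grid >= 40.0) & (grid <= 60.0)).astype(float)
        assert L.estimate_fwhm(grid, y) == pytest.approx(20.0, abs=0.5)

    def test_asymmetric_triangle_matches_fine_grid_oracle(self):
        def triangle(x):
            return np.clip(np.where(x < 500.0, (x - 480.0) / 20.0,
                                    (530.0 - x) / 30.0), 0.0, None)

        coarse = np.arange(470.0, 540.5, 0.5)
        est = L.estimate_fwhm(coarse, triangle(coarse))
        fine = np.arange(470.0, 540.001, 0.001)
        yf = triangle(fine)
        above = fine[yf >= yf.max() / 2.0]
        oracle = above.max() - above.min()
        assert est == pytest.approx(oracle, abs=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(1e-3, 1e3))
    def test_invariant_to_intensity_rescaling(self, scale):
        band = L.SpectralBand("560", 560.0, 12.0)
        grid = np.arange(500.0, 620.1, 0.2)
        y = L.led_emission_spectrum(band, grid)
        assert L.estimate_fwhm(grid, scale * y) == pytest.approx(
            L.estimate_fwhm(grid, y), rel=1e-9)

    def test_truncated_peak_rejected(self):
        grid = np.arange(630.0, 700.0, 0.5)  # left flank cut off
        band = L.SpectralBand("632", 632.0, 10.0)
        with pytest.raises(ValueError, match="truncated"):
            L.estimate_fwhm(grid, L.led_emission_spectrum(band, grid))
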