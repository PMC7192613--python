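"""Background subtraction, spline smoothing, interval resampling, cutoff."""

import numpy as np
import pytest

import rgelquant as rg
from rgelquant.densitometry import determine_cutoff, resample_intervals


def _bands_profile(noise_sd=0.0, baseline=None, seed=0, step=0.1, length=100.0):
    """A few Gaussian bands on an optional baseline; returns (profile, band truth)."""
    rng = np.random.default_rng(seed)
    d = np.arange(0.0, length + step / 2, step)
    y = np.zeros_like(d)
    bands = [(25.0, 4.0, 4000.0), (45.0, 5.0, 9000.0), (62.0, 4.0, 3000.0)]
    for c, s, area in bands:
        y += area / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((d - c) / s) ** 2)
    truth = y.copy()
    if baseline is not None:
        y = y + baseline(d)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, d.size)
    return rg.IntensityProfile(d, y), truth


class TestSubtractBackground:
    def test_constant_offset_recovered(self):
        profile, truth = _bands_profile(baseline=lambda d: np.full_like(d, 7.0))
        out = rg.subtract_background(profile, method="constant")
        np.testing.assert_allclose(out.intensities, truth, atol=1e-9)

    def test_all_zero_profile_stays_zero(self):
        profile = rg.IntensityProfile(np.arange(0.0, 10.0, 0.1), np.zeros(100))
        out = rg.subtract_background(profile, method="constant")
        assert np.all(out.intensities == 0)
        out = rg.subtract_background(profile, method="linear_baseline")
        np.testing.assert_allclose(out.intensities, 0, atol=1e-9)

    def test_linear_baseline_band_integral_within_2pct(self):
        profile, truth = _bands_profile(noise_sd=2.0, seed=5,
                                        baseline=lambda d: 12.0 - 0.08 * d)
        out = rg.subtract_background(profile, method="linear_baseline")
        band = (profile.distances > 10) & (profile.distances < 80)
        est = np.trapezoid(out.intensities[band], profile.distances[band])
        ref = np.trapezoid(truth[band], profile.distances[band])
        assert est == pytest.approx(ref, rel=0.02)

    def test_empty_lane_method(self):
        profile, truth = _bands_profile(baseline=lambda d: 3.0 + 0.05 * d)
        empty = rg.IntensityProfile(profile.distances, 3.0 + 0.05 * profile.distances)
        out = rg.subtract_background(profile, method="empty_lane", empty=empty)
        np.testing.assert_allclose(out.intensities, truth, atol=1e-9)
        with pytest.raises(ValueError, match="empty"):
            rg.subtract_background(profile, method="empty_lane")

    def test_never_negative(self):
        profile, _ = _bands_profile(noise_sd=3.0, seed=2)
        out = rg.subtract_background(profile, method="linear_baseline")
        assert out.intensities.min() >= 0


class TestSmoothProfile:
    def test_reproduces_cubic_polynomial(self):
        d = np.arange(0.0, 50.0, 0.1)
        y = 1e-3 * (d - 10) ** 3 + 0.2 * d + 50  # nonnegative cubic
        profile = rg.IntensityProfile(d, y)
        out = rg.smooth_profile(profile)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-6, atol=1e-6)

    def test_constant_profile_unchanged(self):
        profile = rg.IntensityProfile(np.arange(0.0, 30.0, 0.1), np.full(300, 4.0))
        out = rg.smooth_profile(profile)
        np.testing.assert_allclose(out.intensities, 4.0, rtol=1e-9)

    def test_noisy_lane_integral_within_3pct(self):
        profile, truth = _bands_profile(noise_sd=3.0, seed=7)
        out = rg.smooth_profile(rg.subtract_background(profile, method="linear_baseline"))
        assert out.integral() == pytest.approx(np.trapezoid(truth, profile.distances), rel=0.03)

    def test_near_idempotent(self):
        """Re-smoothing a smoothed lane changes its integral by < 1%.

        Exact idempotence is broken by the clip at zero and by re-derived
        knot positions; the integral must still be essentially unchanged.
        """
        profile, _ = _bands_profile(noise_sd=3.0, seed=3)
        once = rg.smooth_profile(profile)
        twice = rg.smooth_profile(once)
        assert twice.integral() == pytest.approx(once.integral(), rel=0.01)

    def test_too_few_samples_rejected(self):
        profile = rg.IntensityProfile(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="at least"):
            rg.smooth_profile(profile, n_knots=15)

    def test_uniform_placement_option(self):
        profile, _ = _bands_profile(noise_sd=1.0, seed=4)
        out = rg.smooth_profile(profile, placement="uniform")
        assert out.integral() == pytest.approx(profile.integral(), rel=0.05)


class TestResampleIntervals:
    def _flat(self, value=1.0, length=10.0, step=0.01):
        d = np.arange(0.0, length + step / 2, step)
        return rg.IntensityProfile(d, np.full(d.size, value))

    def test_constant_lane_unit_intervals(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        series = resample_intervals(self._flat(), cal, delta_d=1.0)
        assert series.mid.size == 10
        np.testing.assert_allclose(series.intensity, 1.0, rtol=1e-9)

    def test_midpoint_size_uses_calibration(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        series = resample_intervals(self._flat(length=20.0), cal, delta_d=1.0)
        np.testing.assert_allclose(series.size, cal.size_at(series.mid), rtol=1e-12)

    def test_total_intensity_matches_trapezoid(self, sim_gel):
        cal = sim_gel["cal"]
        smoothed = rg.smooth_profile(
            rg.subtract_background(sim_gel["lane"], empty=sim_gel["empty"]))
        series = resample_intervals(smoothed, cal, delta_d=1.0)
        covered = smoothed.distances <= series.mid[-1] + series.width / 2
        ref = np.trapezoid(smoothed.intensities[covered], smoothed.distances[covered])
        assert series.intensity.sum() == pytest.approx(ref, rel=0.01)

    def test_invalid_width_rejected(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        with pytest.raises(ValueError, match="delta_d"):
            resample_intervals(self._flat(), cal, delta_d=0.0)

    def test_halving_delta_d_preserves_estimate(self, sim_gel):
        """Interval width cancels downstream: N changes < 1% between 1 and 0.5 mm."""
        cal, empty = sim_gel["cal"], sim_gel["empty"]
        smoothed = rg.smooth_profile(rg.subtract_background(sim_gel["lane"], empty=empty))
        out = {}
        for delta in (1.0, 0.5):
            series = resample_intervals(smoothed, cal, delta_d=delta)
            series = determine_cutoff(series, sim_gel["lane"], empty)
            table = rg.normalize_per_gb(rg.counts_from_intensity(series))
            out[delta] = rg.estimate_total(table).n_prelim
        assert out[0.5] == pytest.approx(out[1.0], rel=0.01)


class TestDetermineCutoff:
    def _series(self, cal, length=100.0):
        d = np.arange(0.0, length, 0.1)
        profile = rg.IntensityProfile(d, np.ones(d.size))
        return resample_intervals(profile, cal, delta_d=1.0), profile

    def test_identical_lanes_cut_everything(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        rng = np.random.default_rng(0)
        d = np.arange(0.0, 100.0, 0.1)
        noise = rng.normal(0, 2, d.size)
        lane = rg.IntensityProfile(d, noise.copy())
        empty = rg.IntensityProfile(d, noise.copy())
        series, _ = self._series(cal)
        series = determine_cutoff(series, lane, empty)
        assert series.d_max == pytest.approx(d[0])
        assert series.excluded.all()

    def test_unreachable_threshold_keeps_everything(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        rng = np.random.default_rng(0)
        d = np.arange(0.0, 100.0, 0.1)
        lane = rg.IntensityProfile(d, rng.normal(10, 2, d.size))
        empty = rg.IntensityProfile(d, rng.normal(0, 2, d.size))
        series, _ = self._series(cal)
        series = determine_cutoff(series, lane, empty, ratio_threshold=0.0)
        assert series.d_max == pytest.approx(d[-1])
        assert not series.excluded.any()

    def test_cutoff_follows_band_end(self):
        """Bands ending near 60 mm put d_max within a window of 60 mm."""
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        rng = np.random.default_rng(1)
        d = np.arange(0.0, 100.0, 0.1)
        signal = 200.0 * np.exp(-0.5 * ((d - 40) / 6) ** 2)
        signal[d > 60] = 0.0
        lane = rg.IntensityProfile(d, signal + rng.normal(0, 2, d.size))
        empty = rg.IntensityProfile(d, rng.normal(0, 2, d.size))
        series, _ = self._series(cal)
        series = determine_cutoff(series, lane, empty, window=3.0)
        assert 52.0 <= series.d_max <= 66.0

    def test_manual_override(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        series, profile = self._series(cal)
        series = determine_cutoff(series, profile, manual_dmax=42.0)
        assert series.d_max == 42.0
        assert series.sz_min == pytest.approx(cal.size_at(42.0))
        assert np.array_equal(series.excluded, series.mid > 42.0)

    def test_szmin_strictly_decreasing_in_dmax(self):
        cal = rg.LadderCalibration(a=180.0, b=-13.0)
        series, profile = self._series(cal)
        sz = [determine_cutoff(series, profile, manual_dmax=dm).sz_min
              for dm in (30.0, 50.0, 70.0, 90.0)]
        assert np.all(np.diff(sz) < 0)
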