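import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enfaceoct.rpe_segmentation import (
    SegmentationParams,
    InsufficientPeaksError,
    BScanSegmentationError,
    smooth_ascan,
    detect_two_peaks,
    initial_rpe_bscan,
    median_smooth_depths,
    refine_rpe_bscan,
    segment_volume,
)
from enfaceoct.synthetic_data import make_phantom, apply_axial_shifts
from conftest import small_params
from _oracles import (
    moving_average_oracle,
    running_median_oracle,
    top_two_peaks_oracle,
    windowed_argmax_oracle,
)


def gaussian_bump(n, center, height, sigma=3.0):
    z = np.arange(n)
    return height * np.exp(-((z - center) ** 2) / (2 * sigma ** 2))


class TestSmoothAscan:
    def test_constant_profile_unchanged(self):
        np.testing.assert_allclose(smooth_ascan(np.full(20, 7.5), 5),
                                   np.full(20, 7.5))

    def test_window_one_is_identity(self, rng):
        p = rng.uniform(0, 100, 30)
        np.testing.assert_allclose(smooth_ascan(p, 1), p)

    def test_unit_impulse_window_three(self):
        p = np.zeros(11)
        p[5] = 1.0
        expected = np.zeros(11)
        expected[4:7] = 1 / 3
        np.testing.assert_allclose(smooth_ascan(p, 3), expected)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_ascan(np.zeros(10), window)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_output_within_input_range(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 255, r.integers(7, 64))
        w = int(r.choice([3, 5, 7]))
        out = smooth_ascan(p, w)
        assert out.min() >= p.min() - 1e-9 and out.max() <= p.max() + 1e-9


class TestDetectTwoPeaks:
    def test_two_gaussian_bumps(self):
        p = gaussian_bump(100, 20, 10) + gaussian_bump(100, 60, 8)
        assert detect_two_peaks(p, min_sep=5) == (20, 60)

    def test_monotone_profile_has_no_peaks(self):
        with pytest.raises(InsufficientPeaksError) as exc:
            detect_two_peaks(np.arange(50, dtype=float), min_sep=5)
        assert exc.value.found == 0

    def test_three_bumps_picks_two_highest(self):
        p = (gaussian_bump(90, 10, 5) + gaussian_bump(90, 40, 9)
             + gaussian_bump(90, 70, 7))
        assert detect_two_peaks(p, min_sep=5) == (40, 70)

    def test_min_sep_excludes_close_pair(self):
        p = gaussian_bump(100, 40, 9, 2.0) + gaussian_bump(100, 48, 8, 2.0)
        with pytest.raises(InsufficientPeaksError):
            detect_two_peaks(p, min_sep=20)

    def test_plateau_takes_first_index(self):
        p = np.array([0, 1, 5, 5, 5, 1, 0, 2, 8, 2], dtype=float)
        assert detect_two_peaks(p, min_sep=3) == (2, 8)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_greedy_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = np.round(r.uniform(0, 50, r.integers(8, 64)), 1)
        min_sep = int(r.integers(1, 10))
        expected = top_two_peaks_oracle(p, min_sep)
        if expected is None:
            with pytest.raises(InsufficientPeaksError):
                detect_two_peaks(p, min_sep)
        else:
            assert detect_two_peaks(p, min_sep) == expected


class TestMedianSmooth:
    def test_constant_unchanged(self):
        np.testing.assert_array_equal(
            median_smooth_depths(np.full(9, 55), 5), np.full(9, 55))

    def test_spike_removed(self):
        np.testing.assert_array_equal(
            median_smooth_depths(np.array([55, 55, 90, 55, 55]), 3),
            np.full(5, 55))

    def test_window_one_is_identity(self, rng):
        d = rng.integers(0, 200, 40)
        np.testing.assert_array_equal(median_smooth_depths(d, 1), d)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth_depths(np.arange(5), 4)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_running_median_oracle_and_membership(self, seed):
        r = np.random.default_rng(seed)
        d = r.integers(0, 100, r.integers(1, 40))
        w = int(r.choice([1, 3, 5, 7, 15]))
        out = median_smooth_depths(d, w)
        np.testing.assert_array_equal(out, running_median_oracle(d, w))
        half = w // 2
        for i, v in enumerate(out):
            assert v in d[max(0, i - half): i + half + 1]


class TestRefine:
    def test_estimate_on_unique_maximum_unchanged(self):
        bscan = np.zeros((40, 3))
        bscan[25, :] = 10
        est = np.full(3, 25)
        np.testing.assert_array_equal(refine_rpe_bscan(bscan, est, 10), est)

    def test_recovers_offset_maximum(self):
        bscan = np.zeros((40, 4))
        bscan[30, :] = 10
        np.testing.assert_array_equal(
            refine_rpe_bscan(bscan, np.full(4, 27), 10), np.full(4, 30))

    def test_never_leaves_window(self):
        bscan = np.zeros((60, 2))
        bscan[50, :] = 99  # brightest pixel 30 px from the estimate
        out = refine_rpe_bscan(bscan, np.full(2, 20), 10)
        assert np.all(np.abs(out - 20) <= 10)

    def test_tie_breaks_toward_estimate_then_smaller_z(self):
        bscan = np.zeros((30, 2))
        bscan[[10, 14], 0] = 5  # equidistant from estimate 12 -> smaller z
        bscan[[11, 14], 1] = 5  # 11 is closer to 12 than 14
        out = refine_rpe_bscan(bscan, np.array([12, 12]), 10)
        np.testing.assert_array_equal(out, [10, 11])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_windowed_argmax_oracle(self, seed):
        r = np.random.default_rng(seed)
        nz, nx = int(r.integers(8, 40)), int(r.integers(1, 8))
        bscan = r.integers(0, 8, (nz, nx)).astype(float)  # ties likely
        est = r.integers(0, nz, nx)
        radius = int(r.integers(0, 12))
        np.testing.assert_array_equal(
            refine_rpe_bscan(bscan, est, radius),
            windowed_argmax_oracle(bscan, est, radius))


class TestInitialBscan:
    def make_bscan(self, nz=80, nx=12, nfl=15, rpe=55):
        # bands at least as wide as the smoothing window with a unique apex,
        # so the smoothed profile has a single maximum per band
        bscan = np.full((nz, nx), 2.0)
        bscan[nfl - 3:nfl + 4] = np.array(
            [15, 40, 70, 120, 70, 40, 15], float)[:, None]
        bscan[rpe - 3:rpe + 4] = np.array(
            [20, 60, 100, 160, 100, 60, 20], float)[:, None]
        return bscan

    def test_phantom_bands_found(self):
        bscan = self.make_bscan()
        np.testing.assert_array_equal(
            initial_rpe_bscan(bscan, SegmentationParams(min_peak_separation_px=20)),
            np.full(12, 55))

    def test_flat_column_interpolated_from_neighbors(self):
        bscan = self.make_bscan()
        bscan[:, 5] = 0.0
        out = initial_rpe_bscan(bscan, SegmentationParams())
        assert out[5] == 55

    def test_all_zero_bscan_fails(self):
        with pytest.raises(BScanSegmentationError):
            initial_rpe_bscan(np.zeros((50, 6)), SegmentationParams())


class TestSegmentVolume:
    def test_noiseless_phantom_recovered_exactly(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        surf = segment_volume(vol)
        np.testing.assert_array_equal(surf.z_rpe, gt.true_rpe)
        assert surf.stage == "final"

    def test_axial_shift_equivariance(self, noiseless_phantom, rng):
        vol, gt = noiseless_phantom
        shifts = rng.integers(-15, 16, vol.n_bscans)
        shifted = apply_axial_shifts(vol, shifts)
        np.testing.assert_array_equal(
            segment_volume(shifted).z_rpe,
            segment_volume(vol).z_rpe + shifts[:, None])

    def test_refinement_containment(self, speckled_phantom):
        vol, _ = speckled_phantom
        params = SegmentationParams()
        for b in range(0, vol.n_bscans, 7):
            bscan = vol.bscan(b)
            est = median_smooth_depths(initial_rpe_bscan(bscan, params),
                                       params.median_window_ascans)
            refined = refine_rpe_bscan(bscan, est, params.refine_radius_px)
            assert np.all(np.abs(refined - est) <= params.refine_radius_px)

    def test_deterministic(self, speckled_phantom):
        vol, _ = speckled_phantom
        a = segment_volume(vol).z_rpe
        b = segment_volume(vol).z_rpe
        np.testing.assert_array_equal(a, b)

    def test_failure_reports_bscan_index(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        data = vol.intensity.copy()
        data[:, :, 3] = 0.0
        with pytest.raises(BScanSegmentationError, match="b=3"):
            segment_volume(vol.with_intensity(data))
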