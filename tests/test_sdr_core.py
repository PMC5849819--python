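"""Unit and property tests for the three-path SDR detection core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sdrmon import (AlgorithmParams, BackgroundModel, DefectSpec, ImageStack,
                    PeakSet, baseline_subtract, blue_path, column_wise_mean,
                    combine_paths, compute_sdr_curve, detect_peaks,
                    gaussian_peak_vector, generate_stack, green_path,
                    median_image, red_path, sdr_area, subtract_row_means)
from sdrmon.extraction import TransducerProfile

from oracles import baseline_oracle, median_oracle, peak_scan_oracle, trapz_oracle


# ---------------------------------------------------------------------------
# parameters


class TestAlgorithmParams:
    def test_defaults_are_the_published_operating_point(self):
        p = AlgorithmParams()
        assert (p.n_stack, p.n_select, p.n_rep) == (150, 15, 100)
        assert (p.r_upper, p.r_lower) == (1, 19)
        assert (p.o_poly_green, p.o_poly_red) == (6, 6)
        assert (p.t_green, p.t_red, p.t_blue) == (2, 5, 10)
        assert (p.p_include, p.p_exclude) == (25, 2)

    @pytest.mark.parametrize("kwargs", [
        dict(n_select=200),            # exceeds n_stack
        dict(r_upper=5, r_lower=2),    # inverted band
        dict(t_green=0),               # non-positive threshold
        dict(p_include=10, p_exclude=20),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlgorithmParams(**kwargs)


# ---------------------------------------------------------------------------
# elementary operations


class TestRowMeanSubtraction:
    def test_constant_frame_becomes_zero(self):
        stack = ImageStack(np.full((3, 4, 5), 42.0))
        out = subtract_row_means(stack)
        assert np.all(out.frames == 0)

    def test_simple_row(self):
        stack = ImageStack(np.array([[[10.0, 20.0, 30.0]]]))
        out = subtract_row_means(stack)
        np.testing.assert_allclose(out.frames[0, 0], [-10, 0, 10])

    @given(hnp.arrays(float, (2, 5, 7), elements=st.floats(0, 255)))
    def test_every_row_sums_to_zero(self, frames):
        out = subtract_row_means(ImageStack(frames))
        np.testing.assert_allclose(out.frames.sum(axis=2), 0, atol=1e-9)


class TestMedianImage:
    def test_identical_frames_fixed_point(self, rng):
        f = rng.uniform(0, 255, (6, 8))
        np.testing.assert_array_equal(median_image([f, f, f]), f)

    def test_three_values(self):
        frames = [np.full((1, 1), v) for v in (1.0, 9.0, 2.0)]
        assert median_image(frames)[0, 0] == 2

    def test_even_count_averages_middle_two(self):
        frames = [np.full((1, 1), v) for v in (1.0, 2.0, 8.0, 9.0)]
        assert median_image(frames)[0, 0] == 5.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            median_image([])

    def test_matches_sort_and_pick_oracle(self, rng):
        for _ in range(30):
            frames = rng.uniform(0, 255, (rng.integers(1, 9), 5, 6))
            np.testing.assert_allclose(median_image(frames),
                                       median_oracle(frames))


class TestColumnWiseMean:
    def test_constant_image(self):
        assert np.all(column_wise_mean(np.full((10, 4), 7.0), 1, 3) == 7.0)

    def test_single_row_band_is_that_row(self, rng):
        img = rng.uniform(0, 9, (8, 5))
        np.testing.assert_array_equal(column_wise_mean(img, 3, 3), img[2])

    def test_default_band_covers_19_rows(self):
        p = AlgorithmParams()
        img = np.zeros((500, 4))
        img[:19] = 1.0  # rows 1..19, 1-based
        np.testing.assert_allclose(
            column_wise_mean(img, p.r_upper, p.r_lower), 1.0)
        assert p.band_rows == 19

    def test_band_outside_image_errors(self):
        with pytest.raises(ValueError):
            column_wise_mean(np.zeros((10, 4)), 1, 19)


class TestBaselineSubtract:
    def test_polynomial_is_removed_exactly(self, rng):
        x = np.linspace(-1, 1, 120)
        curve = 3 - 2 * x + 0.5 * x**4 - x**6
        resid = baseline_subtract(curve, 6)
        assert np.max(np.abs(resid)) < 1e-8 * np.ptp(curve)

    def test_constant_curve_zero_residual(self):
        np.testing.assert_allclose(baseline_subtract(np.full(50, 9.0), 6), 0,
                                   atol=1e-9)

    def test_spike_on_polynomial_survives(self, rng):
        x = np.linspace(-1, 1, 200)
        curve = 1 + x - x**3
        curve[77] += 1.0
        resid = baseline_subtract(curve, 6)
        assert resid[77] >= 0.9

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            curve = rng.uniform(-5, 5, rng.integers(20, 80))
            order = int(rng.integers(0, 7))
            np.testing.assert_allclose(baseline_subtract(curve, order),
                                       baseline_oracle(curve, order),
                                       atol=1e-8)

    def test_short_curve_errors(self):
        with pytest.raises(ValueError):
            baseline_subtract(np.zeros(5), 6)


class TestDetectPeaks:
    def test_monotone_curve_has_no_peaks(self):
        assert detect_peaks(np.arange(20.0)).n == 0

    def test_triangular_peak(self):
        curve = np.concatenate([np.arange(10.0), np.arange(8.0, -1, -1)])
        pk = detect_peaks(curve)
        assert pk.n == 1
        assert pk.positions[0] == 9
        assert pk.heights[0] == 9.0

    def test_plateau_reports_first_sample(self):
        curve = np.array([0.0, 1, 3, 3, 3, 1, 0])
        pk = detect_peaks(curve)
        assert list(pk.positions) == [2]
        assert pk.heights[0] == 3.0

    def test_two_gaussian_curve_matches_scan_oracle(self):
        x = np.arange(120.0)
        curve = (5 * np.exp(-((x - 30) / 6) ** 2)
                 + 9 * np.exp(-((x - 80) / 4) ** 2))
        pk = detect_peaks(curve)
        pos_o, h_o, w_o = peak_scan_oracle(curve)
        np.testing.assert_array_equal(np.sort(pk.positions), np.sort(pos_o))
        np.testing.assert_allclose(np.sort(pk.heights), np.sort(h_o))
        np.testing.assert_allclose(np.sort(pk.widths), np.sort(w_o), rtol=0.1)

    def test_random_curves_match_scan_oracle(self, rng):
        for _ in range(30):
            curve = rng.normal(size=rng.integers(10, 60))
            pk = detect_peaks(curve)
            pos_o, h_o, w_o = peak_scan_oracle(curve)
            np.testing.assert_array_equal(pk.positions, pos_o)
            np.testing.assert_allclose(pk.heights, h_o)
            np.testing.assert_allclose(pk.widths, w_o, rtol=1e-6)


class TestGaussianPeakVector:
    def test_center_value_equals_height(self):
        pk = PeakSet(np.array([10.0]), np.array([5.0]), np.array([3.0]))
        assert gaussian_peak_vector(pk, 30)[10] == pytest.approx(5.0)

    def test_half_width_point(self):
        # one peak (pos=10, height=5, width=4): f(12) = 5/e
        pk = PeakSet(np.array([10.0]), np.array([5.0]), np.array([4.0]))
        assert gaussian_peak_vector(pk, 30)[12] == pytest.approx(
            5 * np.exp(-1), abs=1e-12)

    def test_empty_peakset_gives_zero_curve(self):
        pk = PeakSet(np.empty(0), np.empty(0), np.empty(0))
        assert np.all(gaussian_peak_vector(pk, 16) == 0)

    def test_nonpositive_width_errors(self):
        pk = PeakSet(np.array([5.0]), np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            gaussian_peak_vector(pk, 10)

    def test_position_outside_domain_errors(self):
        pk = PeakSet(np.array([99.0]), np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            gaussian_peak_vector(pk, 10)


# ---------------------------------------------------------------------------
# the three paths


class TestRedPath:
    def test_flat_curve_gives_zeros(self):
        p = AlgorithmParams()
        assert np.all(red_path(np.full(100, 3.0), p) == 0)

    def test_only_spike_above_threshold_survives(self):
        p = AlgorithmParams()
        x = np.linspace(-1, 1, 200)
        curve = 2 * x**2 - x  # removable baseline
        curve[60] += 9.0
        out = red_path(curve, p)
        assert out[60] > p.t_red
        assert np.count_nonzero(np.delete(out, 60)) == 0

    def test_broad_depression_yields_contiguous_run(self):
        p = AlgorithmParams()
        curve = np.zeros(336)
        curve[100:110] += 8.0  # inverted CWM: dark band = positive bump
        out = red_path(curve, p)
        run = np.flatnonzero(out)
        assert run.size > 0
        assert run.min() >= 98 and run.max() <= 111
        assert np.all(np.diff(run) == 1)
        assert 8 <= run.size <= 12  # extent ≈ injected 10 columns


class TestBluePath:
    p = AlgorithmParams()

    def test_end_zone_value_above_threshold_kept(self):
        curve = np.zeros(256)
        curve[3] = 12.0  # 3 < floor(0.25*256) = 64 and 12 > 10
        assert blue_path(curve, self.p)[3] == 12.0

    def test_central_value_zeroed(self):
        curve = np.zeros(256)
        curve[128] = 12.0
        assert np.all(blue_path(curve, self.p) == 0)

    def test_subthreshold_value_zeroed(self):
        curve = np.zeros(256)
        curve[3] = 9.0
        assert np.all(blue_path(curve, self.p) == 0)

    def test_right_end_zone_kept(self):
        curve = np.zeros(256)
        curve[250] = 11.0
        assert blue_path(curve, self.p)[250] == 11.0


class TestCombinePaths:
    def test_elementwise_maximum(self):
        p = AlgorithmParams(p_exclude=0)
        out = combine_paths(np.array([0.0, 3, 0]), np.array([1.0, 1, 1]),
                            np.array([0.0, 0, 5]), p)
        np.testing.assert_array_equal(out.values, [1, 3, 5])

    def test_exclusion_zeroes_floor_2_percent(self):
        p = AlgorithmParams()
        ones = np.ones(336)
        out = combine_paths(ones, ones, ones, p)
        assert np.all(out.values[:6] == 0)    # floor(0.02*336) = 6
        assert np.all(out.values[-6:] == 0)
        assert np.all(out.values[6:-6] == 1)

    def test_all_zero_inputs(self):
        p = AlgorithmParams()
        out = combine_paths(np.zeros(50), np.zeros(50), np.zeros(50), p)
        assert out.area == 0 and np.all(out.values == 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            combine_paths(np.zeros(5), np.zeros(6), np.zeros(5),
                          AlgorithmParams())


class TestSdrArea:
    def test_zero_curve(self):
        assert sdr_area(np.zeros(100), 100) == 0

    def test_constant_closed_form(self):
        # trapezoid of constant c over m columns: c*(m-1)/m after normalizing
        assert sdr_area(np.full(336, 4.0), 336) == pytest.approx(4 * 335 / 336)

    def test_triangle_closed_form(self):
        curve = np.zeros(101)
        curve[40:61] = np.concatenate([np.arange(11.0), np.arange(9, -1, -1)])
        assert sdr_area(curve, 101) == pytest.approx(100 / 101)

    def test_matches_loop_oracle(self, rng):
        for _ in range(30):
            curve = rng.uniform(0, 9, rng.integers(2, 50))
            assert sdr_area(curve, curve.size) == pytest.approx(
                trapz_oracle(curve, curve.size))


class TestGreenPath:
    def test_constant_stack_gives_zero_curve(self, fast_params):
        stack = subtract_row_means(ImageStack(np.full((20, 30, 40), 80.0)))
        assert np.all(green_path(stack, fast_params) == 0)

    def test_persistent_single_column_defect_detected(self, small_profile,
                                                      quiet_background,
                                                      fast_params):
        bg = BackgroundModel(mean_level=100, blob_count=0, blob_amplitude=0,
                             speckle_sigma=0.05)
        stack = generate_stack(20, small_profile, bg,
                               [DefectSpec(30, 1, strength=20)], seed=5)
        centered = subtract_row_means(stack)
        curve = green_path(centered, fast_params)
        assert curve.max() > fast_params.t_green
        assert abs(int(np.argmax(curve)) - 30) <= 1

    def test_seeded_reproducibility(self, small_profile, fast_params):
        bg = BackgroundModel(speckle_sigma=0.1)
        stack = generate_stack(20, small_profile, bg,
                               [DefectSpec(20, 2, strength=25)], seed=6)
        centered = subtract_row_means(stack)
        c1 = green_path(centered, fast_params)
        c2 = green_path(centered, fast_params)
        np.testing.assert_array_equal(c1, c2)

    def test_n_select_larger_than_stack_errors(self):
        stack = ImageStack(np.zeros((4, 30, 20)))
        with pytest.raises(ValueError):
            green_path(stack, AlgorithmParams(n_stack=150, n_select=15))


# ---------------------------------------------------------------------------
# full pipeline properties


class TestComputeSdrCurve:
    def test_undersized_stack_errors(self, fast_params):
        with pytest.raises(ValueError):
            compute_sdr_curve(ImageStack(np.zeros((5, 30, 20))), fast_params)

    def test_noise_free_uniform_stack_is_exactly_zero(self, small_profile,
                                                      quiet_background,
                                                      fast_params):
        stack = generate_stack(20, small_profile, quiet_background, [], seed=0)
        curve = compute_sdr_curve(stack, fast_params)
        assert np.all(curve.values == 0)
        assert curve.area == 0

    def test_red_blue_paths_permutation_invariant(self, small_profile,
                                                  fast_params, rng):
        bg = BackgroundModel(speckle_sigma=0.1)
        stack = generate_stack(20, small_profile, bg,
                               [DefectSpec(40, 3, strength=30)], seed=9)
        centered = subtract_row_means(stack)
        band = lambda s: median_image(
            s.frames[:, fast_params.r_upper - 1:fast_params.r_lower, :])
        perm = rng.permutation(len(stack))
        shuffled = ImageStack(centered.frames[perm])
        inv1 = -band(centered).mean(axis=0)
        inv2 = -band(shuffled).mean(axis=0)
        np.testing.assert_array_equal(red_path(inv1, fast_params),
                                      red_path(inv2, fast_params))
        np.testing.assert_array_equal(blue_path(inv1, fast_params),
                                      blue_path(inv2, fast_params))

    def test_full_pipeline_deterministic_given_seed(self, small_profile,
                                                    fast_params):
        bg = BackgroundModel(speckle_sigma=0.1)
        stack = generate_stack(20, small_profile, bg,
                               [DefectSpec(25, 2, strength=25)], seed=11)
        c1 = compute_sdr_curve(stack, fast_params)
        c2 = compute_sdr_curve(stack, fast_params)
        np.testing.assert_array_equal(c1.values, c2.values)
        assert c1.area == c2.area

    def test_curve_invariants(self, small_profile, fast_params):
        bg = BackgroundModel(speckle_sigma=0.15)
        stack = generate_stack(20, small_profile, bg,
                               [DefectSpec(32, 3, strength=30)], seed=13)
        curve = compute_sdr_curve(stack, fast_params)
        cut = int(np.floor(fast_params.p_exclude / 100 * 64))
        assert np.all(curve.values >= 0)
        if cut:
            assert np.all(curve.values[:cut] == 0)
            assert np.all(curve.values[-cut:] == 0)
        assert (curve.area == 0) == bool(np.all(curve.values == 0))

    def test_localization_overlaps_injection_across_seeds(self):
        """Detected SDR support overlaps the defect columns (Jaccard > 0)
        for strength >= 15, width >= 2, away from the excluded ends, in at
        least 90 % of 20 seeds."""
        profile = TransducerProfile("SIM-96", element_count=96,
                                    resized_height=60)
        params = AlgorithmParams(n_stack=30, n_select=10, n_rep=40)
        bg = BackgroundModel()
        defect_cols = set(range(47, 50))  # width 3 centered at 48
        hits = 0
        for s in range(20):
            stack = generate_stack(30, profile, bg,
                                   [DefectSpec(48, 3, strength=15)],
                                   seed=500 + s)
            curve = compute_sdr_curve(stack, params.with_seed(s))
            support = set(np.flatnonzero(curve.values).tolist())
            inter = len(support & defect_cols)
            union = len(support | defect_cols)
            if union and inter / union > 0:
                hits += 1
        assert hits >= 18
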