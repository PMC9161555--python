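"""Focus metric, Gaussian best-focus fitting, and scan-axis calibration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import lsmkit as L
from lsmkit.autofocus import radial_log_spectrum
from lsmkit.errors import (
    CalibrationDomainError,
    CalibrationError,
    DegenerateSweepError,
    EmptyImageError,
    FocusFitError,
    ResolutionUndefinedError,
)


class TestRadialLogSpectrum:
    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        spec = radial_log_spectrum(rng.uniform(0.0, 1.0, (128, 128)))
        assert spec.values.std() < 0.1 * abs(spec.values.mean())

    def test_intensity_scaling_shifts_by_log_constant(self):
        rng = np.random.default_rng(1)
        image = rng.uniform(0.0, 1.0, (64, 64)) * 100 + 1
        s1 = radial_log_spectrum(image)
        s10 = radial_log_spectrum(image * 10)
        np.testing.assert_allclose(
            s10.values - s1.values, np.log(100.0), atol=1e-9
        )

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        # oracle: FFT of a frequency-k sinusoid concentrates at radius k
        n, k = 128, 16
        image = 0.5 + 0.5 * np.sin(2 * np.pi * k * np.arange(n) / n) * np.ones((n, 1))
        spec = radial_log_spectrum(image)
        assert spec.radii[int(np.argmax(spec.values))] == k

    def test_radii_start_at_one_and_increase(self):
        spec = radial_log_spectrum(np.random.default_rng(2).poisson(50, (40, 40)).astype(float))
        assert spec.radii[0] == 1
        assert np.all(np.diff(spec.radii) == 1)

    def test_all_zero_image_rejected(self):
        with pytest.raises(EmptyImageError):
            radial_log_spectrum(np.zeros((32, 32)))

    @pytest.mark.parametrize(
        "image", [np.ones((8, 8)), np.full((32, 32), np.nan), -np.ones((32, 32))]
    )
    def test_invalid_images_rejected(self, image):
        with pytest.raises(ValueError):
            radial_log_spectrum(image)


class TestFocusMeasure:
    def test_constant_image_scores_zero(self):
        m = L.focus_measure(np.full((64, 64), 7.0))
        assert m.count == 0
        assert m.f_max == 0

    def test_sharp_beats_blurred_phantom_plane(self, camera, scan):
        mid = 0.5 * (scan.do_start + scan.do_end)
        sharp = camera.acquire(mid, 0.0)
        blurred = gaussian_filter(sharp.astype(float), 3.0) + np.random.default_rng(
            5
        ).normal(0, 2.0, sharp.shape).clip(-10, 10)
        blurred = np.clip(blurred, 0, None)
        assert L.focus_measure(sharp).count > L.focus_measure(blurred).count

    def test_invariant_under_intensity_scaling(self, camera, scan):
        image = camera.acquire(0.5 * (scan.do_start + scan.do_end), 2.0).astype(float)
        m1 = L.focus_measure(image)
        m10 = L.focus_measure(image * 10.0)
        assert (m1.count, m1.f_max) == (m10.count, m10.f_max)

    def test_nonincreasing_in_defocus_blur(self, phantom, scan):
        """Blur applied before the camera noise floor (the defocus model)
        monotonically erodes the high-frequency content."""
        camera = L.FrameSource(
            phantom=phantom, scan=scan, seed=1, shot_noise_scale=0, read_noise=0, base_blur=0
        )
        mid = 0.5 * (scan.do_start + scan.do_end)
        clean = camera.acquire(mid, 0.0).astype(float)
        rng = np.random.default_rng(3)
        counts = []
        for sigma in (0, 1, 2, 4, 8):
            img = gaussian_filter(clean, sigma) if sigma else clean
            img = np.clip(rng.poisson(img) + rng.normal(0, 2.0, img.shape), 0, 65535)
            counts.append(L.focus_measure(img).count)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]


class TestResolutionFormula:
    def test_nyquist_returns_pixel_size(self):
        assert L.estimate_resolution(2048, 0.405, 1024) == pytest.approx(0.405)

    @pytest.mark.parametrize("n,p", [(64, 0.405), (128, 1.0), (2304, 0.65)])
    def test_quarter_band_gives_twice_pixel(self, n, p):
        assert L.estimate_resolution(n, p, n // 4) == pytest.approx(2 * p)

    def test_hand_evaluated_example(self):
        # 2304 * 0.405 / (2 * 288) computed by hand
        assert L.estimate_resolution(2304, 0.405, 288) == pytest.approx(1.62)

    def test_zero_fmax_is_undefined(self):
        with pytest.raises(ResolutionUndefinedError):
            L.estimate_resolution(2048, 0.405, 0)


class TestNormalization:
    def test_affine_map(self):
        np.testing.assert_allclose(L.normalize_measures([2, 6, 10]), [0.0, 0.5, 1.0])

    def test_bounds_always_zero_and_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = rng.integers(0, 100, size=rng.integers(3, 50))
            if vals.max() == vals.min():
                continue
            norm = L.normalize_measures(vals)
            assert norm.min() == 0.0 and norm.max() == 1.0

    def test_degenerate_sweep_rejected(self):
        with pytest.raises(DegenerateSweepError):
            L.normalize_measures([5, 5, 5])


class TestBestFocusFit:
    def test_recovers_noiseless_gaussian_center(self):
        x = np.arange(0.0, 25.0)
        y = np.exp(-((x - 12.3) ** 2) / (2 * 4.0**2))
        _, best = L.fit_best_focus(x, y)
        assert best == pytest.approx(12.3, abs=1e-6)

    def test_symmetric_data_centers_at_zero(self):
        x = np.arange(-10.0, 11.0)
        y = np.exp(-(x**2) / 18.0) + 0.05
        _, best = L.fit_best_focus(x, y)
        assert best == pytest.approx(0.0, abs=1e-6)

    def test_unfittable_data_raises(self):
        x = np.arange(0.0, 25.0)
        alternating = np.tile([0.0, 1.0], 13)[:25]
        with pytest.raises(FocusFitError):
            L.fit_best_focus(x, alternating)

    def test_single_sample_spike_raises(self):
        x = np.arange(0.0, 25.0)
        spike = np.zeros(25)
        spike[10] = 1.0
        with pytest.raises(FocusFitError):
            L.fit_best_focus(x, spike)


class TestFocusSweep:
    def test_default_sweep_acquires_41_planes_at_1um(self, camera, scan):
        calls = []
        original = camera.acquire

        def tracking(do, off):
            calls.append(off)
            return original(do, off)

        camera.acquire = tracking
        result = L.run_focus_sweep(camera, 0.5 * (scan.do_start + scan.do_end))
        assert len(calls) == 41
        assert np.allclose(np.diff(sorted(calls)), 1.0)
        assert result.positions.min() == -20.0 and result.positions.max() == 20.0

    def test_recovers_known_misalignment(self, phantom, scan):
        truth = 3.0
        camera = L.FrameSource(
            phantom=phantom, scan=scan, seed=9, true_mapping=L.offset_mapping(scan, truth)
        )
        sweep = L.run_focus_sweep(camera, 0.5 * (scan.do_start + scan.do_end))
        assert abs(sweep.best_position - truth) < 0.5

    def test_aligned_camera_centers_near_zero(self, camera, scan):
        sweep = L.run_focus_sweep(camera, 0.5 * (scan.do_start + scan.do_end))
        assert abs(sweep.best_position) < 0.5

    def test_degenerate_sweep_propagates(self, scan):
        class FlatCamera:
            def acquire(self, do, off):
                return np.full((32, 32), 50.0)

        with pytest.raises(DegenerateSweepError):
            L.run_focus_sweep(FlatCamera(), 100.0, n_planes=5)


class TestCalibrationFunction:
    def test_interpolant_exact_at_knots(self):
        knots = [(0.0, 0.1), (50.0, 0.62), (100.0, 1.08), (150.0, 1.65), (200.0, 2.1)]
        calib = L.CalibrationFunction.from_knots(knots)
        for do, v in knots:
            assert calib.eval(do) == pytest.approx(v, abs=1e-12)

    def test_no_extrapolation(self):
        calib = L.CalibrationFunction.from_knots([(0.0, 0.0), (10.0, 1.0)])
        with pytest.raises(CalibrationDomainError):
            calib.eval(11.0)

    def test_collinear_knots_have_no_deviation(self):
        xs = np.linspace(0, 200, 5)
        calib = L.CalibrationFunction.from_knots([(x, 0.01 * x) for x in xs])
        assert calib.max_dev_from_linear < 1e-3


class TestAxialCalibration:
    def test_probes_five_do_positions(self, phantom, scan):
        camera = L.FrameSource(phantom=phantom, scan=scan, seed=1)
        do_seen = []
        original = camera.acquire

        def tracking(do, off):
            do_seen.append(do)
            return original(do, off)

        camera.acquire = tracking
        calib = L.calibrate_axial_mapping(camera, scan)
        unique = sorted(set(do_seen))
        assert len(unique) == 5
        np.testing.assert_allclose(unique, np.linspace(scan.do_start, scan.do_end, 5))
        assert len(calib.knots) == 5

    def test_linear_rig_yields_near_linear_calibration(self, phantom, scan):
        camera = L.FrameSource(phantom=phantom, scan=scan, seed=4)
        calib = L.calibrate_axial_mapping(camera, scan)
        # best-focus error <= one sweep step (1 μm) at each knot
        assert calib.max_dev_from_linear <= 2 * scan.beam_gain * 1.0

    def test_recovers_quadratic_nonlinearity(self, phantom, scan):
        sag = 0.04
        camera = L.FrameSource(
            phantom=phantom, scan=scan, seed=5, true_mapping=L.quadratic_mapping(scan, sag)
        )
        calib = L.calibrate_axial_mapping(camera, scan)
        truth = L.quadratic_mapping(scan, sag)
        grid = np.linspace(scan.do_start, scan.do_end, 101)
        err_um = np.max(np.abs(calib.eval(grid) - np.array([truth(x) for x in grid]))) / scan.beam_gain
        assert err_um <= 1.0  # within one sweep step everywhere

    def test_failed_sweep_names_do_position(self, scan):
        class FlatCamera:
            def acquire(self, do, off):
                return np.full((32, 32), 50.0)

        with pytest.raises(CalibrationError) as err:
            L.calibrate_axial_mapping(FlatCamera(), scan)
        assert f"{scan.do_start:.2f}" in str(err.value)
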