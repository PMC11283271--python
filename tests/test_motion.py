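import numpy as np
import pytest

from stentoct import synthetic as syn
from stentoct.motion import (
    CDispRecord,
    MotionError,
    average_replicates,
    compensate_bulk_phase,
    compute_cdisp,
    default_reference_mask,
    doppler_scale_um_s_per_rad,
    ellipse_pixel_mask,
    extract_tm_motion,
    extract_tm_waveform,
    frame_phase_difference,
    integrate_displacement,
    lowpass_time,
    nyquist_velocity_um_s,
    phase_to_velocity,
    register_frames,
)
from stentoct.volume import BMScanSeries

LAMBDA0, N_TISSUE, DT = 1050.0, 1.38, 7.0 / 3000.0


def speckle_series(rng, n_frames=4, shape=(24, 40), **kw):
    base = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    return BMScanSeries(np.broadcast_to(base, (n_frames,) + shape).copy(), **kw)


class TestRegistration:
    def test_identical_frames_register_to_zero(self, rng):
        s = speckle_series(rng)
        _, shifts = register_frames(s)
        np.testing.assert_allclose(shifts, 0.0, atol=1e-9)

    def test_known_subpixel_shift_recovered(self, rng):
        from scipy import ndimage

        base = (rng.standard_normal((48, 64)) + 1j * rng.standard_normal((48, 64))) / np.sqrt(2)
        injected = (0.30, -0.70)
        shifted = np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(base), injected))
        s = BMScanSeries(np.stack([base, shifted]))
        registered, shifts = register_frames(s, upsample_factor=100)
        # correction is the negative of the injected drift
        np.testing.assert_allclose(shifts[1], [-0.30, 0.70], atol=0.05)
        np.testing.assert_allclose(registered.field[1], base, atol=1e-6)

    def test_single_frame_and_zero_energy_errors(self, rng):
        with pytest.raises(MotionError):
            register_frames(BMScanSeries(np.ones((1, 8, 8), complex)))
        f = np.ones((3, 8, 8), complex)
        f[1] = 0
        with pytest.raises(MotionError, match="zero-energy"):
            register_frames(BMScanSeries(f))


class TestBulkPhaseCompensation:
    def test_constant_global_phase_jump_removed_exactly(self, rng):
        base = (rng.standard_normal((16, 20)) + 1j * rng.standard_normal((16, 20))) / np.sqrt(2)
        frames = np.stack([base * np.exp(1j * 0.4 * k) for k in range(6)])
        s = BMScanSeries(frames)
        ref = np.ones((16, 20), dtype=bool)
        comp = compensate_bulk_phase(s, ref)
        dphi = frame_phase_difference(comp)
        assert np.abs(dphi[:, ref].mean(axis=1)).max() <= 1e-6

    def test_local_oscillation_survives_bulk_ramp_removal(self, rng):
        base = (rng.standard_normal((20, 30)) + 1j * rng.standard_normal((20, 30))) / np.sqrt(2)
        tm = np.zeros((20, 30), dtype=bool)
        tm[8:12, 12:18] = True
        true_phase = 0.3 * np.sin(np.linspace(0, 2 * np.pi, 12))
        frames = []
        for k in range(12):
            f = base * np.exp(1j * 0.25 * k)  # bulk ramp
            f = np.where(tm, f * np.exp(1j * true_phase[k]), f)
            frames.append(f)
        s = BMScanSeries(np.stack(frames))
        comp = compensate_bulk_phase(s, ~tm)
        roi = comp.field[:, tm]
        measured = np.angle(roi * np.conj(roi[0]))[1:].mean(axis=1)
        np.testing.assert_allclose(measured, (true_phase - true_phase[0])[1:], rtol=0.01, atol=1e-9)

    def test_empty_or_dead_reference_rejected(self, rng):
        s = speckle_series(rng)
        with pytest.raises(MotionError, match="empty"):
            compensate_bulk_phase(s, np.zeros((24, 40), dtype=bool))


class TestPhaseDifference:
    def test_static_series_gives_zero(self, rng):
        # z * conj(z) has a vanishing imaginary part up to rounding
        assert np.abs(frame_phase_difference(speckle_series(rng))).max() <= 1e-12

    def test_uniform_rotation_gives_constant(self, rng):
        base = (rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8)))
        frames = np.stack([base * np.exp(1j * np.pi / 3 * k) for k in range(4)])
        dphi = frame_phase_difference(BMScanSeries(frames))
        np.testing.assert_allclose(dphi, np.pi / 3, rtol=1e-12)

    def test_wrapping_matches_complex_argument_oracle(self, rng):
        base = (rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8)))
        step = 1.9 * np.pi
        frames = np.stack([base, base * np.exp(1j * step)])
        dphi = frame_phase_difference(BMScanSeries(frames))
        expected = np.angle(np.exp(1j * step))  # = -0.1 pi
        np.testing.assert_allclose(dphi, expected, rtol=1e-12)
        assert dphi.max() <= np.pi and dphi.min() > -np.pi


class TestDopplerConversion:
    def test_zero_phase_zero_velocity(self):
        assert phase_to_velocity(0.0, LAMBDA0, N_TISSUE, DT) == 0.0

    def test_quarter_turn_matches_hand_evaluation(self):
        """v(pi/2) = lambda0 / (8 n dT), evaluated independently in um/s."""
        hand = (1050e-3) / (8.0 * 1.38 * (7.0 / 3000.0))
        v = phase_to_velocity(np.pi / 2, LAMBDA0, N_TISSUE, DT)
        assert abs(v - hand) / hand < 1e-9

    def test_pi_reaches_nyquist_velocity(self):
        v = phase_to_velocity(np.pi, LAMBDA0, N_TISSUE, DT)
        assert v == pytest.approx(nyquist_velocity_um_s(LAMBDA0, N_TISSUE, DT), rel=1e-12)
        hand_nyquist = (1050e-3) / (4.0 * 1.38 * (7.0 / 3000.0))
        assert v == pytest.approx(hand_nyquist, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(lambda0_nm=0), dict(n_tissue=0), dict(dt_s=0)])
    def test_nonpositive_parameters_rejected(self, bad):
        kw = dict(lambda0_nm=LAMBDA0, n_tissue=N_TISSUE, dt_s=DT)
        kw.update(bad)
        with pytest.raises(MotionError):
            doppler_scale_um_s_per_rad(**kw)


class TestLowpass:
    def test_constant_signal_unchanged(self):
        x = np.full(3000, 2.5)
        np.testing.assert_allclose(lowpass_time(x, DT), x, rtol=1e-9)

    def test_stopband_and_passband_match_analytic_magnitude(self):
        t = np.arange(3000) * DT
        for f, bound in [(10.0, "stop"), (2.0, "pass")]:
            x = np.sin(2 * np.pi * f * t)
            y = lowpass_time(x, DT, order=20, cutoff_hz=6.0)
            amp = np.abs(y[500:-500]).max()
            h = 1.0 / np.sqrt(1.0 + (f / 6.0) ** 40)
            if bound == "stop":
                assert amp <= 1e-4  # analytic |H(10)| ~ 3.7e-5
            else:
                assert abs(amp - 1.0) <= 1e-3  # |H(2)| within 0.1% of 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(MotionError):
            lowpass_time(np.zeros(100), dt_s=0.1, cutoff_hz=6.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(MotionError):
            lowpass_time(np.zeros(4), DT)


class TestEllipseAveraging:
    def test_uniform_field_gives_constant_waveform(self):
        v = np.full((5, 20, 30), 3.25)
        w = extract_tm_waveform(v, (10, 15), (25.0, 7.5), (10.0, 3.0))
        np.testing.assert_allclose(w, 3.25)

    def test_pixel_set_matches_bruteforce_rasterization(self):
        mask = ellipse_pixel_mask((40, 60), (20, 30), (25.0, 7.5), (10.0, 3.0))
        for z in range(40):
            for x in range(60):
                dx = (x - 30) * 10.0
                dz = (z - 20) * 3.0
                assert mask[z, x] == ((dx / 25.0) ** 2 + (dz / 7.5) ** 2 <= 1.0)

    def test_ellipse_outside_grid_rejected(self):
        with pytest.raises(MotionError):
            ellipse_pixel_mask((40, 60), (200, 300), (25.0, 7.5), (10.0, 3.0))


class TestIntegration:
    def test_zero_velocity_zero_displacement(self):
        d = integrate_displacement(np.zeros(100), DT)
        np.testing.assert_array_equal(d, 0.0)
        assert d[0] == 0.0

    def test_sine_amplitude_matches_analytic_antiderivative(self):
        f, v0 = 1.0, 3.0
        t = np.arange(5000) * DT  # fs >> f
        v = v0 * np.sin(2 * np.pi * f * t)
        d = integrate_displacement(v, DT, detrend=False)
        # integral of v0 sin = (v0 / 2 pi f)(1 - cos): amplitude v0/(2 pi f)
        assert (d.max() - d.min()) / 2 == pytest.approx(v0 / (2 * np.pi * f), rel=0.01)

    def test_constant_velocity_annihilated_by_detrend(self):
        d = integrate_displacement(np.full(200, 5.0), DT, detrend=True)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(MotionError):
            integrate_displacement(np.array([1.0]), DT)


class TestCDisp:
    def test_constant_displacement_gives_zero(self):
        assert compute_cdisp(np.full(50, 1.7)) == 0.0

    def test_sinusoid_range_is_twice_amplitude(self):
        t = np.linspace(0, 2, 2001)
        assert compute_cdisp(0.8 * np.sin(2 * np.pi * t)) == pytest.approx(1.6, rel=1e-4)

    def test_empty_series_rejected(self):
        with pytest.raises(MotionError):
            compute_cdisp(np.array([]))

    def test_replicate_averaging(self):
        recs = [
            CDispRecord(c, eye="OD", location_label="between", day_label="d1", replicate_index=i)
            for i, c in enumerate((0.8, 1.0, 1.2))
        ]
        avg = average_replicates(recs)
        assert avg.cdisp_um == pytest.approx(1.0)
        assert avg.replicate_index is None

    def test_replicate_label_mismatch(self):
        recs = [
            CDispRecord(1.0, eye="OD", location_label="between", day_label="d1"),
            CDispRecord(1.0, eye="OD", location_label="remote", day_label="d1"),
        ]
        with pytest.raises(MotionError, match="mismatch"):
            average_replicates(recs)


class TestPipelineProperties:
    def test_filter_and_ellipse_average_commute(self, rng):
        """Both operators are linear: order must not matter (1e-10 relative)."""
        v_grid = rng.standard_normal((256, 20, 30))
        center, semi, pitches = (10, 15), (25.0, 7.5), (10.0, 3.0)
        a = lowpass_time(extract_tm_waveform(v_grid, center, semi, pitches), DT)
        b = extract_tm_waveform(lowpass_time(v_grid, DT, axis=0), center, semi, pitches)
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)

    def test_per_pixel_path_equals_mean_path(self, small_bmscan):
        series, truth = small_bmscan
        kw = dict(tm_center=truth.motion["tm_center"], register=False, compensate=False)
        w1 = extract_tm_motion(series, roi_average="mean", **kw)
        w2 = extract_tm_motion(series, per_pixel_filter=True, **kw)
        # fixture is stored complex64: agreement is limited by that precision
        np.testing.assert_allclose(w1.velocity_um_s, w2.velocity_um_s, rtol=2e-6, atol=1e-7)

    def test_end_to_end_recovery_on_short_record(self, small_bmscan):
        series, truth = small_bmscan
        w = extract_tm_motion(series, truth.motion["tm_center"])
        expected = syn.truth_cdisp(truth)
        assert w.cdisp_um == pytest.approx(expected, rel=0.10)

    def test_static_scene_noise_floor(self):
        series, truth = syn.make_bmscan_series(
            n_frames=1024, shape_zx=(32, 120), amplitude_um=0.0, seed=5
        )
        w = extract_tm_motion(series, truth.motion["tm_center"])
        assert w.cdisp_um <= 0.05

    def test_default_reference_mask_excludes_tm(self, small_bmscan):
        series, truth = small_bmscan
        ref = default_reference_mask(series, truth.motion["tm_center"])
        ell = ellipse_pixel_mask(
            series.field.shape[1:], truth.motion["tm_center"],
            (25.0, 7.5), (series.pitch_x_um, series.pitch_z_um),
        )
        assert not (ref & ell).any()
        assert ref.any()


class TestAliasingGuard:
    def test_generator_refuses_supranyquist_motion(self):
        with pytest.raises(syn.SyntheticError, match="aliasing"):
            syn.make_bmscan_series(n_frames=512, shape_zx=(24, 64), amplitude_um=60.0, seed=0)

    def test_opt_in_aliasing_wraps_and_underestimates(self):
        series, truth = syn.make_bmscan_series(
            n_frames=512,
            shape_zx=(24, 64),
            amplitude_um=60.0,
            phase_snr_db=None,
            bulk_shift_amplitude_px=(0, 0),
            bulk_phase_step_rad=0.0,
            allow_aliasing=True,
            dtype=np.complex128,
            seed=0,
        )
        dphi = frame_phase_difference(series)
        assert dphi.max() <= np.pi and dphi.min() > -np.pi
        w = extract_tm_motion(series, truth.motion["tm_center"], register=False, compensate=False)
        true_peak = np.abs(truth.motion["velocity_um_s"]).max()
        nyq = nyquist_velocity_um_s(series.lambda0_nm, series.n_tissue, series.dt_s)
        assert true_peak > nyq
        assert np.abs(w.velocity_um_s).max() < true_peak
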