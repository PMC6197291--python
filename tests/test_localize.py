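"""Split-image localization: spot fitting, calibration, tracking."""

import numpy as np
import pytest

from ciliatip.errors import ParameterError, TrackingQualityError
from ciliatip.imaging import ImageStack, render_spot
from ciliatip.localize import (
    CalibrationCurve,
    calibrate,
    combine_pair,
    detect_two_spots,
    fit_gaussian_spot,
    fit_two_spots,
    localization_precision,
    track,
)
from ciliatip.synth import (
    OpticsParams,
    WaveformParams,
    generate_calibration_stack,
    generate_free_beating,
    render_split_frames,
)
from ciliatip.trap import TrapParams  # noqa: F401  (sanity: no circular import)


class TestSpotFitting:
    def test_pixel_centered_spot_recovered_exactly(self):
        frame = render_spot((21, 21), (10.0, 10.0), 1.3, 5000.0, offset=5.0)
        x0, y0, flux, sigma, offset, rms = fit_gaussian_spot(frame, (10, 10))
        assert x0 == pytest.approx(10.0, abs=1e-9)
        assert y0 == pytest.approx(10.0, abs=1e-9)
        assert rms < 1e-6

    def test_subpixel_spot_within_milli_pixel(self):
        frame = render_spot((21, 21), (10.30, 7.60), 1.3, 5000.0, offset=5.0)
        x0, y0, *_ = fit_gaussian_spot(frame, (10, 8))
        assert x0 == pytest.approx(10.30, abs=1e-3)
        assert y0 == pytest.approx(7.60, abs=1e-3)

    def test_monte_carlo_precision_within_2x_estimate(self, optics):
        """Empirical scatter of noisy fits <= 2x the photon-budget estimate."""
        rng = np.random.default_rng(7)
        est_nm = localization_precision(optics)["sigma_spot_nm"]
        xs = []
        clean = render_spot((15, 15), (7.21, 7.43), optics.psf_sigma_px,
                            optics.photons_per_spot, offset=optics.background_per_px)
        for _ in range(100):
            noisy = rng.poisson(clean) + rng.normal(0, optics.camera_noise_sd, clean.shape)
            x0, *_ = fit_gaussian_spot(np.clip(noisy, 0, None), (7, 7))
            xs.append(x0)
        emp_nm = np.std(xs, ddof=1) * optics.pixel_size_nm
        assert emp_nm <= 2 * est_nm

    def test_two_spot_ordering_by_x(self):
        frame = render_spot((15, 31), (22.0, 7.0), 1.3, 4000.0)
        frame += render_spot((15, 31), (8.0, 7.0), 1.3, 4000.0)
        pair = fit_two_spots(frame, [(8, 7), (22, 7)])
        assert pair.x1 > pair.x2
        assert pair.x1 == pytest.approx(22.0, abs=1e-6)

    def test_detect_two_spots(self):
        frame = render_spot((15, 31), (22.0, 7.0), 1.3, 4000.0)
        frame += render_spot((15, 31), (8.0, 7.0), 1.3, 4000.0)
        (a, b) = detect_two_spots(frame, 5)
        xs = sorted([a[0], b[0]])
        assert xs == pytest.approx([8, 22], abs=1)


class TestCombinePair:
    def _pair(self, x1, x2, y1=5.0, y2=5.0):
        from ciliatip.localize import SpotPair

        return SpotPair(x1=x1, y1=y1, x2=x2, y2=y2, amp1=1, amp2=1,
                        sigma1=1.3, sigma2=1.3, residual_rms=0.0)

    def test_printed_arithmetic(self):
        """x1=10, x2=6 px -> lateral mean 8 px; raw half-difference 2 px."""
        cal = CalibrationCurve(slope=1.0, intercept_nm=0.0, r_squared=1.0)
        x, y, z = combine_pair(self._pair(10.0, 6.0), cal, pixel_size_nm=1000.0)
        assert x == pytest.approx(8.0)  # 8 px at 1 um/px
        assert z == pytest.approx(2.0)  # half-difference 2 px = 2000 nm / slope 1

    def test_equal_spots_map_to_calibration_zero(self):
        cal = CalibrationCurve(slope=0.7, intercept_nm=0.0, r_squared=1.0)
        _, _, z = combine_pair(self._pair(6.0, 6.0), cal, pixel_size_nm=100.0)
        assert z == 0.0

    def test_slope_half_doubles_z(self):
        """slope 0.5, intercept 0, raw half-difference 10 nm -> z = 20 nm."""
        cal = CalibrationCurve(slope=0.5, intercept_nm=0.0, r_squared=1.0)
        _, _, z = combine_pair(self._pair(6.1, 5.9), cal, pixel_size_nm=100.0)
        assert z * 1000.0 == pytest.approx(20.0)


class TestCalibration:
    def test_two_noiseless_points_r2_exactly_one(self, quiet_optics):
        stack, known = generate_calibration_stack(
            quiet_optics, [-200, 200], seed=1, shot_noise=False
        )
        cal = calibrate(stack, known)
        assert cal.r_squared == 1.0

    def test_slope_recovery_within_one_percent(self, optics):
        stack, known = generate_calibration_stack(
            optics, list(range(-300, 301, 50)), seed=3
        )
        cal = calibrate(stack, known)
        assert cal.slope == pytest.approx(optics.z_split_slope, rel=0.01)
        assert cal.r_squared > 0.999

    def test_identical_steps_rejected(self, quiet_optics):
        stack, known = generate_calibration_stack(
            quiet_optics, [-100, 100], seed=1, shot_noise=False
        )
        with pytest.raises(ParameterError):
            calibrate(stack, [50.0, 50.0])


@pytest.fixture(scope="module")
def short_noiseless():
    p = WaveformParams(
        freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=0.0, n_cycles=1
    )
    return generate_free_beating(p, seed=3)


class TestTracking:
    def test_noiseless_round_trip_below_1nm(self, short_noiseless, quiet_optics):
        stack = render_split_frames(short_noiseless, quiet_optics, seed=5,
                                    shot_noise=False)
        cal_stack, known = generate_calibration_stack(
            quiet_optics, [-300, 0, 300], seed=7, shot_noise=False
        )
        cal = calibrate(cal_stack, known)
        trk = track(stack, cal)
        err_nm = (trk.positions - short_noiseless.positions) * 1e3
        assert np.sqrt((err_nm**2).mean()) < 1.0
        assert np.all(np.diff(trk.t) > 0)

    def test_z_linearity_noiseless(self, quiet_optics):
        """Doubling the true z displacement doubles the recovered z (0.5%)."""
        from ciliatip.trajectory import Trajectory

        cal_stack, known = generate_calibration_stack(
            quiet_optics, [-400, 0, 400], seed=7, shot_noise=False
        )
        cal = calibrate(cal_stack, known)
        zs = []
        for dz in (0.1, 0.2):
            tr = Trajectory(t=np.array([0.0, 0.01]), x=np.zeros(2),
                            y=np.zeros(2), z=np.array([0.0, dz]))
            stack = render_split_frames(tr, quiet_optics, seed=1, z_ref_um=0.0,
                                        shot_noise=False)
            trk = track(stack, cal)
            zs.append(trk.z[1] - trk.z[0])
        assert zs[1] / zs[0] == pytest.approx(2.0, rel=0.005)

    def test_empty_stack_rejected(self, quiet_optics):
        stack = ImageStack(
            frames=np.empty((0, 5, 5)), times=np.empty(0), optics=quiet_optics
        )
        cal = CalibrationCurve(slope=0.5, intercept_nm=0.0, r_squared=1.0)
        with pytest.raises(ParameterError):
            track(stack, cal)

    def test_dark_frames_flagged_and_interpolated(self, short_noiseless, quiet_optics):
        stack = render_split_frames(short_noiseless, quiet_optics, seed=5,
                                    shot_noise=False)
        stack.frames[3] = 0.0  # one dropout frame
        cal_stack, known = generate_calibration_stack(
            quiet_optics, [-300, 0, 300], seed=7, shot_noise=False
        )
        trk = track(stack, calibrate(cal_stack, known))
        assert not trk.quality[3]
        assert np.isfinite(trk.positions).all()

    def test_mostly_dark_stack_fails_quality_gate(self, short_noiseless, quiet_optics):
        stack = render_split_frames(short_noiseless, quiet_optics, seed=5,
                                    shot_noise=False)
        stack.frames[: stack.n_frames // 2] = 0.0
        cal_stack, known = generate_calibration_stack(
            quiet_optics, [-300, 0, 300], seed=7, shot_noise=False
        )
        with pytest.raises(TrackingQualityError):
            track(stack, calibrate(cal_stack, known))
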