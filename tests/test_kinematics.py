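"""Alignment, smoothing, segmentation and waveform metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciliatip.errors import (
    AmbiguousPlaneWarning,
    FrequencyUndeterminedError,
    LowAsymmetryWarning,
    ParameterError,
    UndefinedGapError,
)
from ciliatip.kinematics import (
    StrokeSegmentation,
    align_axes,
    beat_frequency,
    curvature_radius,
    fit_circle_radius,
    geometric_summary,
    segment_strokes,
    smooth_trajectory,
    x_amplitude,
    z_gap,
)
from ciliatip.model import FreeBeatAnalysis
from ciliatip.synth import WaveformParams, generate_free_beating
from ciliatip.trajectory import Trajectory

FS = 354.61


def _traj(x, y=None, z=None, fs=FS):
    n = len(x)
    return Trajectory(
        t=np.arange(n) / fs,
        x=np.asarray(x, dtype=float),
        y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        z=np.zeros(n) if z is None else np.asarray(z, dtype=float),
        sample_rate_hz=fs,
    )


class TestAlignment:
    def test_already_aligned_is_fixed_point(self, det_trajectory):
        a = align_axes(det_trajectory)
        assert abs(a.rotation_deg) < 2.0
        assert not a.flip_applied

    def test_inverts_known_rotation(self, det_trajectory):
        rotated = det_trajectory.rotated_z(37.0)
        a = align_axes(rotated)
        # net applied rotation undoes the 37 degrees
        assert a.rotation_deg % 360 == pytest.approx(-37.0 % 360, abs=0.5)

    def test_fast_stroke_toward_minus_x_gets_flipped(self, det_trajectory):
        mirrored = det_trajectory.rotated_z(180.0)
        a = align_axes(mirrored)
        assert a.flip_applied
        # effective stroke ends at +x again
        assert np.corrcoef(a.x, det_trajectory.x)[0, 1] > 0.999

    def test_idempotent(self, det_trajectory):
        once = align_axes(det_trajectory.rotated_z(25.0))
        twice = align_axes(once)
        assert abs(twice.rotation_deg) < 0.5
        assert not twice.flip_applied

    def test_isotropic_motion_warns(self):
        t = np.arange(400) / FS
        tr = _traj(np.cos(2 * np.pi * 5 * t), y=np.sin(2 * np.pi * 5 * t))
        with pytest.warns(AmbiguousPlaneWarning):
            align_axes(tr)

    def test_z_untouched(self, det_trajectory):
        a = align_axes(det_trajectory.rotated_z(63.0))
        assert np.array_equal(a.z, det_trajectory.z)


class TestSmoothing:
    def test_quartic_polynomial_reproduced_exactly(self):
        t = np.arange(200) / FS
        x = 1 + t - 3 * t**2 + 0.5 * t**4
        tr = _traj(x)
        sm = smooth_trajectory(tr, 11, order=4)
        assert np.allclose(sm.x, x, atol=1e-10)
        assert np.array_equal(sm.t, tr.t)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        for s in range(5):
            x = rng.normal(size=500)
            sm = smooth_trajectory(_traj(x), 11, order=4)
            assert sm.x.var() < x.var()

    @pytest.mark.parametrize("window", [4, 3, 9999])
    def test_bad_windows_rejected(self, window):
        tr = _traj(np.arange(100, dtype=float))
        with pytest.raises(ParameterError):
            smooth_trajectory(tr, window, order=4)


class TestFrequency:
    def test_pure_tone_recovered(self):
        t = np.arange(int(2 * FS)) / FS
        tr = _traj(np.sin(2 * np.pi * 5.0 * t))
        assert beat_frequency(tr) == pytest.approx(5.0, abs=0.25)

    def test_constant_position_is_undetermined(self):
        tr = _traj(np.full(500, 1.23))
        with pytest.raises(FrequencyUndeterminedError):
            beat_frequency(tr)

    def test_generator_default_recovered_over_seeds(self):
        p = WaveformParams()  # 1 cP defaults with per-seed draws and noise
        est, realized = [], []
        for s in range(1, 16):
            tr = generate_free_beating(p, seed=s)
            est.append(beat_frequency(align_axes(tr)))
            realized.append(tr.meta["realized_freq_hz"])
        assert np.mean(est) == pytest.approx(np.mean(realized), rel=0.02)
        assert np.mean(est) == pytest.approx(4.9, rel=0.05)


class TestSegmentation:
    def test_fast_rise_slow_fall_labels_rising_effective(self):
        """Sawtooth-like cycles: the faster arc is the effective stroke."""
        fs = 500.0
        cycles = 6
        rise, fall = 20, 80
        one = np.r_[np.linspace(-1, 1, rise, endpoint=False),
                    np.linspace(1, -1, fall, endpoint=False)]
        x = np.tile(one, cycles)
        tr = _traj(x, fs=fs)
        seg = segment_strokes(tr, freq_hint=fs / (rise + fall))
        eff = seg.labels == "effective"
        # brute-force oracle: mean |dx/dt| on rising vs falling samples
        v = np.gradient(x) * fs
        assert np.abs(v[eff]).mean() > np.abs(v[seg.labels == "recovery"]).mean()
        rising = np.gradient(x) > 0
        assert (eff & ~rising).sum() < 0.05 * eff.sum()

    def test_symmetric_sine_tie_breaks_toward_plus_x(self):
        t = np.arange(int(3 * FS)) / FS
        tr = _traj(np.sin(2 * np.pi * 4.0 * t))
        with pytest.warns(LowAsymmetryWarning):
            seg = segment_strokes(tr, freq_hint=4.0)
        for i in range(seg.n_cycles):
            sl = seg.cycle_slice(i)
            eff = seg.labels[sl] == "effective"
            assert np.gradient(tr.x[sl])[eff].mean() > 0

    def test_duty_cycle_recovered(self, det_trajectory):
        res = FreeBeatAnalysis(det_trajectory).fit()
        pc = res.segmentation.per_cycle
        frac = (pc.effective_duration_s / pc.duration_s).mean()
        assert frac == pytest.approx(0.35, abs=0.05)

    def test_effective_speed_dominates_every_cycle(self, noisy_trajectory):
        res = FreeBeatAnalysis(noisy_trajectory).fit()
        pc = res.segmentation.per_cycle
        assert (pc.effective_mean_speed_um_s > pc.recovery_mean_speed_um_s).all()


class TestAmplitude:
    def test_sine_peak_to_peak_is_2A(self):
        t = np.arange(int(3 * FS)) / FS
        tr = _traj(1.7 * np.sin(2 * np.pi * 4.0 * t))
        with pytest.warns(LowAsymmetryWarning):
            seg = segment_strokes(tr, freq_hint=4.0)
        assert x_amplitude(tr, seg) == pytest.approx(2 * 1.7, rel=1e-3)

    def test_generator_default_recovered(self, det_trajectory):
        res = FreeBeatAnalysis(det_trajectory).fit()
        assert res.waveform.x_amplitude_um == pytest.approx(3.6, rel=0.02)


class TestZGap:
    def test_configured_gap_recovered(self):
        p = WaveformParams(z_gap_um=0.3, freq_sd_hz=0.0, x_amplitude_sd_um=0.0)
        vals = [FreeBeatAnalysis(generate_free_beating(p, s)).fit().waveform.z_gap_um
                for s in (1, 2, 3)]
        assert np.mean(vals) == pytest.approx(0.30, abs=0.03)

    def test_zero_gap_measures_near_zero(self):
        p = WaveformParams(L_eff_um=5.0, L_rec_um=5.0, z_gap_um=0.0,
                           freq_sd_hz=0.0, x_amplitude_sd_um=0.0)
        res = FreeBeatAnalysis(generate_free_beating(p, 1)).fit()
        assert abs(res.waveform.z_gap_um) < 3 * 0.010  # 3x the 10 nm noise floor

    def test_disjoint_x_ranges_undefined(self):
        n = 100
        tr = _traj(np.r_[np.linspace(0, 1, 50), np.linspace(3, 4, 50)])
        labels = np.r_[["effective"] * 50, ["recovery"] * 50]
        seg = StrokeSegmentation(
            boundaries=np.array([0, n - 1]), labels=labels, per_cycle=None
        )
        with pytest.raises(UndefinedGapError):
            z_gap(tr, seg)


class TestCurvature:
    def test_exact_circle_recovered_to_machine_precision(self):
        th = np.linspace(0.3, 2.0, 50)
        assert fit_circle_radius(4.0 * np.cos(th), 4.0 * np.sin(th)) == pytest.approx(
            4.0, rel=1e-12
        )

    def test_noisy_circle_within_one_percent(self):
        rng = np.random.default_rng(11)
        th = np.linspace(0.2, 2.4, 300)
        x = 4.0 * np.cos(th) + rng.normal(0, 0.020, th.size)
        z = 4.0 * np.sin(th) + rng.normal(0, 0.020, th.size)
        assert fit_circle_radius(x, z) == pytest.approx(4.0, rel=0.01)

    def test_collinear_points_flagged_infinite(self):
        assert fit_circle_radius(np.array([0.0, 1.0, 2.0]),
                                 np.array([0.0, 1.0, 2.0])) == np.inf

    def test_phase_selection_needs_enough_points(self):
        tr = _traj(np.linspace(0, 1, 10))
        seg = StrokeSegmentation(
            boundaries=np.array([0, 9]),
            labels=np.array(["effective"] * 3 + ["recovery"] * 7),
            per_cycle=None,
        )
        with pytest.raises(ParameterError):
            curvature_radius(tr, seg)


class TestGeometricSummary:
    def test_equal_values(self):
        assert geometric_summary([3.0, 3.0, 3.0]) == (pytest.approx(3.0), pytest.approx(1.0))

    def test_decades(self):
        gmean, gsd = geometric_summary([1.0, 10.0, 100.0])
        assert gmean == pytest.approx(10.0)
        assert gsd == pytest.approx(np.exp(np.std([0, 1, 2], ddof=1) * np.log(10)))

    @pytest.mark.parametrize("bad", [[1.0, 0.0], [1.0, -2.0], []])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ParameterError):
            geometric_summary(bad)


class TestRotationInvariance:
    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(angle=st.floats(min_value=-180.0, max_value=180.0))
    def test_metrics_invariant_under_pre_rotation(self, angle, det_trajectory):
        """Waveform metrics do not depend on the raw lateral orientation."""
        base = FreeBeatAnalysis(det_trajectory).fit().waveform
        rot = FreeBeatAnalysis(det_trajectory.rotated_z(angle)).fit().waveform
        assert rot.freq_hz == pytest.approx(base.freq_hz, rel=1e-6)
        assert rot.x_amplitude_um == pytest.approx(base.x_amplitude_um, rel=1e-3)
        assert rot.z_gap_um == pytest.approx(base.z_gap_um, abs=0.01)
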