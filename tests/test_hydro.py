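"""Sphere fit, Yamakawa drag, flux and pumped volume."""

import numpy as np
import pytest

from ciliatip.errors import ModelDomainError, ParameterError
from ciliatip.hydro import (
    HydroParams,
    drag_coefficient,
    drag_force,
    fit_attachment_sphere,
    flow_volume,
    flux,
    shoelace_area,
    single_cilium_flux_estimate,
)
from ciliatip.kinematics import StrokeSegmentation
from ciliatip.model import FreeBeatAnalysis
from ciliatip.synth import WaveformParams, generate_free_beating
from ciliatip.trajectory import Trajectory


def hand_drag(eta_cp, L, v, a=0.1, gamma=1.111):
    """Independent hand evaluation of the closed-form drag."""
    return 2 * np.pi * (eta_cp * 1e-3) * L * v / (np.log(L / (2 * a)) + gamma)


class TestDragForce:
    def test_closed_form_hand_value(self):
        """eta=1 cP, L=5 um, V=100 um/s -> |F| ~ 0.7256 pN."""
        f = drag_coefficient(5.0, HydroParams()) * 100.0
        assert f == pytest.approx(hand_drag(1.0, 5.0, 100.0), rel=1e-12)
        assert f == pytest.approx(0.7256, abs=2e-4)

    def test_linear_in_viscosity(self):
        c1 = drag_coefficient(5.0, HydroParams(eta_cp=1.0))
        c2 = drag_coefficient(5.0, HydroParams(eta_cp=2.0))
        assert c2 == pytest.approx(2 * c1, rel=1e-14)

    def test_domain_error_for_short_length(self):
        with pytest.raises(ModelDomainError):
            drag_coefficient(0.15, HydroParams())  # L <= 2a

    def test_zero_velocity_zero_force(self, det_trajectory):
        res = FreeBeatAnalysis(det_trajectory).fit()
        n = 50
        still = Trajectory(
            t=np.arange(n) / 354.61,
            x=np.ones(n), y=np.ones(n), z=np.full(n, 4.0),
        )
        seg = StrokeSegmentation(
            boundaries=np.array([0, n - 1]),
            labels=np.array(["effective"] * n),
            per_cycle=None,
        )
        series = drag_force(still, seg, res.sphere, HydroParams())
        assert np.allclose(series.F, 0.0, atol=1e-12)


class TestSphereFit:
    def test_exact_recovery_on_noiseless_data(self, det_trajectory):
        res = FreeBeatAnalysis(det_trajectory).fit()
        assert res.sphere.method == "free_center"
        assert np.linalg.norm(res.sphere.center_um) < 2e-3
        assert res.sphere.L_eff_um == pytest.approx(4.95, rel=1e-3)
        assert res.sphere.L_rec_um == pytest.approx(4.90, rel=1e-3)

    def test_noisy_recovery_within_tolerances(self):
        """Monte-Carlo recovery at 20 nm noise: mean centre within 100 nm,
        mean radii within 1%.

        (A single 2-s recording leaves the centre soft along the sphere
        normal — scatter ~60 nm — so the recovery oracle is the ensemble
        mean.)
        """
        p = WaveformParams(freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=20.0)
        centers, Le, Lr = [], [], []
        for s in range(1, 11):
            res = FreeBeatAnalysis(generate_free_beating(p, s)).fit()
            centers.append(res.sphere.center_um)
            Le.append(res.sphere.L_eff_um)
            Lr.append(res.sphere.L_rec_um)
        assert np.linalg.norm(np.mean(centers, axis=0)) < 0.100  # 100 nm
        assert np.mean(Le) == pytest.approx(4.95, rel=0.01)
        assert np.mean(Lr) == pytest.approx(4.90, rel=0.01)

    def test_planar_arc_engages_constrained_fallback(self):
        """A constant-z arc leaves the centre unidentifiable: flag the fall-back."""
        th = np.linspace(0, np.pi, 200)
        tr = Trajectory(
            t=np.arange(200) / 354.61,
            x=3 * np.cos(th), y=3 * np.sin(th), z=np.full(200, 2.0),
        )
        labels = np.array(["effective"] * 100 + ["recovery"] * 100)
        seg = StrokeSegmentation(
            boundaries=np.array([0, 199]), labels=labels, per_cycle=None
        )
        fit = fit_attachment_sphere(tr, seg)
        assert fit.method == "plane_constrained"

    def test_translation_invariance(self, det_trajectory):
        """Rigid translation of the raw data leaves all results unchanged."""
        base = FreeBeatAnalysis(det_trajectory).fit()
        moved = FreeBeatAnalysis(det_trajectory.translated([5.0, -3.0, 2.0])).fit()
        assert moved.net_flux_um3_cycle == pytest.approx(
            base.net_flux_um3_cycle, rel=1e-6
        )
        assert moved.maxF_effective_pN == pytest.approx(
            base.maxF_effective_pN, rel=1e-6
        )
        assert moved.sphere.L_eff_um == pytest.approx(base.sphere.L_eff_um, rel=1e-6)


class TestFlux:
    def test_hand_value(self):
        """z=5 um, F=0.7256 pN, 1 cP -> |J| ~ 770 um^3/s."""
        J = 2 * 5.0 * 0.7256 / (3 * np.pi * 1e-3)
        assert J == pytest.approx(770.0, rel=1e-3)

    def test_zero_height_pumps_nothing(self, det_trajectory):
        res = FreeBeatAnalysis(det_trajectory).fit()
        series = res.series
        z = res.smoothed.z.copy()
        m = np.argmin(np.abs(z))
        assert series.J[m] == pytest.approx(
            2 * z[m] * series.F[m] / (3 * np.pi * 1e-3)
        )
        # direct: J is odd in F and vanishes with z
        assert flux_value(0.0, 1.0) == 0.0
        assert flux_value(5.0, -1.0) == -flux_value(5.0, 1.0)

    def test_eta_cancels_in_flux(self, det_trajectory):
        r1 = FreeBeatAnalysis(det_trajectory, hydro_params=HydroParams(eta_cp=1.0)).fit()
        r15 = FreeBeatAnalysis(det_trajectory, hydro_params=HydroParams(eta_cp=15.0)).fit()
        assert r15.net_flux_um3_cycle == pytest.approx(
            r1.net_flux_um3_cycle, rel=1e-12
        )
        assert r15.maxF_effective_pN == pytest.approx(15 * r1.maxF_effective_pN, rel=1e-12)


def flux_value(z, F, eta_cp=1.0):
    return 2 * z * F / (3 * np.pi * eta_cp * 1e-3)


class TestFlowVolume:
    def test_constant_flux_integrates_exactly(self):
        n = 101
        t = np.linspace(0, 1, n)
        from ciliatip.hydro import ForceFluxSeries

        series = ForceFluxSeries(
            t=t, V=np.zeros((n, 3)), F=np.zeros(n), F_mag=np.zeros(n),
            J=np.full(n, 3.0),
        )
        seg = StrokeSegmentation(
            boundaries=np.array([0, n - 1]),
            labels=np.array(["effective"] * n),
            per_cycle=None,
        )
        series = flow_volume(series, seg)
        assert series.cumulative_volume[-1] == pytest.approx(3.0, rel=1e-12)
        assert series.summaries["net_flux_um3_s"] == pytest.approx(3.0, rel=1e-12)

    def test_scallop_degenerate_case_near_zero(self):
        p = WaveformParams(L_eff_um=4.95, L_rec_um=4.95, z_gap_um=0.0,
                           freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=0.0)
        res = FreeBeatAnalysis(generate_free_beating(p, 1)).fit()
        assert abs(res.net_flux_um3_cycle) < 1e-3

    def test_volume_monotone_in_z_gap(self):
        """Scallop theorem: pumped volume grows from zero with the asymmetry."""
        vols = []
        for gap in (0.0, 0.05, 0.1, 0.2):
            p = WaveformParams(L_eff_um=4.95, L_rec_um=4.95, z_gap_um=gap,
                               freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=0.0)
            vols.append(FreeBeatAnalysis(generate_free_beating(p, 1)).fit().net_flux_um3_cycle)
        assert abs(vols[0]) < 1e-3
        assert all(b > a for a, b in zip(vols, vols[1:]))

    def test_enclosed_area_oracle_constant_L(self):
        """Pipeline volume matches the independent shoelace-area closed form."""
        p = WaveformParams(L_eff_um=4.95, L_rec_um=4.95, z_gap_um=0.15,
                           freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=0.0)
        tr = generate_free_beating(p, 1)
        res = FreeBeatAnalysis(tr).fit()
        seg = res.segmentation
        i0, i1 = seg.boundaries[0], seg.boundaries[-1]
        # ∮ z dx = -(shoelace area of the (x, z) polygon)
        area = -shoelace_area(tr.x[i0:i1], tr.z[i0:i1]) / seg.n_cycles
        oracle = 2 * drag_coefficient(4.95, HydroParams()) * area / (3 * np.pi * 1e-3)
        assert res.net_flux_um3_cycle == pytest.approx(oracle, rel=0.01)


class TestFluxEstimate:
    def test_worked_example(self):
        """A = 1/3 um^2, v = 10 um/s -> q = 10/3 ~ 3.33 um^3/s."""
        q = single_cilium_flux_estimate(A_override=1.0 / 3.0, v_um_s=10.0)
        assert q == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_zero_speed(self):
        assert single_cilium_flux_estimate(6.0, 0.4, 0.0) == 0.0

    def test_density_fraction_arithmetic(self):
        assert single_cilium_flux_estimate(2.5, 0.4, 7.0) == pytest.approx(7.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(density_per_um2=-1.0, ciliated_fraction=0.4, v_um_s=1.0),
            dict(density_per_um2=6.0, ciliated_fraction=0.0, v_um_s=1.0),
            dict(A_override=-0.5, v_um_s=1.0),
            dict(density_per_um2=6.0, ciliated_fraction=0.4, v_um_s=-1.0),
        ],
    )
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ParameterError):
            single_cilium_flux_estimate(**kwargs)
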