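"""Model/Results surface tying the analysis stages together.

Two fitted-model entry points mirror the two experimental modes:

* :class:`FreeBeatAnalysis` — free-beating tip trajectory → beating-plane
  alignment, Savitzky-Golay smoothing, stroke segmentation, waveform
  metrics, attachment-point sphere fit, and the Yamakawa drag/flux series.
* :class:`TrapAnalysis` — trapped-phase trajectory → axial amplitude,
  spring forces, peaks per cycle and (optionally) the trapped/free
  frequency ratio.

Both follow the ``model = Analysis(data, ...); results = model.fit()``
idiom; results objects carry the estimates plus ``summary()`` and
``to_report()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import hydro, kinematics, trap
from .errors import FrequencyUndeterminedError, ParameterError
from .hydro import ForceFluxSeries, HydroParams, SphereFit
from .kinematics import StrokeSegmentation, WaveformMetrics
from .trajectory import Trajectory
from .trap import TrapMetrics, TrapParams


def _fmt_row(name, value, unit=""):
    if isinstance(value, float):
        value = f"{value:.4g}"
    return f"{name:<32s} {value:>12} {unit}"


class FreeBeatAnalysis:
    """Full free-beating analysis chain as a fittable model.

    Parameters
    ----------
    trajectory : Trajectory
        Raw or aligned tip trajectory (μm, s).
    hydro_params : HydroParams, optional
        Viscosity/geometry of the drag model (default 1 cP, a = 0.1 μm,
        γ⊥ = 1.111).
    smooth_window : int, optional
        Savitzky-Golay window (samples); default ≈ 10% of the beat period.
    smooth_order : int
        Savitzky-Golay polynomial order (default 4).
    """

    def __init__(
        self,
        trajectory: Trajectory,
        hydro_params: Optional[HydroParams] = None,
        smooth_window: Optional[int] = None,
        smooth_order: int = 4,
    ):
        self.trajectory = trajectory
        self.hydro_params = hydro_params or HydroParams()
        self.smooth_window = smooth_window
        self.smooth_order = smooth_order

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FreeBeatAnalysis":
        return cls(Trajectory.from_frame(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FreeBeatAnalysis":
        from .io import read_trajectory_csv

        return cls(read_trajectory_csv(path), **kwargs)

    def fit(self) -> "FreeBeatResults":
        aligned = kinematics.align_axes(self.trajectory)
        freq = kinematics.beat_frequency(aligned)
        window = self.smooth_window or kinematics.default_smooth_window(
            aligned.sample_rate_hz, freq, self.smooth_order
        )
        smoothed = kinematics.smooth_trajectory(aligned, window, self.smooth_order)
        seg = kinematics.segment_strokes(smoothed, freq_hint=freq)
        metrics = kinematics.waveform_metrics(smoothed, seg, freq=freq)
        sphere = hydro.fit_attachment_sphere(smoothed, seg)
        centered = sphere.recenter(smoothed)
        series = hydro.drag_force(
            centered, seg, sphere, self.hydro_params,
            deriv_window=window, deriv_order=self.smooth_order,
        )
        series = hydro.flux(series, centered, self.hydro_params)
        series = hydro.flow_volume(series, seg)
        return FreeBeatResults(
            model=self,
            aligned=aligned,
            smoothed=centered,
            segmentation=seg,
            waveform=metrics,
            sphere=sphere,
            series=series,
            smooth_window=window,
        )


@dataclass
class FreeBeatResults:
    """Estimates from one free-beating recording."""

    model: FreeBeatAnalysis
    aligned: Trajectory
    smoothed: Trajectory  # smoothed and re-centred on the attachment point
    segmentation: StrokeSegmentation
    waveform: WaveformMetrics
    sphere: SphereFit
    series: ForceFluxSeries
    smooth_window: int

    @property
    def net_flux_um3_cycle(self) -> float:
        return self.series.summaries["net_flux_um3_cycle"]

    @property
    def net_flux_um3_s(self) -> float:
        return self.series.summaries["net_flux_um3_s"]

    @property
    def maxF_effective_pN(self) -> float:
        return self.series.summaries["maxF_effective_pN"]

    @property
    def maxF_recovery_pN(self) -> float:
        return self.series.summaries["maxF_recovery_pN"]

    def to_report(self) -> dict:
        """Flat, units-suffixed report dictionary."""
        c = self.sphere.center_um
        return {
            "freq_hz": self.waveform.freq_hz,
            "x_amplitude_um": self.waveform.x_amplitude_um,
            "z_gap_um": self.waveform.z_gap_um,
            "curvature_radius_um": self.waveform.curvature_radius_um,
            "n_cycles": self.waveform.n_cycles,
            "rotation_deg": self.aligned.rotation_deg,
            "flip_applied": bool(self.aligned.flip_applied),
            "smooth_window_samples": int(self.smooth_window),
            "L_eff_um": self.sphere.L_eff_um,
            "L_rec_um": self.sphere.L_rec_um,
            "center_x_um": float(c[0]),
            "center_y_um": float(c[1]),
            "center_z_um": float(c[2]),
            "sphere_rms_residual_um": self.sphere.rms_residual_um,
            "sphere_method": self.sphere.method,
            "maxF_effective_pN": self.maxF_effective_pN,
            "maxF_recovery_pN": self.maxF_recovery_pN,
            "net_flux_um3_s": self.net_flux_um3_s,
            "net_flux_um3_cycle": self.net_flux_um3_cycle,
            "eta_cp": self.model.hydro_params.eta_cp,
        }

    def summary(self) -> str:
        r = self.to_report()
        lines = [
            "Free-beating cilium analysis",
            "=" * 50,
            _fmt_row("beat frequency", r["freq_hz"], "Hz"),
            _fmt_row("x amplitude (peak-to-peak)", r["x_amplitude_um"], "um"),
            _fmt_row("z-gap (eff - rec)", r["z_gap_um"], "um"),
            _fmt_row("radius of curvature", r["curvature_radius_um"], "um"),
            _fmt_row("cycles analysed", r["n_cycles"]),
            "-" * 50,
            _fmt_row("sphere fit method", r["sphere_method"]),
            _fmt_row("L effective", r["L_eff_um"], "um"),
            _fmt_row("L recovery", r["L_rec_um"], "um"),
            _fmt_row("fit rms residual", r["sphere_rms_residual_um"], "um"),
            "-" * 50,
            _fmt_row("viscosity", r["eta_cp"], "cP"),
            _fmt_row("max |F| effective stroke", r["maxF_effective_pN"], "pN"),
            _fmt_row("max |F| recovery stroke", r["maxF_recovery_pN"], "pN"),
            _fmt_row("net flux", r["net_flux_um3_s"], "um^3/s"),
            _fmt_row("net flux per cycle", r["net_flux_um3_cycle"], "um^3/cycle"),
            "=" * 50,
        ]
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_trajectory(self, ax=None):
        """xz trajectory coloured by stroke phase."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lab = self.segmentation.labels
        for phase, color in (("effective", "tab:orange"), ("recovery", "tab:blue")):
            m = lab == phase
            ax.plot(self.smoothed.x[m], self.smoothed.z[m], ".", ms=2,
                    color=color, label=phase)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("z (um)")
        ax.legend()
        return ax

    def plot_force_flux(self, axes=None):
        """Force and cumulative pumped volume vs time."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 1, sharex=True)
        axes[0].plot(self.series.t, self.series.F)
        axes[0].set_ylabel("F on fluid (pN)")
        axes[1].plot(self.series.t, self.series.cumulative_volume)
        axes[1].set_ylabel("pumped volume (um^3)")
        axes[1].set_xlabel("t (s)")
        return axes


class TrapAnalysis:
    """Trapped-phase analysis as a fittable model.

    ``trap_params`` may be omitted when the trajectory was produced by the
    synthetic generator (stiffness and centre are then read from its
    metadata).  ``free_trajectory`` enables the trapped/free frequency
    ratio.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        trap_params: Optional[TrapParams] = None,
        free_trajectory: Optional[Trajectory] = None,
        smooth_window: Optional[int] = None,
        smooth_order: int = 4,
    ):
        if trap_params is None:
            meta = trajectory.meta
            if "k_z_pn_nm" not in meta:
                raise ParameterError("trap_params required for non-synthetic input")
            trap_params = TrapParams(
                k_xy_pn_nm=meta["k_xy_pn_nm"],
                k_z_pn_nm=meta["k_z_pn_nm"],
                trap_center_um=tuple(meta.get("trap_center_um", (0.0, 0.0, 0.0))),
            )
        self.trajectory = trajectory
        self.trap_params = trap_params
        self.free_trajectory = free_trajectory
        self.smooth_window = smooth_window
        self.smooth_order = smooth_order

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TrapAnalysis":
        return cls(Trajectory.from_frame(df), **kwargs)

    def fit(self) -> "TrapResults":
        traj = self.trajectory
        try:
            freq = kinematics.beat_frequency(traj, axis="z")
        except FrequencyUndeterminedError:
            # z may carry no oscillation (e.g. null axial amplitude);
            # fall back on the residual lateral motion
            freq = kinematics.beat_frequency(traj, axis="x")
        fs = traj.sample_rate_hz
        window = self.smooth_window or trap_smooth_window(fs, freq, self.smooth_order)
        smoothed = kinematics.smooth_trajectory(traj, window, self.smooth_order)
        if np.ptp(traj.z) == 0:
            denoised = traj
            z_amp = 0.0
            peaks = 0
        else:
            # cycle delimitation and peak counting on the running-window
            # smooth; amplitudes/forces on the per-cycle harmonic fit
            # (whose extremes carry no noise-maximum bias)
            bounds = trap._cycle_bounds(smoothed.z, fs, freq, smoothed, "z")
            denoised = trap.harmonic_denoise(traj, freq, cycle_bounds=bounds)
            z_amp = trap.oscillation_amplitude(denoised, axis="z", freq_hint=freq)
            peaks = trap.count_peaks_per_cycle(smoothed, axis="z", freq_hint=freq)
        forces = trap.trap_force_series(denoised, self.trap_params)
        maxFz = float(np.abs(forces["F_z_pN"]).max())
        maxFx = float(np.abs(forces["F_x_pN"]).max())
        ratio = None
        if self.free_trajectory is not None:
            ratio = trap.frequency_ratio(smoothed, self.free_trajectory)
        metrics = TrapMetrics(
            z_amp_nm=z_amp,
            maxF_z_pN=maxFz,
            maxF_x_pN=maxFx,
            freq_trapped_hz=freq,
            freq_ratio=ratio,
            peaks_per_cycle=peaks,
        )
        return TrapResults(
            model=self, smoothed=smoothed, metrics=metrics,
            forces=forces, smooth_window=window,
        )


def trap_smooth_window(sample_rate_hz: float, freq_hz: float, order: int = 4) -> int:
    """Savitzky-Golay window for trapped series: ~1/8 beat period, odd.

    Narrower than the free-beating default so the second-harmonic (2f)
    content that produces the double peak is preserved.
    """
    w = int(round(sample_rate_hz / freq_hz / 8.0))
    if w % 2 == 0:
        w += 1
    return max(w, order + 3 if (order + 3) % 2 == 1 else order + 2)


@dataclass
class TrapResults:
    """Estimates from one trapped-phase recording."""

    model: TrapAnalysis
    smoothed: Trajectory
    metrics: TrapMetrics
    forces: dict = field(repr=False, default_factory=dict)
    smooth_window: int = 0

    def to_report(self) -> dict:
        m = self.metrics
        out = {
            "z_amp_nm": m.z_amp_nm,
            "maxF_z_pN": m.maxF_z_pN,
            "maxF_x_pN": m.maxF_x_pN,
            "freq_trapped_hz": m.freq_trapped_hz,
            "peaks_per_cycle": m.peaks_per_cycle,
            "k_xy_pn_nm": self.model.trap_params.k_xy_pn_nm,
            "k_z_pn_nm": self.model.trap_params.k_z_pn_nm,
            "smooth_window_samples": int(self.smooth_window),
        }
        if m.freq_ratio is not None:
            out["freq_ratio"] = m.freq_ratio
        return out

    def summary(self) -> str:
        r = self.to_report()
        lines = [
            "Trapped-phase cilium analysis",
            "=" * 50,
            _fmt_row("z oscillation amplitude", r["z_amp_nm"], "nm"),
            _fmt_row("max |F_z|", r["maxF_z_pN"], "pN"),
            _fmt_row("max |F_x|", r["maxF_x_pN"], "pN"),
            _fmt_row("oscillation frequency", r["freq_trapped_hz"], "Hz"),
            _fmt_row("peaks per cycle (mode)", r["peaks_per_cycle"]),
            _fmt_row("k_xy", r["k_xy_pn_nm"], "pN/nm"),
            _fmt_row("k_z", r["k_z_pn_nm"], "pN/nm"),
        ]
        if "freq_ratio" in r:
            lines.append(_fmt_row("freq ratio (trapped/free)", r["freq_ratio"]))
        lines.append("=" * 50)
        return "\n".join(lines)

    def plot_z(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.smoothed.t, self.smoothed.z * 1000.0)
        ax.set_xlabel("t (s)")
        ax.set_ylabel("z (nm)")
        return ax
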