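"""Beat-plane alignment, smoothing, stroke segmentation and waveform metrics.

Conventions
-----------
* The beating plane is aligned so the principal lateral axis is x and the
  faster (effective) stroke moves toward +x; z (the optical axis) is never
  touched by alignment.
* "Amplitude" is the per-cycle peak-to-peak x excursion, averaged over
  cycles.  (Half-amplitude conventions exist; this package always reports
  peak-to-peak.)
* Cycles are delimited at x minima, i.e. at the start of the effective
  stroke under the sign convention above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, periodogram, savgol_filter

from .errors import (
    AmbiguousPlaneWarning,
    FrequencyUndeterminedError,
    LowAsymmetryWarning,
    ParameterError,
    SegmentationError,
    UndefinedGapError,
)
from .trajectory import PHASE_EFFECTIVE, PHASE_PAUSE, PHASE_RECOVERY, Trajectory

#: fraction of the cycle's peak speed below which samples are labelled pause
PAUSE_SPEED_FRACTION = 0.1


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------
def align_axes(traj: Trajectory, seg_hint=None) -> Trajectory:
    """Rotate about z so the principal lateral axis is x, effective stroke +x.

    The in-plane rotation comes from the lateral covariance eigenvectors; the
    sign is fixed so that the faster-moving direction of travel is +x.  A
    near-isotropic lateral cloud (principal-axis ratio < 1.2) triggers an
    :class:`AmbiguousPlaneWarning` but alignment proceeds.
    """
    if traj.n < 8:
        raise ParameterError("need at least one beat cycle to align")
    xc = traj.x - traj.x.mean()
    yc = traj.y - traj.y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    ratio = np.sqrt(max(evals) / max(min(evals), 1e-30))
    if ratio < 1.2:
        warnings.warn(
            "lateral motion nearly isotropic; beating-plane rotation uncertain",
            AmbiguousPlaneWarning,
        )
    angle = np.degrees(np.arctan2(major[1], major[0]))
    # keep the rotation minimal (principal axis has sign ambiguity)
    if angle > 90:
        angle -= 180
    elif angle < -90:
        angle += 180
    out = traj.rotated_z(-angle)

    vx = np.gradient(out.x, traj.t)
    fwd = vx > 0
    flip = False
    if fwd.any() and (~fwd).any():
        v_fwd = np.abs(vx[fwd]).mean()
        v_bwd = np.abs(vx[~fwd]).mean()
        if v_bwd > v_fwd * (1 + 1e-9):
            flip = True
    if flip:
        out.x = -out.x
        out.y = -out.y
    out.rotation_deg = float(-angle + (180.0 if flip else 0.0))
    out.flip_applied = flip
    return out


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------
def default_smooth_window(sample_rate_hz: float, freq_hz: float, order: int = 4) -> int:
    """Savitzky-Golay window: ~10% of a beat period, odd, > order."""
    w = int(round(0.1 * sample_rate_hz / freq_hz))
    if w % 2 == 0:
        w += 1
    return max(w, order + 3 if (order + 3) % 2 == 1 else order + 2)


def smooth_trajectory(traj: Trajectory, window_samples: int, order: int = 4) -> Trajectory:
    """Savitzky-Golay smooth all three coordinates; timestamps unchanged."""
    if window_samples % 2 == 0 or window_samples <= order:
        raise ParameterError("window must be odd and greater than the polynomial order")
    if window_samples >= traj.n:
        raise ParameterError("window must be shorter than the series")
    out = traj.copy()
    out.x = savgol_filter(traj.x, window_samples, order)
    out.y = savgol_filter(traj.y, window_samples, order)
    out.z = savgol_filter(traj.z, window_samples, order)
    out.rotation_deg = traj.rotation_deg
    out.flip_applied = traj.flip_applied
    return out


# --------------------------------------------------------------------------
# frequency
# --------------------------------------------------------------------------
def beat_frequency(traj: Trajectory, axis: str = "x", min_snr: float = 5.0) -> float:
    """Dominant periodogram frequency of the chosen coordinate, in Hz.

    Mean-subtracted, Hann-windowed periodogram; the peak bin is refined by
    parabolic interpolation on log-power.  Raises
    :class:`FrequencyUndeterminedError` when no peak stands ``min_snr`` times
    above the median spectral level.
    """
    sig = np.asarray(getattr(traj, axis), dtype=float)
    if traj.n < 16:
        raise FrequencyUndeterminedError("series too short for frequency estimation")
    fs = traj.sample_rate_hz or 1.0 / np.median(np.diff(traj.t))
    f, p = periodogram(sig - sig.mean(), fs=fs, window="hann")
    f, p = f[1:], p[1:]  # drop DC
    if not np.any(p > 0):
        raise FrequencyUndeterminedError("flat signal: no spectral peak")
    k = int(np.argmax(p))
    floor = np.median(p)
    if floor > 0 and p[k] < min_snr * floor:
        raise FrequencyUndeterminedError("no periodogram peak above the noise floor")
    if 0 < k < p.size - 1 and p[k - 1] > 0 and p[k + 1] > 0:
        la, lb, lc = np.log(p[k - 1]), np.log(p[k]), np.log(p[k + 1])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = f[1] - f[0]
    return float(f[k] + delta * df)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------
@dataclass
class StrokeSegmentation:
    """Per-cycle stroke labelling of an aligned trajectory."""

    boundaries: np.ndarray  # indices of cycle starts (x minima), len = n_cycles+1
    labels: np.ndarray  # per-sample phase ('' outside complete cycles)
    per_cycle: pd.DataFrame = field(repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def cycle_slice(self, i: int) -> slice:
        return slice(int(self.boundaries[i]), int(self.boundaries[i + 1]))


def segment_strokes(traj: Trajectory, freq_hint: Optional[float] = None) -> StrokeSegmentation:
    """Delimit beat cycles at x minima and label effective/recovery/pause.

    Each cycle is split at its x maximum into a forward (+x) and a backward
    arc; samples slower than 10% of the cycle's peak speed are labelled
    pause; of the two arcs the one with the higher mean (non-pause) speed is
    the effective stroke.  Ties break toward the +x-moving arc with a
    :class:`LowAsymmetryWarning`.
    """
    f0 = freq_hint if freq_hint is not None else beat_frequency(traj)
    fs = traj.sample_rate_hz or 1.0 / np.median(np.diff(traj.t))
    dist = max(int(0.6 * fs / f0), 1)
    ptp = np.ptp(traj.x)
    if ptp == 0:
        raise SegmentationError("no lateral motion to segment")
    minima, _ = find_peaks(-traj.x, distance=dist, prominence=0.25 * ptp)
    if minima.size < 2:
        raise SegmentationError("fewer than one complete beat cycle detected")

    v = np.linalg.norm(np.gradient(traj.positions, traj.t, axis=0), axis=1)
    labels = np.full(traj.n, "", dtype="<U9")
    rows = []
    for i0, i1 in zip(minima[:-1], minima[1:]):
        sl = slice(i0, i1)
        imax = i0 + int(np.argmax(traj.x[sl]))
        v_cyc = v[sl]
        pause = v_cyc < PAUSE_SPEED_FRACTION * v_cyc.max()
        idx = np.arange(i0, i1)
        up = idx < imax
        lab = np.where(up, "up", "down").astype("<U9")
        lab[pause] = PHASE_PAUSE

        def mean_speed(arc):
            m = lab == arc
            return v[idx[m]].mean() if m.any() else 0.0

        v_up, v_down = mean_speed("up"), mean_speed("down")
        # a few-percent difference is within sampling jitter of a symmetric
        # waveform: treat as a tie and use the sign convention
        if abs(v_up - v_down) <= 0.05 * max(v_up, v_down):
            warnings.warn(
                "effective/recovery mean speeds nearly equal; "
                "labelling the +x-moving arc effective",
                LowAsymmetryWarning,
            )
            eff_arc = "up"
        else:
            eff_arc = "up" if v_up > v_down else "down"
        out = np.where(lab == eff_arc, PHASE_EFFECTIVE,
                       np.where(lab == PHASE_PAUSE, PHASE_PAUSE, PHASE_RECOVERY))
        labels[idx] = out
        dt = 1.0 / fs
        rows.append(
            {
                "start": int(i0),
                "end": int(i1),
                "t_start_s": float(traj.t[i0]),
                "duration_s": float(traj.t[i1] - traj.t[i0]),
                "effective_duration_s": float((out == PHASE_EFFECTIVE).sum() * dt),
                "recovery_duration_s": float((out == PHASE_RECOVERY).sum() * dt),
                "pause_duration_s": float((out == PHASE_PAUSE).sum() * dt),
                "effective_mean_speed_um_s": float(mean_speed(eff_arc)),
                "recovery_mean_speed_um_s": float(
                    mean_speed("down" if eff_arc == "up" else "up")
                ),
                "x_ptp_um": float(np.ptp(traj.x[sl])),
            }
        )
    return StrokeSegmentation(
        boundaries=minima.astype(int),
        labels=labels,
        per_cycle=pd.DataFrame(rows),
    )


# --------------------------------------------------------------------------
# waveform metrics
# --------------------------------------------------------------------------
def x_amplitude(traj: Trajectory, seg: StrokeSegmentation) -> float:
    """Mean over cycles of the per-cycle peak-to-peak x excursion (μm)."""
    return float(seg.per_cycle["x_ptp_um"].mean())


def z_gap(traj: Trajectory, seg: StrokeSegmentation, n_grid: int = 100) -> float:
    """Maximal height difference between the phase-averaged stroke arcs (μm).

    Each phase's (x, z) arc is interpolated cycle-by-cycle onto a common
    100-point x grid spanning the overlap of the two phases' x ranges, then
    averaged across cycles; the returned gap is the maximum over the grid of
    z_effective − z_recovery.
    """
    eff = seg.labels == PHASE_EFFECTIVE
    rec = seg.labels == PHASE_RECOVERY
    if not eff.any() or not rec.any():
        raise UndefinedGapError("both stroke phases are required")
    lo = max(traj.x[eff].min(), traj.x[rec].min())
    hi = min(traj.x[eff].max(), traj.x[rec].max())
    if hi <= lo:
        raise UndefinedGapError("effective and recovery strokes share no x-range")
    grid = np.linspace(lo, hi, n_grid)

    def mean_arc(mask):
        curves = []
        for i in range(seg.n_cycles):
            sl = seg.cycle_slice(i)
            m = mask[sl]
            if m.sum() < 2:
                continue
            xs = traj.x[sl][m]
            zs = traj.z[sl][m]
            order = np.argsort(xs)
            xs, zs = xs[order], zs[order]
            xs, uniq = np.unique(xs, return_index=True)
            curves.append(np.interp(grid, xs, zs[uniq], left=np.nan, right=np.nan))
        if not curves:
            raise UndefinedGapError("no usable cycles for phase averaging")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(np.vstack(curves), axis=0)

    gap = mean_arc(eff) - mean_arc(rec)
    gap = gap[np.isfinite(gap)]
    if gap.size == 0:
        raise UndefinedGapError("phase arcs do not overlap after averaging")
    return float(gap.max())


def per_cycle_z_gap(traj: Trajectory, seg: StrokeSegmentation, n_grid: int = 100) -> np.ndarray:
    """Per-cycle maximal z-gap (supplementary to the phase-averaged gap)."""
    out = []
    for i in range(seg.n_cycles):
        sl = seg.cycle_slice(i)
        sub = Trajectory(
            t=traj.t[sl], x=traj.x[sl], y=traj.y[sl], z=traj.z[sl],
            sample_rate_hz=traj.sample_rate_hz,
        )
        subseg = StrokeSegmentation(
            boundaries=np.array([0, sub.n - 1]),
            labels=seg.labels[sl],
            per_cycle=seg.per_cycle.iloc[[i]],
        )
        try:
            out.append(z_gap(sub, subseg, n_grid))
        except UndefinedGapError:
            out.append(np.nan)
    return np.asarray(out)


def curvature_radius(traj: Trajectory, seg: StrokeSegmentation,
                     phase: str = PHASE_EFFECTIVE) -> float:
    """Radius of the least-squares circle through the phase's (x, z) points.

    Algebraic (Kåsa) fit; collinear points return ``inf``.
    """
    m = seg.labels == phase
    if m.sum() < 5:
        raise ParameterError("need at least 5 points in the analysed phase")
    return fit_circle_radius(traj.x[m], traj.z[m])


def fit_circle_radius(x: np.ndarray, y: np.ndarray) -> float:
    """Kåsa circle fit; returns the radius (``inf`` for collinear input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, res, rank, sval = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sval[-1] < 1e-10 * sval[0]:
        return float("inf")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        return float("inf")
    return float(np.sqrt(r2))


def geometric_summary(values) -> tuple:
    """Geometric mean and geometric s.d. (sample, n−1) of positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty input")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ParameterError("geometric summary requires positive finite values")
    logs = np.log(v)
    gmean = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else 1.0
    return gmean, gsd


@dataclass
class WaveformMetrics:
    """Summary waveform statistics of one free-beating recording."""

    freq_hz: float
    x_amplitude_um: float
    z_gap_um: float
    curvature_radius_um: float
    n_cycles: int
    per_cycle: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")


def waveform_metrics(traj: Trajectory, seg: StrokeSegmentation,
                     freq: Optional[float] = None) -> WaveformMetrics:
    """Compute the standard metric set from an aligned, smoothed trajectory."""
    return WaveformMetrics(
        freq_hz=freq if freq is not None else beat_frequency(traj),
        x_amplitude_um=x_amplitude(traj, seg),
        z_gap_um=z_gap(traj, seg),
        curvature_radius_um=curvature_radius(traj, seg),
        n_cycles=seg.n_cycles,
        per_cycle=seg.per_cycle,
    )
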