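"""Split-image 3-D localization: two-spot Gaussian fitting and z calibration.

Each frame contains two images of the same bead produced by a wedge prism.
Subpixel centres ``(x1, y1)`` and ``(x2, y2)`` come from least-squares 2-D
Gaussian fits; the pair mean gives the lateral position and the half-
difference ``(x1 − x2)/2`` maps linearly to the axial position through a
piezo-calibrated line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from scipy.stats import linregress

from .errors import LocalizationError, ParameterError, TrackingQualityError
from .imaging import ImageStack
from .synth import OpticsParams
from .trajectory import Trajectory

DEFAULT_FIT_WINDOW = 11


@dataclass
class SpotPair:
    """Fitted subpixel centres of the two split images in one frame."""

    x1: float
    y1: float
    x2: float
    y2: float
    amp1: float
    amp2: float
    sigma1: float
    sigma2: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ParameterError("fitted widths must be positive")


@dataclass
class CalibrationCurve:
    """Line mapping the raw half-difference (nm) to true z displacement (nm)."""

    slope: float  # dimensionless: d(half-difference)/dz
    intercept_nm: float
    r_squared: float
    z_step_range_nm: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("calibration slope must be non-zero")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ParameterError("r_squared must lie in [0, 1]")


# --------------------------------------------------------------------------
# single-spot Gaussian fitting
# --------------------------------------------------------------------------
def _gauss_model(theta, xs, ys):
    amp, x0, y0, sigma, offset = theta
    s = math.sqrt(2.0) * sigma
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return amp * np.outer(fy, fx) + offset


def fit_gaussian_spot(frame: np.ndarray, approx_center, window: int = DEFAULT_FIT_WINDOW):
    """Least-squares pixel-integrated 2-D Gaussian fit in a window.

    Returns ``(x0, y0, flux, sigma, offset, residual_rms)``.  Raises
    :class:`LocalizationError` on divergence or amplitude below background.
    """
    h, w = frame.shape
    cx, cy = approx_center
    half = window // 2
    ix = int(round(cx))
    iy = int(round(cy))
    x_lo, x_hi = max(ix - half, 0), min(ix + half + 1, w)
    y_lo, y_hi = max(iy - half, 0), min(iy + half + 1, h)
    if x_hi - x_lo < 5 or y_hi - y_lo < 5:
        raise LocalizationError("fit window extends outside the image")
    sub = frame[y_lo:y_hi, x_lo:x_hi].astype(float)
    xs = np.arange(x_lo, x_hi)
    ys = np.arange(y_lo, y_hi)

    offset0 = float(np.percentile(sub, 10))
    amp0 = float(sub.sum() - offset0 * sub.size)
    if amp0 <= 0:
        raise LocalizationError("no signal above background in the fit window")
    weights = np.clip(sub - offset0, 0, None)
    wsum = weights.sum()
    x0 = float((weights.sum(axis=0) * xs).sum() / wsum)
    y0 = float((weights.sum(axis=1) * ys).sum() / wsum)
    theta0 = np.array([amp0, x0, y0, 1.3, offset0])

    def resid(theta):
        return (_gauss_model(theta, xs, ys) - sub).ravel()

    try:
        res = least_squares(
            resid, theta0,
            bounds=([0, x_lo - 1, y_lo - 1, 0.3, -np.inf],
                    [np.inf, x_hi, y_hi, half + 2, np.inf]),
            xtol=1e-12, ftol=1e-12,
        )
    except Exception as exc:  # pragma: no cover - scipy failure modes
        raise LocalizationError(f"spot fit failed: {exc}") from exc
    amp, x0, y0, sigma, offset = res.x
    peak = amp / (2 * np.pi * sigma**2)
    noise_scale = math.sqrt(max(offset, 1.0))
    if not res.success or amp <= 0 or peak < 2 * noise_scale:
        raise LocalizationError("spot fit diverged or amplitude below background")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return float(x0), float(y0), float(amp), float(sigma), float(offset), rms


def fit_two_spots(
    frame: np.ndarray,
    approx_centers: Sequence,
    window: int = DEFAULT_FIT_WINDOW,
) -> SpotPair:
    """Fit both split images; spot 1 is the one at larger x."""
    (c1, c2) = approx_centers
    f1 = fit_gaussian_spot(frame, c1, window)
    f2 = fit_gaussian_spot(frame, c2, window)
    if f1[0] < f2[0]:
        f1, f2 = f2, f1
    return SpotPair(
        x1=f1[0], y1=f1[1], x2=f2[0], y2=f2[1],
        amp1=f1[2], amp2=f2[2], sigma1=f1[3], sigma2=f2[3],
        residual_rms=float(np.hypot(f1[5], f2[5]) / math.sqrt(2)),
    )


def detect_two_spots(frame: np.ndarray, min_separation_px: float = 5.0):
    """Initial centres from the two dominant intensity maxima."""
    f = np.asarray(frame, dtype=float)
    iy, ix = np.unravel_index(np.argmax(f), f.shape)
    masked = f.copy()
    r = int(math.ceil(min_separation_px))
    y_lo, y_hi = max(iy - r, 0), min(iy + r + 1, f.shape[0])
    x_lo, x_hi = max(ix - r, 0), min(ix + r + 1, f.shape[1])
    masked[y_lo:y_hi, x_lo:x_hi] = f.min()
    jy, jx = np.unravel_index(np.argmax(masked), f.shape)
    return (float(ix), float(iy)), (float(jx), float(jy))


# --------------------------------------------------------------------------
# pair combination and calibration
# --------------------------------------------------------------------------
def combine_pair(pair: SpotPair, cal: CalibrationCurve, pixel_size_nm: float):
    """(x, y, z) in μm from the printed split-image arithmetic.

    x and y are the pair means (the nominal split separation cancels in the
    mean because the two channels move symmetrically); z comes from the
    calibrated half-difference line.
    """
    x_um = (pair.x1 + pair.x2) / 2.0 * pixel_size_nm / 1000.0
    y_um = (pair.y1 + pair.y2) / 2.0 * pixel_size_nm / 1000.0
    half_diff_nm = (pair.x1 - pair.x2) / 2.0 * pixel_size_nm
    z_um = (half_diff_nm - cal.intercept_nm) / cal.slope / 1000.0
    return x_um, y_um, z_um


def raw_half_difference_nm(pair: SpotPair, pixel_size_nm: float) -> float:
    return (pair.x1 - pair.x2) / 2.0 * pixel_size_nm


def calibrate(stack: ImageStack, known_z_nm, window: int = DEFAULT_FIT_WINDOW) -> CalibrationCurve:
    """OLS line of raw half-difference vs piezo-commanded z."""
    known_z = np.asarray(known_z_nm, dtype=float)
    if known_z.size < 2 or np.unique(known_z).size < 2:
        raise ParameterError("need at least 2 distinct known z values")
    if known_z.size != stack.n_frames:
        raise ParameterError("known z values must match the number of frames")
    centers = detect_two_spots(stack.frames[0], stack.optics.spot_separation_px / 2)
    px = stack.optics.pixel_size_nm
    d = np.empty(known_z.size)
    for i in range(stack.n_frames):
        pair = fit_two_spots(stack.frames[i], centers, window)
        d[i] = raw_half_difference_nm(pair, px)
        centers = ((pair.x1, pair.y1), (pair.x2, pair.y2))
    if known_z.size == 2:
        slope = (d[1] - d[0]) / (known_z[1] - known_z[0])
        intercept = d[0] - slope * known_z[0]
        r2 = 1.0
    else:
        fit = linregress(known_z, d)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    if abs(slope) < 1e-6:
        raise ParameterError("degenerate optics: calibration slope ~ 0")
    return CalibrationCurve(
        slope=slope,
        intercept_nm=float(intercept),
        r_squared=r2,
        z_step_range_nm=(float(known_z.min()), float(known_z.max())),
    )


# --------------------------------------------------------------------------
# whole-stack tracking
# --------------------------------------------------------------------------
def track(
    stack: ImageStack,
    cal: CalibrationCurve,
    approx_centers=None,
    window: int = DEFAULT_FIT_WINDOW,
    max_failed_fraction: float = 0.2,
) -> Trajectory:
    """Track the split pair through a stack → 3-D trajectory in μm.

    Each frame's fit is seeded by the previous frame's centres; frames whose
    fit fails are linearly interpolated and flagged (``quality`` False).
    More than ``max_failed_fraction`` failures raises
    :class:`TrackingQualityError`.
    """
    if stack.n_frames == 0:
        raise ParameterError("empty stack")
    if approx_centers is None:
        approx_centers = detect_two_spots(
            stack.frames[0], stack.optics.spot_separation_px / 2
        )
    px = stack.optics.pixel_size_nm
    n = stack.n_frames
    xyz = np.full((n, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    centers = approx_centers
    for i in range(n):
        try:
            pair = fit_two_spots(stack.frames[i], centers, window)
        except LocalizationError:
            continue
        x_um, y_um, z_rel = combine_pair(pair, cal, px)
        xyz[i] = (
            x_um + stack.origin_um[0],
            y_um + stack.origin_um[1],
            z_rel + stack.z_ref_um,
        )
        ok[i] = True
        centers = ((pair.x1, pair.y1), (pair.x2, pair.y2))
    n_failed = int((~ok).sum())
    if n_failed > max_failed_fraction * n or ok.sum() < 2:
        raise TrackingQualityError(
            f"{n_failed}/{n} frames failed localization"
        )
    if n_failed:
        good = np.flatnonzero(ok)
        for axis in range(3):
            xyz[:, axis] = np.interp(np.arange(n), good, xyz[good, axis])
    return Trajectory(
        t=stack.times.copy(),
        x=xyz[:, 0],
        y=xyz[:, 1],
        z=xyz[:, 2],
        quality=ok,
        meta={"source": "tracked", "n_failed_frames": n_failed},
    )


# --------------------------------------------------------------------------
# precision estimate
# --------------------------------------------------------------------------
def localization_precision(optics: OpticsParams) -> dict:
    """Photon-statistics (Thompson-style) localization precision in nm.

    Lateral precision per spot combines PSF width, pixelation and
    background; the pair mean improves it by √2 and the axial estimate
    propagates the half-difference through the calibration slope.
    """
    a = optics.pixel_size_nm
    s = optics.psf_sigma_px * a
    N = optics.photons_per_spot
    b2 = optics.background_per_px + optics.camera_noise_sd**2
    sa2 = s**2 + a**2 / 12.0
    var = sa2 / N + 8 * np.pi * s**4 * b2 / (a**2 * N**2)
    sigma_spot = float(np.sqrt(var))
    sigma_lateral = sigma_spot / math.sqrt(2.0)
    sigma_z = sigma_spot / math.sqrt(2.0) / abs(optics.z_split_slope)
    return {
        "sigma_spot_nm": sigma_spot,
        "sigma_xy_nm": sigma_lateral,
        "sigma_z_nm": sigma_z,
    }
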