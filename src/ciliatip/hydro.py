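"""Slender-body hydrodynamics of a single surface-attached cilium.

The cilium is idealized as a straight chain of beads of radius *a* reaching
from its attachment point (the centre of the sphere the tip trajectory lies
on) to the tip.  The transverse viscous drag on such a chain of length L
moving with tip velocity V is

    |F| = 2π η L |V| / [ln(L / 2a) + γ⊥],        γ⊥ = 1.111 (Yamakawa)

and, because the drag on each segment grows linearly with its height above
the wall, the instantaneous volume flux it imparts to the fluid is

    J = 2 z F_x / (3π η)

with z the tip height above the attachment point and F_x the x-component of
the force exerted *on the fluid* (positive when the tip moves toward +x, the
effective-stroke direction, so the cumulative pumped volume grows over
cycles).  Internal units are μm, s and pN with η stored in pN·s/μm²
(1 cP ≡ 10⁻³ pN·s/μm², exactly), so the formulas evaluate without
conversion factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .errors import FitDegenerateError, ModelDomainError, ParameterError
from .kinematics import StrokeSegmentation
from .trajectory import PHASE_EFFECTIVE, PHASE_PAUSE, PHASE_RECOVERY, Trajectory

#: exact identity: 1 centipoise in pN·s/μm²
CP_TO_PN_S_UM2 = 1.0e-3

#: Yamakawa end-correction constant for transverse drag on a slender cylinder
GAMMA_PERP = 1.111


@dataclass
class HydroParams:
    """Viscous-drag model parameters."""

    eta_cp: float = 1.0  # medium viscosity in centipoise
    a_um: float = 0.1  # cilium radius
    gamma_perp: float = GAMMA_PERP

    def __post_init__(self) -> None:
        if self.eta_cp <= 0 or self.a_um <= 0:
            raise ParameterError("viscosity and cilium radius must be positive")

    @property
    def eta(self) -> float:
        """Viscosity in internal units (pN·s/μm²)."""
        return self.eta_cp * CP_TO_PN_S_UM2


def drag_coefficient(L_um: float, hydro: HydroParams) -> float:
    """c(L) = 2π η L / [ln(L/2a) + γ⊥] in pN·s/μm (so F = c·V)."""
    L = np.asarray(L_um, dtype=float)
    denom = np.log(L / (2 * hydro.a_um)) + hydro.gamma_perp
    if np.any(L <= 2 * hydro.a_um) or np.any(denom <= 0):
        raise ModelDomainError("drag formula requires L > 2a and ln(L/2a) + gamma > 0")
    return 2 * np.pi * hydro.eta * L / denom


# --------------------------------------------------------------------------
# attachment-point sphere fit
# --------------------------------------------------------------------------
@dataclass
class SphereFit:
    """Shared-centre, per-phase-radius sphere fit of a tip trajectory."""

    center_um: np.ndarray
    L_eff_um: float
    L_rec_um: float
    rms_residual_um: float
    method: str  # 'free_center' or 'plane_constrained'

    def __post_init__(self) -> None:
        self.center_um = np.asarray(self.center_um, dtype=float)
        if self.L_eff_um <= 0 or self.L_rec_um <= 0:
            raise ParameterError("fitted radii must be positive")

    def recenter(self, traj: Trajectory) -> Trajectory:
        """Translate a trajectory so the fitted centre is the origin."""
        return traj.translated(-self.center_um)

    def radius_for_phase(self, phase_labels: np.ndarray) -> np.ndarray:
        """Per-sample radius; pause samples inherit the preceding stroke."""
        L = np.where(phase_labels == PHASE_EFFECTIVE, self.L_eff_um,
                     np.where(phase_labels == PHASE_RECOVERY, self.L_rec_um, np.nan))
        # forward-fill pauses / unlabelled samples with the preceding stroke
        last = self.L_eff_um
        for i in range(L.size):
            if np.isnan(L[i]):
                L[i] = last
            else:
                last = L[i]
        return L


#: free-fit fall-back triggers
_CENTER_Y_TOL_UM = 1.0
_CONDITION_LIMIT = 1.0e6


def fit_attachment_sphere(traj: Trajectory, seg: StrokeSegmentation) -> SphereFit:
    """Joint least-squares sphere fit with shared centre, per-phase radii.

    Both stroke phases are fitted together: residual ``|p − c| − L_phase``.
    If the free fit is degenerate (ill-conditioned normal equations, or a
    centre implausibly far off the beating plane) the fit is repeated with
    the centre's y fixed at the trajectory's mean y, and ``method`` records
    the fall-back.
    """
    eff = seg.labels == PHASE_EFFECTIVE
    rec = seg.labels == PHASE_RECOVERY
    if eff.sum() < 4 or rec.sum() < 4:
        raise FitDegenerateError("need both stroke phases for the sphere fit")
    # samples next to a label change are phase-ambiguous (the tip is mid
    # transition between the two sphere radii); keep the stroke cores
    core = np.zeros(seg.labels.size, dtype=bool)
    for m in (eff, rec):
        interior = m.copy()
        change = np.flatnonzero(np.diff(m.astype(int)) != 0)
        for i in change:
            interior[max(i - 2, 0) : i + 4] = False
        core |= interior & m
    if core[eff].sum() >= 4 and core[rec].sum() >= 4:
        eff = eff & core
        rec = rec & core
    pts = traj.positions
    p = pts[eff | rec]
    is_eff = eff[eff | rec]

    # algebraic initialization: |p|^2 - 2 p·c + (|c|^2 - L_ph^2) = 0 is linear
    # in (c, k_eff, k_rec)
    A = np.column_stack([
        2 * p,
        np.where(is_eff, -1.0, 0.0),
        np.where(is_eff, 0.0, -1.0),
    ])
    b = (p**2).sum(axis=1)
    sol, _, rank, sval = np.linalg.lstsq(A, b, rcond=None)
    cond = sval[0] / max(sval[-1], 1e-300)
    c0 = sol[:3]
    mean_y = float(traj.y.mean())
    degenerate = (
        rank < 5
        or cond > _CONDITION_LIMIT
        or abs(c0[1] - mean_y) > _CENTER_Y_TOL_UM
    )

    def residuals(theta, fix_y=None):
        if fix_y is None:
            c = theta[:3]
            Le, Lr = theta[3], theta[4]
        else:
            c = np.array([theta[0], fix_y, theta[1]])
            Le, Lr = theta[2], theta[3]
        d = np.linalg.norm(p - c[None, :], axis=1)
        return d - np.where(is_eff, Le, Lr)

    def radii_guess(c):
        d = np.linalg.norm(p - np.asarray(c)[None, :], axis=1)
        return float(d[is_eff].mean()), float(d[~is_eff].mean())

    if not degenerate:
        Le0, Lr0 = radii_guess(c0)
        res = least_squares(residuals, np.r_[c0, Le0, Lr0], method="lm")
        center = res.x[:3]
        Le, Lr = res.x[3], res.x[4]
        ok = (
            res.x[3] > 0 and res.x[4] > 0
            and abs(center[1] - mean_y) <= _CENTER_Y_TOL_UM
        )
        if ok:
            rms = float(np.sqrt(np.mean(res.fun**2)))
            return SphereFit(center, float(Le), float(Lr), rms, "free_center")
        degenerate = True

    # plane-constrained fall-back: centre y fixed on the beating plane
    c_init = np.array([float(traj.x.mean()), mean_y, float(traj.z.mean() - np.ptp(traj.z))])
    if np.all(np.isfinite(c0)) and cond < 1e12:
        c_init = np.array([c0[0], mean_y, c0[2]])
    Le0, Lr0 = radii_guess(c_init)
    theta0 = np.array([c_init[0], c_init[2], max(Le0, 1e-3), max(Lr0, 1e-3)])
    res = least_squares(residuals, theta0, kwargs={"fix_y": mean_y}, method="lm")
    center = np.array([res.x[0], mean_y, res.x[1]])
    Le, Lr = float(res.x[2]), float(res.x[3])
    if Le <= 0 or Lr <= 0 or not np.all(np.isfinite(res.x)):
        raise FitDegenerateError("sphere fit failed even with plane-constrained centre")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return SphereFit(center, Le, Lr, rms, "plane_constrained")


# --------------------------------------------------------------------------
# force, flux, pumped volume
# --------------------------------------------------------------------------
@dataclass
class ForceFluxSeries:
    """Time series of tip velocity, drag force, flux and pumped volume."""

    t: np.ndarray
    V: np.ndarray  # (n, 3) tip velocity, μm/s
    F: np.ndarray  # signed force on the fluid along x, pN
    F_mag: np.ndarray  # |F| from the full tip speed, pN
    J: Optional[np.ndarray] = None  # instantaneous flux, μm³/s
    cumulative_volume: Optional[np.ndarray] = None  # μm³
    summaries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_s": self.t,
                "vx_um_s": self.V[:, 0],
                "vy_um_s": self.V[:, 1],
                "vz_um_s": self.V[:, 2],
                "F_pN": self.F,
            }
        )
        if self.J is not None:
            df["J_um3_s"] = self.J
        if self.cumulative_volume is not None:
            df["cumvol_um3"] = self.cumulative_volume
        return df


def drag_force(
    traj: Trajectory,
    seg: StrokeSegmentation,
    sphere: SphereFit,
    hydro: HydroParams,
    deriv_window: Optional[int] = None,
    deriv_order: int = 4,
) -> ForceFluxSeries:
    """Fill V and F: Yamakawa chain drag from the smoothed tip velocity.

    ``traj`` must already be centred on the fitted attachment point (see
    :meth:`SphereFit.recenter`); per-sample L is the radius of the sample's
    stroke phase.  On uniformly sampled data the velocity comes from the
    derivative of the local Savitzky-Golay polynomial (window
    ``deriv_window``), which is higher-order accurate than centred
    differences; otherwise centred differences are used.
    """
    dt = np.diff(traj.t)
    uniform = np.allclose(dt, dt[0], rtol=1e-6) if dt.size else False
    if (
        uniform
        and deriv_window is not None
        and deriv_window % 2 == 1
        and deriv_order < deriv_window <= traj.n
    ):
        from scipy.signal import savgol_filter

        V = np.column_stack([
            savgol_filter(getattr(traj, ax), deriv_window, deriv_order,
                          deriv=1, delta=float(dt[0]))
            for ax in ("x", "y", "z")
        ])
    else:
        V = np.gradient(traj.positions, traj.t, axis=0)
    L = sphere.radius_for_phase(seg.labels)
    c = drag_coefficient(L, hydro)
    F = c * V[:, 0]
    F_mag = c * np.linalg.norm(V, axis=1)
    return ForceFluxSeries(t=traj.t.copy(), V=V, F=F, F_mag=F_mag)


def flux(series: ForceFluxSeries, traj: Trajectory, hydro: HydroParams) -> ForceFluxSeries:
    """Fill J = 2·z·F_x/(3π η); z measured from the attachment point."""
    series.J = 2.0 * traj.z * series.F / (3.0 * np.pi * hydro.eta)
    return series


def flow_volume(series: ForceFluxSeries, seg: StrokeSegmentation) -> ForceFluxSeries:
    """Fill the cumulative pumped volume and the summary statistics.

    Net flux per second uses the whole series; net flux per cycle integrates
    over the integer number of complete cycles the segmentation delimits.
    The running cumulative volume is trapezoidal; the net summaries use
    Simpson quadrature on the same J series (higher-order, so the spurious
    O(dt²) residual of a retraced loop vanishes below the physical signal).
    Maximal |F| is reported per stroke phase over complete cycles.
    """
    from scipy.integrate import simpson

    if series.J is None:
        raise ParameterError("flux must be computed before flow_volume")
    vol = cumulative_trapezoid(series.J, series.t, initial=0.0)
    series.cumulative_volume = vol
    duration = series.t[-1] - series.t[0]
    summaries = {
        "net_flux_um3_s": float(simpson(series.J, x=series.t) / duration)
        if duration > 0
        else np.nan,
    }
    if seg.n_cycles >= 1:
        i0, i1 = int(seg.boundaries[0]), int(seg.boundaries[-1])
        summaries["net_flux_um3_cycle"] = float(
            simpson(series.J[i0 : i1 + 1], x=series.t[i0 : i1 + 1]) / seg.n_cycles
        )
        inside = np.zeros(series.t.size, dtype=bool)
        inside[i0:i1] = True
        m_eff = inside & (seg.labels == PHASE_EFFECTIVE)
        m_rec = inside & (seg.labels == PHASE_RECOVERY)
        summaries["maxF_effective_pN"] = float(np.abs(series.F[m_eff]).max()) if m_eff.any() else np.nan
        summaries["maxF_recovery_pN"] = float(np.abs(series.F[m_rec]).max()) if m_rec.any() else np.nan
    else:
        warnings.warn("fewer than one complete cycle: per-cycle flux unavailable")
        summaries["net_flux_um3_cycle"] = np.nan
        summaries["maxF_effective_pN"] = np.nan
        summaries["maxF_recovery_pN"] = np.nan
    series.summaries.update(summaries)
    return series


def single_cilium_flux_estimate(
    density_per_um2: Optional[float] = None,
    ciliated_fraction: Optional[float] = None,
    v_um_s: float = 0.0,
    A_override: Optional[float] = None,
) -> float:
    """Order-of-magnitude flux per cilium from tissue-level numbers: q = A·v.

    ``A`` is the surface area worked by one cilium, either given directly or
    as 1/(areal density × ciliated fraction); ``v`` is the measured surface
    flow speed.
    """
    if v_um_s < 0:
        raise ParameterError("flow speed must be non-negative")
    if A_override is not None:
        if A_override <= 0:
            raise ParameterError("A_override must be positive")
        A = A_override
    else:
        if density_per_um2 is None or ciliated_fraction is None:
            raise ParameterError("provide density and ciliated fraction, or A_override")
        if density_per_um2 <= 0 or not 0 < ciliated_fraction <= 1:
            raise ParameterError("density must be > 0 and ciliated fraction in (0, 1]")
        A = 1.0 / (density_per_um2 * ciliated_fraction)
    return float(A * v_um_s)


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the closed polygon (x, y) — independent loop oracle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
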