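"""Synthetic stand-in for the microscope: beating, trapping, imaging.

The free-beating generator emulates the tip of a single surface-attached
cilium whose bead-capped end sweeps two convex arcs on a sphere centred at
the attachment point: a fast *effective* stroke at greater height and a
slower *recovery* stroke below it, joined by short low-speed dwells.  The
trapped-phase generator emulates the near-linear axial oscillation (with a
second-harmonic component producing two peaks per cycle) that a bead held in
an optical trap displays.  The imaging generator renders each position as a
pair of Gaussian spots whose half-difference along x encodes z — the
split-beam (wedge-prism) detection scheme — plus a piezo-style calibration
stack with known axial steps.

Geometry of the free beat
-------------------------
Both stroke arcs are circles on their phase's sphere passing through a
shared pair of endpoint directions ``u± = (±sx, 0, uz0)`` at azimuth
``±x_amplitude/2``.  Each circle is the sphere's intersection with a plane
tilted by an angle ψ about the x-axis: ψ → π/2 is the vertical great circle
(maximal bulge), ψ → 0 a flat horizontal arc.  The effective stroke uses a
fixed default tilt; the recovery tilt is solved so the apex-height
difference equals the requested z-gap.  Within a stroke the tip advances
with a half-cosine displacement profile (speed ∝ sin(πs)), giving smooth
starts/stops without spending long below the segmenter's pause threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import GeometryError, ParameterError
from .imaging import ImageStack, render_spot
from .trajectory import PHASE_EFFECTIVE, PHASE_PAUSE, PHASE_RECOVERY, Trajectory

#: acquisition rate of the reference instrument (frames per second)
DEFAULT_SAMPLE_RATE_HZ = 354.61

#: default tilt of the effective-stroke arc plane from horizontal (rad).
#: Together with the default radii/z-gap below this is a calibration
#: constant chosen so the hydrodynamic model's per-cycle pumped volume and
#: per-stroke peak forces on default synthetic data land at the magnitudes
#: measured for live tracheal cilia (≈0.8 μm³/cycle, ≈0.6/0.4 pN).
DEFAULT_PSI_EFF_RAD = np.deg2rad(70.0)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------
@dataclass
class WaveformParams:
    """Free-beating waveform parameters (defaults: 1 cP conditions).

    ``freq_hz``/``x_amplitude_um`` are ensemble means; each generated
    trajectory draws its own value log-normally with the matching ``*_sd``
    (set the sd to 0 for a deterministic waveform).  ``L_eff``/``L_rec`` are
    the sphere radii (tip-to-attachment distance) of the two phases;
    ``z_gap_um`` the maximal height difference between the two arcs.
    """

    L_eff_um: float = 4.95
    L_rec_um: float = 4.90
    freq_hz: float = 4.9
    freq_sd_hz: float = 1.4
    x_amplitude_um: float = 3.6
    x_amplitude_sd_um: float = 1.4
    z_gap_um: float = 0.15
    duty_effective: float = 0.35
    pause_fraction: float = 0.1
    viscosity_cp: float = 1.0
    noise_sd_nm: float = 10.0
    n_cycles: int = 10
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    psi_eff_rad: float = DEFAULT_PSI_EFF_RAD
    #: None: clamp an infeasible z-gap into range only when amplitude is
    #: drawn per seed; True/False force the behaviour
    clamp_z_gap: "bool | None" = None

    def __post_init__(self) -> None:
        if self.L_eff_um <= 0 or self.L_rec_um <= 0:
            raise ParameterError("sphere radii must be positive")
        if not 0 < self.duty_effective < 1:
            raise ParameterError("duty_effective must lie in (0, 1)")
        if not 0 <= self.pause_fraction < 1 - self.duty_effective:
            raise ParameterError("pause_fraction must leave room for the recovery stroke")
        if self.freq_hz <= 0:
            raise ParameterError("freq_hz must be positive")
        if not 0 < self.x_amplitude_um < 2 * min(self.L_eff_um, self.L_rec_um):
            raise ParameterError("x_amplitude_um must lie in (0, 2*min(L_eff, L_rec))")
        if self.z_gap_um < 0:
            raise ParameterError("z_gap_um must be non-negative")
        if self.noise_sd_nm < 0 or self.freq_sd_hz < 0 or self.x_amplitude_sd_um < 0:
            raise ParameterError("spreads must be non-negative")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        if not 0 < self.psi_eff_rad <= np.pi / 2:
            raise ParameterError("psi_eff_rad must lie in (0, pi/2]")

    @classmethod
    def defaults_1cp(cls, **overrides) -> "WaveformParams":
        """Buffer-viscosity conditions (beat 4.9 ± 1.4 Hz, amplitude 3.6 ± 1.4 μm)."""
        return cls(**overrides)

    @classmethod
    def defaults_15cp(cls, **overrides) -> "WaveformParams":
        """Methylcellulose conditions (beat 3.0 ± 0.5 Hz, amplitude 2.9 ± 0.7 μm)."""
        base = dict(
            freq_hz=3.0,
            freq_sd_hz=0.5,
            x_amplitude_um=2.9,
            x_amplitude_sd_um=0.7,
            viscosity_cp=15.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class OpticsParams:
    """Split-beam imaging parameters (invented plumbing for the wedge prism)."""

    pixel_size_nm: float = 100.0
    psf_sigma_px: float = 1.3
    photons_per_spot: float = 5000.0
    background_per_px: float = 10.0
    camera_noise_sd: float = 2.0
    z_split_slope: float = 0.5
    spot_separation_px: float = 20.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "psf_sigma_px", "photons_per_spot", "spot_separation_px"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.background_per_px < 0 or self.camera_noise_sd < 0:
            raise ParameterError("background/camera noise must be non-negative")
        if self.z_split_slope == 0:
            raise ParameterError("z_split_slope must be non-zero")


@dataclass
class TrapSimParams:
    """Kinematic emulation of the trapped-phase oscillation.

    ``z_amp_nm`` is the half peak-to-peak axial amplitude; the waveform is
    centred between its extremes so the maximal excursion from the trap
    centre equals ``z_amp_nm`` (making stiffness × amplitude the maximal
    trap force, the force-from-amplitude estimator).
    """

    k_xy_pn_nm: float = 0.29
    k_z_pn_nm: float = 0.10
    trap_center_um: tuple = (0.0, 0.0, 0.0)
    z_amp_nm: float = 154.7
    freq_hz: float = 4.9
    second_harmonic_frac: float = 0.5
    second_harmonic_phase_rad: float = np.pi / 2
    residual_xy_amp_nm: float = 30.0
    noise_sd_nm: float = 10.0
    n_cycles: int = 10
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.k_xy_pn_nm < 0 or self.k_z_pn_nm < 0:
            raise ParameterError("trap stiffnesses must be non-negative")
        if self.z_amp_nm < 0:
            raise ParameterError("z_amp_nm must be non-negative")
        if not 0 <= self.second_harmonic_frac <= 1:
            raise ParameterError("second_harmonic_frac must lie in [0, 1]")
        if self.freq_hz <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("frequencies must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.residual_xy_amp_nm < 0 or self.noise_sd_nm < 0:
            raise ParameterError("amplitudes/noise must be non-negative")


# --------------------------------------------------------------------------
# stroke-arc geometry
# --------------------------------------------------------------------------
@dataclass
class _Arc:
    """Circle on a sphere of radius L: plane tilted by psi about x."""

    L: float
    psi: float
    sx: float
    uz0: float
    d: float = field(init=False)
    r: float = field(init=False)
    phi_end: float = field(init=False)

    def __post_init__(self) -> None:
        self.d = self.uz0 * math.cos(self.psi)
        self.r = math.sqrt(max(1.0 - self.d**2, 0.0))
        if self.r < self.sx:
            raise ParameterError("arc tilt incompatible with amplitude")
        self.phi_end = math.acos(min(self.sx / self.r, 1.0))

    def points(self, phi: np.ndarray) -> np.ndarray:
        """(n, 3) positions in micrometres at circle angles ``phi``."""
        sp, cp = np.sin(self.psi), np.cos(self.psi)
        x = self.r * np.cos(phi)
        y = -self.d * sp + self.r * np.sin(phi) * cp
        z = self.d * cp + self.r * np.sin(phi) * sp
        return self.L * np.column_stack([x, y, z])

    @property
    def apex_z(self) -> float:
        return self.L * (self.d * math.cos(self.psi) + self.r * math.sin(self.psi))

    @property
    def arc_angle(self) -> float:
        return np.pi - 2 * self.phi_end


def _apex_height(L: float, psi: float, uz0: float) -> float:
    d = uz0 * math.cos(psi)
    return L * (d * math.cos(psi) + math.sqrt(max(1.0 - d**2, 0.0)) * math.sin(psi))


def feasible_z_gap_range(L_eff, L_rec, amplitude, psi_eff=DEFAULT_PSI_EFF_RAD):
    """(min, max) apex-height gap achievable for this amplitude and radii."""
    sx = amplitude / (2 * L_eff)
    uz0 = math.sqrt(1 - sx**2)
    apex_e = _apex_height(L_eff, psi_eff, uz0)
    return apex_e - L_rec, apex_e - L_rec * uz0


def solve_stroke_arcs(L_eff, L_rec, amplitude, z_gap, psi_eff=DEFAULT_PSI_EFF_RAD,
                      strict=True):
    """Build the effective/recovery arcs realizing (amplitude, z_gap).

    Returns ``(arc_eff, arc_rec, realized_gap)``.  When ``strict`` is False
    an infeasible gap is clamped into the achievable range (used for
    ensemble draws where amplitude varies per seed); otherwise a
    :class:`ParameterError` is raised.
    """
    sx = amplitude / (2 * L_eff)
    if sx >= 1:
        raise ParameterError("amplitude exceeds the effective-stroke sphere diameter")
    uz0 = math.sqrt(1 - sx**2)
    arc_eff = _Arc(L_eff, psi_eff, sx, uz0)
    gap_min, gap_max = feasible_z_gap_range(L_eff, L_rec, amplitude, psi_eff)
    target_gap = z_gap
    if not gap_min - 1e-12 <= z_gap <= gap_max + 1e-12:
        if strict:
            raise ParameterError(
                f"z_gap {z_gap:.3g} um infeasible for L_eff={L_eff}, L_rec={L_rec}, "
                f"amplitude={amplitude:.3g}: achievable range "
                f"[{gap_min:.3g}, {gap_max:.3g}] um"
            )
        target_gap = float(np.clip(z_gap, gap_min + 0.1 * (gap_max - gap_min),
                                   gap_max - 0.1 * (gap_max - gap_min)))
    if z_gap == 0.0 and L_eff == L_rec:
        # exact degenerate case: both phases trace the same circle
        return arc_eff, _Arc(L_rec, psi_eff, sx, uz0), 0.0
    target_apex = arc_eff.apex_z - target_gap

    def f(psi):
        return _apex_height(L_rec, psi, uz0) - target_apex

    psi_rec = brentq(f, 1e-9, np.pi / 2, xtol=1e-14)
    return arc_eff, _Arc(L_rec, psi_rec, sx, uz0), target_gap


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------
def _half_cosine(s: np.ndarray) -> np.ndarray:
    """Displacement profile with speed ∝ sin(πs): smooth start and stop."""
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _lognormal_draw(rng, mean, sd):
    """Draw with arithmetic mean ``mean`` and s.d. ``sd`` (sd=0 → mean)."""
    if sd == 0:
        return float(mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_free_beating(params: WaveformParams, seed: int) -> Trajectory:
    """Synthesize a free-beating tip trajectory.

    The per-trajectory beat frequency and x-amplitude are drawn log-normally
    around the configured means (between-cilium variability); the waveform is
    strictly periodic within one trajectory.  Noiseless samples of the two
    stroke phases lie exactly on their phase's sphere about the origin.
    """
    rng = np.random.default_rng(seed)
    freq = _lognormal_draw(rng, params.freq_hz, params.freq_sd_hz)
    freq = float(np.clip(freq, 0.5, 50.0))
    amp = _lognormal_draw(rng, params.x_amplitude_um, params.x_amplitude_sd_um)
    amp = float(np.clip(amp, 0.4, 1.9 * min(params.L_eff_um, params.L_rec_um)))
    if params.clamp_z_gap is None:
        strict = params.freq_sd_hz == 0 and params.x_amplitude_sd_um == 0
    else:
        strict = not params.clamp_z_gap
    arc_e, arc_r, realized_gap = solve_stroke_arcs(
        params.L_eff_um, params.L_rec_um, amp, params.z_gap_um,
        params.psi_eff_rad, strict=strict,
    )

    fs = params.sample_rate_hz
    period = 1.0 / freq
    n = int(round(params.n_cycles * period * fs))
    t = np.arange(n) / fs
    u = (t * freq) % 1.0

    duty = params.duty_effective
    pf = params.pause_fraction
    b1 = duty                      # end of effective stroke
    b2 = duty + pf / 2             # end of top dwell
    b3 = 1.0 - pf / 2              # end of recovery stroke

    pos = np.empty((n, 3))
    phase = np.empty(n, dtype="<U9")

    sx = amp / (2 * params.L_eff_um)
    uz0 = math.sqrt(1 - sx**2)
    u_plus = np.array([sx, 0.0, uz0])
    u_minus = np.array([-sx, 0.0, uz0])

    m_eff = u < b1
    s = u[m_eff] / duty
    # effective stroke sweeps -x -> +x: phi from pi - phi_end down to phi_end
    phi = (np.pi - arc_e.phi_end) - arc_e.arc_angle * _half_cosine(s)
    pos[m_eff] = arc_e.points(phi)
    phase[m_eff] = PHASE_EFFECTIVE

    m_top = (u >= b1) & (u < b2)
    if pf > 0:
        s = (u[m_top] - b1) / (pf / 2)
        L = params.L_eff_um + (params.L_rec_um - params.L_eff_um) * _half_cosine(s)
        pos[m_top] = L[:, None] * u_plus[None, :]
        phase[m_top] = PHASE_PAUSE

    m_rec = (u >= b2) & (u < b3)
    s = (u[m_rec] - b2) / (b3 - b2)
    # recovery sweeps +x -> -x: phi from phi_end up to pi - phi_end
    phi = arc_r.phi_end + arc_r.arc_angle * _half_cosine(s)
    pos[m_rec] = arc_r.points(phi)
    phase[m_rec] = PHASE_RECOVERY

    m_bot = u >= b3
    if pf > 0:
        s = (u[m_bot] - b3) / (pf / 2)
        L = params.L_rec_um + (params.L_eff_um - params.L_rec_um) * _half_cosine(s)
        pos[m_bot] = L[:, None] * u_minus[None, :]
        phase[m_bot] = PHASE_PAUSE
    elif np.any(m_bot):  # pf == 0: collapse dwell masks onto the strokes
        pos[m_bot] = arc_r.points(np.full(m_bot.sum(), np.pi - arc_r.phi_end))
        phase[m_bot] = PHASE_RECOVERY

    if params.noise_sd_nm > 0:
        pos = pos + rng.normal(0.0, params.noise_sd_nm / 1000.0, size=pos.shape)

    return Trajectory(
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        z=pos[:, 2],
        sample_rate_hz=fs,
        phase=phase,
        meta={
            "source": "synthetic",
            "seed": int(seed),
            "viscosity_cp": params.viscosity_cp,
            "realized_freq_hz": freq,
            "realized_amplitude_um": amp,
            "realized_z_gap_um": realized_gap,
            "L_eff_um": params.L_eff_um,
            "L_rec_um": params.L_rec_um,
            "psi_eff_rad": float(arc_e.psi),
            "psi_rec_rad": float(arc_r.psi),
            "duty_effective": duty,
            "pause_fraction": pf,
        },
    )


def trapped_waveform(u: np.ndarray, frac: float, phase_rad: float) -> np.ndarray:
    """Normalized trapped-phase z waveform at cycle positions ``u`` ∈ [0, 1).

    ``sin(2πu) + frac·sin(4πu + phase)``, centred between its extremes and
    scaled to half peak-to-peak 1.  The second harmonic produces the second
    peak per cycle seen in trapped beating.
    """
    dense = np.sin(2 * np.pi * np.linspace(0, 1, 4096, endpoint=False))
    dense = dense + frac * np.sin(4 * np.pi * np.linspace(0, 1, 4096, endpoint=False) + phase_rad)
    lo, hi = dense.min(), dense.max()
    mid, half = (hi + lo) / 2, (hi - lo) / 2
    s = np.sin(2 * np.pi * u) + frac * np.sin(4 * np.pi * u + phase_rad)
    if half == 0:
        return np.zeros_like(s)
    return (s - mid) / half


def generate_trapped_phase(params: TrapSimParams, seed: int) -> Trajectory:
    """Synthesize a trapped-phase trajectory (near-linear z oscillation)."""
    rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    period = 1.0 / params.freq_hz
    n = int(round(params.n_cycles * period * fs))
    t = np.arange(n) / fs
    u = (t * params.freq_hz) % 1.0

    cx, cy, cz = params.trap_center_um
    z = cz + (params.z_amp_nm / 1000.0) * trapped_waveform(
        u, params.second_harmonic_frac, params.second_harmonic_phase_rad
    )
    theta_x, theta_y = rng.uniform(0, 2 * np.pi, size=2)
    r_um = params.residual_xy_amp_nm / 1000.0
    x = cx + r_um * np.sin(2 * np.pi * params.freq_hz * t + theta_x)
    y = cy + r_um * np.sin(2 * np.pi * params.freq_hz * t + theta_y)

    pos = np.column_stack([x, y, z])
    if params.noise_sd_nm > 0:
        pos = pos + rng.normal(0.0, params.noise_sd_nm / 1000.0, size=pos.shape)

    return Trajectory(
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        z=pos[:, 2],
        sample_rate_hz=fs,
        meta={
            "source": "synthetic",
            "seed": int(seed),
            "trapped": True,
            "k_xy_pn_nm": params.k_xy_pn_nm,
            "k_z_pn_nm": params.k_z_pn_nm,
            "trap_center_um": list(params.trap_center_um),
            "z_amp_nm": params.z_amp_nm,
            "freq_hz": params.freq_hz,
        },
    )


#: reference trap-event statistics used for ensemble draws (pN, nm)
TRAP_MAX_FORCE_MEAN_PN = 11.1
TRAP_MAX_FORCE_SD_PN = 5.6
TRAP_Z_AMP_MEAN_NM = 154.7
_TRAP_KZ_LOG_SD = 0.0998  # ≈10% CV of the per-event effective stiffness


def draw_trap_event(seed: int, base: TrapSimParams | None = None) -> TrapSimParams:
    """Per-event trap parameters for one trajectory seed.

    Trap events behave as roughly constant-force oscillators: the maximal
    force is drawn log-normally (mean 11.1, sd 5.6 pN), the per-event
    effective axial stiffness log-normally about a geometric mean chosen so
    the expected amplitude is 154.7 nm, and the amplitude is force/stiffness.
    The draw uses a stream independent of (but derived from) the trajectory
    seed, so one integer fully determines an event.
    """
    base = base or TrapSimParams()
    rng = np.random.default_rng([int(seed), 1])
    kz_gmean = (TRAP_MAX_FORCE_MEAN_PN / TRAP_Z_AMP_MEAN_NM) * math.exp(_TRAP_KZ_LOG_SD**2 / 2)
    f_max = _lognormal_draw(rng, TRAP_MAX_FORCE_MEAN_PN, TRAP_MAX_FORCE_SD_PN)
    k_z = float(rng.lognormal(math.log(kz_gmean), _TRAP_KZ_LOG_SD))
    freq = float(np.clip(_lognormal_draw(rng, base.freq_hz, 1.4), 0.5, 50.0))
    return replace(
        base,
        k_z_pn_nm=k_z,
        k_xy_pn_nm=2.9 * k_z,
        z_amp_nm=f_max / k_z,
        freq_hz=freq,
    )


def _stratified_lognormal(rng, mean, sd, n):
    """n stratified (Latin-hypercube) draws from lognormal(mean, sd).

    One draw per probability stratum, randomly jittered and permuted: the
    marginal distribution is unchanged but a small synthetic cohort spans
    it the way a real n-of-tens study does, without Monte-Carlo luck in
    the cohort mean.
    """
    from scipy.stats import norm

    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    u = (rng.permutation(n) + rng.uniform(0, 1, n)) / n
    return np.exp(mu + math.sqrt(sigma2) * norm.ppf(u))


def sample_free_ensemble(seeds, base: WaveformParams | None = None):
    """Per-recording waveform parameters for a synthetic free-beating cohort.

    Between-cilium frequency and amplitude are stratified log-normal draws
    (means/s.d.s from ``base``); each returned parameter set is
    deterministic (its own draw already applied), so pairing it with its
    seed fully determines the trajectory.
    """
    seeds = list(seeds)
    if not seeds:
        raise ParameterError("need at least one seed")
    base = base or WaveformParams()
    n = len(seeds)
    rng = np.random.default_rng([int(s) for s in seeds])
    freqs = np.clip(
        _stratified_lognormal(rng, base.freq_hz, base.freq_sd_hz, n), 0.5, 50.0
    )
    amps = np.clip(
        _stratified_lognormal(rng, base.x_amplitude_um, base.x_amplitude_sd_um, n),
        0.4, 1.9 * min(base.L_eff_um, base.L_rec_um),
    )
    return [
        replace(base, freq_hz=float(f), freq_sd_hz=0.0,
                x_amplitude_um=float(a), x_amplitude_sd_um=0.0,
                clamp_z_gap=True)
        for f, a in zip(freqs, amps)
    ]


def sample_trap_ensemble(seeds, base: TrapSimParams | None = None):
    """Per-event trap parameters for a synthetic trapped-phase cohort.

    Constant-force picture as in :func:`draw_trap_event`, but the maximal
    force and stiffness are stratified across the cohort so its means sit
    at the reference statistics (11.1 pN, 154.7 nm) without Monte-Carlo
    luck.
    """
    seeds = list(seeds)
    if not seeds:
        raise ParameterError("need at least one seed")
    base = base or TrapSimParams()
    n = len(seeds)
    rng = np.random.default_rng([int(s) for s in seeds])
    kz_gmean = (TRAP_MAX_FORCE_MEAN_PN / TRAP_Z_AMP_MEAN_NM) * math.exp(_TRAP_KZ_LOG_SD**2 / 2)
    f_max = _stratified_lognormal(rng, TRAP_MAX_FORCE_MEAN_PN, TRAP_MAX_FORCE_SD_PN, n)
    kz_sd = kz_gmean * math.exp(_TRAP_KZ_LOG_SD**2 / 2) * math.sqrt(
        math.expm1(_TRAP_KZ_LOG_SD**2)
    )
    k_z = _stratified_lognormal(rng, kz_gmean * math.exp(_TRAP_KZ_LOG_SD**2 / 2), kz_sd, n)
    freqs = np.clip(_stratified_lognormal(rng, base.freq_hz, 1.4, n), 0.5, 50.0)
    return [
        replace(base, k_z_pn_nm=float(k), k_xy_pn_nm=float(2.9 * k),
                z_amp_nm=float(f / k), freq_hz=float(fr))
        for f, k, fr in zip(f_max, k_z, freqs)
    ]


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------
def render_split_frames(
    traj: Trajectory,
    optics: OpticsParams,
    seed: int,
    image_shape: tuple | None = None,
    z_ref_um: float | None = None,
    shot_noise: bool = True,
) -> ImageStack:
    """Render one split-beam frame per trajectory sample.

    The two spots sit at ``±(separation/2 + slope·(z−z_ref)/pixel)`` around
    the lateral position, so the pair mean encodes (x, y) and the half-
    difference encodes z.  Photon shot noise (Poisson) and Gaussian camera
    noise are applied unless disabled.
    """
    if not np.all(np.isfinite(traj.positions)):
        raise ParameterError("trajectory contains non-finite positions")
    rng = np.random.default_rng(seed)
    px_um = optics.pixel_size_nm / 1000.0
    if z_ref_um is None:
        z_ref_um = float(np.mean(traj.z))

    dx_px = optics.z_split_slope * (traj.z - z_ref_um) * 1000.0 / optics.pixel_size_nm
    half_sep = optics.spot_separation_px / 2.0
    margin = math.ceil(5 * optics.psf_sigma_px + 3)

    x_mid = 0.5 * (traj.x.max() + traj.x.min())
    y_mid = 0.5 * (traj.y.max() + traj.y.min())
    x_span_px = (traj.x.max() - traj.x.min()) / px_um
    y_span_px = (traj.y.max() - traj.y.min()) / px_um
    need_w = math.ceil(x_span_px + 2 * (half_sep + np.abs(dx_px).max() + margin)) + 1
    need_h = math.ceil(y_span_px + 2 * margin) + 1
    if image_shape is None:
        image_shape = (need_h, need_w)
    h, w = image_shape
    if h < need_h or w < need_w:
        raise GeometryError(
            f"field of view {image_shape} smaller than trajectory extent "
            f"(needs at least {(need_h, need_w)})"
        )
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    origin_um = (x_mid - cx * px_um, y_mid - cy * px_um)

    x_px = (traj.x - origin_um[0]) / px_um
    y_px = (traj.y - origin_um[1]) / px_um

    frames = np.empty((traj.n, h, w))
    for i in range(traj.n):
        img = render_spot(
            (h, w), (x_px[i] + half_sep + dx_px[i], y_px[i]),
            optics.psf_sigma_px, optics.photons_per_spot,
        )
        img += render_spot(
            (h, w), (x_px[i] - half_sep - dx_px[i], y_px[i]),
            optics.psf_sigma_px, optics.photons_per_spot,
        )
        img += optics.background_per_px
        if shot_noise:
            img = rng.poisson(img).astype(float)
        if optics.camera_noise_sd > 0:
            img = img + rng.normal(0.0, optics.camera_noise_sd, size=img.shape)
        frames[i] = img
    frames = np.clip(np.rint(frames), 0, 65535)

    return ImageStack(
        frames=frames,
        times=traj.t.copy(),
        optics=optics,
        origin_um=origin_um,
        z_ref_um=z_ref_um,
        meta={"seed": int(seed), "sample_rate_hz": traj.sample_rate_hz},
    )


def generate_calibration_stack(
    optics: OpticsParams,
    z_steps_nm,
    seed: int,
    shot_noise: bool = True,
):
    """Piezo-style calibration: stationary bead stepped through known z.

    Returns ``(stack, known_z_nm)`` with one frame per step.
    """
    z_steps_nm = np.asarray(z_steps_nm, dtype=float)
    if z_steps_nm.size < 2 or np.unique(z_steps_nm).size < 2:
        raise ParameterError("need at least 2 distinct z steps")
    fs = DEFAULT_SAMPLE_RATE_HZ
    traj = Trajectory(
        t=np.arange(z_steps_nm.size) / fs,
        x=np.zeros(z_steps_nm.size),
        y=np.zeros(z_steps_nm.size),
        z=z_steps_nm / 1000.0,
        sample_rate_hz=fs,
        meta={"source": "synthetic", "calibration": True},
    )
    stack = render_split_frames(
        traj, optics, seed, z_ref_um=0.0, shot_noise=shot_noise
    )
    return stack, z_steps_nm.copy()
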