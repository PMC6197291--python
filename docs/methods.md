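# Methods

This note records the models, estimators and numerical choices behind
`ciliatip`, in the order the pipeline applies them.

## Synthetic free-beating waveform

The generator emulates the tip of a single surface-attached cilium whose two
stroke phases trace arcs on spheres centred at the attachment point (the
origin), with radii `L_eff` (default 4.95 μm) and `L_rec` (4.90 μm): the
cilium effectively shortens slightly during recovery. Both arcs are circles on
their sphere passing through a shared pair of endpoint directions
`u± = (±sx, 0, uz0)` with `sx = A/(2·L_eff)`, so the peak-to-peak x excursion
of the effective stroke equals the configured amplitude `A` exactly. Each
circle is the sphere's intersection with a plane tilted by ψ about the x-axis:
ψ = π/2 is the vertical great circle, ψ → 0 a flat horizontal arc. The
effective stroke uses a fixed tilt (ψ_eff = 70°); the recovery tilt is solved
(Brent's method on the monotone apex-height function) so the apex-height
difference between the arcs equals the configured z-gap (default 0.15 μm).
Both arcs are convex in the xz projection, so z shows two peaks per beat
cycle, and the recovery arc swings out of plane (|y| up to ~1 μm), as recovery
strokes do.

Because the arcs share endpoint *directions*, the achievable z-gap is bounded
by the geometry (`feasible_z_gap_range`); an infeasible request raises an
error for explicit parameters and is clamped into range for per-seed ensemble
draws, with the realized gap recorded in the trajectory metadata.

Timing: one period is split into effective stroke (duty 0.35), a top dwell, a
recovery stroke, and a bottom dwell (dwells 0.05 each — the "temporal drift
with a lowered speed" between strokes; they interpolate radially between the
two sphere radii). Within a stroke the tip advances with a half-cosine
displacement profile (speed ∝ sin(πs)). A raised-cosine *speed* profile was
rejected: it spends ~20% of each stroke below the segmenter's 10%-of-peak
pause threshold, so the measured effective-duration fraction would
misrepresent the configured duty cycle by ~7 points.

Between-cilium variability: each trajectory draws its beat frequency and
amplitude log-normally around the configured means with the configured
spreads (defaults 4.9 ± 1.4 Hz, 3.6 ± 1.4 μm at 1 cP; 3.0 ± 0.5 Hz,
2.9 ± 0.7 μm at 15 cP via `defaults_15cp`); within one trajectory the
waveform is strictly periodic. Localization noise is isotropic Gaussian,
default 10 nm, added to positions. Sampling is 354.61 frames/s (2.82 ms).

The defaults `L_eff = 4.95`, `L_rec = 4.90`, `z_gap = 0.15`, `ψ_eff = 70°`,
`duty = 0.35` are calibration constants: they were chosen once, analytically,
so the hydrodynamic model evaluated on the default waveform lands at the
magnitudes measured for live tracheal cilia (maximal effective/recovery
stroke forces ≈ 0.59/0.43 pN at 1 cP, net pumped volume ≈ 0.8 μm³/cycle) —
the direct geometric observables that would pin them down are only available
as figure-level data. They were not revisited afterwards.

## Synthetic trapped phase

Under a trap the tip oscillates almost linearly along z. The generator uses a
kinematic waveform `sin(2πft) + c·sin(4πft + φ)` with second-harmonic
fraction `c = 0.5` and phase `φ = π/2`, centred between its extremes and
scaled so the half peak-to-peak amplitude equals `z_amp_nm` (default
154.7 nm). Centring makes the maximal excursion from the trap centre equal
the amplitude, i.e. stiffness × amplitude ≡ maximal trap force — the
force-from-amplitude estimator. The second harmonic produces exactly two
maxima per cycle for any `c > 0.25` (the prominence-thresholded *counter*
requires `c ≳ 0.4`, hence the 0.5 default). No Langevin/thermal dynamics are
modelled; the trap phase is a kinematic emulation. Residual lateral motion
(default 30 nm) and isotropic noise (10 nm) are added.

Ensembles of trap events follow a constant-force picture: the maximal force
is drawn log-normally (mean 11.1, sd 5.6 pN), the per-event effective axial
stiffness log-normally (geometric mean ≈ 0.072 pN/nm, 10% CV — events were
recorded at several laser powers, so the effective stiffness varies), and the
amplitude is force/stiffness; expected amplitude is then 154.7 nm by
construction. `draw_trap_event` draws i.i.d. per seed;
`sample_trap_ensemble` / `sample_free_ensemble` draw the cohort *stratified*
(Latin-hypercube over the same log-normals): marginals are unchanged but a
30-recording synthetic cohort spans the distribution the way a real
n-of-tens study does, so cohort means are not hostage to Monte-Carlo luck.

## Split-beam imaging and localization

Frames carry two pixel-integrated Gaussian spots (erf model) at
`±(separation/2 + slope·(z − z_ref)/pixel)` around the lateral position:
the pair mean encodes (x, y) — the nominal separation cancels — and the
half-difference `(x₁−x₂)/2` encodes z. Poisson shot noise and Gaussian camera
noise are applied; frames are 16-bit TIFF with a JSON sidecar (optics, times,
coordinate origin, focal reference).

Localization fits each spot with a least-squares pixel-integrated 2-D
Gaussian (amplitude, centre, width, constant background) in an 11×11 px
window seeded by the previous frame; failed frames (divergence, or amplitude
below the background noise scale) are linearly interpolated and flagged, and
more than 20% failures abort the track. Calibration regresses the raw
half-difference against piezo-commanded z steps (OLS); z is then
`(half-difference − intercept)/slope`. `localization_precision` gives a
Thompson-style photon-budget estimate used as the round-trip noise floor
(defaults: ~1.4 nm lateral, ~2.8 nm axial).

## Kinematics

* **Alignment** rotates about z only (the optical axis is left intact) so the
  principal lateral axis is x, then flips 180° if the faster direction of
  travel is −x. Near-isotropic lateral motion (principal-axis ratio < 1.2)
  warns but proceeds.
* **Smoothing** is fourth-order Savitzky–Golay; default window ≈ 10% of the
  beat period (odd). The order is standard for this assay; the window is a
  package choice.
* **Segmentation** delimits cycles at x minima, splits each cycle at its x
  maximum, labels samples below 10% of the cycle's peak speed as pause, and
  calls the faster arc effective. Mean-speed differences within 5% count as a
  tie, broken toward the +x arc with a warning (sampling jitter alone
  produces ~2% differences on a symmetric waveform).
* **Frequency** is the dominant Hann-windowed periodogram peak of x(t),
  parabolic-interpolated on log power. (The choice of estimator is validated
  against synthetic ground truth only.)
* **Amplitude** is peak-to-peak x per cycle, averaged — *not* half-amplitude.
* **z-gap** averages each phase's (x, z) arc across cycles on a common
  100-point x grid over the phases' overlap and reports the maximal
  z_eff − z_rec; per-cycle gaps are available separately.
* **Radius of curvature** is an algebraic (Kåsa) circle fit to the
  effective-stroke xz points; collinear input returns infinity.

## Attachment-point sphere fit

A joint least-squares fit with shared centre and per-phase radii (geometric
distance residuals, Levenberg–Marquardt, algebraic linear initialization).
Samples within ±2–3 of a segmentation label change are excluded: they are
phase-ambiguous transition points and otherwise bias the fit's soft mode.
If the algebraic system is ill-conditioned (>10⁶) or the centre lands >1 μm
off the beating plane in y, the fit is rerun with the centre's y fixed at the
trajectory's mean y (`plane_constrained`). The trajectory is then translated
so the fitted centre is the origin, which makes downstream results invariant
to rigid translations of the raw data.

A caveat quantified during development: with ±22° of arc coverage and one
~2-s recording, the centre is soft along the sphere normal (scatter ~60 nm at
20 nm noise, near the information limit), so recovery statements are about
ensemble means, not single fits.

## Force, flux, pumped volume

Velocity comes from the derivative of the Savitzky–Golay polynomial (same
window/order as the smoother) on uniformly sampled data — higher-order
accurate than centred differences — with centred differences as the fallback.
Per sample, L is the fitted radius of the sample's phase (pauses inherit the
preceding stroke), `F = c(L)·v_x` is the x-component of the force on the
fluid (sign convention: positive when the tip moves +x, so the effective
stroke pumps forward and the cumulative volume grows), and
`J = 2·z·F/(3πη)`. The running cumulative volume is trapezoidal; the *net*
summaries (flux per second, volume per cycle over the integer cycles the
segmentation delimits) use Simpson quadrature: with trapezoid + centred
differences a perfectly reciprocal (zero-pumping) stroke leaves an O(dt²)
artefact of ≈1.3×10⁻³ μm³/cycle at 354.61 Hz, an order of magnitude above the
Simpson residual (≈2×10⁻⁴). Maximal |F| is reported per phase over complete
cycles. V is the *tip* velocity throughout — the bead-chain picture justifies
the drag coefficient, it is not integrated separately — so instantaneous J
values are large compared with net fluxes; only net quantities are treated as
physically comparable.

`single_cilium_flux_estimate` is the tissue-level order-of-magnitude check
q = A·v with A the area worked by one cilium (given directly or as
1/(density × ciliated fraction)).

## Trap analysis

Cycle delimitation and peak counting use the Savitzky–Golay smooth (window
≈ 1/8 beat period, narrow enough to preserve the 2f component). Amplitudes
and spring forces are measured on a per-cycle harmonic regression (Fourier
basis, 3 harmonics, least squares on the raw samples; first/last models
extend over the partial edge cycles): the extremes of a low-dof fitted curve
carry essentially none of the noise-maximum inflation that pointwise extremes
of a smoothed noisy series do (+5–10% at 10 nm noise on a 155 nm signal;
residual bias of the regression estimator is +2–4%). The trapped-phase
amplitude is the per-cycle half peak-to-peak, maximum over cycles; a constant
signal returns 0. Peaks count when their prominence exceeds 10% of the
cycle's half peak-to-peak. Spring forces are `F_i = k_i (p_i − c_i)` per
axis; condition comparisons (e.g. displaced trap centre) use geometric
mean ± geometric s.d. of paired force-amplitude ratios.

## What the synthetic data does and does not show

The generator reproduces the *summary statistics* and qualitative structure
of single-cilium recordings (stroke asymmetry, z-gap, two z-peaks, trapped
linearization, between-cilium spread). It does not model cilium bending
dynamics, hydrodynamic coupling between bead and cilium body, thermal motion
in the trap, drift, or photobleaching. Passing parameter-recovery tests
therefore demonstrates that the *analysis chain* is unbiased and
self-consistent at realistic noise levels — not that the model captures
everything in real recordings. The hydrodynamic force/flux numbers inherit
the bead-chain model's idealizations; their defaults are calibrated to
measured magnitudes (see above) and agreement at the factor-of-two level is
the appropriate reading.

## Problem sizes

Default trajectories are 10 beat cycles (~2 s, ~720 samples); ensembles use
30 recordings; localization round-trip checks render 1–2 beat cycles
(~70–150 frames of ~30×80 px). The full test suite runs in a few seconds and
`scripts/acceptance.py` in ~2 s.
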