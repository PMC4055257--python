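# Methods

`rotob1` simulates magnetic-resonance image encoding performed *without*
B0 gradient coils: a single transmit surface coil with a spatially
nonuniform B1+ field is mechanically rotated about the sample, the RF
amplitude is stepped from repetition to repetition, and the image is
recovered by algebraic inversion of the resulting "pseudo k-space" rather
than by Fourier transform.

## Signal model

During one repetition (TR) of duration `T` (default 5 ms) an RF pulse with
unit envelope `b(t)` plays while the coil rotates at `omega_rot`; complex
data points are sampled during the pulse. The per-TR amplitude scale is

    g_alpha = alpha - M/2 - 1/2,   alpha = 1..M,

antisymmetric about zero, and each TR starts from a fresh coil offset
(`360/M` degrees in 2D, `360/M^2` in 3D) so the sample is uniformly
illuminated over the acquisition. The RF amplitude is calibrated once so
that the on-resonance flip angle

    phi(alpha) = gamma * g_alpha * A * |B1|_peak * \int b dt

equals the target (default 90 deg) at `alpha = M` and its negative at
`alpha = 1`.

Every sine-model data point has the form

    D_i = sum_r M(r) * [B1_i(r)/|B1_i(r)|] * sin( gamma g_alpha A w(t_i) |B1_i(r)| )

with `B1_i` the coil map rotated to the event's angle. Three rules for the
nutation-time weight `w(t)` are implemented (`flip_model`):

* **global** (default) — `w(t) = t_global * b(t)`, with `t_global` the
  elapsed acquisition time. The sin argument then winds up to roughly
  `M * 90` degrees across the acquisition while the physical per-TR flip
  stays at the calibrated 90 deg; the winding number acts as the pseudo-k
  coordinate. This is the only rule under which the encoding matrix attains
  full numerical column rank (measured condition number ~1e12 at 32x32),
  i.e. under which the inverse problem is solvable at the image resolution.
* **instantaneous** — `w(t) = C(t)`, the running envelope integral within
  the current TR; each data point is its own quasi-static excitation and the
  nutation never exceeds the calibrated maximum. Every row of the encoding
  matrix is then the sine of an *affine* function of position (for a linear
  gradient map) with total argument spread of only ~2.4 rad; the system is a
  classical moment problem whose numerical rank saturates near the number of
  distinct coil angles (~40 of 480 columns at 32x32). Provided for
  comparison; it cannot support full-resolution inversion at a 90 deg flip
  ceiling, regardless of solver.
* **path** — the accumulated complex nutation
  `Z(r,t) = gamma g_alpha A \int_0^t b B1_theta(t') (r) dt'`, signal
  `e^{i arg Z} sin|Z|`. This is the analytic small-tip solution of the truly
  rotating field, and for a field of spatially constant phase (the linear
  gradient map) it is the *exact* Bloch solution, since all nutation axes
  coincide. It is the reference the Bloch solver is validated against.

The full **Bloch mode** evolves each voxel's magnetization from
`(0, 0, Mz = intensity)` through the rotating, pulse-shaped transverse field
and records the demodulated transverse component `-i (Mx + i My)`; with a
zero-phase field the magnetization tips toward +y, matching the sine models'
phase convention. Because rotations are linear in the initial state, the
Bloch encoding matrix for all voxels is obtained from a single vectorized
grid evolution per TR. Sub-steps are chosen so that data samples land on
step boundaries and the step never exceeds the configured `dt` (default
20 steps x 250 us per 5 ms TR); the rotating map is sampled at sub-step
midpoints, matching the midpoint centering of the update rule.

## Bloch solver

The relaxation-free Bloch equation `dM/dt = gamma M x B` is advanced by the
midpoint finite-difference rule

    M(n+1) = M(n) + gamma dt / (1 + (gamma dt B / 2)^2)
             * (M(n) + gamma dt / 2 * M(n) x B) x B,

the Cayley transform of the cross-product generator: an exact rotation about
the field axis by `2 atan(gamma |B| dt / 2)`. Its eigenvalues are
`1, (1 + i gamma B dt/2)/(1 - i gamma B dt/2)` and the conjugate — all of
unit modulus for any field and step, so the scheme is unconditionally stable
and conserves `|M|` to machine precision. The step angle differs from the
exact `gamma |B| dt` at third order, giving global O(dt^2) convergence
against the Rodrigues rotation oracle. `gamma` defaults to the 1H value
2.675e8 rad/s/T. No T1/T2 relaxation or off-resonance terms are modeled; TR
is assumed long enough for full recovery, and all dynamics live in the
rotating frame.

## Coil maps

* **Linear gradient** — signed real field increasing along +x with slope
  `unit_gradient` (reference 37.5 nT/m). The quarter-max convention fixes the
  scale: the field at the grid midpoint equals a quarter of the edge maximum,
  `B1max = G (L/2) / (3/4)`; on a 0.32 m grid this puts the zero crossing
  0.213 m from the near edge, so the far side is negative (phase pi) — the
  standard rotating-frame zeugmatography picture.
* **Surface loop** — quasi-static Biot-Savart field of a circular current
  loop (complete elliptic integrals, full off-axis solution), loop plane
  perpendicular to +x, optionally displaced along z. The complex map is the
  transverse component `(Bx + i By)/2`; its magnitude and phase are both
  spatially nonlinear. Rotating the coil multiplies the map by the
  angular-position phase `e^{i theta}` (enabled for the loop, not for the
  idealized gradient map). For 3D encoding the loop **must** be displaced
  along z: a loop centered on the mid-slice plane has z-mirror-symmetric
  magnitude and cannot distinguish +z from -z. Defaults scale with the grid
  (radius 2.2x, standoff 2.5x, z displacement -1.45x the half-extent).

Mechanical rotation is modeled by rotating the real and imaginary channels
about the isocenter with cubic-spline (default) or linear interpolation,
zero-filled outside the support; 3D maps rotate slice-wise about the slice
axis. Positive angles are counterclockwise with +y up. Rotated maps are
cached per distinct angle; acquisition noise, when enabled, is a single
uniform draw in +/-`fraction` x peak magnitude per channel applied to each
distinct rotated map (default fraction 0.002), so events revisiting an angle
see the same imperfect map. Simulated data use the noisy maps; the encoding
matrix uses the nominal ones — that is how map noise propagates into the
image instead of cancelling.

## Reconstruction

`D = E G` is solved over the voxels of a thresholded support mask
(columns in C-scan order). `solve_pinv` is the truncated-SVD minimum-norm
least-squares solution; the default relative cutoff 1e-12 keeps everything
down to the double-precision floor, the behavior of a stock pseudo-inverse
routine. (An earlier 1e-6 cutoff was rejected: it truncates the legitimate
small-singular-value encoding content and leaves 14.5% reconstruction error
on a noiseless 32x32 system that inverts to 0.09% at 1e-12.) `solve_lsqr`
wraps LSQR with the stopping rule "400 iterations or relative residual
1e-6", residual-based stopping only. Deviation metrics peak-normalize both
magnitudes over the mask and report the signed per-voxel difference in
percent, its maximum absolute value, mean, standard deviation, and a
histogram (default 50 bins).

## Experiments and the synthetic data they emulate

All inputs are generated internally; no external data exist.

* **exp1** — 2D Shepp-Logan phantom (the original ellipse table, intensities
  in [0, 1], voxel-center rendering with no anti-aliasing, 5 mm voxels),
  linear gradient map, gauss pulse (FWHM half the duration),
  `omega_rot = 1256` rad/s (one revolution per 5 ms TR), M = image columns,
  samples per TR = image rows. Pseudo-inverse and/or Bloch-LSQR
  reconstruction; an optional gradient sweep holds the RF amplitude at the
  reference calibration so the maximum flip scales with the swept gradient.
* **exp2_synthetic** — the same pipeline with the loop map,
  `omega_rot = 90` rad/s (25.8 deg of rotation per TR), and the
  angular-position phase; reports both solvers and the measurement-vector
  amplitude/phase traces. The Shepp-Logan phantom stands in for a head
  image; the loop surrogate stands in for a full-wave simulated or measured
  coil map.
* **exp4** — 3D three-layer rectangular phantom (block spanning the central
  2/3 in-plane and the largest multiple of three slices, default intensities
  1.0/0.6/0.3), loop map, sinc (time-bandwidth 10.5) and sech (4.2) pulses,
  `omega_rot = 628` rad/s, per-TR offset `360/M^2` deg, Bloch-LSQR on the
  block support mask. Because the data carry absolute magnetization units,
  recovered layer means are compared with truth without normalization. SNR
  is defined as mean reconstructed magnitude in the block over the standard
  deviation of the in-block error; the sech/sinc SNR ratio is reported, not
  asserted. Default samples per TR give ~1.4 events per grid voxel. The
  demonstration grid is 11x11x11 (a 21x21x21 run is configuration only);
  sizes were chosen so a full run completes in seconds to minutes on one
  core, with LSQR run to its iteration cap for this noiseless consistency
  study (the 1e-6 residual stop fires long before the image converges).

## What passing and failing runs show — noise fragility

The noiseless pipelines validate the machinery end to end: the global-model
encoding matrix has full numerical rank, the pseudo-inverse recovers the
32x32 Shepp-Logan phantom to better than 0.1% maximum deviation, and the
3D Bloch-LSQR run recovers all three layer means within 10%.

With rotated-map noise enabled, reconstruction quality collapses rather
than settling at a small plateau. This is intrinsic to amplitude-modulated
B1 encoding, not an implementation artifact: resolving N voxels per
direction requires nutation windings of order `N x pi/2` radians, and a
perturbation of the map by a fraction `eps` of its peak then perturbs the
sin arguments by ~`eps x winding` — about 0.3 rad for `eps = 0.002` at the
reference winding — an O(1) corruption of exactly the high-order components
that carry the resolution. Conversely, capping the winding at one 90 deg
flip makes the system noise-robust but collapses its numerical rank to a
few dozen modes. No operating point of this model family delivers both
full-resolution recovery and percent-level deviations under 0.2% map noise;
this trade-off is the historical reason rotating-frame nutation encoding
saw limited clinical use. The noisy-case tests assert the small-deviation
behavior as claimed and are expected to fail; they are retained as an
honest record of the discrepancy.

The Bloch-model reconstructions are additionally blurred relative to the
design model: the truly rotating field filters the azimuthal harmonics of
the map through the envelope spectrum, attenuating high pseudo-k components
— visible as smoothing in Bloch-LSQR images.

## Numerical choices and degenerate inputs

* Envelopes are sampled on `linspace(0, T, n)` and peak-normalized; values
  between samples are linearly interpolated; envelope integrals use the
  trapezoid rule. Bandwidth-time products use a >=16x zero-padded DFT with
  interpolated half-maximum crossings.
* The sech width parameter comes from the analytic sech spectrum
  (`beta = tbw * pi^2 / (2 asech(1/2) T)`); the sinc is unapodized with
  zero crossings at `tbw (t - T/2)/T` integer.
* Zero-magnitude map voxels contribute zero signal (their phase is
  undefined). A `g_alpha = 0` encode measures exactly zero. An all-zero
  phantom yields an all-zero measurement without touching the noise stream.
* Rotation angles are cached modulo 360 deg with 1e-9 deg rounding.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  configurations and seeds reproduce reports bit-for-bit.

## Limitations

* No relaxation, off-resonance, chemical shift, diffusion, slice-profile or
  SAR modeling; reception is a uniform body coil with zero phase.
* The loop map is quasi-static; wavelength and tissue-interaction effects
  present at 85 MHz and above are not represented.
* The gradient-sweep plateau onset depends on the interplay of winding,
  truncation and noise described above and shifts relative to published
  hardware-scale studies.
* Masked reconstruction assumes the support is known exactly.
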