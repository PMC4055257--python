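"""Pseudo k-space simulation and encoding-matrix assembly.

One repetition (TR) plays an amplitude-modulated RF pulse of duration T while
the transmit coil rotates at omega_rot; complex data points are sampled
during the pulse. The per-TR field scale is g_alpha = alpha - M/2 - 1/2 and
each TR starts from a fresh coil offset (360/M degrees in 2D, 360/M^2 in 3D),
so that over the acquisition the sample is uniformly "illuminated".

Two signal models are provided, plus a choice of flip-accumulation rule for
the sine model. Every sine-model data point has the ridge form
(B1/|B1|) sin(gamma g_alpha A w(t) |B1_theta(t)(r)|); the three rules differ
in the nutation-time weight w(t):

* ``flip_model="global"`` (default): w(t) = t_global * b(t), with t_global
  the elapsed acquisition time (TR index x pulse duration + in-TR time) and
  b the unit envelope at the sample instant. This is the pseudo k-space
  *design* model: the sin argument winds ~M x 90 deg across the acquisition,
  which is what gives the encoding matrix full numerical rank — the winding
  number is the pseudo-k coordinate. The physical flip delivered within one
  TR still peaks at the calibrated +/-90 deg.
* ``flip_model="instantaneous"``: w(t) = C(t), the running envelope integral
  within the current TR — each data point is its own quasi-static excitation,
  the per-TR textbook reading. Nutation then never exceeds the calibrated
  maximum flip, and the sine system is a low-winding moment problem of small
  numerical rank; provided for comparison.
* ``flip_model="path"``: the analytic small-tip solution of the actually
  rotating field — the accumulated complex nutation
  Z(r, t) = gamma g_alpha A int_0^t b(t') B1_{theta(t')}(r) dt', signal
  e^{i arg Z} sin |Z|. It coincides with the instantaneous model whenever the
  map is static over the pulse, and with the Bloch solver's small-angle limit
  always (for a field of spatially fixed phase, e.g. the linear-gradient map,
  it is the *exact* Bloch solution, since all nutation axes coincide).

``bloch`` mode ignores flip_model: every voxel's magnetization starts at
(0, 0, Mz) and is evolved through the midpoint finite-difference scheme with
the rotating transverse field (Re B1, Im B1, 0) sampled at sub-step
midpoints; the recorded signal is the demodulated transverse component
-i (Mx + i My), which has the same phase convention as the sine models (a
zero-phase field tips M toward +y). The rotating-field (path/bloch) dynamics
filter the azimuthal harmonics of the map through the envelope spectrum,
which visibly blurs Bloch-model reconstructions relative to the design
model — the two are compared, not interchanged.

The encoding matrix E (rows = schedule events, columns = masked voxels in
C-scan order) is the measurement of a unit point source per voxel; by
linearity of both models, E @ intensities reproduces the corresponding
simulated measurement exactly when the same maps are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bloch import SolverConfig, bloch_step
from .coil_maps import B1Map, RotationOptions, rotate_map
from .phantoms import Mask, ScalarImage
from .rf_pulses import FlipCalibration, PulseWaveform, phase_encode_scale

__all__ = [
    "AcquisitionSchedule",
    "build_schedule",
    "simulate_measurement_linear",
    "simulate_measurement_bloch",
    "build_encoding_matrix",
]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Full event list (alpha, g_alpha, in-TR sample time, coil angle)."""

    M_encodes: int
    samples_per_rotation: int
    omega_rot: float  # rad s^-1
    pulse: PulseWaveform
    dims: int = 2
    alpha: np.ndarray = field(default=None, repr=False)
    g: np.ndarray = field(default=None, repr=False)
    t_sample: np.ndarray = field(default=None, repr=False)
    theta_deg: np.ndarray = field(default=None, repr=False)

    @property
    def n_events(self) -> int:
        return self.M_encodes * self.samples_per_rotation

    @property
    def delta_theta(self) -> float:
        """Per-TR starting offset in degrees."""
        if self.dims == 2:
            return 360.0 / self.M_encodes
        return 360.0 / self.M_encodes**2

    def start_offset(self, alpha: int) -> float:
        return (alpha - 1) * self.delta_theta


def build_schedule(
    M_encodes: int,
    samples_per_rotation: int,
    omega_rot: float,
    pulse: PulseWaveform,
    dims: int = 2,
) -> AcquisitionSchedule:
    """Assemble the acquisition event list.

    Within each TR the ``samples_per_rotation`` data points sit at
    t_k = (k+1) T / I0 (the last sample coincides with the end of the pulse);
    the coil angle of an event is start_offset(alpha) + omega_rot * t in
    degrees. In the reference 2D configuration omega_rot * T = 2 pi, i.e. one
    pulse spans exactly one coil revolution.
    """
    if M_encodes < 1 or samples_per_rotation < 1:
        raise ValueError("counts must be >= 1")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    T = pulse.duration
    i0 = samples_per_rotation
    t_in_tr = (np.arange(i0) + 1) * T / i0
    dtheta = 360.0 / M_encodes if dims == 2 else 360.0 / M_encodes**2
    alphas = np.repeat(np.arange(1, M_encodes + 1), i0)
    g = np.array([phase_encode_scale(a, M_encodes) for a in range(1, M_encodes + 1)])
    g_events = np.repeat(g, i0)
    t_events = np.tile(t_in_tr, M_encodes)
    theta = (alphas - 1) * dtheta + np.degrees(omega_rot * t_events)
    return AcquisitionSchedule(
        M_encodes=M_encodes,
        samples_per_rotation=i0,
        omega_rot=omega_rot,
        pulse=pulse,
        dims=dims,
        alpha=alphas,
        g=g_events,
        t_sample=t_events,
        theta_deg=theta,
    )


class _RotatedMapCache:
    """Rotated maps keyed by angle (degrees modulo 360).

    Each distinct incremental rotation is computed once; if a noise fraction
    is given, that rotated map receives a single uniform +/-fraction-of-peak
    perturbation per channel when it is first produced, and every event
    revisiting the angle sees the same noisy map.
    """

    def __init__(
        self,
        b1map: B1Map,
        options: RotationOptions,
        noise_fraction: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        self._map = b1map
        self._options = options
        self._noise = noise_fraction
        self._rng = rng
        self._cache: dict[float, np.ndarray] = {}

    def field_at(self, angle_deg: float) -> np.ndarray:
        key = round(angle_deg % 360.0, 9)
        cached = self._cache.get(key)
        if cached is None:
            fld = rotate_map(self._map, key, self._options).field
            if self._noise > 0.0 and self._rng is not None:
                amp = self._noise * np.abs(fld).max()
                fld = fld + self._rng.uniform(-amp, amp, fld.shape)
                fld = fld + 1j * self._rng.uniform(-amp, amp, fld.shape)
            cached = self._cache[key] = fld
        return cached


def _substeps_per_sample(samples_per_tr: int, solver_cfg: SolverConfig | None) -> int:
    """Sub-steps per data sample so step count per TR >= the solver's n_steps."""
    n_target = solver_cfg.n_steps if solver_cfg is not None else 20
    return max(1, math.ceil(n_target / samples_per_tr))


def _tr_field_samples(
    cache: _RotatedMapCache,
    schedule: AcquisitionSchedule,
    cal: FlipCalibration,
    alpha: int,
    flat_idx: np.ndarray,
    sub: int,
):
    """Complex transverse field (tesla) at every sub-step midpoint of one TR.

    Returns an array of shape (n_steps, n_voxels) plus the step length.
    """
    T = schedule.pulse.duration
    n_steps = sub * schedule.samples_per_rotation
    dt = T / n_steps
    t_mid = (np.arange(n_steps) + 0.5) * dt
    theta_mid = schedule.start_offset(alpha) + np.degrees(schedule.omega_rot * t_mid)
    b_mid = schedule.pulse.envelope_at(t_mid)
    g_a = phase_encode_scale(alpha, schedule.M_encodes)
    scale = g_a * cal.amplitude_scale

    out = np.empty((n_steps, flat_idx.size), dtype=complex)
    for s in range(n_steps):
        fld = cache.field_at(theta_mid[s])
        out[s] = (scale * b_mid[s]) * fld.ravel()[flat_idx]
    return out, dt


def _sine_signal(Z: np.ndarray) -> np.ndarray:
    """e^{i arg Z} sin |Z|, with zero-magnitude entries contributing zero."""
    mag = np.abs(Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(mag > 0, Z / np.where(mag > 0, mag, 1.0), 0.0)
    return phase * np.sin(mag)


def _measure(
    mode: str,
    flat_idx: np.ndarray,
    b1map: B1Map,
    cal: FlipCalibration,
    schedule: AcquisitionSchedule,
    solver_cfg: SolverConfig | None,
    noise_fraction: float,
    noise_seed,
    rotation: RotationOptions,
    initial_mz: np.ndarray | None,
    flip_model: str = "global",
) -> np.ndarray:
    """Shared engine: per-event signal matrix (I x J) or weighted sum (I,)."""
    if mode not in ("linear", "bloch"):
        raise ValueError("mode must be 'linear' or 'bloch'")
    if flip_model not in ("global", "instantaneous", "path"):
        raise ValueError("flip_model must be 'global', 'instantaneous' or 'path'")
    rng = None
    if noise_fraction > 0.0:
        rng = (
            noise_seed
            if isinstance(noise_seed, np.random.Generator)
            else np.random.default_rng(noise_seed)
        )
    cache = _RotatedMapCache(b1map, rotation, noise_fraction, rng)
    sub = _substeps_per_sample(schedule.samples_per_rotation, solver_cfg)
    i0 = schedule.samples_per_rotation
    n_vox = flat_idx.size
    reduce = initial_mz is not None
    out = np.empty(
        (schedule.n_events,) if reduce else (schedule.n_events, n_vox), dtype=complex
    )
    gamma = cal.gamma
    T = schedule.pulse.duration
    sample_rows = sub * np.arange(1, i0 + 1) - 1  # sub-step index ending each sample

    for a_i, alpha in enumerate(range(1, schedule.M_encodes + 1)):
        if mode == "linear" and flip_model in ("global", "instantaneous"):
            # each sample is its own quasi-static excitation at its coil angle
            g_a = phase_encode_scale(alpha, schedule.M_encodes)
            t_k = schedule.t_sample[:i0]
            theta_k = schedule.start_offset(alpha) + np.degrees(schedule.omega_rot * t_k)
            if flip_model == "global":
                # nutation-time weight = global acquisition time x envelope
                w_k = ((alpha - 1) * T + t_k) * schedule.pulse.envelope_at(t_k)
            else:
                # per-TR running envelope integral
                w_k = schedule.pulse.cumulative_integral_at(t_k)
            sig = np.empty((i0, n_vox), dtype=complex)
            for k in range(i0):
                fld = cache.field_at(theta_k[k])
                Z = (gamma * g_a * cal.amplitude_scale * w_k[k]) * fld.ravel()[flat_idx]
                sig[k] = _sine_signal(Z)
            rows = slice(a_i * i0, (a_i + 1) * i0)
            out[rows] = sig @ initial_mz if reduce else sig
            continue
        F, dt = _tr_field_samples(cache, schedule, cal, alpha, flat_idx, sub)
        if mode == "linear":
            Z = gamma * dt * np.cumsum(F, axis=0)[sample_rows]  # (I0, J)
            sig = _sine_signal(Z)
        else:
            cfg = SolverConfig(gamma=gamma, dt=dt, n_steps=F.shape[0])
            M = np.zeros((n_vox, 3))
            M[:, 2] = 1.0
            sig = np.empty((i0, n_vox), dtype=complex)
            B = np.empty((n_vox, 3))
            B[:, 2] = 0.0
            k = 0
            for s in range(F.shape[0]):
                B[:, 0] = F[s].real
                B[:, 1] = F[s].imag
                M = bloch_step(M, B, cfg)
                if s == sample_rows[k]:
                    sig[k] = -1j * (M[:, 0] + 1j * M[:, 1])
                    k += 1
        rows = slice(a_i * i0, (a_i + 1) * i0)
        out[rows] = sig @ initial_mz if reduce else sig
    return out


def simulate_measurement_linear(
    phantom: ScalarImage,
    b1map: B1Map,
    cal: FlipCalibration,
    schedule: AcquisitionSchedule,
    *,
    noise_fraction: float = 0.0,
    noise_seed=None,
    rotation: RotationOptions | None = None,
    solver_cfg: SolverConfig | None = None,
    flip_model: str = "global",
) -> np.ndarray:
    """Pseudo k-space data under the sine (design) signal model."""
    if phantom.grid != b1map.grid:
        raise ValueError("phantom and map must share a grid")
    support = np.flatnonzero(phantom.values.ravel())
    if support.size == 0:
        return np.zeros(schedule.n_events, dtype=complex)
    weights = phantom.values.ravel()[support]
    return _measure(
        "linear",
        support,
        b1map,
        cal,
        schedule,
        solver_cfg,
        noise_fraction,
        noise_seed,
        rotation or RotationOptions(),
        weights,
        flip_model=flip_model,
    )


def simulate_measurement_bloch(
    phantom: ScalarImage,
    b1map: B1Map,
    cal: FlipCalibration,
    schedule: AcquisitionSchedule,
    solver_cfg: SolverConfig | None = None,
    *,
    noise_fraction: float = 0.0,
    noise_seed=None,
    rotation: RotationOptions | None = None,
) -> np.ndarray:
    """Pseudo k-space data from the full Bloch evolution (Mz(0) = intensity)."""
    if phantom.grid != b1map.grid:
        raise ValueError("phantom and map must share a grid")
    support = np.flatnonzero(phantom.values.ravel())
    if support.size == 0:
        return np.zeros(schedule.n_events, dtype=complex)
    weights = phantom.values.ravel()[support]
    return _measure(
        "bloch",
        support,
        b1map,
        cal,
        schedule,
        solver_cfg,
        noise_fraction,
        noise_seed,
        rotation or RotationOptions(),
        weights,
    )


def build_encoding_matrix(
    mode: str,
    mask: Mask,
    b1map: B1Map,
    cal: FlipCalibration,
    schedule: AcquisitionSchedule,
    solver_cfg: SolverConfig | None = None,
    *,
    noise_fraction: float = 0.0,
    noise_seed=None,
    rotation: RotationOptions | None = None,
    flip_model: str = "global",
) -> np.ndarray:
    """Encoding matrix E (n_events x n_masked_voxels).

    Column j is the measurement of a unit point source at masked voxel j.
    The reconstruction normally uses the noiseless nominal maps
    (noise_fraction = 0) while the simulated data carry map noise — that is
    how acquisition noise propagates into the image instead of cancelling.
    """
    if mask.grid != b1map.grid:
        raise ValueError("mask and map must share a grid")
    return _measure(
        mode,
        mask.flat_indices,
        b1map,
        cal,
        schedule,
        solver_cfg,
        noise_fraction,
        noise_seed,
        rotation or RotationOptions(),
        None,
        flip_model=flip_model,
    )
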