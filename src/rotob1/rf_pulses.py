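"""RF pulse envelopes and the per-encode flip-angle modulation schedule.

Envelopes are unit-normalized (peak amplitude 1 before calibration) and
sampled on ``numpy.linspace(0, duration, n_samples)``. The flip angle on
resonance is phi = gamma * integral(|B1+|) dt over the pulse; the per-encode
scale g_alpha = alpha - M/2 - 1/2 sweeps it antisymmetrically about zero, so
a calibration targeting phi_max degrees delivers -phi_max at alpha = 1 and
+phi_max at alpha = M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseWaveform",
    "FlipCalibration",
    "gauss_pulse",
    "sinc_pulse",
    "sech_pulse",
    "rect_pulse",
    "bandwidth_time_product",
    "phase_encode_scale",
    "calibrate_amplitude",
    "flip_angle",
]


@dataclass(frozen=True)
class PulseWaveform:
    duration: float  # seconds
    envelope: np.ndarray  # unit-normalized amplitude samples
    shape_name: str

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        object.__setattr__(self, "envelope", env)
        if env.ndim != 1 or env.size < 2:
            raise ValueError("envelope needs at least 2 samples")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not np.all(np.isfinite(env)):
            raise ValueError("envelope must be finite")

    @property
    def n_samples(self) -> int:
        return self.envelope.size

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_samples)

    def envelope_at(self, t) -> np.ndarray:
        """Linear interpolation of the envelope at arbitrary times in [0, T]."""
        return np.interp(t, self.times, self.envelope)

    def integral(self) -> float:
        """Trapezoid integral of the envelope over the pulse, in seconds."""
        return float(np.trapezoid(self.envelope, self.times))

    def cumulative_integral_at(self, t) -> np.ndarray:
        """Running integral of the envelope from 0 to t (trapezoid, seconds)."""
        dt = self.duration / (self.n_samples - 1)
        cum = np.concatenate([[0.0], np.cumsum((self.envelope[1:] + self.envelope[:-1]) * dt / 2)])
        return np.interp(t, self.times, cum)


@dataclass(frozen=True)
class FlipCalibration:
    """Amplitude scale (tesla multiplier on the unit envelope x unit map)."""

    gamma: float  # rad s^-1 T^-1
    target_max_flip: float  # degrees, delivered at alpha = M
    amplitude_scale: float  # dimensionless multiplier, > 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.amplitude_scale <= 0:
            raise ValueError("gamma and amplitude_scale must be positive")


def _normalized(env: np.ndarray) -> np.ndarray:
    peak = np.abs(env).max()
    if peak == 0:
        raise ValueError("degenerate all-zero envelope")
    return env / peak


def gauss_pulse(duration: float, n_samples: int, fwhm_fraction: float = 0.5) -> PulseWaveform:
    """Gaussian envelope centered at duration/2 with the given FWHM fraction."""
    if not 0 < fwhm_fraction <= 1:
        raise ValueError("fwhm_fraction must lie in (0, 1]")
    t = np.linspace(0.0, duration, n_samples)
    sigma = fwhm_fraction * duration / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    env = np.exp(-0.5 * ((t - duration / 2.0) / sigma) ** 2)
    return PulseWaveform(duration, _normalized(env), "gauss")


def sinc_pulse(duration: float, n_samples: int, tbw: float = 10.5) -> PulseWaveform:
    """Truncated (unapodized) sinc with the requested bandwidth-time product.

    The window spans tbw side-lobe zero crossings, giving an approximately
    rectangular frequency response of width tbw / duration.
    """
    if tbw <= 0:
        raise ValueError("tbw must be positive")
    t = np.linspace(0.0, duration, n_samples)
    x = tbw * (t - duration / 2.0) / duration  # zero crossings at integer x
    env = np.sinc(x)
    return PulseWaveform(duration, _normalized(env), "sinc")


_ARCSECH_HALF = np.log(2.0 + np.sqrt(3.0))  # sech(x) = 1/2 at this x


def sech_pulse(duration: float, n_samples: int, tbw: float = 4.2) -> PulseWaveform:
    """Hyperbolic-secant amplitude envelope sech(beta (t - T/2)).

    beta is set from the analytic sech spectrum (Fourier transform of sech is
    again a sech with half-max at f = arcsech(1/2) * beta / pi^2) so that the
    spectral FWHM times the pulse duration equals ``tbw``. Amplitude only; no
    frequency sweep is applied.
    """
    if tbw <= 0:
        raise ValueError("tbw must be positive")
    beta = tbw * np.pi**2 / (2.0 * _ARCSECH_HALF * duration)
    t = np.linspace(0.0, duration, n_samples)
    env = 1.0 / np.cosh(beta * (t - duration / 2.0))
    return PulseWaveform(duration, _normalized(env), "sech")


def rect_pulse(duration: float, n_samples: int) -> PulseWaveform:
    env = np.ones(n_samples)
    return PulseWaveform(duration, env, "rect")


def bandwidth_time_product(pulse: PulseWaveform, pad_factor: int = 16) -> float:
    """duration x spectral FWHM of the envelope magnitude spectrum.

    The spectrum is a zero-padded DFT (>= ``pad_factor`` x oversampling); the
    half-maximum crossings are located by linear interpolation.
    """
    env = pulse.envelope
    if np.abs(env).max() == 0:
        raise ValueError("degenerate all-zero envelope")
    dt = pulse.duration / (pulse.n_samples - 1)
    n_fft = int(2 ** np.ceil(np.log2(pulse.n_samples * pad_factor)))
    spec = np.abs(np.fft.rfft(env, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=dt)
    half = spec.max() / 2.0
    below = np.flatnonzero(spec < half)
    if below.size == 0:
        raise ValueError("spectrum never falls below half maximum; pad more")
    k = below[0]  # first crossing moving away from DC (envelopes peak at f=0)
    f_cross = np.interp(half, [spec[k], spec[k - 1]], [freqs[k], freqs[k - 1]])
    return 2.0 * f_cross * pulse.duration


def phase_encode_scale(alpha: int, M: int) -> float:
    """Per-TR field scaling g_alpha = alpha - M/2 - 1/2, alpha in 1..M."""
    if not 1 <= alpha <= M:
        raise ValueError(f"alpha must lie in 1..{M}, got {alpha}")
    return alpha - M / 2.0 - 0.5


def calibrate_amplitude(
    pulse: PulseWaveform,
    M: int,
    unit_field_peak: float,
    gamma: float,
    target_max_flip: float = 90.0,
) -> FlipCalibration:
    """Choose the amplitude scale delivering +/-target_max_flip at alpha = M/1.

    The on-resonance hard-pulse flip is phi(alpha) = gamma * g_alpha * A *
    unit_field_peak * integral(envelope) dt; A is solved so phi(M) equals the
    target. g_alpha is antisymmetric about (M+1)/2, so phi(1) = -phi(M).
    """
    if target_max_flip <= 0:
        raise ValueError("target_max_flip must be positive")
    if unit_field_peak <= 0:
        raise ValueError("unit_field_peak must be positive")
    integ = pulse.integral()
    if integ == 0:
        raise ValueError("zero envelope integral")
    g_max = phase_encode_scale(M, M)
    scale = np.radians(target_max_flip) / (gamma * g_max * unit_field_peak * integ)
    return FlipCalibration(gamma, target_max_flip, float(scale))


def flip_angle(
    cal: FlipCalibration, pulse: PulseWaveform, alpha: int, M: int, unit_field_peak: float
) -> float:
    """Delivered hard-pulse flip angle in degrees at phase-encode index alpha."""
    g = phase_encode_scale(alpha, M)
    return float(
        np.degrees(cal.gamma * g * cal.amplitude_scale * unit_field_peak * pulse.integral())
    )
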