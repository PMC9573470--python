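"""Synthetic radar baseband echoes from chest-wall motion.

A continuous-wave Doppler radar pointed at a person's chest receives an
echo whose phase is modulated by the chest displacement: breathing moves
the chest wall by millimetres, the heartbeat by fractions of a millimetre.
After quadrature zero-IF demodulation the baseband signal is a unit
phasor ``exp(j*4*pi*x(t)/lambda)`` riding on static clutter (ground and
furniture echoes at zero Doppler), direct transmit-to-receive antenna
leakage, and circular complex Gaussian receiver noise.

This module is the fixture generator for every downstream stage: the MTI
clutter filter, the CA-CFAR detector and the spectral rate estimators all
consume :class:`BasebandSignal` records produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "RadarParams",
    "ChestMotion",
    "InterferenceParams",
    "BasebandSignal",
    "chest_displacement",
    "chest_velocity",
    "doppler_shift",
    "echo_phase",
    "synthesize_baseband",
]

#: Propagation speed of the carrier in vacuum, m/s.
SPEED_OF_LIGHT = 2.9979e8

_MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class RadarParams:
    """Radar carrier and slow-time acquisition parameters.

    Parameters
    ----------
    carrier_freq : float
        Transmit carrier frequency in Hz. Default 24 GHz (mm-wave band).
    propagation_speed : float
        Wave propagation speed in m/s.
    slow_sample_rate : float
        Frames per second of the slow-time series, Hz. Must exceed twice
        the highest simulated motion frequency. Default 20 Hz.
    duration : float
        Observation window in seconds.
    seed : int
        Seed for the noise generator; identical seed and parameters give
        bitwise-identical output.
    """

    carrier_freq: float = 24e9
    propagation_speed: float = SPEED_OF_LIGHT
    slow_sample_rate: float = 20.0
    duration: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carrier_freq <= 0:
            raise ValueError("carrier_freq must be positive")
        if self.propagation_speed <= 0:
            raise ValueError("propagation_speed must be positive")
        if self.slow_sample_rate <= 0:
            raise ValueError("slow_sample_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength c/f in metres."""
        return self.propagation_speed / self.carrier_freq


@dataclass(frozen=True)
class ChestMotion:
    """Two-tone sinusoidal chest-wall motion model.

    Respiration and heartbeat each contribute one sinusoid; the defaults
    sit inside the physiological bands (respiration 0.1-0.5 Hz at 4-12 mm,
    heartbeat 0.6-2 Hz at 0.15-0.5 mm, never above 0.6 mm). Respiration
    harmonics arise naturally downstream through the nonlinear
    displacement-to-I/Q phase map; no explicit waveform shaping is done.
    """

    resp_freq: float = 0.267
    resp_amp_mm: float = 8.0
    heart_freq: float = 1.383
    heart_amp_mm: float = 0.4
    resp_phase: float = 0.0
    heart_phase: float = 0.0
    standoff_m: float = 0.5

    #: Hard physiological ceiling on heartbeat chest displacement, mm.
    MAX_HEART_AMP_MM = 0.6

    def __post_init__(self) -> None:
        if self.resp_amp_mm < 0 or self.heart_amp_mm < 0:
            raise ValueError("motion amplitudes must be nonnegative")
        if self.heart_amp_mm > self.MAX_HEART_AMP_MM:
            raise ValueError(
                f"heart amplitude {self.heart_amp_mm} mm exceeds the "
                f"physiological maximum {self.MAX_HEART_AMP_MM} mm"
            )
        if self.resp_freq < 0 or self.heart_freq < 0:
            raise ValueError("motion frequencies must be nonnegative")
        if self.standoff_m <= 0:
            raise ValueError("standoff distance must be positive")

    @property
    def max_frequency(self) -> float:
        """Highest motion frequency with nonzero amplitude, Hz."""
        freqs = []
        if self.resp_amp_mm > 0:
            freqs.append(self.resp_freq)
        if self.heart_amp_mm > 0:
            freqs.append(self.heart_freq)
        return max(freqs, default=0.0)


@dataclass(frozen=True)
class InterferenceParams:
    """Additive disturbances on the baseband signal.

    ``noise_power`` is the total power of the circular complex Gaussian
    receiver noise (split evenly between I and Q). ``clutter_amp`` is the
    constant complex amplitude of the zero-Doppler static echo;
    ``leakage_amp`` that of the direct transmit-to-receive antenna
    leakage. Both are constants in slow time and thus indistinguishable
    to the MTI filter, but they are kept distinct so clutter-rejection
    tests can target each.
    """

    noise_power: float = 0.0
    clutter_amp: complex = 0j
    leakage_amp: complex = 0j

    def __post_init__(self) -> None:
        if self.noise_power < 0:
            raise ValueError("noise_power must be nonnegative")


@dataclass
class BasebandSignal:
    """Complex baseband slow-time record.

    ``samples`` is 1-D (slow time) or 2-D (slow time x fast time).
    """

    samples: np.ndarray
    sample_rate: float
    seed: int | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_slow(self) -> int:
        return self.samples.shape[0]

    @property
    def n_fast(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Slow-time stamps in seconds."""
        return np.arange(self.n_slow) / self.sample_rate


def chest_displacement(motion: ChestMotion, t):
    """Absolute chest-to-antenna distance d(t) = d0 + x(t) in metres.

    x(t) is the two-tone motion: resp_amp*sin(2*pi*f_r*t + phi_r) +
    heart_amp*sin(2*pi*f_h*t + phi_h), amplitudes converted mm -> m.
    Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    x = motion.resp_amp_mm * _MM * np.sin(
        2 * np.pi * motion.resp_freq * t + motion.resp_phase
    ) + motion.heart_amp_mm * _MM * np.sin(
        2 * np.pi * motion.heart_freq * t + motion.heart_phase
    )
    return motion.standoff_m + x


def chest_velocity(motion: ChestMotion, t):
    """Analytic chest-wall radial velocity dx/dt in m/s (oracle helper)."""
    t = np.asarray(t, dtype=float)
    return (
        motion.resp_amp_mm * _MM * 2 * np.pi * motion.resp_freq
        * np.cos(2 * np.pi * motion.resp_freq * t + motion.resp_phase)
        + motion.heart_amp_mm * _MM * 2 * np.pi * motion.heart_freq
        * np.cos(2 * np.pi * motion.heart_freq * t + motion.heart_phase)
    )


def doppler_shift(v, carrier_freq: float, c: float = SPEED_OF_LIGHT):
    """Two-way Doppler shift 2*v*f/c in Hz; sign follows the sign of v."""
    if c <= 0:
        raise ValueError("propagation speed must be positive")
    return 2.0 * np.asarray(v, dtype=float) * carrier_freq / c


def echo_phase(displacement, wavelength: float):
    """Round-trip echo phase 4*pi*x/lambda in radians.

    Linear in displacement; one full cycle per half wavelength of
    displacement (the factor 4*pi reflects the two-way path).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive: invalid radar configuration")
    return 4.0 * np.pi * np.asarray(displacement, dtype=float) / wavelength


def synthesize_baseband(
    radar: RadarParams,
    motion: ChestMotion,
    interference: InterferenceParams | None = None,
    fast_time_bins: int = 1,
) -> BasebandSignal:
    """Simulate the quadrature-demodulated baseband echo.

    Each slow-time sample is

        exp(j * 4*pi*(d(t) - d0)/lambda) + clutter + leakage + w(n)

    with w(n) circular complex Gaussian of total power ``noise_power``.
    With ``fast_time_bins > 1`` the same target phasor is replicated
    across fast-time channels with independent noise per channel, so that
    N-channel MTI filtering can be exercised; range migration is not
    modelled.

    Raises
    ------
    ValueError
        If the slow sample rate is at or below the Nyquist rate for the
        configured motion frequencies.
    """
    if interference is None:
        interference = InterferenceParams()
    if fast_time_bins < 1:
        raise ValueError("fast_time_bins must be >= 1")
    f_max = motion.max_frequency
    if f_max > 0 and radar.slow_sample_rate <= 2 * f_max:
        raise ValueError(
            f"slow_sample_rate {radar.slow_sample_rate} Hz is at or below the "
            f"Nyquist rate for motion at {f_max} Hz"
        )

    n = int(round(radar.duration * radar.slow_sample_rate))
    t = np.arange(n) / radar.slow_sample_rate
    disp = chest_displacement(motion, t) - motion.standoff_m
    target = np.exp(1j * echo_phase(disp, radar.wavelength))

    rng = np.random.default_rng(radar.seed)
    shape = (n,) if fast_time_bins == 1 else (n, fast_time_bins)
    sigma = np.sqrt(interference.noise_power / 2.0)
    noise = sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))

    if fast_time_bins == 1:
        samples = target + interference.clutter_amp + interference.leakage_amp + noise
    else:
        samples = (
            target[:, None]
            + interference.clutter_amp
            + interference.leakage_amp
            + noise
        )
    return BasebandSignal(
        samples=samples,
        sample_rate=radar.slow_sample_rate,
        seed=radar.seed,
        source="synthetic",
    )
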