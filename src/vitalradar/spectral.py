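"""Overflow-controlled FFT and phase-based vital-sign rate estimation.

The FFT here mimics a fixed-point hardware pipeline: a radix-2 butterfly
can at most double the larger input magnitude per stage
(max(|a'|,|b'|) <= max(2|a|, 2|b|)), so halving every stage's outputs
guarantees a 16-bit word never overflows while shrinking the rounding
noise injected at each stage along with the data. The result is the DFT
scaled by 1/N, with the accumulated scale exponent log2(N) carried in
the result record. The butterfly is the decimation-in-frequency form
a' = a + b, b' = (a - b) * W; float mode runs the identical pipeline
without quantization and is the reference path for rate estimation.

Rate estimation converts the slow-time echo into an unwrapped phase
sequence (phase expansion), which is proportional to chest displacement,
and reads the respiration and heartbeat rates off band-limited
periodogram peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "FixedPointFormat",
    "FFTResult",
    "VitalBands",
    "RateEstimate",
    "butterfly",
    "fft_scaled",
    "select_target_bin",
    "fit_circle_center",
    "phase_sequence",
    "phase_diff",
    "estimate_rate",
    "next_pow2",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Two's-complement fixed-point grid: total_bits wide, frac_bits
    fractional. Default Q2.14-style (16 total, 14 fractional), giving a
    representable range of about +/-2 with resolution 2**-14."""

    total_bits: int = 16
    frac_bits: int = 14

    def __post_init__(self) -> None:
        if not (self.total_bits >= self.frac_bits >= 0):
            raise ValueError("require total_bits >= frac_bits >= 0")
        if self.total_bits < 2:
            raise ValueError("total_bits must be >= 2")

    @property
    def resolution(self) -> float:
        """One least-significant bit."""
        return 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        return (2 ** (self.total_bits - 1) - 1) * self.resolution

    @property
    def min_value(self) -> float:
        return -(2 ** (self.total_bits - 1)) * self.resolution

    def quantize(self, z: np.ndarray) -> np.ndarray:
        """Round each real/imaginary part to the nearest grid point,
        saturating at the representable range."""
        lo = -(2 ** (self.total_bits - 1))
        hi = 2 ** (self.total_bits - 1) - 1
        re = np.clip(np.round(z.real / self.resolution), lo, hi)
        im = np.clip(np.round(z.imag / self.resolution), lo, hi)
        return (re + 1j * im) * self.resolution


@dataclass
class FFTResult:
    """Spectrum bins with the accumulated per-stage halving exponent:
    2**scale_exponent * bins reconstructs the unscaled DFT (up to
    quantization error in fixed-point mode)."""

    bins: np.ndarray
    scale_exponent: int
    n: int


@dataclass(frozen=True)
class VitalBands:
    """Physiological search bands in Hz: respiration below heartbeat."""

    heart: tuple[float, float] = (0.6, 2.0)
    resp: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if self.resp[0] >= self.resp[1] or self.heart[0] >= self.heart[1]:
            raise ValueError("band edges must be increasing")
        if self.resp[1] > self.heart[0]:
            raise ValueError("respiration band must lie below the heart band")


@dataclass
class RateEstimate:
    """Band-limited periodogram peak expressed per minute.

    ``rate`` = 60 * ``peak_freq``; ``resolution`` is the bin width
    sample_rate/N of the zero-padded spectrum; ``low_confidence`` flags a
    peak that does not stand clear (3x) of the band's median power.
    """

    rate: float
    peak_freq: float
    resolution: float
    band: tuple[float, float]
    low_confidence: bool = False


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (n - 1).bit_length()


def butterfly(a: complex, b: complex, twiddle: complex) -> tuple[complex, complex]:
    """Radix-2 butterfly a' = a + b, b' = (a - b) * W with |W| = 1.

    The growth bound max(|a'|,|b'|) <= |a| + |b| <= max(2|a|, 2|b|) is
    what licenses the divide-by-two-per-stage overflow control.
    """
    if abs(abs(twiddle) - 1.0) > 1e-12:
        raise ValueError("twiddle factor must have unit magnitude")
    a_out = a + b
    b_out = (a - b) * twiddle
    bound = max(2 * abs(a), 2 * abs(b))
    assert max(abs(a_out), abs(b_out)) <= bound * (1 + 1e-12)
    return a_out, b_out


def _bit_reverse_indices(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=int)
    for _ in range(bits):
        rev = (rev << 1) | (idx & 1)
        idx >>= 1
    return rev


def fft_scaled(x, fmt: FixedPointFormat | None = None) -> FFTResult:
    """Radix-2 FFT with divide-by-two overflow control at every stage.

    Decimation in frequency: natural-order input, butterflies per stage,
    bit-reversal reorder at the end. Each stage's butterfly outputs are
    halved before the next stage, so the result is DFT/N and no
    intermediate can overflow a fixed-point word. With ``fmt`` given,
    values are rounded to the fixed-point grid after every stage and the
    input must keep both real and imaginary parts within half the
    representable maximum (twiddle rotation can swing a component by up
    to a factor of two before the halving).
    """
    x = np.asarray(x, dtype=np.complex128)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    n = len(x)
    if n == 0 or n & (n - 1):
        raise ValueError(f"length {n} is not a power of two")

    if fmt is not None:
        limit = fmt.max_value / 2.0
        if np.max(np.abs(x.real)) > limit or np.max(np.abs(x.imag)) > limit:
            raise ValueError(
                "overflow risk: input components must stay within half the "
                f"representable maximum ({limit:g}) in fixed-point mode"
            )
        y = fmt.quantize(x)
    else:
        y = x.copy()

    stages = n.bit_length() - 1
    m = n
    while m >= 2:
        half = m // 2
        blocks = y.reshape(-1, m)
        a = blocks[:, :half]
        b = blocks[:, half:]
        tw = np.exp(-2j * np.pi * np.arange(half) / m)
        a_out = a + b
        b_out = (a - b) * tw
        y = np.concatenate([a_out, b_out], axis=1).reshape(-1)
        y *= 0.5  # per-stage overflow control
        if fmt is not None:
            y = fmt.quantize(y)
        m = half

    y = y[_bit_reverse_indices(n)]
    return FFTResult(bins=y, scale_exponent=stages, n=n)


def select_target_bin(frames) -> int:
    """Index of the bin with the largest mean power across frames.

    ``frames`` is a (n_frames, n_bins) array of per-frame spectra (or a
    single 1-D spectrum). Ties break to the lowest index.
    """
    frames = np.asarray(frames)
    if frames.size == 0:
        raise ValueError("no frames given")
    if frames.ndim == 1:
        frames = frames[None, :]
    mean_power = np.mean(np.abs(frames) ** 2, axis=0)
    return int(np.argmax(mean_power))


def fit_circle_center(values) -> complex:
    """Least-squares center of a complex I/Q trajectory (Kasa fit).

    The echo of a moving chest traces an arc of a circle in the I/Q
    plane whose center is the sum of all static contributions (clutter
    and antenna leakage). Subtracting the fitted center before taking
    the phase removes the static offset without distorting the target
    phasor — unlike a DC notch, which also removes the target's own
    zero-frequency component and bends the trajectory off its circle.

    Solves ``min sum((|z - c|^2 - r^2)^2)`` which is linear in the
    center coordinates and r^2. Falls back to the complex mean if the
    system is degenerate (e.g. a motionless target).
    """
    z = np.asarray(values, dtype=np.complex128)
    if z.ndim != 1 or len(z) < 3:
        raise ValueError("need at least three samples of a 1-D trajectory")
    x, y = z.real, z.imag
    design = np.column_stack([2 * x, 2 * y, np.ones(len(z))])
    rhs = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 3 or not np.all(np.isfinite(sol)):
        return complex(np.mean(z))
    return complex(sol[0], sol[1])


def phase_sequence(values) -> np.ndarray:
    """Four-quadrant phase followed by phase expansion (unwrapping).

    Successive differences are forced into (-pi, pi] by adding multiples
    of 2*pi, recovering the continuous echo phase — and through
    x = lambda * phi / (4*pi), the chest displacement.
    """
    values = np.asarray(values, dtype=np.complex128)
    if np.any(values == 0):
        raise ValueError("zero-magnitude sample has undefined phase")
    return np.unwrap(np.angle(values))


def phase_diff(phase) -> np.ndarray:
    """First differences of a phase sequence (length reduced by one).

    A positive difference means the later sample's phase leads; the
    differences are proportional to chest-wall radial velocity.
    """
    phase = np.asarray(phase, dtype=float)
    if len(phase) < 2:
        raise ValueError("need at least two phase samples")
    return np.diff(phase)


def estimate_rate(
    series,
    sample_rate: float,
    band: tuple[float, float],
    smooth: bool = False,
    smooth_window: int = 11,
    smooth_order: int = 3,
    exclude_harmonics_of: float | None = None,
) -> RateEstimate:
    """Band-limited periodogram rate estimate in events per minute.

    Optionally Savitzky-Golay smooths the series (window 11, order 3 by
    default), removes the mean, zero-pads to the next power of two, takes
    the magnitude spectrum via :func:`fft_scaled`, and picks the peak bin
    inside ``band``. ``exclude_harmonics_of`` drops bins within one bin
    of integer multiples of a given fundamental (used to keep respiration
    harmonics out of the heart band). The rate is 60x the peak frequency,
    reported without interpolation together with the bin-width
    resolution.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series too short")
    if not (0 < band[0] < band[1] <= sample_rate / 2):
        raise ValueError("band must satisfy 0 < low < high <= Nyquist")
    if smooth and len(x) > smooth_window:
        x = savgol_filter(x, smooth_window, smooth_order)
    x = x - np.mean(x)

    n = next_pow2(len(x))
    padded = np.zeros(n, dtype=np.complex128)
    padded[: len(x)] = x
    mag = np.abs(fft_scaled(padded).bins)
    resolution = sample_rate / n
    freqs = np.arange(n) * resolution

    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (np.arange(n) <= n // 2)
    if np.count_nonzero(in_band) < 2:
        raise ValueError(
            f"band {band} holds fewer than two bins at resolution {resolution:g} Hz"
        )
    mask = in_band.copy()
    if exclude_harmonics_of is not None and exclude_harmonics_of > 0:
        k = 2
        while k * exclude_harmonics_of <= band[1] + resolution:
            harmonic = k * exclude_harmonics_of
            # fundamental is known only to +-resolution/2, an error that
            # multiplies by k at the k-th harmonic: widen the notch with k
            tol = (1.0 + 0.5 * k) * resolution
            mask &= np.abs(freqs - harmonic) > tol
            k += 1
        if not np.any(mask):  # never empty the band entirely
            mask = in_band

    band_idx = np.flatnonzero(mask)
    peak = band_idx[np.argmax(mag[band_idx])]
    band_median = float(np.median(mag[in_band]))
    low_conf = mag[peak] < 3.0 * band_median
    return RateEstimate(
        rate=60.0 * freqs[peak],
        peak_freq=float(freqs[peak]),
        resolution=resolution,
        band=(band[0], band[1]),
        low_confidence=bool(low_conf),
    )
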