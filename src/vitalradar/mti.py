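"""Moving-target-indication (MTI) clutter filter.

Static scatterers (ground, walls, antenna leakage) put all their echo
energy at zero Doppler; chest motion does not. MTI is therefore a
high-pass filter along slow time. Here it is a first-order IIR high-pass
obtained by bilinear transform of the analog prototype H(s) = s/(s + Wp),
realized in transposed direct form II, with optional coefficient
quantization to a power-of-two grid for fixed-point hardware.

The design chain is: pick passband/stopband cutoffs and attenuations
(:class:`HighpassSpec`), confirm a first-order Butterworth suffices
(:func:`butterworth_order`), map the prototype through the bilinear
transform (:func:`design_highpass`), optionally quantize
(:func:`quantize_coeffs`), then run it over every fast-time channel of a
slow-time record (:func:`mti_apply`). I and Q are filtered by identical
real coefficient sets, so an N-bin record is equivalent to two N-channel
real IIR filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .simulate import BasebandSignal

__all__ = [
    "HighpassSpec",
    "FirstOrderIIR",
    "FilterState",
    "butterworth_order",
    "design_highpass",
    "quantize_coeffs",
    "magnitude_response",
    "mti_apply",
]


@dataclass(frozen=True)
class HighpassSpec:
    """High-pass design targets in normalized digital frequency.

    Cutoffs are in rad/sample with the stopband below the passband;
    attenuations are negative dB. Defaults follow the clutter-rejection
    design point: passband edge 0.02*pi at -3 dB, stopband edge 0.002*pi
    at -20 dB.
    """

    passband_cutoff: float = 0.02 * math.pi
    stopband_cutoff: float = 0.002 * math.pi
    passband_atten_db: float = -3.0
    stopband_atten_db: float = -20.0

    def __post_init__(self) -> None:
        if not (0 < self.stopband_cutoff < self.passband_cutoff < math.pi):
            raise ValueError("require 0 < stopband_cutoff < passband_cutoff < pi")
        # equality allowed: zero required selectivity, order clamps to 1
        if not (self.stopband_atten_db <= self.passband_atten_db < 0):
            raise ValueError("require stopband_atten_db <= passband_atten_db < 0 (dB)")


@dataclass(frozen=True)
class FirstOrderIIR:
    """First-order IIR high-pass y(n) = b0*[x(n) - x(n-1)] + a1*y(n-1).

    ``quant_bits`` records coefficient quantization (coefficients are
    then integer multiples of 2**-quant_bits); arithmetic itself stays in
    floating point. ``sampling_period`` is bookkeeping only — the
    bilinear-transform algebra cancels T.
    """

    b0: float
    a1: float
    quant_bits: int | None = None
    sampling_period: float = 1.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if abs(self.a1) >= 1:
            raise ValueError(f"unstable filter: |a1| = {abs(self.a1)} >= 1")
        if self.quant_bits is not None:
            scale = 2 ** self.quant_bits
            for c in (self.b0, self.a1):
                if c * scale != round(c * scale):
                    raise ValueError(
                        f"coefficient {c} is not a multiple of 2**-{self.quant_bits}"
                    )

    @property
    def b(self) -> np.ndarray:
        """Feedforward taps (b0, -b0)."""
        return np.array([self.b0, -self.b0])

    @property
    def a(self) -> np.ndarray:
        """Feedback taps (1, -a1) in scipy convention."""
        return np.array([1.0, -self.a1])


@dataclass
class FilterState:
    """Caller-owned transposed direct-form II delay state, one slot per
    fast-time channel, so block-wise streaming equals one-shot filtering."""

    values: np.ndarray  # shape (1, n_channels), complex

    @classmethod
    def zeros(cls, n_channels: int = 1) -> "FilterState":
        return cls(values=np.zeros((1, n_channels), dtype=np.complex128))

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def butterworth_order(spec: HighpassSpec) -> tuple[float, int]:
    """Minimum Butterworth order meeting a high-pass spec.

    Returns the real-valued order

        N = lg[(10^(|as|/10) - 1)/(10^(|ap|/10) - 1)] / (2*lg(wp/ws))

    and its integer ceiling (at least 1). For the default spec (3 dB /
    20 dB, cutoff ratio 10) the real order is 0.9988, hence first order.
    """
    if spec.passband_cutoff == spec.stopband_cutoff:
        raise ValueError("degenerate spec: equal cutoffs")
    num = (10 ** (abs(spec.stopband_atten_db) / 10) - 1) / (
        10 ** (abs(spec.passband_atten_db) / 10) - 1
    )
    order_real = math.log10(num) / (
        2 * math.log10(spec.passband_cutoff / spec.stopband_cutoff)
    )
    order = max(1, math.ceil(order_real))
    return order_real, order


def design_highpass(passband_cutoff: float, sampling_period: float = 1.0) -> FirstOrderIIR:
    """Bilinear-transform design of the first-order high-pass.

    Maps H(s) = s/(s + Wp) through s = (2/T)(1 - z^-1)/(1 + z^-1); T
    cancels, leaving

        b0 = 1/(1 + wp/2),   a1 = (1 - wp/2)/(1 + wp/2)

    for passband cutoff wp in rad/sample. No frequency pre-warping is
    applied: the design algebra maps wp directly, which reproduces the
    intended coefficients (0.9695, 0.9391 at wp = 0.02*pi).
    """
    if not (0 < passband_cutoff < math.pi):
        raise ValueError("passband_cutoff must lie in (0, pi) rad/sample")
    half = passband_cutoff / 2.0
    return FirstOrderIIR(
        b0=1.0 / (1.0 + half),
        a1=(1.0 - half) / (1.0 + half),
        sampling_period=sampling_period,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def quantize_coeffs(filt: FirstOrderIIR, bits: int) -> FirstOrderIIR:
    """Round both coefficients to the nearest multiple of 2**-bits.

    Ties round away from zero. Raises if the rounded feedback coefficient
    leaves the unit circle (unstable quantized filter).
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    scale = 2 ** bits
    b0q = _round_half_away(filt.b0 * scale) / scale
    a1q = _round_half_away(filt.a1 * scale) / scale
    if abs(a1q) >= 1:
        raise ValueError(
            f"quantization to {bits} bits yields |a1| = {abs(a1q)} >= 1 (unstable)"
        )
    return replace(filt, b0=b0q, a1=a1q, quant_bits=bits)


def magnitude_response(filt: FirstOrderIIR, omega):
    """Gain in dB at normalized frequency omega (rad/sample).

    Evaluates 20*log10 |b0(1 - e^-jw)/(1 - a1 e^-jw)|. The high-pass has
    an exact zero at DC, so omega = 0 returns -inf.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0) or np.any(omega > math.pi):
        raise ValueError("omega must lie in [0, pi]")
    z = np.exp(-1j * omega)
    mag = np.abs(filt.b0 * (1 - z) / (1 - filt.a1 * z))
    with np.errstate(divide="ignore"):
        db = 20 * np.log10(mag)
    if db.ndim == 0:
        return float(db)
    return db


def mti_apply(
    signal: BasebandSignal,
    filt: FirstOrderIIR,
    state: FilterState | None = None,
) -> tuple[BasebandSignal, FilterState]:
    """Filter every fast-time channel along slow time.

    Uses the transposed direct-form II recursion (scipy's ``lfilter``
    structure) with an explicit, caller-owned state so that processing a
    record in blocks is sample-identical to processing it in one shot.
    Real and imaginary parts pass through the same real coefficients.

    Returns the filtered record and the updated state.
    """
    x = signal.samples
    two_d = x.ndim == 2
    xm = x if two_d else x[:, None]
    n_ch = xm.shape[1]
    if state is None:
        state = FilterState.zeros(n_ch)
    if state.n_channels != n_ch:
        raise ValueError(
            f"filter state has {state.n_channels} channels, signal has {n_ch}"
        )
    y, zf = lfilter(filt.b, filt.a, xm, axis=0, zi=state.values)
    out = y if two_d else y[:, 0]
    return (
        BasebandSignal(
            samples=out,
            sample_rate=signal.sample_rate,
            seed=signal.seed,
            source=signal.source,
        ),
        FilterState(values=zf),
    )
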