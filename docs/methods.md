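# Methods

## Signal model

The simulator emits the slow-time baseband record of a continuous-wave
Doppler radar watching a breathing person:

    s(n) = exp(j·φ(n)) + c_clutter + c_leak + w(n),
    φ(n) = 4π·x(n/fs)/λ,
    x(t) = a_r·sin(2π f_r t + ψ_r) + a_h·sin(2π f_h t + ψ_h).

The two-way path gives the factor 4π/λ: half a wavelength of chest travel
is one full phase cycle. Clutter (ground/wall echoes) and transmit-antenna
leakage are constant complex terms — indistinguishable in slow time, but
kept as separate parameters so rejection tests can target each. Noise is
circular complex Gaussian with total power σ² split evenly between
quadratures, matching the narrowband model whose envelope is Rayleigh and
whose square-law power is exponential with mean σ².

Defaults (the package's study conditions): carrier 24 GHz (λ = 12.49 mm),
slow-time rate 20 Hz (comfortably above twice the 2 Hz heart-band top),
duration 120 s, respiration 0.267 Hz at 8 mm, heartbeat 1.383 Hz at
0.4 mm, standoff 0.5 m, noise power 10^-1.5 (15 dB SNR against the
unit-amplitude target). Amplitudes are bounded by physiology: the heart
never displaces the chest more than 0.6 mm; respiration amplitudes of
4–12 mm are typical for an adult.

What the generator does *not* emulate: body scattering and RF-chain
effects, amplitude modulation of the echo, non-sinusoidal heartbeat
waveforms, multiple subjects, range migration, and drift/motion artifacts.
Respiration harmonics still arise downstream, but only through the
nonlinear displacement-to-I/Q map, not from waveform shape. Passing tests
therefore demonstrate correctness of the processing chain under the model,
not robustness to every artifact of field data.

## MTI clutter filter

Design targets: passband cutoff ωp = 0.02π rad/sample at −3 dB, stopband
cutoff 0.002π at −20 dB. The Butterworth order formula

    N = lg[(10^{|αs|/10} − 1)/(10^{|αp|/10} − 1)] / (2·lg(ωp/ωs)) = 0.9988

licenses a first-order design. The bilinear transform of H(s) = s/(s+Ωp)
is applied without frequency pre-warping — the design algebra maps ωp
directly and T cancels — giving b0 = 1/(1+ωp/2) = 0.9695 and
a1 = (1−ωp/2)/(1+ωp/2) = 0.9391 (the exact feedforward value is
0.969541; a commonly printed 0.9696 comes from rounding an intermediate).
Realization is transposed direct form II (scipy's `lfilter` structure)
with explicit caller-owned per-channel state, so block-wise streaming is
sample-identical to one-shot filtering and an N-bin fast-time record is
two N-channel real IIR filters (I and Q share coefficients).

Coefficient quantization rounds to the nearest multiple of 2^−B with ties
away from zero (B = 5 gives 31/32 and 30/32) and re-checks |a1| < 1;
filter arithmetic itself stays in floating point — only the coefficients
are quantized, and the 5-bit response deviates from the exact one by less
than 0.5 dB above 0.01π. The filter's start-up transient has time
constant −1/ln(a1) ≈ 16 samples; the pipeline discards a 10 s settle
window (200 samples, by which point a step input has decayed below 1 %)
before spectral detection.

## CA-CFAR detection

Square-law bins of Gaussian noise are exponential, so P_FA = e^{−T/σ²}
and T = −σ²·ln(P_FA). The per-bin noise power is the arithmetic mean of
32 training cells (the exponential maximum-likelihood estimate) taken on
the leading flank beyond 2 guard cells; at array edges the window
reflects to the trailing flank, and a two-sided mode splits the training
cells across both flanks. Guard cells are a standard hedge against target
energy leaking into the training mean; setting 0 recovers the plain
cell-averaging description.

The plug-in threshold −σ̂²·ln(pfa) is used as derived. Its realized alarm
rate over an M-cell-averaged exponential background is
(1 + ln(1/pfa)/M)^{−M} — about 0.0135 at pfa = 0.01, M = 32 — and this
CFAR loss is documented and tested rather than corrected, since the
correction is not part of the chain being modelled. The pipeline default
pfa is 10^-6 so that, over the ~2000 positive-frequency bins of a 120 s
record, the expected number of false alarms is ≪ 1 and an empty scene
reliably reports "no detection".

## Overflow-controlled FFT

The FFT mimics a 16-bit fixed-point hardware pipeline. The
decimation-in-frequency butterfly a′ = a + b, b′ = (a − b)·W (|W| = 1)
obeys max(|a′|,|b′|) ≤ |a|+|b| ≤ max(2|a|,2|b|): magnitudes can at most
double per stage, so halving every stage's outputs guarantees no
overflow, and the result is DFT/N with scale exponent log2 N. (The
butterfly as stated is the DIF form, so the transform is implemented DIF
with natural-order input and a bit-reversal reorder at the end; the
spectrum is identical to a DIT implementation.) In fixed-point mode every
stage output is rounded to a two's-complement Q-grid (default 16 total /
14 fractional bits) with saturation that cannot trigger while the input
obeys the conditioning rule: twiddle rotation can swing a real or
imaginary part by up to 2×, so input components must stay within half
the representable maximum. Because each stage's rounding noise is halved
by all following stages, the accumulated error stays within a few LSB
(≤ 8 LSB is the tested bound at N = 1024; ~1.5 LSB typical), whereas
pre-scaling the input by 1/N would discard log2 N bits immediately.

## Phase demodulation and rate estimation

The echo phase is recovered by four-quadrant arctangent plus phase
expansion (unwrapping: successive differences forced into (−π, π]), and
λ/(4π)·φ reproduces the chest displacement. Before the arctangent the
static offset is removed by subtracting the least-squares center of the
I/Q trajectory (Kasa algebraic circle fit, linear in the center
coordinates; fallback to the complex mean for degenerate trajectories).
The center of the target circle is exactly clutter + leakage, so this
removes static offsets of any strength without bending the trajectory.
Taking the phase of the MTI output instead is deliberately avoided: the
high-pass also strips the target phasor's own low-frequency content,
which shifts the trajectory off its circle and folds respiration
harmonics and intermodulation into the heart band. The MTI filter's role
in the pipeline is the detection gate, where it is indispensable — with
30 dB static clutter the zero-padded record's spectral leakage otherwise
swamps the respiration line.

Rates are 60× the peak frequency of the magnitude spectrum of the
(mean-removed, zero-padded to a power of two) phase series, restricted to
the physiological band: respiration 0.1–0.5 Hz, heart 0.6–2 Hz. No peak
interpolation is applied; the bin width fs/N is reported alongside
(0.29 per-minute units for 120 s at 20 Hz padded to 4096). Optional
Savitzky–Golay smoothing (window 11, order 3 — chosen as the shortest
window that usefully smooths 20 Hz data without attenuating the 2 Hz
band top) is off by default. A peak below 3× the band median is flagged
low-confidence. An optional notch excludes integer multiples of the
detected respiration fundamental from the heart-band search, widened by
~(1 + k/2) bins at harmonic k because the fundamental's half-bin
quantization error scales with k; it is off by default in the pipeline
because the circle-compensated phase is linear in displacement — resp
harmonics do not arise there, and the notch can only mask a heart rate
that happens to coincide with a multiple of the respiration estimate.

## Pipeline and evaluation

Stage order: synthesize (or load I/Q text) → MTI (optionally 5-bit
quantized) → settle discard → power spectrum (optionally 16-bit
fixed-point FFT, input normalized to half range first — CFAR is scale
invariant) → CA-CFAR over positive-frequency bins excluding DC →
presence gate → circle-centered phase → per-band rate estimates, rounded
to integers per minute. Errors carry their stage identity; identical
configs (YAML round-trippable) give bitwise-identical reports.

Relative error against a reference-device rate is
100·|radar − reference|/reference; dividing by the reference value (not
the measured one) is the convention that reproduces all thirty published
comparison percentages at one-decimal rounding (ties away from zero),
and a `denominator="measured"` switch provides the alternative reading.
The shipped 15-trial table yields error ranges (0, 6.3) % for heart and
(0, 9.5) % for respiration.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for seconds-scale runs: 120 s
records at 20 Hz (2400 samples, 4096-point FFTs), 10^6-bin CFAR
calibrations, 10^5-draw distribution checks, and a 100-scene end-to-end
recovery study (rates and amplitudes drawn inside the physiological
bands, 10 dB SNR, success = both rates within 2 per-minute units,
≥ 95/100 required; the default scene reproduces 83 beats / 16 breaths
per minute). Ties in peak picking break to the lowest bin; quantization
ties round away from zero; the DC bin of the high-pass response is
reported as −inf.

## Known limitations

Single subject, single range cell; no random body motion or posture
change; rectangular observation windows (no tapering before the
detection spectrum); rates reported without peak interpolation, so
accuracy is resolution-limited for short records; the fixed-point
emulation covers the FFT only (filter arithmetic stays floating point
with quantized coefficients); detection probability is characterized
empirically, not in closed form.
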