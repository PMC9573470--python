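# vitalradar

Non-contact vital-sign detection with a Doppler radar: simulate chest-wall
baseband echoes, reject static clutter with an MTI high-pass filter, gate
target presence with square-law CA-CFAR thresholding, and estimate heart and
respiration rates from the demodulated echo phase.

## The problem and the signal model

A continuous-wave radar pointed at a person receives an echo whose phase
encodes the chest-wall displacement x(t): breathing moves the chest by
millimetres (0.1–0.5 Hz, 4–12 mm), the heartbeat by fractions of a
millimetre (0.6–2 Hz, 0.15–0.5 mm). After quadrature zero-IF demodulation
the slow-time baseband sample is

    s(n) = exp(j·4π·x(n/fs)/λ) + c + w(n)

with λ the carrier wavelength (12.5 mm at 24 GHz), c the constant complex
sum of static clutter and antenna leakage, and w circular complex Gaussian
noise. The processing chain answers two questions: *is a moving target
present?* and *at what rates is its chest moving?*

- **MTI clutter filter** — a first-order IIR high-pass from the bilinear
  transform of H(s) = s/(s+Ωp): y(n) = b0·[x(n) − x(n−1)] + a1·y(n−1) with
  b0 = 1/(1+ωp/2), a1 = (1−ωp/2)/(1+ωp/2). At the design point
  ωp = 0.02π this gives (0.9695, 0.9391), or (31/32, 30/32) after 5-bit
  quantization for fixed-point hardware; the Butterworth order formula
  confirms first order suffices (N = 0.9988).
- **CA-CFAR detection** — narrowband noise has a Rayleigh envelope, so
  square-law (power) bins are exponential and the threshold
  T = −σ̂²·ln(P_FA) holds the false-alarm rate constant; σ̂² is the
  maximum-likelihood cell average of 32 training cells beside each bin.
- **Overflow-controlled FFT** — a radix-2 butterfly (a′ = a+b,
  b′ = (a−b)W) can at most double a magnitude per stage, so halving every
  stage's outputs lets a 16-bit word never overflow; the result is DFT/N
  with the scale exponent log2 N carried along.
- **Phase-based rate estimation** — subtract the fitted I/Q circle center
  (the static offset), unwrap the four-quadrant phase (phase expansion),
  and read each rate as 60× the band-limited periodogram peak:
  heart band 0.6–2 Hz, respiration band 0.1–0.5 Hz.
- **Evaluation** — relative error 100·|radar − reference|/reference,
  matching a 15-trial comparison against a wearable reference whose error
  ranges are 0–6.3 % (heart) and 0–9.5 % (respiration).

## Worked example

```sh
python examples/05_full_pipeline.py
```

prints, for the default 120 s scene (respiration 0.267 Hz / 8 mm, heart
1.383 Hz / 0.4 mm, 15 dB SNR, seed 1):

```
detection triggered: True
heart rate:          83 beats/min (peak 1.3818 Hz)
respiration rate:    16 breaths/min (peak 0.2686 Hz)
spectral resolution: 0.29 per-minute units
vs a reference of 85: relative error 2.4%
15-trial reference study error ranges: heart (0.0, 6.3)%, respiration (0.0, 9.5)%
```

The detection gate triggered on the moving chest (a static-only scene
reports no detection), and both estimated rates equal the simulated ground
truth — 60×1.383 ≈ 83 and 60×0.267 ≈ 16 per minute — to within one
spectral bin (0.29 per-minute units at this record length). The other
examples exercise each stage on its own: echo synthesis (`01`), filter
design (`02`), CFAR thresholding (`03`) and the fixed-point FFT (`04`).

A `vitalradar` command with `generate`, `design-filter`, `detect`, `run`
and `evaluate` subcommands wraps the same functions for shell use
(`vitalradar run --seed 1`).

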