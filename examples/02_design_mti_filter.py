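"""Design, quantize and characterize the MTI clutter-rejection filter.

A first-order IIR high-pass (bilinear transform of H(s) = s/(s + Wp))
suppresses the zero-Doppler echo of walls and furniture. The printed
order below shows why first order suffices for a 3 dB / 20 dB spec with
a decade between cutoffs; the 5-bit coefficients are what a fixed-point
hardware implementation would use.
"""

import math

import vitalradar as vr

spec = vr.HighpassSpec()  # 0.02*pi passband, 0.002*pi stopband
order_real, order = vr.butterworth_order(spec)
print(f"required Butterworth order: {order_real:.4f} -> {order}")

filt = vr.design_highpass(spec.passband_cutoff)
print(f"coefficients: b0 = {filt.b0:.4f}, a1 = {filt.a1:.4f}")

quant = vr.quantize_coeffs(filt, 5)
print(f"5-bit quantized: b0 = {quant.b0 * 32:.0f}/32, a1 = {quant.a1 * 32:.0f}/32")

for label, omega in (("passband edge", spec.passband_cutoff),
                     ("stopband edge", spec.stopband_cutoff)):
    exact = vr.magnitude_response(filt, omega)
    rough = vr.magnitude_response(quant, omega)
    print(f"gain at {label} ({omega / math.pi:.3f}*pi): "
          f"{exact:6.2f} dB exact, {rough:6.2f} dB quantized")
print("the DC gain is -inf: static clutter is nulled exactly")
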