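"""Inspect the built-in filter registry and basic responses.

Prints each built-in filter's size, then evaluates the reduced-order IIR
filter's DC gain, Nyquist gain and first impulse-response samples.
"""

import numpy as np

import roiir as rk

for name in rk.builtin_names():
    f = rk.builtin_filter(name)
    print(f"{name:14s} numerator {len(f.b):3d} taps, denominator {len(f.a):3d}  - {f.label}")

f = rk.builtin_filter("roiir")
curve = rk.frequency_response(f, np.array([0.0, np.pi]))
print(f"\nreduced-order IIR H(1)  = {curve.values[0].real:+.6f}   (DC gain, 17/41)")
print(f"reduced-order IIR H(-1) = {curve.values[1].real:+.6f}   (Nyquist gain, -11/41)")

h = rk.impulse_response(f, 4).samples
print(f"impulse response        = {np.round(h, 6)}  (taps 3/41, 14/41, then zero)")
# The two nonzero samples are the filter's entire memory: a 2-tap FIR-like
# numerator over a pure gain, which is what makes it so cheap to realize.
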