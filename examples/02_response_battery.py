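"""Frequency-domain evaluation: magnitude, group delay, phase delay.

Compares the group-delay swing of the reduced-order IIR against the
60-order FIR and the 16-order IIR, and shows the linear-phase FIR's
constant 30-sample delay.
"""

import numpy as np

import roiir as rk

grid = rk.default_grid()

for name in ("fir60", "iir16", "bpf", "roiir"):
    f = rk.builtin_filter(name)
    s = rk.group_delay_summary(rk.group_delay(f, grid))
    print(
        f"{name:6s} group delay: mean {s.mean_gd:8.4f}  min {s.min_gd:8.4f}  "
        f"max {s.max_gd:8.4f}  swing {s.ptp_swing:8.4f}  (samples)"
    )
# The 60-order FIR is exactly linear phase (swing ~ 0 at delay 30); the
# reduced-order IIR swings by only ~0.45 samples across the whole band,
# far flatter than the 16-order IIR it approximates.

f = rk.builtin_filter("roiir")
mag = rk.magnitude_db(f, np.array([0.0, np.pi / 2]))
pd = rk.phase_delay(f, np.array([0.0, np.pi / 2]))
print(f"\nroiir magnitude at DC      : {mag.values[0]:.3f} dB  (20 log10 17/41)")
print(f"roiir phase delay at pi/2  : {pd.values[1]:.5f} samples")

s = rk.impulse_summary(f)
print(f"roiir impulse max          : {s.max_coeff:.5f}  (= 14/41)")
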