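"""End-to-end R-peak detection on synthetic ECG.

Generates a 60 s MIT-BIH-like record (360 Hz, 72 bpm), contaminates it with
powerline, baseline-wander, EMG and motion-artefact noise, and runs the
Pan-Tompkins-style detector with the bidirectional reduced-order IIR front
end.  Scores against the generator's exact ground truth at +-50 ms.
"""

import numpy as np

import roiir as rk

ecg = rk.generate_ecg(rk.ECGConfig(duration=60, heart_rate=72, seed=1))
print(f"clean record : {len(ecg.signal)} samples, {len(ecg.r_peaks)} true beats")

for label, signal in [
    ("clean", ecg.signal),
    ("noisy", rk.add_noise(ecg, rk.NoiseConfig(seed=2)).signal),
]:
    detected = rk.detect_rpeaks(signal)  # bidirectional roiir front end
    res = rk.evaluate_detection(detected, ecg.r_peaks, tolerance=0.05, fs=360.0)
    offsets = [d - t for t, d in res.matched_pairs]
    print(
        f"{label:6s} ECG : sensitivity {res.sensitivity:.3f}  PPV {res.ppv:.3f}  "
        f"(TP {res.tp}, FP {res.fp}, FN {res.fn}), median offset "
        f"{np.median(offsets):+.1f} samples"
    )

# Forward-only filtering keeps the detector working but shifts every
# detection by the filter's group delay; the bidirectional pass is
# zero-phase, so detections land exactly on the true R apices.
fwd = rk.detect_rpeaks(ecg.signal, rk.DetectorParams(bidirectional=False))
res = rk.evaluate_detection(fwd, ecg.r_peaks, tolerance=0.05, fs=360.0)
offsets = [d - t for t, d in res.matched_pairs]
print(f"forward-only : median offset {np.median(offsets):+.1f} samples")
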