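"""Pan-Tompkins-style R-peak detection with a pluggable front-end filter.

Pipeline: front-end band filtering (the reduced-order IIR by default,
applied bidirectionally for zero phase) -> five-point derivative ->
squaring -> moving-window integration -> adaptive dual-threshold peak
picking with a refractory period and missed-beat searchback.  Each accepted
detection is refined to the local maximum of the band-filtered signal
within +-50 ms, so with a zero-phase front end detections land on the R
apex itself.

The derivative and integration stages are realized as centered (zero-delay)
convolutions; all adaptive constants are exposed in
:class:`DetectorParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .filters import DigitalFilterTF, Signal, apply_filter, builtin_filter

__all__ = [
    "DetectorParams",
    "DetectionResult",
    "detect_rpeaks",
    "evaluate_detection",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the detection pipeline.

    ``threshold_gain_signal``/``threshold_gain_noise`` are the update
    weights of the running signal/noise peak estimates (classical value
    0.125); ``searchback_factor`` times the running RR mean triggers a
    missed-beat search at half threshold.
    """

    front_end: DigitalFilterTF = field(default_factory=lambda: builtin_filter("roiir"))
    bidirectional: bool = True
    integration_window: float = 0.150  # s
    refractory: float = 0.200          # s
    searchback_factor: float = 1.66
    threshold_gain_signal: float = 0.125
    threshold_gain_noise: float = 0.125
    refine_window: float = 0.05        # s; half-width of the apex refinement

    def __post_init__(self) -> None:
        if min(self.integration_window, self.refractory, self.refine_window) <= 0:
            raise ValueError("durations must be positive")
        if self.searchback_factor <= 1:
            raise ValueError("searchback_factor must exceed 1")


@dataclass(frozen=True)
class DetectionResult:
    detected: np.ndarray
    matched_pairs: list[tuple[int, int]]
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float


def detect_rpeaks(x: Signal, params: DetectorParams | None = None) -> np.ndarray:
    """Detect R-peak sample indices in a single-lead ECG signal."""
    params = params or DetectorParams()
    fs = x.fs
    if len(x) < 3 * fs:
        raise ValueError("signal must be at least 3 s long")

    band = apply_filter(params.front_end, x, bidirectional=params.bidirectional).samples

    kernel = (fs / 8.0) * np.array([1.0, 2.0, 0.0, -2.0, -1.0])
    deriv = np.convolve(band, kernel, mode="same")
    squared = deriv**2
    win = max(1, round(params.integration_window * fs))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refr = max(1, round(params.refractory * fs))
    peaks, _ = _sig.find_peaks(mwi, distance=refr)
    if len(peaks) == 0:
        return np.array([], dtype=int)

    # Adaptive dual thresholds initialized from the first 2 seconds.
    head = mwi[: max(win, round(2 * fs))]
    spk = 0.25 * float(np.max(head)) if np.max(head) > 0 else 0.0
    npk = 0.5 * float(np.mean(head))
    g_s, g_n = params.threshold_gain_signal, params.threshold_gain_noise

    qrs: list[int] = []
    noise_peaks: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npk + 0.25 * (spk - npk)

    for p in peaks:
        accepted = False
        if mwi[p] > threshold() and (not qrs or p - qrs[-1] > refr):
            accepted = True
        if accepted:
            spk = g_s * mwi[p] + (1 - g_s) * spk
            if qrs:
                rr_history.append(p - qrs[-1])
                rr_history[:] = rr_history[-8:]
            qrs.append(int(p))
        else:
            npk = g_n * mwi[p] + (1 - g_n) * npk
            noise_peaks.append(int(p))
            # Missed-beat searchback: if the gap since the last QRS exceeds
            # searchback_factor * mean RR, re-examine skipped candidates at
            # half threshold.
            if qrs and rr_history:
                rr_mean = float(np.mean(rr_history))
                if p - qrs[-1] > params.searchback_factor * rr_mean:
                    cands = [
                        q for q in noise_peaks
                        if qrs[-1] + refr < q <= p and mwi[q] > 0.5 * threshold()
                    ]
                    if cands:
                        best = max(cands, key=lambda q: mwi[q])
                        spk = 0.25 * mwi[best] + 0.75 * spk
                        qrs.append(int(best))
                        qrs.sort()
                        noise_peaks = [q for q in noise_peaks if q != best]

    # Refine each detection to the apex of the band-filtered signal.
    half = max(1, round(params.refine_window * fs))
    refined = []
    for p in qrs:
        lo, hi = max(0, p - half), min(len(band), p + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi])))

    # Enforce strictly increasing indices and the refractory separation.
    refined.sort()
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refr:
            if band[p] > band[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


def evaluate_detection(
    detected: np.ndarray,
    truth: np.ndarray,
    tolerance: float = 0.05,
    fs: float = 360.0,
) -> DetectionResult:
    """Score detections against ground truth by greedy one-to-one matching.

    Pairs within ``tolerance`` seconds are matched nearest-first; unmatched
    truth beats count as false negatives, unmatched detections as false
    positives.
    """
    detected = np.asarray(detected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if np.any(np.diff(detected) < 0) or np.any(np.diff(truth) < 0):
        raise ValueError("detected and truth must be sorted")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    tol_samples = tolerance * fs

    pairs = [
        (abs(int(d) - int(t)), ti, di)
        for ti, t in enumerate(truth)
        for di, d in enumerate(detected)
        if abs(int(d) - int(t)) <= tol_samples
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched.append((int(truth[ti]), int(detected[di])))
    matched.sort()

    tp = len(matched)
    fp = len(detected) - tp
    fn = len(truth) - tp
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    return DetectionResult(
        detected=detected,
        matched_pairs=matched,
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        ppv=ppv,
    )
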