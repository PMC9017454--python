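"""Rational digital filters in the delay variable, and the built-in filter registry.

A filter is written as

    H(z) = (b[0] + b[1] z^-1 + ... + b[M] z^-M) / (a[0] + a[1] z^-1 + ... + a[N] z^-N)

so ``b[k]`` multiplies the k-th delay of the input and ``a[k]`` the k-th delay
of the output.  Published transfer functions in this area are usually printed
as polynomials in descending powers; transcribing the printed coefficients in
order yields exactly this convention (highest printed power -> delay 0).

Responses are always computed on the normalized view (``a[0] == 1``);
implementation-cost accounting deliberately is not (see :mod:`roiir.cost`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "InvalidFilterError",
    "DigitalFilterTF",
    "Signal",
    "make_filter",
    "builtin_filter",
    "builtin_names",
    "frequency_response",
    "impulse_response",
    "step_response",
    "apply_filter",
    "filter_to_json",
    "filter_from_json",
    "save_signal_csv",
    "load_signal_csv",
]

DEFAULT_FS = 360.0  # Hz; the MIT-BIH single-lead convention


class InvalidFilterError(ValueError):
    """Raised for an empty/zero-leading denominator or non-finite coefficients."""


@dataclass(frozen=True)
class DigitalFilterTF:
    """A rational transfer function in the delay (z^-1) variable.

    Parameters
    ----------
    b, a
        Numerator / denominator coefficients; index k multiplies the k-th
        delay.  Trailing zeros are preserved (they matter for length and
        state counts in the cost model).
    fs
        Sampling rate in Hz the filter is meant to run at.
    label
        Free-text description.
    """

    b: tuple[float, ...]
    a: tuple[float, ...]
    fs: float = DEFAULT_FS
    label: str = ""

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.b)
        a = tuple(float(v) for v in self.a)
        if len(a) == 0:
            raise InvalidFilterError("denominator must be non-empty")
        if len(b) == 0:
            raise InvalidFilterError("numerator must be non-empty")
        if a[0] == 0.0:
            raise InvalidFilterError("leading denominator coefficient must be nonzero")
        if not all(np.isfinite(b)) or not all(np.isfinite(a)):
            raise InvalidFilterError("all coefficients must be finite")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", a)

    @property
    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, a) divided by a[0]; the view every response computation uses."""
        a0 = self.a[0]
        return np.asarray(self.b) / a0, np.asarray(self.a) / a0

    def with_label(self, label: str) -> "DigitalFilterTF":
        return replace(self, label=label)


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued signal (amplitudes in mV for ECG)."""

    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def make_filter(
    b: Sequence[float],
    a: Sequence[float],
    fs: float = DEFAULT_FS,
    label: str = "",
) -> DigitalFilterTF:
    """Construct a :class:`DigitalFilterTF`, validating the coefficient vectors."""
    return DigitalFilterTF(b=tuple(b), a=tuple(a), fs=fs, label=label)


# ---------------------------------------------------------------------------
# Built-in registry: the published transfer functions, transcribed
# digit-for-digit from their display equations (descending powers -> delays).
# ---------------------------------------------------------------------------

_SPEECH_IIR_B = (
    0.02426, 0.2165, 1.039, 3.401, 8.38, 16.32, 25.868, 33.89, 37.05,
    33.89, 25.86, 16.32, 8.38, 3.401, 1.039, 0.2165, 0.02426,
)
_SPEECH_IIR_A = (
    1.0, 5.194, 13.43, 23.61, 32.38, 36.66, 34.85, 28.07, 19.36, 11.44,
    5.75, 2.427, 0.8482, 0.2382, 0.05069, 0.007401, 0.0005974,
)

_BPF_B = (0.2066, 0.0, -0.4131, 0.0, 0.2066)
_BPF_A = (1.0, 0.5488, 0.4535, 0.1763, 0.1958)

_IIR16_B = (
    0.3201, 4.517, 30.45, 130.0, 393.2, 892.9, 1574.0, 2196.0, 2452.0,
    2196.0, 1574.0, 892.9, 393.2, 130.0, 30.45, 4.517, 0.3201,
)
_IIR16_A = (
    1.0, 12.12, 70.25, 258.1, 672.2, 1316.0, 2004.0, 2419.0, 2340.0,
    1819.0, 113.0, 559.4, 214.8, 62.0, 12.7, 1.649, 0.102,
)

# 60-order low-pass FIR; the printed polynomial is palindromic
# (linear phase), which the test suite asserts programmatically.
_FIR60_B = (
    -4.168e-19, 0.0004528, -0.0008864, 0.001208, -0.00127, 0.0009014,
    -5.451e-18, -0.001371, 0.002909, -0.004086, 0.004272, -0.002955,
    3.791e-17, 0.004159, -0.008473, 0.01146, -0.01158, 0.00778,
    -2.215e-17, -0.01052, 0.02122, -0.02865, 0.02921, -0.02005,
    2.962e-17, 0.02986, -0.06616, 0.1037, -0.1364, 0.1587, 0.8331,
    0.1587, -0.1364, 0.1037, -0.06616, 0.02986, 2.962e-17, -0.02005,
    0.02921, -0.02865, 0.02122, -0.01052, -2.215e-17, 0.00778, -0.01158,
    0.01146, -0.008473, 0.004159, 3.791e-17, -0.002955, 0.004272,
    -0.004086, 0.002909, -0.001371, -5.451e-18, 0.0009014, -0.00127,
    0.001208, -0.0008864, 0.0004528, -4.168e-19,
)

_PAN_TOMPKINS_B = (
    0.03125, 0.0, 0.0, 0.0, 0.0, 0.0, -0.0625, 0.0, 0.0, 0.0, 0.0, 0.0, 0.03125,
)
_PAN_TOMPKINS_A = (1.0, -2.0, 1.0)

_ROIIR_B = (3.0, 14.0)
_ROIIR_A = (41.0,)

_REGISTRY: dict[str, tuple[tuple[float, ...], tuple[float, ...], str]] = {
    "speech_iir": (_SPEECH_IIR_B, _SPEECH_IIR_A, "two-stage 16-order IIR (speech front-end)"),
    "bpf": (_BPF_B, _BPF_A, "4-order ECG band-pass filter"),
    "iir16": (_IIR16_B, _IIR16_A, "two-stage 16-order ECG IIR filter"),
    "fir60": (_FIR60_B, (1.0,), "60-order linear-phase low-pass FIR"),
    "pan_tompkins": (_PAN_TOMPKINS_B, _PAN_TOMPKINS_A, "Pan-Tompkins 32-order band-pass"),
    "roiir": (_ROIIR_B, _ROIIR_A, "reduced-order IIR filter (3z+14)/41"),
}


def builtin_names() -> list[str]:
    """Names of the built-in filters."""
    return list(_REGISTRY)


def builtin_filter(name: str, fs: float = DEFAULT_FS) -> DigitalFilterTF:
    """Look up one of the built-in published transfer functions by name.

    Valid names: ``speech_iir``, ``bpf``, ``iir16``, ``fir60``,
    ``pan_tompkins``, ``roiir``.
    """
    try:
        b, a, label = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown filter {name!r}; valid names: {', '.join(_REGISTRY)}"
        ) from None
    return DigitalFilterTF(b=b, a=a, fs=fs, label=label)


# ---------------------------------------------------------------------------
# Responses and application
# ---------------------------------------------------------------------------

def _evaluate_polys(
    b: np.ndarray, a: np.ndarray, omegas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate numerator and denominator at e^{j omega}."""
    kb = np.arange(len(b))
    ka = np.arange(len(a))
    B = np.exp(-1j * np.outer(omegas, kb)) @ b
    A = np.exp(-1j * np.outer(omegas, ka)) @ a
    return B, A


def frequency_response(f: DigitalFilterTF, grid) -> "ResponseCurve":
    """Complex frequency response H(e^{j omega}) on the grid.

    Grid points where the denominator evaluates to exactly zero are flagged
    undefined rather than raising.
    """
    from .response import ResponseCurve, as_grid

    grid = as_grid(grid)
    b, a = f.normalized
    B, A = _evaluate_polys(b, a, grid.omegas)
    defined = A != 0
    values = np.full(len(grid.omegas), np.nan + 0j, dtype=complex)
    values[defined] = B[defined] / A[defined]
    return ResponseCurve(grid=grid, values=values, defined=defined)


def impulse_response(f: DigitalFilterTF, n: int) -> Signal:
    """First ``n`` samples of the unit-impulse response (zero initial state)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    b, a = f.normalized
    x = np.zeros(n)
    x[0] = 1.0
    return Signal(samples=_sig.lfilter(b, a, x), fs=f.fs)


def step_response(f: DigitalFilterTF, n: int) -> Signal:
    """First ``n`` samples of the unit-step response (running sum of the impulse)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    b, a = f.normalized
    return Signal(samples=_sig.lfilter(b, a, np.ones(n)), fs=f.fs)


def apply_filter(f: DigitalFilterTF, x: Signal, bidirectional: bool = False) -> Signal:
    """Run the filter over a signal.

    The forward pass runs the difference equation with zero initial state.
    The bidirectional pass filters forward then time-reversed with reflect
    padding of length ``3 * max(len(a), len(b))`` at both ends, which cancels
    the phase response (zero phase) and squares the magnitude response.
    """
    if len(x) == 0:
        raise ValueError("signal must be non-empty")
    b, a = f.normalized
    if not bidirectional:
        return Signal(samples=_sig.lfilter(b, a, x.samples), fs=x.fs)
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise ValueError(
            f"signal of length {len(x)} too short for bidirectional filtering "
            f"(needs > {padlen} samples)"
        )
    y = _sig.filtfilt(b, a, x.samples, padtype="even", padlen=padlen)
    return Signal(samples=y, fs=x.fs)


# ---------------------------------------------------------------------------
# Exchange formats
# ---------------------------------------------------------------------------

def filter_to_json(f: DigitalFilterTF) -> str:
    """Serialize a filter to the ``{label, fs, b, a}`` JSON object."""
    return json.dumps(
        {"label": f.label, "fs": f.fs, "b": list(f.b), "a": list(f.a)}, indent=2
    )


def filter_from_json(text: str) -> DigitalFilterTF:
    """Inverse of :func:`filter_to_json` (lossless round-trip)."""
    obj = json.loads(text)
    return DigitalFilterTF(
        b=tuple(obj["b"]), a=tuple(obj["a"]),
        fs=float(obj.get("fs", DEFAULT_FS)), label=obj.get("label", ""),
    )


def save_signal_csv(x: Signal, path: str | Path) -> None:
    """Write a signal as CSV: a ``fs,<Hz>`` header row then one sample per line."""
    with open(path, "w") as fh:
        fh.write(f"fs,{float(x.fs)!r}\n")
        for v in x.samples:
            fh.write(f"{float(v)!r}\n")


def load_signal_csv(path: str | Path) -> Signal:
    """Read a signal written by :func:`save_signal_csv`."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if len(header) != 2 or header[0] != "fs":
            raise ValueError("expected header row 'fs,<Hz>'")
        fs = float(header[1])
        samples = np.array([float(line) for line in fh if line.strip()])
    return Signal(samples=samples, fs=fs)
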