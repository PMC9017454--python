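"""Pole-zero extraction and stability classification in the z-plane.

A causal digital filter is stable iff all poles lie strictly inside the unit
circle.  The verdict is three-way because a filter can sit exactly on the
circle (the Pan-Tompkins band-pass has a double pole at z = 1): within
``tol`` of modulus 1 it is *marginally stable*, strictly inside *stable*,
otherwise *unstable*.  Root finding uses companion-matrix eigenvalues with
coefficient balancing (``numpy.roots``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import DigitalFilterTF

__all__ = ["PoleZeroSet", "StabilityReport", "poles_zeros", "stability_report"]

DEFAULT_TOL = 1e-10


@dataclass(frozen=True)
class PoleZeroSet:
    """Roots of the numerator (zeros) and denominator (poles) as polynomials
    in z, plus the leading-coefficient gain ratio.

    Structural poles/zeros at the origin arising from a length mismatch of
    the two coefficient vectors are included, so the pole and zero counts
    are always equal.
    """

    poles: np.ndarray
    zeros: np.ndarray
    gain: float


@dataclass(frozen=True)
class StabilityReport:
    verdict: str  # "stable" | "marginally_stable" | "unstable"
    max_pole_modulus: float


def _trim_trailing(c: np.ndarray) -> np.ndarray:
    """Drop trailing zero delays (they do not change the transfer function)."""
    nz = np.flatnonzero(c)
    if len(nz) == 0:
        return c[:1]
    return c[: nz[-1] + 1]


def _z_poly(c: np.ndarray, length: int) -> np.ndarray:
    """Coefficients of c as a polynomial in z of degree length-1.

    H(z^-1) terms c[k] z^-k, multiplied through by z^(length-1), give a
    z-polynomial whose descending coefficients are c padded with zeros.
    """
    return np.concatenate([c, np.zeros(length - len(c))])


def poles_zeros(f: DigitalFilterTF) -> PoleZeroSet:
    """Poles, zeros and gain of the filter on the z-polynomial view."""
    b = _trim_trailing(np.asarray(f.b, dtype=float))
    a = _trim_trailing(np.asarray(f.a, dtype=float))
    length = max(len(b), len(a))
    zeros = np.roots(_z_poly(b, length))
    poles = np.roots(_z_poly(a, length))
    b_lead = b[np.flatnonzero(b)[0]] if np.any(b) else 0.0
    return PoleZeroSet(poles=poles, zeros=zeros, gain=float(b_lead / a[0]))


def stability_report(f: DigitalFilterTF, tol: float = DEFAULT_TOL) -> StabilityReport:
    """Classify the filter by its maximum pole modulus.

    FIR filters (constant denominator) have no poles away from the origin
    and are unconditionally stable.
    """
    pz = poles_zeros(f)
    max_mod = float(np.max(np.abs(pz.poles))) if len(pz.poles) else 0.0
    if max_mod < 1.0 - tol:
        verdict = "stable"
    elif abs(max_mod - 1.0) <= tol:
        verdict = "marginally_stable"
    else:
        verdict = "unstable"
    return StabilityReport(verdict=verdict, max_pole_modulus=max_mod)
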