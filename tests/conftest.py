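import numpy as np
import pytest

import roiir as rk


@pytest.fixture(scope="session")
def grid():
    return rk.default_grid()


@pytest.fixture(scope="session")
def registry():
    return {name: rk.builtin_filter(name) for name in rk.builtin_names()}


def numerical_group_delay(f, omegas, d=3e-7):
    """Independent oracle: central difference of the principal phase.

    Evaluates the response phase at w +- d directly (extended precision) and
    wraps the difference into (-pi, pi] before dividing, so the estimate is
    immune to 2-pi ambiguity as long as no phase jump lies inside the
    bracket.
    """
    b, a = f.normalized
    bl = b.astype(np.longdouble)
    al = a.astype(np.longdouble)
    kb = np.arange(len(b), dtype=np.longdouble)
    ka = np.arange(len(a), dtype=np.longdouble)

    def phase(w):
        Eb = np.exp((-1j * np.clongdouble(1)) * np.outer(w, kb))
        Ea = np.exp((-1j * np.clongdouble(1)) * np.outer(w, ka))
        return np.angle((Eb @ bl) / (Ea @ al))

    dphi = np.angle(np.exp(1j * (phase(omegas + d) - phase(omegas - d))))
    return -dphi / (2 * d)
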