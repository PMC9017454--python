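"""Minimal plotting layer (pole-zero charts, response curves)."""

from __future__ import annotations

import numpy as np

from .filters import DigitalFilterTF
from .response import ResponseCurve
from .stability import poles_zeros


def plot_pole_zero(f: DigitalFilterTF, path: str, title: str | None = None) -> None:
    """Save a unit-circle pole-zero chart for a filter as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pz = poles_zeros(f)
    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 400)
    ax.plot(np.cos(theta), np.sin(theta), "k--", lw=0.8)
    ax.plot(np.real(pz.zeros), np.imag(pz.zeros), "o", mfc="none", label="zeros")
    ax.plot(np.real(pz.poles), np.imag(pz.poles), "x", label="poles")
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("Re(z)")
    ax.set_ylabel("Im(z)")
    ax.set_title(title or (f.label or "pole-zero chart"))
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_curve(curve: ResponseCurve, path: str, ylabel: str = "value", title: str = "") -> None:
    """Save a response curve (defined points only) as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    m = curve.defined
    ax.plot(curve.omegas[m] / np.pi, np.real(curve.values[m]), lw=1.0)
    ax.set_xlabel("normalized frequency (×π rad/sample)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
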