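"""Implementation-cost accounting for a single-rate direct-form realization.

Counts are taken on the *as-printed* coefficient vectors, not the normalized
view: a filter published as (3z + 14)/41 is realized with the literal
constants 3, 14 and 41, and normalizing first would silently change the
multiplier count.  Trivial coefficients (0, +1, -1) cost nothing — a zero
tap is absent from the structure and a +-1 tap is a wire/negation:

* multipliers  = numerator coefficients not in {0, +1, -1}
               + denominator coefficients after the first not in {0, +1, -1}
               + 1 if the leading denominator coefficient is not +-1
* adders       = max(nonzero numerator coefficients - 1, 0)
               + nonzero denominator coefficients after the first
* states       = max(numerator length, denominator length) - 1

For a single-rate direct form the per-input-sample counts equal the totals.
Lengths count the as-printed vectors including interior and trailing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

from .filters import DigitalFilterTF
from .stability import stability_report

__all__ = ["CostReport", "cost_report"]


@dataclass(frozen=True)
class CostReport:
    multipliers: int
    adders: int
    states: int
    mults_per_input: int
    adds_per_input: int
    numerator_length: int
    denominator_length: int
    stable: str  # verdict from the stability module


def _nontrivial(c: float) -> bool:
    return c not in (0.0, 1.0, -1.0)


def cost_report(f: DigitalFilterTF) -> CostReport:
    """Count multipliers, adders and states on the as-printed coefficients."""
    b, a = f.b, f.a
    mults = sum(_nontrivial(c) for c in b)
    mults += sum(_nontrivial(c) for c in a[1:])
    if a[0] not in (1.0, -1.0):
        mults += 1
    adders = max(sum(c != 0.0 for c in b) - 1, 0)
    adders += sum(c != 0.0 for c in a[1:])
    states = max(len(b), len(a)) - 1
    return CostReport(
        multipliers=mults,
        adders=adders,
        states=states,
        mults_per_input=mults,
        adds_per_input=adders,
        numerator_length=len(b),
        denominator_length=len(a),
        stable=stability_report(f).verdict,
    )
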