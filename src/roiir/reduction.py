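"""Minimax (Chebyshev) order reduction of digital IIR filters.

Given a high-order reference transfer function, find low-order numerator and
denominator coefficient vectors [b, a] (a0 fixed at 1) minimizing the
worst-case weighted deviation of the complex frequency response over a grid:

    minimize over b, a   max_w  weight(w) * | H(e^{jw}; b, a) - H_ref(e^{jw}) |

The default search is a seeded differential-evolution population over the
coefficient box [-20, 20], followed by a Nelder-Mead polish (a simplex
method; the Chebyshev objective is non-smooth, so gradient-based polishing
is inappropriate).  An alternative "consecutive" mode optimizes one
coefficient at a time, cycling until the change falls below 1e-9.

Stability is enforced by penalty: any candidate with a pole modulus >= 1
pays ``stability_penalty * (max modulus - 1)`` on top of its error, and the
returned filter is guaranteed to have all poles strictly inside the unit
circle (or none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize as _opt

from .filters import DigitalFilterTF, make_filter
from .response import FrequencyGrid, as_grid, default_grid
from .stability import stability_report

__all__ = [
    "ReductionConfig",
    "ReducedFilterResult",
    "minimax_error",
    "reduce_order",
]

_BIG = 1e12  # objective value for candidates whose response is not finite


@dataclass(frozen=True)
class ReductionConfig:
    """Configuration of the reduction problem and optimizer.

    ``num_order``/``den_order`` are polynomial orders, so the result has
    ``num_order + 1`` numerator and ``den_order + 1`` denominator
    coefficients.  ``objective`` selects what is matched: the complex
    response ("complex", default) or only its magnitude ("magnitude").
    """

    num_order: int
    den_order: int
    grid: Optional[FrequencyGrid] = None
    weight: Optional[np.ndarray] = None
    popsize: int = 15          # population multiplier per free coefficient
    max_iterations: int = 2000
    local_polish: bool = True
    seed: int = 0
    stability_penalty: float = 1e3
    mode: str = "global"       # "global" | "consecutive"
    objective: str = "complex"  # "complex" | "magnitude"
    coeff_bound: float = 20.0
    x0: Optional[np.ndarray] = None  # optional initial candidate [b..., a1...]

    def __post_init__(self) -> None:
        if self.num_order < 0 or self.den_order < 0:
            raise ValueError("orders must be nonnegative")
        if self.num_order + self.den_order < 1:
            raise ValueError("at least one of num_order/den_order must be >= 1")
        if self.mode not in ("global", "consecutive"):
            raise ValueError("mode must be 'global' or 'consecutive'")
        if self.objective not in ("complex", "magnitude"):
            raise ValueError("objective must be 'complex' or 'magnitude'")
        grid = default_grid() if self.grid is None else as_grid(self.grid)
        object.__setattr__(self, "grid", grid)
        if self.weight is not None:
            w = np.asarray(self.weight, dtype=float)
            if len(w) != len(grid) or np.any(w < 0):
                raise ValueError("weight must be nonnegative and match the grid")
            object.__setattr__(self, "weight", w)


@dataclass(frozen=True)
class ReducedFilterResult:
    filter: DigitalFilterTF
    minimax_error: float
    converged: bool
    iterations_used: int


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _response_on(b: np.ndarray, a: np.ndarray, E_num: np.ndarray, E_den: np.ndarray):
    B = E_num[:, : len(b)] @ b
    A = E_den[:, : len(a)] @ a
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(A != 0, B / np.where(A != 0, A, 1.0), np.inf + 0j)


def _eval_matrix(omegas: np.ndarray, ncoef: int) -> np.ndarray:
    return np.exp(-1j * np.outer(omegas, np.arange(ncoef)))


def minimax_error(
    f: DigitalFilterTF,
    ref: DigitalFilterTF,
    grid=None,
    weight: Optional[np.ndarray] = None,
) -> float:
    """Weighted Chebyshev distance between two filters' complex responses.

    max over defined grid points of weight(w) * |H_f(e^{jw}) - H_ref(e^{jw})|.
    """
    grid = default_grid() if grid is None else as_grid(grid)
    om = grid.omegas
    bf, af = f.normalized
    br, ar = ref.normalized
    Hf = _response_on(bf, af, _eval_matrix(om, len(bf)), _eval_matrix(om, len(af)))
    Hr = _response_on(br, ar, _eval_matrix(om, len(br)), _eval_matrix(om, len(ar)))
    diff = np.abs(Hf - Hr)
    if weight is not None:
        diff = np.asarray(weight, dtype=float) * diff
    ok = np.isfinite(diff)
    if not np.any(ok):
        return float("inf")
    return float(np.max(diff[ok]))


def _max_pole_modulus(a_tail: np.ndarray) -> float:
    if len(a_tail) == 0:
        return 0.0
    return float(np.max(np.abs(np.roots(np.concatenate([[1.0], a_tail])))))


class _Problem:
    def __init__(self, ref: DigitalFilterTF, cfg: ReductionConfig):
        self.cfg = cfg
        self.nb = cfg.num_order + 1
        self.na = cfg.den_order
        om = cfg.grid.omegas
        br, ar = ref.normalized
        Href = _response_on(
            br, ar, _eval_matrix(om, len(br)), _eval_matrix(om, len(ar))
        )
        self.mask = np.isfinite(Href)
        self.Href = Href[self.mask]
        if cfg.objective == "magnitude":
            self.Href = np.abs(self.Href)
        self.E_num = _eval_matrix(om[self.mask], self.nb)
        self.E_den = _eval_matrix(om[self.mask], self.na + 1)
        self.weight = None if cfg.weight is None else cfg.weight[self.mask]

    def split(self, x: np.ndarray):
        return x[: self.nb], np.concatenate([[1.0], x[self.nb :]])

    def error(self, x: np.ndarray) -> float:
        b, a = self.split(x)
        H = _response_on(b, a, self.E_num, self.E_den)
        if self.cfg.objective == "magnitude":
            H = np.abs(H)
        diff = np.abs(H - self.Href)
        if self.weight is not None:
            diff = self.weight * diff
        if not np.all(np.isfinite(diff)):
            return _BIG
        return float(np.max(diff)) if len(diff) else 0.0

    def penalized(self, x: np.ndarray) -> float:
        err = self.error(x)
        mod = _max_pole_modulus(x[self.nb :])
        if mod >= 1.0:
            err += self.cfg.stability_penalty * (mod - 1.0) + 1e-6
        return err


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def reduce_order(ref: DigitalFilterTF, cfg: ReductionConfig) -> ReducedFilterResult:
    """Find the reduced-order filter minimizing the minimax response error.

    Deterministic for a fixed seed.  If ``cfg.x0`` is given, that candidate
    joins the initial population (useful for warm starts, e.g. nesting a
    lower-order optimum inside a larger model class).
    """
    prob = _Problem(ref, cfg)
    nfree = prob.nb + prob.na
    bounds = [(-cfg.coeff_bound, cfg.coeff_bound)] * nfree
    if cfg.x0 is not None and len(cfg.x0) != nfree:
        raise ValueError(f"x0 must have {nfree} entries")

    if cfg.mode == "consecutive":
        x, iters, converged = _coordinate_descent(prob, bounds, cfg)
    else:
        kwargs = dict(
            bounds=bounds,
            seed=cfg.seed,
            maxiter=cfg.max_iterations,
            tol=1e-10,
            popsize=cfg.popsize,
            polish=False,
            init="latinhypercube",
        )
        if cfg.x0 is not None:
            kwargs["x0"] = np.asarray(cfg.x0, dtype=float)
        de = _opt.differential_evolution(prob.penalized, **kwargs)
        x, iters, converged = de.x, int(de.nit), bool(de.success)

    if cfg.local_polish:
        nm = _opt.minimize(
            prob.penalized,
            x,
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxiter=4000 * nfree),
        )
        if nm.fun <= prob.penalized(x):
            x = nm.x
        iters += int(nm.nit)

    x = _ensure_stable(x, prob)
    b, a_tail = x[: prob.nb], x[prob.nb :]
    filt = make_filter(
        b=b,
        a=np.concatenate([[1.0], a_tail]),
        fs=ref.fs,
        label=f"minimax reduction of {ref.label or 'reference'} "
        f"to order ({cfg.num_order},{cfg.den_order})",
    )
    return ReducedFilterResult(
        filter=filt,
        minimax_error=prob.error(x),
        converged=converged,
        iterations_used=iters,
    )


def _coordinate_descent(prob: _Problem, bounds, cfg: ReductionConfig):
    """Optimize one coefficient at a time, cycling until change < 1e-9."""
    nfree = prob.nb + prob.na
    x = (
        np.asarray(cfg.x0, dtype=float).copy()
        if cfg.x0 is not None
        else np.zeros(nfree)
    )
    max_cycles = max(1, cfg.max_iterations // nfree)
    converged = False
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        x_prev = x.copy()
        for i in range(nfree):
            def f1d(v, i=i):
                xt = x.copy()
                xt[i] = v
                return prob.penalized(xt)

            res = _opt.minimize_scalar(
                f1d, bounds=bounds[i], method="bounded",
                options=dict(xatol=1e-12),
            )
            if res.fun <= prob.penalized(x):
                x[i] = res.x
        if np.max(np.abs(x - x_prev)) < 1e-9:
            converged = True
            break
    return x, cycles * nfree, converged


def _ensure_stable(x: np.ndarray, prob: _Problem) -> np.ndarray:
    """Radially shrink any on/outside-circle poles to modulus < 1.

    The penalty keeps the search inside the stable region; this is a final
    safeguard so the returned filter always satisfies the strict criterion.
    """
    a_tail = x[prob.nb :]
    if len(a_tail) == 0:
        return x
    mod = _max_pole_modulus(a_tail)
    if mod < 1.0 - 1e-12:
        return x
    roots = np.roots(np.concatenate([[1.0], a_tail]))
    roots = np.where(np.abs(roots) >= 1.0 - 1e-12, roots * (0.995 / np.abs(roots)), roots)
    a_new = np.real(np.poly(roots))
    x = x.copy()
    x[prob.nb :] = a_new[1:]
    return x
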