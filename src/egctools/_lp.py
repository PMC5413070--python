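"""Thin wrapper around scipy's HiGHS linear-programming interface.

All flux LPs in this package (viability, detection, certification) go through
:func:`solve_lp`; keeping a single entry point makes solver status handling
uniform and the simplex method selectable in one place.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog


class SolverError(RuntimeError):
    """The LP/MILP solver failed in a way the caller cannot recover from."""


_STATUS = {
    0: "optimal",
    1: "iteration_limit",
    2: "infeasible",
    3: "unbounded",
    4: "numerical",
}


@dataclass
class LPResult:
    status: str
    objective: float | None
    x: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_lp(c, bounds, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
             maximize=False, simplex=False) -> LPResult:
    """Solve min (or max) c'x subject to A_eq x = b_eq, A_ub x <= b_ub, bounds.

    `bounds` is a sequence of (lo, hi) pairs.  With ``simplex=True`` HiGHS'
    dual simplex is forced, which guarantees a vertex (basic) solution --
    needed when the support of the solution is the quantity of interest.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    method = "highs-ds" if simplex else "highs"
    res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method=method)
    status = _STATUS.get(res.status, f"unknown({res.status})")
    if res.status == 0:
        return LPResult("optimal", sign * float(res.fun), res.x)
    if res.status in (2, 3):
        return LPResult(status, None, None)
    raise SolverError(f"LP solver failed with status '{status}': {res.message}")
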