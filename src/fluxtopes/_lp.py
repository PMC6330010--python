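"""Thin wrapper around scipy's HiGHS LP interface.

All feasibility and optimization problems in the package are linear
programs over the flux variables v with the steady-state rows ``N v = 0``,
per-variable box bounds, and optionally extra dense rows (e.g. an
objective-optimality window ``d - tol <= c^T v <= d``).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

#: HiGHS primal/dual feasibility tolerance used for every solve.
SOLVER_TOL = 1e-10

UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """The LP solver failed for numerical (not feasibility) reasons."""


class InfeasibleError(RuntimeError):
    """The constraint system admits no solution."""


class UnboundedError(RuntimeError):
    """The objective is unbounded over the feasible set."""


def _clean_bounds(lb, ub):
    lo = np.where(np.isneginf(lb), None, lb)
    hi = np.where(np.isposinf(ub), None, ub)
    return list(zip(lo.tolist(), hi.tolist()))


def solve(N: np.ndarray, *, c: np.ndarray | None = None, sense: str = "min",
          lb: np.ndarray, ub: np.ndarray,
          extra_rows: list[tuple[np.ndarray, float, float]] | None = None):
    """Solve ``min/max c^T v`` s.t. ``N v = 0``, ``lb <= v <= ub`` and
    ``lo <= a^T v <= hi`` for each extra row ``(a, lo, hi)``.

    Returns ``(status, value, x)`` where status is "optimal", "infeasible"
    or "unbounded"; with ``c=None`` a pure feasibility problem is solved.
    """
    m, r = N.shape
    obj = np.zeros(r) if c is None else np.asarray(c, float)
    sign = 1.0 if sense == "min" else -1.0
    A_ub, b_ub = [], []
    for a, lo, hi in extra_rows or []:
        a = np.asarray(a, float)
        if np.isfinite(hi):
            A_ub.append(a)
            b_ub.append(hi)
        if np.isfinite(lo):
            A_ub.append(-a)
            b_ub.append(-lo)
    res = linprog(
        sign * obj,
        A_eq=N if m else None,
        b_eq=np.zeros(m) if m else None,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=_clean_bounds(np.asarray(lb, float), np.asarray(ub, float)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status == 0:
        return "optimal", sign * res.fun, res.x
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise SolverError(f"LP solver failed: {res.message}")


def feasible(N, lb, ub, extra_rows=None) -> tuple[bool, np.ndarray | None]:
    """Feasibility of ``N v = 0, lb <= v <= ub`` (+ extra rows)."""
    status, _, x = solve(N, lb=lb, ub=ub, extra_rows=extra_rows)
    return status == "optimal", x
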