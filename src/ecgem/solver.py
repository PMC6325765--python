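"""Thin, deterministic LP/QP layer over scipy (HiGHS) and OSQP.

The rest of the package talks to these two functions only, so the numerical
backends can be swapped without touching the analysis code.  Both backends are
deterministic given identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = ["LPResult", "solve_lp", "solve_qp", "FEASIBILITY_TOL"]

#: primal feasibility tolerance requested from the solvers
FEASIBILITY_TOL = 1e-9


@dataclass
class LPResult:
    x: np.ndarray | None
    objective: float | None
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    message: str = ""


_HIGHS_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "min",
) -> LPResult:
    """min (or max) cᵀx  s.t.  A_eq·x = b_eq,  lb ≤ x ≤ ub."""
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=sparse.csr_matrix(A_eq),
        b_eq=np.asarray(b_eq, dtype=float),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _HIGHS_STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(None, None, status, res.message)
    return LPResult(res.x, sign * res.fun, "optimal", res.message)


def solve_qp(
    P: sparse.spmatrix,
    q: np.ndarray,
    A: sparse.spmatrix,
    l: np.ndarray,
    u: np.ndarray,
) -> LPResult:
    """min ½ xᵀPx + qᵀx  s.t.  l ≤ A·x ≤ u   (convex; OSQP with polishing)."""
    import osqp

    prob = osqp.OSQP()
    prob.setup(
        P=sparse.csc_matrix(P),
        q=np.asarray(q, dtype=float),
        A=sparse.csc_matrix(A),
        l=np.asarray(l, dtype=float),
        u=np.asarray(u, dtype=float),
        verbose=False,
        eps_abs=1e-9,
        eps_rel=1e-9,
        eps_prim_inf=1e-10,
        eps_dual_inf=1e-10,
        max_iter=200000,
        polishing=True,
        polish_refine_iter=10,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status.lower()
    if "solved" in status:
        return LPResult(np.asarray(res.x, dtype=float), float(res.info.obj_val), "optimal", status)
    if "infeasible" in status and "dual" not in status:
        return LPResult(None, None, "infeasible", status)
    if "dual infeasible" in status:
        return LPResult(None, None, "unbounded", status)
    return LPResult(None, None, "error", status)
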