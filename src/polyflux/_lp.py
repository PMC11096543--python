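"""Thin wrapper around scipy's HiGHS LP interface with package-level errors."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleError, SolverError


def solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    """Solve min c·x; raise InfeasibleError / SolverError instead of returning failure."""
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("LP infeasible")
    if res.status == 3:
        raise SolverError("LP unbounded")
    if not res.success:
        raise SolverError(f"LP solver failure: {res.message}")
    return res


def lp_feasible(A_eq, b_eq, bounds) -> bool:
    c = np.zeros(A_eq.shape[1] if A_eq is not None else len(bounds))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return bool(res.success)
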