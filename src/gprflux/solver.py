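"""Thin LP/QP layer over scipy (HiGHS for LP, trust-constr for convex QP).

All simulation methods in the package reduce to problems of the form

    min c.x  (or min ||P.x - r||^2)
    s.t. A_eq.x = b_eq,  A_ub.x <= b_ub,  lb <= x <= ub

This module keeps the solver dependency in one place.  The QP path is a
declared capability: callers may check :func:`qp_capable` and quadratic
methods raise :class:`SolverCapabilityError` when it is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

__all__ = ["LPResult", "SolverCapabilityError", "solve_lp", "solve_qp", "qp_capable"]

FEAS_TOL = 1e-9


class SolverCapabilityError(RuntimeError):
    """A required solver capability (e.g. quadratic objectives) is missing."""


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded | error
    x: np.ndarray | None
    fun: float | None
    #: dual values of equality constraints (shadow prices), if available
    duals_eq: np.ndarray | None = None
    #: reduced costs of variables, if available
    reduced_costs: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _status_from_scipy(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")


def solve_lp(c, A_eq=None, b_eq=None, bounds=None, A_ub=None, b_ub=None) -> LPResult:
    """Minimize ``c.x`` with HiGHS.  ``bounds`` is a list of (lb, ub) pairs
    (``None``/inf for unbounded)."""
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=bounds, method="highs",
    )
    status = _status_from_scipy(res)
    duals = None
    rc = None
    if status == "optimal":
        if getattr(res, "eqlin", None) is not None:
            duals = np.asarray(res.eqlin.marginals)
        if getattr(res, "lower", None) is not None:
            rc = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)
    return LPResult(status=status,
                    x=np.asarray(res.x) if res.x is not None else None,
                    fun=float(res.fun) if status == "optimal" else None,
                    duals_eq=duals, reduced_costs=rc)


def qp_capable() -> bool:
    return True


def solve_qp(P, r, A_eq=None, b_eq=None, bounds=None, A_ub=None, b_ub=None,
             x0=None) -> LPResult:
    """Minimize ``||P.x - r||^2`` subject to linear constraints.

    Solved with scipy's trust-constr; intended for desk-scale problems
    (hundreds of variables).  ``x0`` should be feasible; when omitted a
    feasibility LP provides one.
    """
    if not qp_capable():  # pragma: no cover - capability declared statically
        raise SolverCapabilityError("no quadratic-programming backend available")
    P = sp.csr_matrix(P)
    n = P.shape[1]
    r = np.asarray(r, dtype=float)

    if x0 is None:
        feas = solve_lp(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                        A_ub=A_ub, b_ub=b_ub)
        if not feas.optimal:
            return LPResult(status=feas.status, x=None, fun=None)
        x0 = feas.x

    PtP = (P.T @ P).tocsr()
    Ptr = P.T @ r

    def fun(x):
        d = P @ x - r
        return float(d @ d)

    def jac(x):
        return 2.0 * (PtP @ x - Ptr)

    def hess(x):
        return 2.0 * PtP

    constraints = []
    if A_eq is not None and getattr(A_eq, "shape", (0,))[0]:
        b_eq_arr = np.asarray(b_eq, dtype=float)
        constraints.append(scipy.optimize.LinearConstraint(
            sp.csr_matrix(A_eq), b_eq_arr, b_eq_arr))
    if A_ub is not None and getattr(A_ub, "shape", (0,))[0]:
        b_ub_arr = np.asarray(b_ub, dtype=float)
        constraints.append(scipy.optimize.LinearConstraint(
            sp.csr_matrix(A_ub), -np.inf, b_ub_arr))
    if bounds is not None:
        lb = np.array([(-np.inf if b[0] is None else b[0]) for b in bounds])
        ub = np.array([(np.inf if b[1] is None else b[1]) for b in bounds])
        bnds = scipy.optimize.Bounds(lb, ub)
    else:
        bnds = None

    res = scipy.optimize.minimize(
        fun, x0, jac=jac, hess=hess, method="trust-constr",
        constraints=constraints, bounds=bnds,
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
    )
    if not res.success and res.status not in (1, 2):  # 1/2: gtol/xtol satisfied
        return LPResult(status="error", x=None, fun=None)
    x = np.asarray(res.x)
    if bnds is not None:  # clip solver noise at the box
        x = np.clip(x, bnds.lb, bnds.ub)
    return LPResult(status="optimal", x=x, fun=fun(x))
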