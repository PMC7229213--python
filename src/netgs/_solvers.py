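"""Linear and quadratic program solvers used by the flux-estimation core.

LPs (flux maximization, pFBA, FVA) go through :func:`scipy.optimize.linprog`
with the HiGHS backend, which is deterministic for a fixed input.

The QPs of this package all have the form

    min 1/2 x' H x + c' x   s.t.  A_eq x = b_eq,  G x <= h,  lb <= x <= ub

with a diagonal positive semidefinite ``H`` (reciprocal-squared weights on
the reactions that carry an objective term).  No general-purpose QP library
is required: :func:`solve_qp` implements a dense primal active-set method
(Nocedal & Wright, ch. 16) with exact KKT solves, started from a HiGHS
phase-1 point.  Reactions without an objective weight receive a tiny ridge
(``free_reg``) so the KKT systems are nonsingular; this acts as a
minimal-norm tie-break among otherwise equivalent optima.  A slow
``trust-constr`` fallback guards against active-set cycling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import InfeasibleError, SolverError, UnboundedError

FEAS_TOL = 1e-7


@dataclass
class LinearSystem:
    """A bundle of linear constraints over n variables."""

    n: int
    A_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    lb: np.ndarray = field(default=None)
    ub: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.lb is None:
            self.lb = np.full(self.n, -np.inf)
        if self.ub is None:
            self.ub = np.full(self.n, np.inf)
        self.lb = np.asarray(self.lb, float)
        self.ub = np.asarray(self.ub, float)

    def with_rows(
        self,
        A_eq_extra: np.ndarray | None = None,
        b_eq_extra: np.ndarray | None = None,
        A_ub_extra: np.ndarray | None = None,
        b_ub_extra: np.ndarray | None = None,
    ) -> "LinearSystem":
        """Return a new system with extra constraint rows appended."""

        def cat(base, extra):
            if extra is None or len(np.atleast_1d(extra)) == 0:
                return base
            extra = np.atleast_1d(np.asarray(extra, float))
            return extra if base is None else np.concatenate([base, extra])

        A_eq = self.A_eq
        b_eq = self.b_eq
        if A_eq_extra is not None and len(A_eq_extra):
            A_eq_extra = np.atleast_2d(np.asarray(A_eq_extra, float))
            A_eq = A_eq_extra if A_eq is None else np.vstack([A_eq, A_eq_extra])
            b_eq = cat(b_eq, b_eq_extra)
        A_ub = self.A_ub
        b_ub = self.b_ub
        if A_ub_extra is not None and len(A_ub_extra):
            A_ub_extra = np.atleast_2d(np.asarray(A_ub_extra, float))
            A_ub = A_ub_extra if A_ub is None else np.vstack([A_ub, A_ub_extra])
            b_ub = cat(b_ub, b_ub_extra)
        return LinearSystem(self.n, A_eq, b_eq, A_ub, b_ub, self.lb.copy(), self.ub.copy())

    def residual(self, x: np.ndarray) -> float:
        """Worst constraint violation at x (0 when feasible)."""
        r = 0.0
        if self.A_eq is not None:
            r = max(r, float(np.max(np.abs(self.A_eq @ x - self.b_eq))))
        if self.A_ub is not None:
            r = max(r, float(np.max(self.A_ub @ x - self.b_ub, initial=0.0)))
        r = max(r, float(np.max(self.lb - x, initial=0.0)))
        r = max(r, float(np.max(x - self.ub, initial=0.0)))
        return r


def solve_lp(
    c: np.ndarray, system: LinearSystem, sense: str = "min", context: str = ""
) -> tuple[np.ndarray, float]:
    """Solve min/max c'x over a LinearSystem.  Returns (x, objective)."""
    sign = 1.0 if sense == "min" else -1.0
    res = optimize.linprog(
        sign * np.asarray(c, float),
        A_ub=system.A_ub,
        b_ub=system.b_ub,
        A_eq=system.A_eq,
        b_eq=system.b_eq,
        bounds=list(zip(system.lb, system.ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible{': ' + context if context else ''}")
    if res.status == 3:
        raise UnboundedError(
            f"LP unbounded{': ' + context if context else ''}; "
            "check for missing exchange-flux bounds"
        )
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}", status=res.status)
    return res.x, float(sign * res.fun)


def _feasible_point(system: LinearSystem, context: str = "") -> np.ndarray:
    x, _ = solve_lp(np.zeros(system.n), system, context=context)
    return x


def _kkt_solve(H, g, A):
    """Solve the equality-constrained step: min 1/2 p'Hp + g'p s.t. A p = 0."""
    n = H.shape[0]
    k = A.shape[0]
    M = np.zeros((n + k, n + k))
    M[:n, :n] = H
    if k:
        M[:n, n:] = A.T
        M[n:, :n] = A
    rhs = np.concatenate([-g, np.zeros(k)])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    if not np.all(np.isfinite(sol)):
        return None, None
    return sol[:n], sol[n:]


def _active_set_qp(H, c, G, h, m_eq, x, tol=1e-10, max_iter=None):
    """Primal active set.  First ``m_eq`` rows of G are equalities (always active)."""
    n = len(c)
    n_rows = G.shape[0]
    if max_iter is None:
        max_iter = 50 * (n + n_rows)
    working = [int(j) for j in np.where(G @ x >= h - 1e-8)[0] if j >= m_eq]
    for _ in range(max_iter):
        act = list(range(m_eq)) + working
        A = G[act] if act else np.zeros((0, n))
        g = H @ x + c
        p, lam = _kkt_solve(H, g, A)
        if p is None:
            return x, "singular"
        if np.max(np.abs(p), initial=0.0) < tol * max(1.0, np.max(np.abs(x))):
            mult = lam[m_eq:]
            if len(mult) == 0 or np.min(mult) >= -1e-8:
                return x, "optimal"
            working.pop(int(np.argmin(mult)))
            continue
        # largest step along p staying feasible for inactive rows
        alpha, block = 1.0, -1
        Gp = G @ p
        slack = h - G @ x
        for j in range(m_eq, n_rows):
            if j in working or Gp[j] <= tol:
                continue
            a = slack[j] / Gp[j]
            if a < alpha:
                alpha, block = a, j
        x = x + max(alpha, 0.0) * p
        if block >= 0:
            working.append(block)
    return x, "maxiter"


def _fallback_qp(H, c, system: LinearSystem, x0: np.ndarray) -> np.ndarray:
    constraints = []
    if system.A_eq is not None:
        constraints.append(optimize.LinearConstraint(system.A_eq, system.b_eq, system.b_eq))
    if system.A_ub is not None:
        constraints.append(optimize.LinearConstraint(system.A_ub, -np.inf, system.b_ub))
    res = optimize.minimize(
        lambda z: 0.5 * z @ H @ z + c @ z,
        x0,
        jac=lambda z: H @ z + c,
        hess=lambda z: H,
        method="trust-constr",
        bounds=optimize.Bounds(system.lb, system.ub),
        constraints=constraints,
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=2000),
    )
    if res.status not in (1, 2):
        raise SolverError(f"QP fallback failed: {res.message}", status=res.status)
    return res.x


def solve_qp(
    H_diag: np.ndarray,
    c: np.ndarray,
    system: LinearSystem,
    x0: np.ndarray | None = None,
    free_reg: float = 1e-10,
    context: str = "",
) -> tuple[np.ndarray, float]:
    """Minimize 1/2 x' diag(H_diag) x + c'x over a LinearSystem.

    Returns ``(x, objective)`` where the objective includes the constant-free
    quadratic only (callers add their own constants).  ``free_reg`` is added
    to zero entries of ``H_diag`` as a minimal-norm tie-break.
    """
    H_diag = np.asarray(H_diag, float)
    n = system.n
    H = np.diag(np.where(H_diag > 0, H_diag, free_reg))
    c = np.asarray(c, float)
    if x0 is None or system.residual(x0) > FEAS_TOL:
        x0 = _feasible_point(system, context=context)
    # assemble rows: equalities first, then inequalities and finite bounds
    rows, rhs = [], []
    m_eq = 0
    if system.A_eq is not None:
        rows.append(system.A_eq)
        rhs.append(system.b_eq)
        m_eq = system.A_eq.shape[0]
    if system.A_ub is not None:
        rows.append(system.A_ub)
        rhs.append(system.b_ub)
    fin_ub = np.where(np.isfinite(system.ub))[0]
    fin_lb = np.where(np.isfinite(system.lb))[0]
    eye = np.eye(n)
    if len(fin_ub):
        rows.append(eye[fin_ub])
        rhs.append(system.ub[fin_ub])
    if len(fin_lb):
        rows.append(-eye[fin_lb])
        rhs.append(-system.lb[fin_lb])
    G = np.vstack(rows) if rows else np.zeros((0, n))
    h = np.concatenate(rhs) if rhs else np.zeros(0)
    x, status = _active_set_qp(H, c, G, h, m_eq, x0.copy())
    if status != "optimal" or system.residual(x) > FEAS_TOL:
        x = _fallback_qp(H, c, system, x0)
    obj = float(0.5 * x @ H @ x + c @ x)
    return x, obj
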