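"""Small dense convex solvers used by the classifier module.

Two problem shapes cover every classifier here:

* box-constrained QP  ``min 1/2 a'Qa + p'a  s.t. 0 <= a <= ub``
  (the twin-bounded SVM dual subproblems), solved with L-BFGS-B;

* the reduced second-order-cone program
  ``min 1/2 v'Pv + C xi  s.t. v'delta - k1 ||v||_M1 - k2 ||v||_M2 >= 2(1 - xi),
  xi >= 0`` obtained from the two-cone robust-SVM program after analytic
  elimination of the offset b (the offset enters no objective term; the two
  cone constraints bound it from below and above, and a feasible b exists iff
  the summed constraint above holds).  Solved with SLSQP on a smoothed
  ``||v||_M = sqrt(v'Mv + eps)`` with eps far below solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["SolverResult", "solve_box_qp", "solve_two_cone_qp", "psd_regularize"]


@dataclass
class SolverResult:
    x: np.ndarray
    objective: float
    status: str
    success: bool
    extra: dict | None = None


def psd_regularize(S: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Symmetrize, clip negative eigenvalues, add a trace-scaled ridge."""
    S = np.asarray(S, dtype=float)
    S = (S + S.T) / 2
    lam, V = np.linalg.eigh(S)
    if lam[0] < 0:
        S = (V * np.clip(lam, 0.0, None)) @ V.T
        S = (S + S.T) / 2
    d = S.shape[0]
    scale = np.trace(S) / d
    if scale <= 0:
        scale = 1.0
    return S + ridge * scale * np.eye(d)


def solve_box_qp(Q: np.ndarray, p: np.ndarray, ub: float,
                 tol: float = 1e-12, maxiter: int = 2000) -> SolverResult:
    """min 1/2 a'Qa + p'a subject to 0 <= a <= ub (Q PSD)."""
    Q = (Q + Q.T) / 2
    m = Q.shape[0]

    def fun(a):
        Qa = Q @ a
        return 0.5 * a @ Qa + p @ a, Qa + p

    x0 = np.full(m, min(ub, 1.0) / 2)
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            bounds=[(0.0, ub)] * m,
                            options={"ftol": tol, "gtol": 1e-12,
                                     "maxiter": maxiter, "maxfun": 10 * maxiter})
    a = np.clip(res.x, 0.0, ub)
    obj = 0.5 * a @ Q @ a + p @ a
    return SolverResult(x=a, objective=float(obj),
                        status=str(res.message), success=bool(res.success))


def solve_two_cone_qp(P: np.ndarray, delta: np.ndarray,
                      kappa1: float, M1: np.ndarray,
                      kappa2: float, M2: np.ndarray,
                      C: float, tol: float = 1e-12,
                      maxiter: int = 1000) -> SolverResult:
    """Reduced two-cone robust-SVM program over (v, xi).

    Returns v, the shared slack xi, and the cone norms ||v||_{M1}, ||v||_{M2}
    needed to reconstruct the offset interval.
    """
    P = (P + P.T) / 2
    d = P.shape[0]
    eps = 1e-12 * (np.trace(M1) / d + np.trace(M2) / d + 1.0)

    def norms(v):
        n1 = np.sqrt(v @ M1 @ v + eps)
        n2 = np.sqrt(v @ M2 @ v + eps)
        return n1, n2

    def objective(z):
        v, xi = z[:-1], z[-1]
        return 0.5 * v @ P @ v + C * xi

    def objective_grad(z):
        v = z[:-1]
        return np.concatenate([P @ v, [C]])

    def constraint(z):
        v, xi = z[:-1], z[-1]
        n1, n2 = norms(v)
        return v @ delta - kappa1 * n1 - kappa2 * n2 + 2 * xi - 2.0

    def constraint_grad(z):
        v = z[:-1]
        n1, n2 = norms(v)
        g = delta - kappa1 * (M1 @ v) / n1 - kappa2 * (M2 @ v) / n2
        return np.concatenate([g, [2.0]])

    z0 = np.zeros(d + 1)
    z0[-1] = 1.0                       # (v=0, xi=1) sits on the constraint
    cons = [{"type": "ineq", "fun": constraint, "jac": constraint_grad},
            {"type": "ineq", "fun": lambda z: z[-1],
             "jac": lambda z: np.eye(d + 1)[-1]}]
    res = optimize.minimize(objective, z0, jac=objective_grad, method="SLSQP",
                            constraints=cons,
                            options={"ftol": tol, "maxiter": maxiter})
    z = res.x
    v, xi = z[:-1], max(float(z[-1]), 0.0)
    n1, n2 = norms(v)
    slack = constraint(z)
    success = bool(res.success) and slack >= -1e-6
    status = str(res.message) if res.success else f"SLSQP: {res.message}"
    if slack < -1e-6:
        status += f" (cone constraint violated by {-slack:.2e})"
    return SolverResult(x=v, objective=float(objective(z)), status=status,
                        success=success,
                        extra={"xi": xi, "norm1": float(n1), "norm2": float(n2),
                               "constraint_slack": float(slack)})
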