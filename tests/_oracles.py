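"""Independent reference solvers used only by the test suite.

Each oracle attacks the same mathematical problem as the package through a
different formulation and a different optimizer, so an agreement in optimal
objective value is a genuine cross-check rather than a tautology:

* soft-margin dual: equality+box constrained QP solved directly by SLSQP
  (the package uses libsvm's SMO);
* twin-bounded subproblem: the *primal* (w, b, xi) program solved by SLSQP
  (the package solves the box-QP dual with L-BFGS-B);
* xi-SOCP: the full (w, b, xi) cone program solved by trust-constr
  (the package eliminates b and xi analytically and runs SLSQP on the
  reduced problem).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist


def kernel_gram(X, Z, kernel, sigma=1.0):
    if kernel == "linear":
        return np.asarray(X) @ np.asarray(Z).T
    return np.exp(-cdist(X, Z, "sqeuclidean") / (2 * sigma ** 2))


def svm_dual_oracle(X, y, C, kernel="linear", sigma=1.0):
    """Optimal value of min 1/2 a'(yy' o K)a - e'a, 0<=a<=C, y'a=0."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m = len(y)
    Q = np.outer(y, y) * kernel_gram(X, X, kernel, sigma)
    Q = (Q + Q.T) / 2

    def fun(a):
        Qa = Q @ a
        return 0.5 * a @ Qa - a.sum(), Qa - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = optimize.minimize(fun, np.full(m, C / 2), jac=True, method="SLSQP",
                            bounds=[(0.0, C)] * m, constraints=cons,
                            options={"ftol": 1e-14, "maxiter": 2000})
    a = res.x
    return float(0.5 * a @ Q @ a - a.sum()), a


def twin_primal_oracle(own, other, c_reg, c_slack, kernel=None, sigma=1.0,
                       X_sorted=None, first=True):
    """Optimal value of one twin-bounded primal subproblem.

    ``own`` is the class the plane passes close to; ``other`` supplies the
    unit-margin constraints.  With a kernel, the design matrices are the
    kernel expansions against the class-sorted training matrix.
    """
    if kernel is not None:
        own = kernel_gram(own, X_sorted, kernel, sigma)
        other = kernel_gram(other, X_sorted, kernel, sigma)
    own = np.asarray(own, float)
    other = np.asarray(other, float)
    mo, d = own.shape
    mb = other.shape[0]
    sign = -1.0 if first else 1.0     # constraint sign: -(Bw+eb)>=e-xi or +(Aw+eb)>=e-xi

    def split(z):
        return z[:d], z[d], z[d + 1:]

    def fun(z):
        w, b, xi = split(z)
        r = own @ w + b
        return 0.5 * r @ r + 0.5 * c_reg * (w @ w + b * b) + c_slack * xi.sum()

    def con(z):
        w, b, xi = split(z)
        return sign * (other @ w + b) - 1.0 + xi

    z0 = np.zeros(d + 1 + mb)
    z0[d + 1:] = 2.0
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * mb
    res = optimize.minimize(fun, z0, method="SLSQP", bounds=bounds,
                            constraints=[{"type": "ineq", "fun": con}],
                            options={"ftol": 1e-14, "maxiter": 3000})
    w, b, xi = split(res.x)
    return float(fun(res.x)), w, float(b)


def _moments(X, y, ridge=1e-8):
    A, B = X[y == 1], X[y == -1]
    out = []
    for M in (A, B):
        mu = M.mean(axis=0)
        S = np.cov(M, rowvar=False, bias=True)
        S = np.atleast_2d(S)
        S = S + ridge * (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
        out.append((mu, S))
    return out


def socp_full_oracle(X, y, C, eta1, eta2, kernel=None, sigma=1.0, ridge=1e-8):
    """Optimal value of the full (w, b, xi) two-cone program via trust-constr."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    k1 = np.sqrt(eta1 / (1 - eta1))
    k2 = np.sqrt(eta2 / (1 - eta2))
    if kernel is None:
        (mu1, S1), (mu2, S2) = _moments(X, y, ridge)
        d = X.shape[1]
        P = np.eye(d)
    else:
        A, B = X[y == 1], X[y == -1]
        Xs = np.vstack([A, B])
        K = kernel_gram(Xs, Xs, kernel, sigma)
        K = (K + K.T) / 2
        m = len(Xs)
        P = K + ridge * (np.trace(K) / m) * np.eye(m)
        mus, Ss = [], []
        for cols in (np.arange(len(A)), np.arange(len(A), m)):
            Mk = K[:, cols]
            mk = len(cols)
            mus.append(Mk.mean(axis=1))
            Cc = np.eye(mk) - np.ones((mk, mk)) / mk
            Xi = Mk @ Cc @ Mk.T / mk
            Xi = (Xi + Xi.T) / 2
            Ss.append(Xi + ridge * (np.trace(Xi) / m) * np.eye(m))
        (mu1, S1), (mu2, S2) = (mus[0], Ss[0]), (mus[1], Ss[1])
        d = m
    eps = 1e-14

    def fun(z):
        v, xi = z[:d], z[-2]          # layout: v..., xi, b
        return 0.5 * v @ P @ v + C * xi

    def c1(z):
        v, xi, b = z[:d], z[-2], z[-1]
        return v @ mu1 + b - 1 + xi - k1 * np.sqrt(v @ S1 @ v + eps)

    def c2(z):
        v, xi, b = z[:d], z[-2], z[-1]
        return -(v @ mu2 + b) - 1 + xi - k2 * np.sqrt(v @ S2 @ v + eps)

    z0 = np.zeros(d + 2)
    z0[-2] = 2.0
    res = optimize.minimize(
        fun, z0, method="trust-constr",
        constraints=[optimize.NonlinearConstraint(c1, 0, np.inf),
                     optimize.NonlinearConstraint(c2, 0, np.inf)],
        bounds=optimize.Bounds(
            np.concatenate([np.full(d, -np.inf), [0.0, -np.inf]]),
            np.full(d + 2, np.inf)),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000})
    return float(fun(res.x)), res.x


def mc_null_plv(n_epochs, n_draws=20000, seed=0):
    """Monte-Carlo E|mean of n_epochs unit phasors with iid uniform phases|."""
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * np.pi, size=(n_draws, n_epochs))
    return float(np.abs(np.exp(1j * ph).mean(axis=1)).mean())
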