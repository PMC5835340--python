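"""Three SVM families for brain-network edge classification.

* soft-margin SVM (hinge loss, parameter C), linear and Gaussian-kernel;
* twin-bounded SVM: two nonparallel hyperplanes, each fit close to one class
  and pushed away from the other, with explicit (c3, c4) regularization that
  keeps both subproblems strongly convex;
* the xi-SOCP SVM: a robust maximum-margin classifier whose per-class
  chance constraints (misclassification rate <= eta_k under the worst
  distribution with the class mean and covariance) become second-order cone
  constraints with coefficient kappa_k = sqrt(eta_k / (1 - eta_k)), sharing a
  single scalar slack xi.  Both a linear and a kernelized version are
  provided; the kernel version replaces means/covariances by their
  kernel-space analogues g_k and Xi_k built from the kernel blocks of the
  class-sorted training matrix.

All estimators follow the fit/predict/decision_function convention.  A
decision value of exactly 0 predicts +1; a twin-model equidistant point
predicts +1.  Every fit records the solver status on the model object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from ._solvers import SolverResult, psd_regularize, solve_box_qp, solve_two_cone_qp

__all__ = [
    "gaussian_kernel", "kernel_matrix", "ClassMoments", "class_moments",
    "SoftMarginSVM", "TwinBoundedSVM", "XiSOCPSVM",
    "train_soft_margin", "train_twin_bounded", "train_xi_socp",
    "predict", "predict_twin", "save_model", "load_model",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# kernels

def gaussian_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """exp(-||x - z||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError("x and z must have equal dimension")
    return float(np.exp(-np.sum((x - z) ** 2) / (2 * sigma ** 2)))


def kernel_matrix(X: np.ndarray, Z: np.ndarray, kernel: str,
                  sigma: float = 1.0) -> np.ndarray:
    """Gram matrix K[i, s] = K(X[i], Z[s]) for 'linear' or 'gaussian'."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if kernel == "linear":
        return X @ Z.T
    if kernel == "gaussian":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return np.exp(-cdist(X, Z, "sqeuclidean") / (2 * sigma ** 2))
    raise ValueError(f"unknown kernel {kernel!r}")


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not np.all(np.abs(y) == 1):
        raise ValueError("labels must be +/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _sign_predict(values: np.ndarray) -> np.ndarray:
    """Decision value 0 maps to +1 by convention."""
    return np.where(values >= 0, 1, -1)


# ---------------------------------------------------------------------------
# soft-margin SVM (standard formulation; solved by libsvm via scikit-learn)

class SoftMarginSVM:
    """Hinge-loss maximum-margin classifier, linear or Gaussian kernel.

    The dual variables are exposed as ``alpha_`` (full-length, one per
    training point, satisfying 0 <= alpha_i <= C and sum alpha_i y_i = 0),
    which the RFE margin criterion consumes.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear",
                 sigma: float = 1.0, tol: float = 1e-8):
        if C <= 0:
            raise ValueError("C must be positive")
        if kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {kernel!r}")
        if kernel == "gaussian" and sigma <= 0:
            raise ValueError("sigma must be positive")
        self.C = C
        self.kernel = kernel
        self.sigma = sigma
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftMarginSVM":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        if self.kernel == "linear":
            svc = SVC(C=self.C, kernel="linear", tol=self.tol)
        else:
            svc = SVC(C=self.C, kernel="rbf",
                      gamma=1.0 / (2 * self.sigma ** 2), tol=self.tol)
        svc.fit(X, y)
        self._svc = svc
        self.X_train_ = X
        self.y_train_ = y
        m = len(y)
        alpha = np.zeros(m)
        # dual_coef_ holds alpha_i * y_i on the support vectors
        alpha[svc.support_] = np.abs(svc.dual_coef_.ravel())
        self.alpha_ = alpha
        self.b_ = float(svc.intercept_[0])
        self.w_ = svc.coef_.ravel().copy() if self.kernel == "linear" else None
        self.support_ = svc.support_.copy()
        self.solver_status_ = "libsvm converged" if svc.fit_status_ == 0 \
            else f"libsvm status {svc.fit_status_}"
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return self._svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sign_predict(self.decision_function(X))

    # objectives, for diagnostics and oracle cross-checks
    def dual_objective(self) -> float:
        """Value of the dual minimization 1/2 a'(yy' o K)a - e'a at alpha_."""
        K = kernel_matrix(self.X_train_, self.X_train_, self.kernel, self.sigma)
        ay = self.alpha_ * self.y_train_
        return float(0.5 * ay @ K @ ay - self.alpha_.sum())

    def primal_objective(self) -> float:
        """1/2 ||w||^2 + C sum xi_i (linear kernel only)."""
        if self.w_ is None:
            raise ValueError("primal objective defined for the linear kernel")
        margins = self.y_train_ * (self.X_train_ @ self.w_ + self.b_)
        return float(0.5 * self.w_ @ self.w_
                     + self.C * np.clip(1 - margins, 0, None).sum())


# ---------------------------------------------------------------------------
# twin-bounded SVM

class TwinBoundedSVM:
    """Two nonparallel hyperplanes; prediction by normalized proximity.

    Each subproblem is solved through its dual, a box-constrained QP whose
    Hessian involves the (H'H + c I)^-1 regularized inverse; c3, c4 > 0
    guarantee invertibility.  With the kernel variant, the design matrices
    become K(A, X) and K(B, X) over the class-sorted training matrix X.
    """

    def __init__(self, c1: float = 1.0, c2: float = 1.0, c3: float = 1.0,
                 c4: float = 1.0, kernel: str = "linear", sigma: float = 1.0):
        for name, c in (("c1", c1), ("c2", c2), ("c3", c3), ("c4", c4)):
            if c <= 0:
                raise ValueError(f"{name} must be positive")
        if kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.c1, self.c2, self.c3, self.c4 = c1, c2, c3, c4
        self.kernel = kernel
        self.sigma = sigma

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwinBoundedSVM":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        return self.fit_classes(X[y == 1], X[y == -1])

    def fit_classes(self, A: np.ndarray, B: np.ndarray) -> "TwinBoundedSVM":
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if A.size == 0 or B.size == 0:
            raise ValueError("both classes must be non-empty")
        if A.shape[1] != B.shape[1]:
            raise ValueError("A and B must share the feature dimension")
        self.n_features_in_ = A.shape[1]
        self.X_sorted_ = np.vstack([A, B])
        if self.kernel == "linear":
            Ad, Bd = A, B
        else:
            Ad = kernel_matrix(A, self.X_sorted_, self.kernel, self.sigma)
            Bd = kernel_matrix(B, self.X_sorted_, self.kernel, self.sigma)
        u1, s1 = self._solve_plane(Ad, Bd, self.c3, self.c1, first=True)
        u2, s2 = self._solve_plane(Bd, Ad, self.c4, self.c2, first=False)
        self.u1_, self.b1_ = u1[:-1], float(u1[-1])
        self.u2_, self.b2_ = u2[:-1], float(u2[-1])
        self.solver_status_ = f"plane1: {s1.status}; plane2: {s2.status}"
        self.solver_success_ = s1.success and s2.success
        self._dual_objectives_ = (s1.objective, s2.objective)
        if self.kernel == "linear":
            self.norm1_ = float(np.linalg.norm(self.u1_))
            self.norm2_ = float(np.linalg.norm(self.u2_))
        else:
            Kxx = kernel_matrix(self.X_sorted_, self.X_sorted_, self.kernel,
                                self.sigma)
            Kxx = (Kxx + Kxx.T) / 2
            self.norm1_ = float(np.sqrt(max(self.u1_ @ Kxx @ self.u1_, 0.0)))
            self.norm2_ = float(np.sqrt(max(self.u2_ @ Kxx @ self.u2_, 0.0)))
        return self

    @staticmethod
    def _solve_plane(own: np.ndarray, other: np.ndarray, c_reg: float,
                     c_slack: float, first: bool) -> tuple[np.ndarray, SolverResult]:
        """Dual of one subproblem; returns the stacked [w; b] solution."""
        H = np.hstack([own, np.ones((own.shape[0], 1))])
        G = np.hstack([other, np.ones((other.shape[0], 1))])
        HtH = H.T @ H + c_reg * np.eye(H.shape[1])
        R = np.linalg.solve(HtH, G.T)          # (d+1) x m_other
        Q = G @ R
        res = solve_box_qp(Q, -np.ones(G.shape[0]), ub=c_slack)
        sign = -1.0 if first else 1.0
        u = sign * (R @ res.x)
        return u, res

    def _plane_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        if self.kernel == "linear":
            Phi = X
        else:
            Phi = kernel_matrix(X, self.X_sorted_, self.kernel, self.sigma)
        return Phi @ self.u1_ + self.b1_, Phi @ self.u2_ + self.b2_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed proximity: positive where plane 1 is the closer one."""
        f1, f2 = self._plane_values(X)
        d1 = np.abs(f1) / max(self.norm1_, 1e-12)
        d2 = np.abs(f2) / max(self.norm2_, 1e-12)
        return d2 - d1

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sign_predict(self.decision_function(X))


# ---------------------------------------------------------------------------
# xi-SOCP SVM

@dataclass
class ClassMoments:
    """First and second moments per class, input-space or kernel-space."""

    kappa1: float
    kappa2: float
    m1: int
    m2: int
    mu1: np.ndarray          # mean (linear) or g_1 (kernel)
    mu2: np.ndarray
    Sigma1: np.ndarray       # covariance (linear) or Xi_1 (kernel), regularized
    Sigma2: np.ndarray
    kernel: str | None = None
    sigma: float = 1.0


def class_moments(X: np.ndarray, y: np.ndarray, eta1: float, eta2: float,
                  kernel: str | None = None, sigma: float = 1.0,
                  ridge: float = 1e-8) -> ClassMoments:
    """Means and covariances per class, or their kernel-space analogues.

    Kernel space: with the class-sorted training matrix, g_k is the mean of
    the class-k kernel columns and Xi_k the kernel covariance block built
    with the centering matrix (I - (1/m_k) e e'); both are PSD-regularized.
    Covariances are the biased (1/m_k) estimates, which is what makes the
    kernel and input-space formulations agree under the linear kernel.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y)
    for eta, name in ((eta1, "eta1"), (eta2, "eta2")):
        if not (0 < eta < 1):
            raise ValueError(f"{name} must lie in (0, 1)")
    A, B = X[y == 1], X[y == -1]
    m1, m2 = len(A), len(B)
    if m1 < 2 or m2 < 2:
        raise ValueError("each class needs >= 2 samples for a covariance")
    kappa1 = float(np.sqrt(eta1 / (1 - eta1)))
    kappa2 = float(np.sqrt(eta2 / (1 - eta2)))
    if kernel is None:
        mu1, mu2 = A.mean(axis=0), B.mean(axis=0)
        S1 = psd_regularize(np.cov(A, rowvar=False, bias=True), ridge)
        S2 = psd_regularize(np.cov(B, rowvar=False, bias=True), ridge)
        return ClassMoments(kappa1, kappa2, m1, m2, mu1, mu2, S1, S2)
    Xs = np.vstack([A, B])
    K = kernel_matrix(Xs, Xs, kernel, sigma)
    K = (K + K.T) / 2
    idx = {1: np.arange(m1), 2: np.arange(m1, m1 + m2)}
    out = {}
    for k, cols in idx.items():
        Mk = K[:, cols]                          # [K_1k; K_2k], m x m_k
        g = Mk.mean(axis=1)
        mk = len(cols)
        centered = Mk - Mk.mean(axis=1, keepdims=True)
        Xi = psd_regularize(centered @ centered.T / mk, ridge)
        out[k] = (g, Xi)
    return ClassMoments(kappa1, kappa2, m1, m2, out[1][0], out[2][0],
                        out[1][1], out[2][1], kernel=kernel, sigma=sigma)


class XiSOCPSVM:
    """Robust SVM with two second-order cone constraints and one shared slack.

    minimize 1/2 ||w||^2 + C xi subject to
        w'mu_1 + b  >= 1 - xi + kappa_1 sqrt(w' Sigma_1 w)
      -(w'mu_2 + b) >= 1 - xi + kappa_2 sqrt(w' Sigma_2 w)
        xi >= 0.

    The kernelized version substitutes (s, K, g_k, Xi_k) for
    (w, I, mu_k, Sigma_k) and classifies with f(x) = s'k(X, x) + b.  The
    offset b does not enter the objective; it is recovered as the midpoint of
    the interval the two cone constraints leave for it (a single point
    whenever the summed constraint is tight, which holds at any optimum with
    w != 0 by homogeneity).
    """

    def __init__(self, C: float = 1.0, eta1: float = 0.5, eta2: float = 0.5,
                 kernel: str = "linear", sigma: float = 1.0, ridge: float = 1e-8):
        if C <= 0:
            raise ValueError("C must be positive")
        if kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.C = C
        self.eta1 = eta1
        self.eta2 = eta2
        self.kernel = kernel
        self.sigma = sigma
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "XiSOCPSVM":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        self.n_features_in_ = X.shape[1]
        linear = self.kernel == "linear"
        moments = class_moments(X, y, self.eta1, self.eta2,
                                kernel=None if linear else self.kernel,
                                sigma=self.sigma, ridge=self.ridge)
        self.moments_ = moments
        if linear:
            P = np.eye(X.shape[1])
        else:
            A, B = X[y == 1], X[y == -1]
            self.X_sorted_ = np.vstack([A, B])
            K = kernel_matrix(self.X_sorted_, self.X_sorted_, self.kernel,
                              self.sigma)
            P = psd_regularize(K, self.ridge)
        delta = moments.mu1 - moments.mu2
        res = solve_two_cone_qp(P, delta, moments.kappa1, moments.Sigma1,
                                moments.kappa2, moments.Sigma2, self.C)
        if not res.success:
            raise RuntimeError(f"xi-SOCP solver failed: {res.status}")
        v = res.x
        self.xi_ = res.extra["xi"]
        b_lo = 1 - self.xi_ + moments.kappa1 * res.extra["norm1"] - v @ moments.mu1
        b_hi = -1 + self.xi_ - moments.kappa2 * res.extra["norm2"] - v @ moments.mu2
        self.b_ = float((b_lo + b_hi) / 2)
        self.objective_ = res.objective
        self.solver_status_ = res.status
        self.constraint_slack_ = res.extra["constraint_slack"]
        if linear:
            self.w_ = v
            self.s_ = None
        else:
            self.w_ = None
            self.s_ = v
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        if self.w_ is not None:
            return X @ self.w_ + self.b_
        Kx = kernel_matrix(X, self.X_sorted_, self.kernel, self.sigma)
        return Kx @ self.s_ + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sign_predict(self.decision_function(X))


# ---------------------------------------------------------------------------
# thin functional surface

def train_soft_margin(X, y, C: float, kernel: str = "linear",
                      sigma: float = 1.0) -> SoftMarginSVM:
    return SoftMarginSVM(C=C, kernel=kernel, sigma=sigma).fit(X, y)


def train_twin_bounded(A, B, c1: float, c2: float, c3: float, c4: float,
                       kernel: str = "linear", sigma: float = 1.0) -> TwinBoundedSVM:
    return TwinBoundedSVM(c1, c2, c3, c4, kernel=kernel,
                          sigma=sigma).fit_classes(A, B)


def train_xi_socp(X, y, C: float, eta1: float, eta2: float,
                  kernel: str = "linear", sigma: float = 1.0) -> XiSOCPSVM:
    return XiSOCPSVM(C=C, eta1=eta1, eta2=eta2, kernel=kernel,
                     sigma=sigma).fit(X, y)


def predict(model, X) -> np.ndarray:
    return model.predict(X)


def predict_twin(model: TwinBoundedSVM, x) -> int:
    return int(model.predict(np.atleast_2d(x))[0])


# ---------------------------------------------------------------------------
# serialization: <base>.json (metadata + params) and <base>.npz (arrays)

_ARRAY_FIELDS = ["w_", "b_", "alpha_", "support_", "X_train_", "y_train_",
                 "u1_", "b1_", "u2_", "b2_", "X_sorted_", "s_", "xi_",
                 "norm1_", "norm2_"]
_PARAM_FIELDS = {"SoftMarginSVM": ["C", "kernel", "sigma", "tol"],
                 "TwinBoundedSVM": ["c1", "c2", "c3", "c4", "kernel", "sigma"],
                 "XiSOCPSVM": ["C", "eta1", "eta2", "kernel", "sigma", "ridge"]}


def save_model(model, base: str | Path) -> None:
    """Write <base>.json + <base>.npz; kernel models embed training points."""
    base = Path(base)
    cls = type(model).__name__
    if cls not in _PARAM_FIELDS:
        raise TypeError(f"cannot serialize {cls}")
    arrays = {}
    for f in _ARRAY_FIELDS:
        v = getattr(model, f, None)
        if v is not None:
            arrays[f] = np.asarray(v)
    meta = {"schema_version": SCHEMA_VERSION, "class": cls,
            "params": {p: getattr(model, p) for p in _PARAM_FIELDS[cls]},
            "n_features_in": getattr(model, "n_features_in_", None),
            "solver_status": getattr(model, "solver_status_", None)}
    base.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{base}.json").write_text(json.dumps(meta, indent=1))
    np.savez(f"{base}.npz", **arrays)


def load_model(base: str | Path):
    base = Path(base)
    meta = json.loads(Path(f"{base}.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {meta.get('schema_version')}")
    cls = {"SoftMarginSVM": SoftMarginSVM, "TwinBoundedSVM": TwinBoundedSVM,
           "XiSOCPSVM": XiSOCPSVM}[meta["class"]]
    model = cls(**meta["params"])
    with np.load(f"{base}.npz", allow_pickle=False) as data:
        for f in _ARRAY_FIELDS:
            if f in data:
                v = data[f]
                setattr(model, f, float(v) if v.ndim == 0 else v)
    model.n_features_in_ = meta["n_features_in"]
    model.solver_status_ = meta["solver_status"]
    if isinstance(model, SoftMarginSVM) and hasattr(model, "X_train_"):
        # rebuild the libsvm backend so decision_function works after reload
        model.fit(model.X_train_, model.y_train_.astype(int))
    return model
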