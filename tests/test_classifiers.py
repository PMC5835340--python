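"""Classifier families: closed-form instances, KKT/feasibility conditions,
and objective agreement with independently-coded generic solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainedge.classifiers import (SoftMarginSVM, TwinBoundedSVM, XiSOCPSVM,
                                   class_moments, gaussian_kernel,
                                   kernel_matrix, load_model, predict_twin,
                                   save_model, train_soft_margin,
                                   train_twin_bounded, train_xi_socp)
from brainedge._solvers import solve_two_cone_qp, psd_regularize

from _oracles import socp_full_oracle, svm_dual_oracle, twin_primal_oracle


def blobs(rng, n=10, d=3, sep=3.0):
    n2 = n // 2
    X = np.vstack([rng.normal(0, 1, (n2, d)) + sep,
                   rng.normal(0, 1, (n - n2, d)) - sep])
    y = np.array([1] * n2 + [-1] * (n - n2))
    return X, y


class TestGaussianKernel:
    def test_identical_points_give_one(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], 0.5) == 1.0

    def test_distance_sqrt_two_sigma(self):
        x = np.zeros(4)
        z = np.zeros(4)
        z[0] = 2.0          # ||x-z||^2 = 4 = 2 sigma^2 for sigma = sqrt(2)
        assert gaussian_kernel(x, z, np.sqrt(2.0)) == pytest.approx(np.exp(-1))

    def test_wide_kernel_limit(self):
        assert gaussian_kernel([0.0], [5.0], 1e8) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_sigma_and_shape(self):
        with pytest.raises(ValueError):
            gaussian_kernel([0.0], [1.0], 0.0)
        with pytest.raises(ValueError):
            gaussian_kernel([0.0], [1.0, 2.0], 1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.3, 5.0))
    def test_gram_matrix_is_psd(self, seed, sigma):
        X = np.random.default_rng(seed).normal(size=(12, 4))
        K = kernel_matrix(X, X, "gaussian", sigma)
        assert np.linalg.eigvalsh((K + K.T) / 2).min() >= -1e-8


class TestSoftMargin:
    def test_two_point_closed_form(self):
        m = train_soft_margin(np.array([[-1.0], [1.0]]), [-1, 1], C=100.0)
        assert m.w_[0] == pytest.approx(1.0, abs=1e-6)
        assert m.b_ == pytest.approx(0.0, abs=1e-6)

    def test_dual_feasibility(self, rng):
        X, y = blobs(rng, n=20, sep=0.5)
        m = train_soft_margin(X, y, C=2.0)
        assert abs((m.alpha_ * m.y_train_).sum()) < 1e-6
        assert np.all(m.alpha_ >= -1e-9) and np.all(m.alpha_ <= 2.0 + 1e-9)

    def test_primal_dual_gap_linear(self, rng):
        X, y = blobs(rng, n=16, sep=1.0)
        m = train_soft_margin(X, y, C=1.0)
        assert m.primal_objective() == pytest.approx(-m.dual_objective(),
                                                     abs=1e-5)

    @pytest.mark.parametrize("kernel,sigma,C", [
        ("linear", 1.0, 1.0), ("linear", 1.0, 10.0), ("gaussian", 2.0, 1.0)])
    def test_dual_objective_matches_qp_oracle(self, kernel, sigma, C):
        rng = np.random.default_rng(17)
        X, y = blobs(rng, n=12, d=3, sep=2.0)
        m = train_soft_margin(X, y, C=C, kernel=kernel, sigma=sigma)
        oracle_obj, _ = svm_dual_oracle(X, y, C, kernel, sigma)
        assert m.dual_objective() == pytest.approx(oracle_obj, abs=1e-5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_soft_margin(rng.normal(size=(5, 2)), [1] * 5, C=1.0)

    def test_training_points_with_margin_keep_their_label(self, rng):
        X, y = blobs(rng, n=20, sep=4.0)
        m = train_soft_margin(X, y, C=10.0)
        assert np.array_equal(m.predict(X), y)


class TestTwinBounded:
    A4 = np.array([[0.0, 0.0], [0.0, 1.0]])
    B4 = np.array([[2.0, 0.0], [2.0, 1.0]])

    def test_four_point_planes(self):
        m = train_twin_bounded(self.A4, self.B4, 10.0, 10.0, 1e-3, 1e-3)
        # plane 1 ~ x=0 through A; plane 2 ~ x=2 through B
        assert abs(self.A4 @ m.u1_ + m.b1_).max() < 0.05
        assert abs(self.B4 @ m.u2_ + m.b2_).max() < 0.05
        assert np.array_equal(m.predict(self.A4), [1, 1])
        assert np.array_equal(m.predict(self.B4), [-1, -1])

    def test_dual_matches_primal_oracle(self):
        for first, (own, other, creg, cs) in enumerate(
                [(self.A4, self.B4, 1e-3, 10.0), (self.B4, self.A4, 0.5, 2.0)]):
            obj, _, _ = twin_primal_oracle(own, other, creg, cs,
                                           first=(first == 0))
            m = train_twin_bounded(self.A4, self.B4, 10.0, 2.0, 1e-3, 0.5)
            dual = m._dual_objectives_[first]
            # strong duality: primal optimum = -(dual minimum)
            assert obj == pytest.approx(-dual, abs=1e-5)

    def test_small_c12_matches_epsilon_regularized_oracle(self, rng):
        X, y = blobs(rng, n=14, d=2, sep=2.0)
        A, B = X[y == 1], X[y == -1]
        eps = 1e-4
        m = train_twin_bounded(A, B, 1.0, 1.0, eps, eps)
        obj1, _, _ = twin_primal_oracle(A, B, eps, 1.0, first=True)
        assert -m._dual_objectives_[0] == pytest.approx(obj1, abs=1e-5)

    def test_kernel_dual_matches_primal_oracle(self, rng):
        X, y = blobs(rng, n=10, d=2, sep=1.5)
        A, B = X[y == 1], X[y == -1]
        m = train_twin_bounded(A, B, 1.0, 1.0, 0.1, 0.1, kernel="gaussian",
                               sigma=2.0)
        obj, _, _ = twin_primal_oracle(A, B, 0.1, 1.0, kernel="gaussian",
                                       sigma=2.0, X_sorted=np.vstack([A, B]),
                                       first=True)
        assert -m._dual_objectives_[0] == pytest.approx(obj, abs=1e-5)

    def test_swapping_classes_flips_predictions(self, rng):
        X, y = blobs(rng, n=12, d=2, sep=2.0)
        A, B = X[y == 1], X[y == -1]
        m = train_twin_bounded(A, B, 1.0, 1.0, 0.1, 0.1)
        swapped = train_twin_bounded(B, A, 1.0, 1.0, 0.1, 0.1)
        probe = rng.normal(size=(8, 2)) * 2
        assert np.array_equal(m.predict(probe), -swapped.predict(probe))

    def test_proximity_rule_and_tiebreak(self):
        m = TwinBoundedSVM(1.0, 1.0, 1.0, 1.0)
        m.u1_, m.b1_ = np.array([1.0, 0.0]), 0.0       # plane x=0
        m.u2_, m.b2_ = np.array([1.0, 0.0]), -2.0      # plane x=2
        m.norm1_ = m.norm2_ = 1.0
        m.n_features_in_ = 2
        m.kernel = "linear"
        assert predict_twin(m, [0.0, 3.0]) == 1        # on plane 1
        assert predict_twin(m, [2.0, -1.0]) == -1      # on plane 2
        assert predict_twin(m, [1.0, 0.0]) == 1        # equidistant -> +1

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_twin_bounded(self.A4, np.empty((0, 2)), 1, 1, 1, 1)


class TestClassMoments:
    @pytest.mark.parametrize("eta,kappa", [(0.8, 2.0), (0.2, 0.5),
                                           (0.4, 0.8164965809),
                                           (0.6, 1.2247448714)])
    def test_kappa_formula(self, rng, eta, kappa):
        X, y = blobs(rng, n=8, d=3)
        cm = class_moments(X, y, eta, eta)
        assert cm.kappa1 == pytest.approx(kappa, abs=1e-6)

    def test_linear_kernel_quadratic_identity(self):
        # s' Xi_k s equals the input-space class variance of w = X's along w
        rng = np.random.default_rng(5)
        X, y = blobs(rng, n=8, d=3, sep=1.0)
        cm = class_moments(X, y, 0.5, 0.5, kernel="linear", ridge=0.0)
        A, B = X[y == 1], X[y == -1]
        Xs = np.vstack([A, B])
        s = rng.normal(size=len(Xs))
        w = Xs.T @ s
        for Xi, M, mu in ((cm.Sigma1, A, A.mean(0)), (cm.Sigma2, B, B.mean(0))):
            direct = np.mean(((M - mu) @ w) ** 2)
            assert s @ Xi @ s == pytest.approx(direct, abs=1e-8)

    def test_tiny_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            class_moments(X, np.array([1, -1, -1]), 0.5, 0.5)

    def test_invalid_eta_rejected(self, rng):
        X, y = blobs(rng, n=8)
        with pytest.raises(ValueError):
            class_moments(X, y, 0.0, 0.5)


class TestXiSOCP:
    def test_recovers_means_difference_direction(self):
        rng = np.random.default_rng(11)
        X, y = blobs(rng, n=20, d=2, sep=3.0)
        m = train_xi_socp(X, y, C=1.0, eta1=0.2, eta2=0.2)
        delta = X[y == 1].mean(0) - X[y == -1].mean(0)
        cos = m.w_ @ delta / np.linalg.norm(m.w_) / np.linalg.norm(delta)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0
        assert np.array_equal(m.predict(X), y)

    @pytest.mark.parametrize("kernel,sigma,eta", [
        (None, 1.0, 0.2), (None, 1.0, 0.6), ("gaussian", 2.0, 0.4)])
    def test_objective_matches_conic_oracle(self, kernel, sigma, eta):
        rng = np.random.default_rng(23)
        X, y = blobs(rng, n=16, d=3, sep=2.0)
        m = train_xi_socp(X, y, C=1.0, eta1=eta, eta2=eta,
                          kernel=kernel or "linear", sigma=sigma)
        oracle_obj, _ = socp_full_oracle(X, y, 1.0, eta, eta,
                                         kernel=kernel, sigma=sigma)
        assert m.objective_ == pytest.approx(oracle_obj, abs=1e-5)

    def test_cone_constraints_hold_at_solution(self, rng):
        X, y = blobs(rng, n=20, d=4, sep=1.0)
        m = train_xi_socp(X, y, C=2.0, eta1=0.6, eta2=0.4)
        cm = m.moments_
        f1 = np.sqrt(m.w_ @ cm.Sigma1 @ m.w_)
        f2 = np.sqrt(m.w_ @ cm.Sigma2 @ m.w_)
        assert m.w_ @ cm.mu1 + m.b_ - (1 - m.xi_ + cm.kappa1 * f1) >= -1e-6
        assert -(m.w_ @ cm.mu2 + m.b_) - (1 - m.xi_ + cm.kappa2 * f2) >= -1e-6
        assert m.xi_ >= -1e-9

    def test_vanishing_kappa_leaves_unit_margins_at_means(self):
        rng = np.random.default_rng(3)
        X, y = blobs(rng, n=16, d=2, sep=3.0)
        m = XiSOCPSVM(C=5.0, eta1=1e-6, eta2=1e-6).fit(X, y)
        mu1, mu2 = X[y == 1].mean(0), X[y == -1].mean(0)
        assert m.w_ @ mu1 + m.b_ >= 1 - m.xi_ - 1e-5
        assert -(m.w_ @ mu2 + m.b_) >= 1 - m.xi_ - 1e-5

    def test_kernel_path_with_linear_kernel_matches_linear_model(self):
        # the kernelized program with K = XX' reproduces the input-space
        # program's decision values
        rng = np.random.default_rng(8)
        X, y = blobs(rng, n=14, d=2, sep=2.5)
        lin = XiSOCPSVM(C=1.0, eta1=0.3, eta2=0.3).fit(X, y)
        cm = class_moments(X, y, 0.3, 0.3, kernel="linear")
        A, B = X[y == 1], X[y == -1]
        Xs = np.vstack([A, B])
        K = psd_regularize(kernel_matrix(Xs, Xs, "linear"), 1e-10)
        res = solve_two_cone_qp(K, cm.mu1 - cm.mu2, cm.kappa1, cm.Sigma1,
                                cm.kappa2, cm.Sigma2, C=1.0)
        s, xi = res.x, res.extra["xi"]
        b_lo = 1 - xi + cm.kappa1 * res.extra["norm1"] - s @ cm.mu1
        b_hi = -1 + xi - cm.kappa2 * res.extra["norm2"] - s @ cm.mu2
        b = (b_lo + b_hi) / 2
        probe = rng.normal(size=(10, 2)) * 2
        dec_kernel = kernel_matrix(probe, Xs, "linear") @ s + b
        assert np.allclose(dec_kernel, lin.decision_function(probe), atol=1e-4)

    def test_objective_nondecreasing_in_eta(self):
        rng = np.random.default_rng(31)
        X, y = blobs(rng, n=20, d=3, sep=1.5)
        objs = [XiSOCPSVM(C=1.0, eta1=e, eta2=e).fit(X, y).objective_
                for e in (0.2, 0.4, 0.6, 0.8)]
        assert all(b >= a - 1e-7 for a, b in zip(objs, objs[1:]))

    def test_label_symmetry(self):
        rng = np.random.default_rng(13)
        X, y = blobs(rng, n=16, d=2, sep=2.0)
        m = train_xi_socp(X, y, C=1.0, eta1=0.6, eta2=0.3)
        mm = train_xi_socp(X, -y, C=1.0, eta1=0.3, eta2=0.6)
        probe = rng.normal(size=(6, 2))
        assert np.allclose(m.decision_function(probe),
                           -mm.decision_function(probe), atol=1e-4)


class TestPredictContract:
    def test_zero_decision_value_maps_to_positive(self):
        from brainedge.classifiers import _sign_predict
        assert _sign_predict(np.array([0.0, -0.1, 0.1])).tolist() == [1, -1, 1]

    def test_consistent_column_permutation_invariance(self, rng):
        X, y = blobs(rng, n=20, d=4, sep=1.0)
        perm = rng.permutation(4)
        probe = rng.normal(size=(7, 4))
        for make in (lambda: SoftMarginSVM(C=1.0),
                     lambda: XiSOCPSVM(C=1.0, eta1=0.4, eta2=0.4),
                     lambda: TwinBoundedSVM(1.0, 1.0, 0.1, 0.1)):
            a = make().fit(X, y).predict(probe)
            b = make().fit(X[:, perm], y).predict(probe[:, perm])
            assert np.array_equal(a, b)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = blobs(rng, n=10, d=3)
        m = train_soft_margin(X, y, C=1.0)
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 5)))


class TestSerialization:
    @pytest.mark.parametrize("make", [
        lambda: SoftMarginSVM(C=2.0, kernel="gaussian", sigma=1.5),
        lambda: TwinBoundedSVM(1.0, 2.0, 0.5, 0.5, kernel="gaussian", sigma=2.0),
        lambda: XiSOCPSVM(C=1.0, eta1=0.4, eta2=0.6),
    ])
    def test_roundtrip_preserves_predictions(self, tmp_path, rng, make):
        X, y = blobs(rng, n=14, d=3, sep=1.5)
        m = make().fit(X, y)
        probe = rng.normal(size=(9, 3))
        save_model(m, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert np.array_equal(back.predict(probe), m.predict(probe))

    def test_schema_version_guard(self, tmp_path, rng):
        import json
        X, y = blobs(rng, n=10, d=2)
        save_model(train_soft_margin(X, y, C=1.0), tmp_path / "m")
        meta = json.loads((tmp_path / "m.json").read_text())
        meta["schema_version"] = 99
        (tmp_path / "m.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="schema"):
            load_model(tmp_path / "m")
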