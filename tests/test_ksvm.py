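import numpy as np
import pytest
from scipy.optimize import minimize

import thzopenset as tzo
from thzopenset.ksvm import (BinarySVMModel, KernelParams, SMONonConvergence,
                             cross_kernel, decision_value, decision_values,
                             dual_objective, fit_binary_svm, kernel_matrix,
                             kernel_value, solve_dual)


def qp_oracle(K, y, c_xi):
    """Reference dual solution by SLSQP on the explicit QP.

    SLSQP can stall from an unlucky start; a few feasible starting points
    are tried and the best converged solution is returned.
    """
    n = y.size
    Q = (y[:, None] * y[None, :]) * K
    best = None
    for scale in (0.0, 0.01, 0.1):
        x0 = np.full(n, scale * c_xi)
        x0 -= (y @ x0 / n) * y  # project onto y'a = 0
        x0 = np.clip(x0, 0.0, c_xi)
        res = minimize(lambda a: 0.5 * a @ Q @ a - a.sum(), x0,
                       jac=lambda a: Q @ a - 1.0, method="SLSQP",
                       bounds=[(0.0, c_xi)] * n,
                       constraints=[{"type": "eq", "fun": lambda a: y @ a,
                                     "jac": lambda a: y}],
                       options={"maxiter": 500, "ftol": 1e-14})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None, "QP oracle failed to converge from any start"
    return best.x, best.fun


class TestKernelValues:
    def test_grbf_unit_at_zero_distance(self):
        k = KernelParams(family="grbf", sigma2=3.7)
        z = np.array([0.3, -1.2, 5.0])
        assert kernel_value(k, z, z) == pytest.approx(1.0)

    def test_linear_special_case(self):
        """Polynomial with d=1, beta0=0 is the plain inner product."""
        k = KernelParams(family="polynomial", degree=1, beta0=0.0)
        zr, zs = np.array([1.0, 2.0]), np.array([-0.5, 4.0])
        assert kernel_value(k, zr, zs) == pytest.approx(zr @ zs)

    def test_grbf_closed_form(self):
        k = KernelParams(family="grbf", sigma2=1.0)
        assert kernel_value(k, np.zeros(2), np.ones(2)) == pytest.approx(
            np.exp(-1.0), abs=1e-9)

    def test_perceptron_form(self):
        k = KernelParams(family="perceptron", beta0=0.5, beta1=0.25)
        zr, zs = np.array([1.0, 1.0]), np.array([2.0, 0.0])
        assert kernel_value(k, zr, zs) == pytest.approx(np.tanh(0.5 * 2 + 0.25))

    def test_polynomial_matches_explicit_degree2_embedding(self):
        """Kernel trick: (z'z + b0)^2 in 2-D equals the inner product of
        the explicit 6-component embedding
        [z1^2, z2^2, sqrt2 z1 z2, sqrt(2 b0) z1, sqrt(2 b0) z2, b0]."""
        b0 = 1.7
        k = KernelParams(family="polynomial", degree=2, beta0=b0)

        def phi(z):
            return np.array([z[0] ** 2, z[1] ** 2, np.sqrt(2) * z[0] * z[1],
                             np.sqrt(2 * b0) * z[0], np.sqrt(2 * b0) * z[1], b0])

        rng = np.random.default_rng(0)
        for _ in range(10):
            zr, zs = rng.standard_normal(2), rng.standard_normal(2)
            assert kernel_value(k, zr, zs) == pytest.approx(phi(zr) @ phi(zs),
                                                            rel=1e-10)

    def test_non_finite_input_rejected(self):
        k = KernelParams()
        with pytest.raises(ValueError):
            kernel_value(k, np.array([np.nan]), np.array([1.0]))


class TestKernelMatrix:
    def test_grbf_symmetric_unit_diagonal(self):
        Z = np.random.default_rng(1).standard_normal((6, 3))
        K = kernel_matrix(KernelParams(family="grbf", sigma2=2.0), Z)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)

    @pytest.mark.parametrize("family", ["grbf", "polynomial"])
    def test_positive_semidefinite(self, family):
        Z = np.random.default_rng(2).standard_normal((5, 4))
        K = kernel_matrix(KernelParams(family=family, sigma2=1.3, degree=3,
                                       beta0=0.5), Z)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)

    def test_single_point(self):
        K = kernel_matrix(KernelParams(family="grbf"), np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(K, [[1.0]])


class TestSolveDual:
    def test_two_point_closed_form(self):
        """z = +1 (y=+1), z = -1 (y=-1), linear kernel, C=10: the dual has
        the closed-form solution lam = (1/2, 1/2), b = 0 (margin width 2),
        confirmed against the QP oracle."""
        Z = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        K = Z @ Z.T
        lam, b = solve_dual(K, y, c_xi=10.0, tol=1e-10)
        np.testing.assert_allclose(lam, [0.5, 0.5], atol=1e-8)
        assert b == pytest.approx(0.0, abs=1e-8)
        lam_ref, obj_ref = qp_oracle(K, y, 10.0)
        assert dual_objective(K, y, lam) == pytest.approx(obj_ref, abs=1e-8)
        model = BinarySVMModel(support_vectors=Z, dual_coeffs=lam * y, bias=b,
                               kernel=KernelParams(family="polynomial",
                                                   degree=1, beta0=0.0))
        assert decision_value(model, np.array([0.0])) == pytest.approx(0.0, abs=1e-8)
        assert decision_value(model, np.array([1.0])) == pytest.approx(1.0, abs=1e-7)

    def test_matches_qp_oracle_on_random_instances(self):
        """SMO dual objective agrees with a generic box-constrained QP
        solver to 1e-6 on 100 seeded random instances (<= 20 points)."""
        rng = np.random.default_rng(2024)
        done = 0
        while done < 100:
            n = int(rng.integers(6, 21))
            Z = rng.standard_normal((n, int(rng.integers(2, 6))))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if np.all(y > 0) or np.all(y < 0):
                continue
            c_xi = float(rng.choice([0.5, 1.0, 10.0]))
            K = kernel_matrix(KernelParams(family="grbf",
                                           sigma2=float(rng.uniform(0.3, 3.0))), Z)
            lam, _ = solve_dual(K, y, c_xi, tol=1e-8)
            _, obj_ref = qp_oracle(K, y, c_xi)
            assert dual_objective(K, y, lam) == pytest.approx(obj_ref, abs=1e-6)
            assert abs(y @ lam) <= 1e-6
            assert lam.min() >= -1e-12 and lam.max() <= c_xi + 1e-12
            done += 1

    def test_separable_limit_zero_training_errors(self):
        rng = np.random.default_rng(5)
        Z = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        model = fit_binary_svm(Z, y, KernelParams(family="grbf", sigma2=4.0,
                                                  c_xi=1e6), tol=1e-8)
        pred = np.sign(decision_values(model, Z))
        np.testing.assert_array_equal(pred, y)

    def test_single_class_raises(self):
        K = np.eye(3)
        with pytest.raises(ValueError, match="both classes"):
            solve_dual(K, np.ones(3), 1.0)

    def test_nonconvergence_carries_best_iterate(self):
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((30, 2))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        K = kernel_matrix(KernelParams(family="grbf", sigma2=1.0), Z)
        with pytest.raises(SMONonConvergence) as exc:
            solve_dual(K, y, 1.0, tol=1e-12, max_iter=3)
        assert exc.value.lam.shape == (30,)
        assert np.isfinite(exc.value.bias)


@pytest.fixture(scope="module")
def trained(binary_scores):
    scores, y, _ = binary_scores
    kernel = KernelParams(family="grbf", sigma2=10.0, c_xi=1.0)
    model = fit_binary_svm(scores, y, kernel, tol=1e-8)
    return model, scores, y


class TestDecisionFunction:
    def test_free_support_vectors_sit_on_margin(self, trained):
        model, scores, y = trained
        lam = np.abs(model.dual_coeffs)
        free = (lam > 1e-6) & (lam < model.kernel.c_xi - 1e-6)
        f = decision_values(model, model.support_vectors[free])
        np.testing.assert_allclose(np.abs(f), 1.0, atol=1e-6)

    def test_dual_balance_constraint(self, trained):
        model, _, _ = trained
        assert abs(model.dual_coeffs.sum()) <= 1e-6  # sum lam_r y_r = 0

    def test_duplicated_support_vector_with_split_mass(self, trained):
        """Splitting one support vector's dual mass across a duplicate
        leaves the decision function unchanged."""
        model, scores, _ = trained
        sv = np.vstack([model.support_vectors, model.support_vectors[:1]])
        coef = np.concatenate([model.dual_coeffs, [model.dual_coeffs[0] / 2]])
        coef[0] /= 2
        split = BinarySVMModel(support_vectors=sv, dual_coeffs=coef,
                               bias=model.bias, kernel=model.kernel)
        np.testing.assert_allclose(decision_values(split, scores),
                                   decision_values(model, scores), atol=1e-6)

    def test_degenerate_model_is_constant(self):
        model = BinarySVMModel(support_vectors=np.zeros((0, 2)),
                               dual_coeffs=np.zeros(0), bias=-0.4,
                               kernel=KernelParams())
        f = decision_values(model, np.random.default_rng(0).standard_normal((5, 2)))
        np.testing.assert_allclose(f, -0.4)

    def test_dimension_mismatch_raises(self, trained):
        model, _, _ = trained
        with pytest.raises(ValueError, match="features"):
            decision_value(model, np.zeros(model.n_features + 2))


def test_linear_kernel_matches_independent_svm():
    """With d=1, beta0=0 the decisions coincide with an independently
    solved linear SVM (scikit-learn's libsvm backend as the oracle)."""
    sklearn_svm = pytest.importorskip("sklearn.svm")
    rng = np.random.default_rng(11)
    Z = np.vstack([rng.normal(-2, 0.8, (15, 2)), rng.normal(2, 0.8, (15, 2))])
    y = np.concatenate([-np.ones(15), np.ones(15)])
    kernel = KernelParams(family="polynomial", degree=1, beta0=0.0, c_xi=1.0)
    mine = fit_binary_svm(Z, y, kernel, tol=1e-8)
    ref = sklearn_svm.SVC(kernel="linear", C=1.0, tol=1e-8).fit(Z, y)
    f_mine = decision_values(mine, Z)
    f_ref = ref.decision_function(Z)
    np.testing.assert_allclose(f_mine, f_ref, atol=1e-4)
    np.testing.assert_array_equal(np.sign(f_mine), np.sign(f_ref))
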