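"""Dual SVM solver: kernel arithmetic, oracle equivalence, CV folds.

The solver's correctness is pinned to an independent quadratic-program
oracle (SciPy SLSQP on the dual with explicit bound and equality
constraints), not to any library's SVM internals.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from dermafluor import (
    ConvergenceError,
    DegenerateTrainingError,
    InvalidInputError,
    SVMModel,
    kfold_cv,
    kkt_residuals,
    poly_kernel,
    predict_spectrum,
    train_svm,
)
from dermafluor.svm_classifier import group_kfold_indices, kernel_matrix


def qp_oracle(X, y, C, scale, degree, class_weight=None):
    """Direct dual solve: min 1/2 a'Qa - e'a, y'a = 0, 0 <= a <= C_i."""
    ys = np.where(np.asarray(y) == 1, 1.0, -1.0)
    n = len(ys)
    K = (1.0 + X @ X.T / scale**2) ** degree
    Q = np.outer(ys, ys) * K
    if class_weight == "balanced":
        w = {c: n / (2.0 * np.sum(np.asarray(y) == c)) for c in (0, 1)}
        bounds = [(0.0, C * w[int(c)]) for c in y]
    else:
        bounds = [(0.0, C)] * n
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        x0=np.array([b[1] / 2 for b in bounds]),
        jac=lambda a: Q @ a - 1.0,
        bounds=bounds,
        constraints=[{"type": "eq", "fun": lambda a: a @ ys, "jac": lambda a: ys}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success
    return res.x, res.fun


def dual_objective(alpha, X, y, scale, degree):
    ys = np.where(np.asarray(y) == 1, 1.0, -1.0)
    Q = np.outer(ys, ys) * ((1.0 + X @ X.T / scale**2) ** degree)
    return 0.5 * alpha @ Q @ alpha - alpha.sum()


class TestKernel:
    def test_zero_vectors(self):
        assert poly_kernel(np.zeros(5), np.zeros(5)) == 1.0

    def test_one_hot_cubed(self):
        e = np.eye(5)[0]
        assert poly_kernel(e, e, scale=1.0, degree=3) == 8.0

    def test_hand_arithmetic(self):
        assert poly_kernel(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == 1728.0

    def test_invalid_scale(self):
        with pytest.raises(InvalidInputError):
            poly_kernel(np.ones(3), np.ones(3), scale=0.0)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            poly_kernel(np.ones(3), np.ones(4))


class TestTraining:
    def test_two_point_minimal_problem(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = train_svm(X, np.array([0, 1]), C=10.0)
        assert len(model.dual_coef) == 2  # both points support the margin
        f = model.decision_function(X)
        assert f[0] < 0 < f[1]

    def test_separable_toy_set_trains_to_zero_error(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.repeat([0, 1], 10)
        model = train_svm(X, y, C=100.0, scale=1.0, degree=3)
        assert np.array_equal(model.predict(X), y)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_svm(np.eye(3), np.zeros(3))

    def test_box_constraints_respected(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        model = train_svm(X, y, C=0.165)
        alpha = model.alpha_
        assert np.all(alpha >= 0) and np.all(alpha <= 0.165 + 1e-12)
        assert abs(np.sum(model.dual_coef)) < 1e-9  # sum alpha_i y_i = 0

    def test_nonconvergence_carries_gap(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        with pytest.raises(ConvergenceError) as exc:
            train_svm(X, y, C=1.0, max_iter=2)
        assert exc.value.gap > 0

    @pytest.mark.parametrize("class_weight", [None, "balanced"])
    def test_qp_oracle_equivalence(self, class_weight):
        rng = np.random.default_rng(7)
        for _ in range(6):
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, 3))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            model = train_svm(X, y, C=0.165, tol=1e-8,
                              class_weight=class_weight)
            _, f_star = qp_oracle(X, y, 0.165, 1.0, 3, class_weight)
            f_mine = dual_objective(model.alpha_, X, y, 1.0, 3)
            assert f_mine <= f_star + 1e-6
            # decision values match the oracle model
            a_star, _ = qp_oracle(X, y, 0.165, 1.0, 3, class_weight)
            ys = np.where(y == 1, 1.0, -1.0)
            K = kernel_matrix(X, X)
            if class_weight == "balanced":
                w = {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}
                upper = 0.165 * np.array([w[int(c)] for c in y])
            else:
                upper = np.full(n, 0.165)
            free = (a_star > 1e-7) & (a_star < upper - 1e-7)
            if free.any():
                b_star = np.mean(ys[free] - (a_star * ys) @ K[:, free])
                f_pts = (a_star * ys) @ kernel_matrix(X, X) + b_star
                np.testing.assert_allclose(
                    model.decision_function(X), f_pts, atol=1e-4
                )

    def test_kkt_residuals_below_tolerance(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, 40)
        for cw in (None, "balanced"):
            model = train_svm(X, y, C=0.5, tol=1e-3, class_weight=cw)
            assert kkt_residuals(model, X, y).max() <= 1e-3


class TestModelProperties:
    def test_scale_doubling_equals_input_halving(self, rng):
        X = rng.normal(size=(16, 3))
        y = rng.integers(0, 2, 16)
        m1 = train_svm(X, y, C=1.0, scale=2.0, tol=1e-8)
        m2 = train_svm(X / 2.0, y, C=1.0, scale=1.0, tol=1e-8)
        Z = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            m1.decision_function(Z), m2.decision_function(Z / 2.0), atol=1e-6
        )

    def test_label_flip_negates_decisions(self, rng):
        X = rng.normal(size=(14, 3))
        y = rng.integers(0, 2, 14)
        m1 = train_svm(X, y, C=0.5, tol=1e-8)
        m2 = train_svm(X, 1 - y, C=0.5, tol=1e-8)
        Z = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            m1.decision_function(Z), -m2.decision_function(Z), atol=1e-6
        )

    def test_support_vector_permutation_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        model = train_svm(X, y, C=1.0)
        perm = rng.permutation(len(model.dual_coef))
        shuffled = SVMModel(
            support_vectors=model.support_vectors[perm],
            dual_coef=model.dual_coef[perm],
            bias=model.bias,
            kernel_degree=model.kernel_degree,
            kernel_scale=model.kernel_scale,
            box_constraint=model.box_constraint,
        )
        Z = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            model.decision_function(Z), shuffled.decision_function(Z)
        )

    def test_zero_decision_value_is_benign(self):
        x = np.array([1.0, 0.0])
        model = SVMModel(
            support_vectors=x[None, :],
            dual_coef=np.array([1.0]),
            bias=-poly_kernel(x, x),
        )
        cls, decision = predict_spectrum(model, x)
        assert decision == 0.0 and cls == 0

    def test_serialization_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, 12)
        model = train_svm(X, y, C=0.3)
        back = SVMModel.load(model.save(tmp_path / "model.json"))
        Z = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            model.decision_function(Z), back.decision_function(Z)
        )


class TestCrossValidation:
    def test_fold_sizes_for_49_lesions_k20(self):
        groups = np.repeat([f"L{i}" for i in range(49)], 3)
        folds = group_kfold_indices(groups, k=20, seed=0)
        lesion_counts = sorted(len(np.unique(groups[f])) for f in folds)
        assert set(lesion_counts) == {2, 3}
        assert sum(lesion_counts) == 49

    def test_folds_partition_lesions(self):
        groups = np.repeat(np.arange(10), 4)
        folds = group_kfold_indices(groups, k=5, seed=1)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(40))
        for f in folds:  # no lesion straddles folds
            assert not set(np.unique(groups[f])) & set(
                np.unique(groups[np.setdiff1d(seen, f)])
            )

    def test_leave_one_lesion_out_limit(self, rng):
        X = rng.normal(size=(12, 2)) + np.repeat([[0], [6]], 6, axis=0)
        y = np.repeat([0, 1], 6)
        groups = np.arange(12)
        report = kfold_cv(X, y, groups, k=12, C=10.0)
        assert len(report.fold_errors) == 12

    def test_separable_classes_have_zero_cv_error(self, rng):
        X = np.vstack([rng.normal(-4, 0.2, (12, 2)), rng.normal(4, 0.2, (12, 2))])
        y = np.repeat([0, 1], 12)
        groups = np.repeat(np.arange(8), 3)
        report = kfold_cv(X, y, groups, k=4, C=50.0)
        assert report.mean_cv_error == 0.0
        assert report.converged

    def test_reproducible_for_fixed_seed(self):
        groups = np.arange(20)
        a = group_kfold_indices(groups, 5, seed=9)
        b = group_kfold_indices(groups, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            group_kfold_indices(np.arange(3), k=5, seed=0)
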