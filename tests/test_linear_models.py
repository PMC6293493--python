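import numpy as np
import pytest
from scipy.optimize import minimize

from misc_impute.linear_models import (
    CLASSIFIER_OBJECTIVES,
    LinearModel,
    cross_validate,
    decision_matrix,
    objective_value,
    predict_classifier,
    predict_svr,
    train_classifier,
    train_svr,
)
from misc_impute.io_matrix import ExpressionMatrix, GeneList
from misc_impute.sample_builder import SampleSet, build_samples


def _sample_set(X, y, role="train"):
    X = np.asarray(X, dtype=float)
    idx = np.column_stack([np.arange(len(X)), np.zeros(len(X), dtype=int)])
    return SampleSet(idx, X, np.asarray(y, dtype=float), role)


def _oracle_minimum(X, y, objective, C, epsilon=0.0, p=2):
    """Independent general-purpose minimizer of the stated objective."""
    Xa = np.hstack([X, np.ones((len(X), 1))])

    def f(w):
        reg = 0.5 * w @ w
        m = Xa @ w
        if objective == "lr_l2":
            return reg + C * np.logaddexp(0, -y * m).sum()
        if objective == "svm_l2_l2loss":
            return reg + C * (np.maximum(0, 1 - y * m) ** 2).sum()
        return reg + C * (np.maximum(0, np.abs(y - m) - epsilon) ** p).sum()

    best = None
    for s in range(3):  # multistart for safety on the piecewise-smooth losses
        x0 = np.zeros(Xa.shape[1]) if s == 0 else np.random.default_rng(s).normal(
            0, 0.1, Xa.shape[1]
        )
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        res2 = minimize(f, res.x, method="Powell",
                        options={"maxiter": 20000, "xtol": 1e-12, "ftol": 1e-14})
        if best is None or res2.fun < best:
            best = res2.fun
    return best


@pytest.fixture(scope="module")
def toy_classification():
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (20, 2))
    y = np.where(X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 20) > 0, 1.0, -1.0)
    if len(np.unique(y)) < 2:  # pragma: no cover
        y[0] = -y[0]
    return X, y


class TestClassifier:
    @pytest.mark.parametrize("objective", CLASSIFIER_OBJECTIVES)
    def test_separable_toy_reaches_perfect_accuracy(self, objective):
        s = _sample_set([[-1.0], [1.0]], [-1.0, 1.0])
        model = train_classifier(s, objective, C=1.0)
        pred, _ = predict_classifier(model, s)
        np.testing.assert_array_equal(pred, s.labels)

    @pytest.mark.parametrize("objective", CLASSIFIER_OBJECTIVES)
    def test_objective_matches_independent_minimizer(self, toy_classification,
                                                     objective):
        X, y = toy_classification
        model = train_classifier(_sample_set(X, y), objective, C=1.0,
                                 tol=1e-12, max_iter=50000)
        ours = objective_value(model, X, y)
        oracle = _oracle_minimum(X, y, objective, C=1.0)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_flipped_labels_negate_weights(self, toy_classification):
        X, y = toy_classification
        a = train_classifier(_sample_set(X, y), "lr_l2", C=1.0, bias=False,
                             tol=1e-10, max_iter=20000)
        b = train_classifier(_sample_set(X, -y), "lr_l2", C=1.0, bias=False,
                             tol=1e-10, max_iter=20000)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-5)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(_sample_set([[1.0], [2.0]], [1.0, 1.0]))

    def test_non_finite_feature_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            train_classifier(_sample_set([[np.nan], [1.0]], [-1.0, 1.0]))

    def test_prediction_rules(self):
        model = LinearModel(weights=np.array([1.0, 0.0]), bias=0.0,
                            objective="lr_l2", C=1.0)
        labels, dec = predict_classifier(model, np.array([[3.0, -5.0],
                                                          [0.0, 7.0]]))
        assert dec[0] == pytest.approx(3.0)
        assert labels[0] == 1
        assert dec[1] == 0.0 and labels[1] == -1  # zero decision -> not missing

    def test_objective_no_worse_than_zero_vector(self, toy_classification):
        X, y = toy_classification
        for objective in CLASSIFIER_OBJECTIVES:
            model = train_classifier(_sample_set(X, y), objective, C=0.7)
            zero = LinearModel(np.zeros(2), 0.0, objective, C=0.7)
            assert objective_value(model, X, y) <= objective_value(zero, X, y) + 1e-9

    def test_doubling_c_does_not_increase_loss_term(self, toy_classification):
        X, y = toy_classification
        losses = []
        for C in (0.5, 1.0, 2.0, 4.0):
            m = train_classifier(_sample_set(X, y), "lr_l2", C=C,
                                 tol=1e-10, max_iter=20000)
            w = np.concatenate([m.weights, [m.bias]])
            reg = 0.5 * w @ w
            losses.append((objective_value(m, X, y) - reg) / C)
        assert all(b <= a + 1e-8 for a, b in zip(losses, losses[1:]))


class TestStrongDuality:
    def test_squared_hinge_duality_gap_small(self, toy_classification):
        X, y = toy_classification
        C = 1.0
        model = train_classifier(_sample_set(X, y), "svm_l2_l2loss", C=C,
                                 tol=1e-12, max_iter=50000)
        primal = objective_value(model, X, y)
        Xa = np.hstack([X, np.ones((len(X), 1))])
        Q = (y[:, None] * Xa) @ (y[:, None] * Xa).T
        Qbar = Q + np.eye(len(y)) / (2 * C)

        def dual(alpha):
            return 0.5 * alpha @ Qbar @ alpha - alpha.sum()

        res = minimize(dual, np.full(len(y), 0.1), jac=lambda a: Qbar @ a - 1,
                       method="L-BFGS-B", bounds=[(0, None)] * len(y),
                       options={"maxiter": 20000, "ftol": 1e-15})
        assert primal == pytest.approx(-res.fun, rel=1e-4)

    def test_svr_l2_primal_dual_agree(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (15, 2))
        y = X @ np.array([1.5, -0.7]) + rng.normal(0, 0.2, 15)
        kw = dict(p=2, C=2.0, epsilon=0.1, tol=1e-10, max_iter=100000)
        primal = train_svr(_sample_set(X, y), formulation="primal", **kw)
        dual = train_svr(_sample_set(X, y), formulation="dual", **kw)
        fp = objective_value(primal, X, y)
        fd = objective_value(dual, X, y)
        assert fp == pytest.approx(fd, rel=1e-4)


class TestCrossValidation:
    def test_separable_data_scores_one(self):
        X = np.concatenate([np.full((20, 1), -2.0), np.full((20, 1), 2.0)])
        y = np.concatenate([-np.ones(20), np.ones(20)])
        report = cross_validate(_sample_set(X, y), "lr_l2", C=10.0, k=4, seed=3)
        assert report.mean_accuracy == 1.0
        assert report.mean_accuracy == pytest.approx(
            np.mean(report.per_fold_accuracy)
        )

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(12)
        n = 600
        X = rng.normal(0, 1, (n, 3))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        report = cross_validate(_sample_set(X, y), "lr_l2", C=1.0, k=5, seed=0)
        sigma = 0.5 / np.sqrt(n)
        assert abs(report.mean_accuracy - 0.5) < 3 * sigma + 0.02

    def test_same_seed_reproduces_report(self, toy_classification):
        X, y = toy_classification
        a = cross_validate(_sample_set(X, y), "lr_l2", 1.0, k=3, seed=7)
        b = cross_validate(_sample_set(X, y), "lr_l2", 1.0, k=3, seed=7)
        assert a.per_fold_accuracy == b.per_fold_accuracy

    def test_k_exceeding_minority_rejected(self):
        X = np.array([[1.0], [2.0], [-1.0], [-3.0], [-4.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="minority"):
            cross_validate(_sample_set(X, y), k=3)


class TestSvr:
    def test_noiseless_line_recovers_slope(self):
        X = np.arange(1, 11, dtype=float).reshape(-1, 1)
        y = 2.0 * X.ravel()
        model = train_svr(_sample_set(X, y), p=2, C=1e6, epsilon=0.0,
                          tol=1e-12, max_iter=100000)
        assert model.weights[0] == pytest.approx(2.0, abs=1e-3)
        pred = predict_svr(model, X)
        assert np.max(np.abs(pred - y)) < 1e-3

    def test_large_c_matches_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 1))
        y = 1.3 * X.ravel() + rng.normal(0, 0.1, 10)
        model = train_svr(_sample_set(X, y), p=2, C=1e6, epsilon=0.0,
                          tol=1e-12, max_iter=200000)
        Xa = np.hstack([X, np.ones((10, 1))])
        w_ols, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        np.testing.assert_allclose(
            np.concatenate([model.weights, [model.bias]]), w_ols, atol=1e-3
        )

    def test_label_shift_moves_bias_only(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (30, 2))
        y = X @ np.array([1.0, -2.0]) + rng.normal(0, 0.1, 30)
        kw = dict(p=2, C=1e6, epsilon=0.0, tol=1e-12, max_iter=200000)
        a = train_svr(_sample_set(X, y), **kw)
        b = train_svr(_sample_set(X, y + 5.0), **kw)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-2)
        assert b.bias - a.bias == pytest.approx(5.0, abs=1e-2)

    def test_l1_primal_unsupported(self):
        with pytest.raises(ValueError, match="dual"):
            train_svr(_sample_set([[1.0], [2.0]], [1.0, 2.0]), p=1,
                      formulation="primal")

    def test_constant_model_predicts_bias(self):
        model = LinearModel(np.zeros(3), 4.5, "svr_l2loss", C=1.0)
        np.testing.assert_allclose(predict_svr(model, np.zeros((5, 3))), 4.5)


class TestDecisionMatrix:
    def test_matches_per_sample_path(self, tiny_matrix):
        genes = GeneList(tiny_matrix.gene_ids)
        s = build_samples(tiny_matrix, genes)
        model = LinearModel(np.array([0.3, -1.2, 0.5]), 0.7, "lr_l2", C=1.0)
        dm = decision_matrix(model, tiny_matrix)
        _, dec = predict_classifier(model, s)
        for k, (g, c) in enumerate(s.element_index):
            assert dm[g, c] == pytest.approx(dec[k], rel=1e-12)
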