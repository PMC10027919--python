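"""Kernel SVM: kernels, dual feasibility, reference-implementation agreement,
metrics, cross-validation, grid search and the confusion-matrix inversion."""

import numpy as np
import pandas as pd
import pytest

from gaitsym.classify import (
    AmbiguousSolution,
    ConfusionMatrix,
    KernelSpec,
    MetricUndefined,
    NoSolution,
    build_feature_sets,
    cross_validate,
    evaluate,
    grid_search,
    holdout_split,
    kernel_eval,
    predict,
    recover_confusion_from_metrics,
    stratified_folds,
    train_svm,
)


class TestKernels:
    def test_linear_dot_product(self):
        assert kernel_eval(KernelSpec("LINEAR"), [1, 2], [3, 4]) == 11.0

    def test_poly_order_two(self):
        assert kernel_eval(KernelSpec("POLY", d=2), [1, 2], [3, 4]) == 144.0

    def test_rbf_unit_at_equal_inputs(self):
        for G in (0.01, 1.0, 50.0):
            assert kernel_eval(KernelSpec("RBF", G=G), [1, 2], [1, 2]) == 1.0

    def test_rbf_gamma_convention(self):
        # K = exp(-G ||u-v||^2), i.e. sigma^2 = 1/(2G)
        val = kernel_eval(KernelSpec("RBF", G=0.5), [0.0], [2.0])
        assert val == pytest.approx(np.exp(-2.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("LINEAR"), [1, 2], [1, 2, 3])

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            KernelSpec("RBF", G=0.0)
        with pytest.raises(ValueError):
            KernelSpec("POLY", d=0)
        with pytest.raises(ValueError):
            KernelSpec("SIGMOID")


def _separable_toy():
    X = np.array([[-5.0], [-4.5], [-5.5], [5.0], [4.5], [5.5]])
    y = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
    return X, y


class TestTrainSvm:
    def test_separable_toy_trains_perfectly(self):
        X, y = _separable_toy()
        model = train_svm(X, y, KernelSpec("LINEAR"), C=1.0)
        assert np.array_equal(predict(model, X), y)
        assert np.sign(model.decision_function([[-5.0]])) == -1
        assert np.sign(model.decision_function([[5.0]])) == 1

    def test_xor_solved_by_rbf(self):
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float)
        y = np.array([1.0, -1.0, -1.0, 1.0])
        model = train_svm(X, y, KernelSpec("RBF", G=1.0), C=100.0,
                          standardize=False)
        assert np.array_equal(predict(model, X), y)

    @pytest.mark.parametrize("kind,G", [("LINEAR", 1.0), ("RBF", 0.5),
                                        ("POLY", 1.0)])
    def test_dual_feasibility_random_problems(self, kind, G, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 6))
            y = np.where(rng.random(30) < 0.5, -1.0, 1.0)
            y[:2] = [-1.0, 1.0]  # both classes guaranteed
            C = float(rng.choice([0.1, 1.0, 10.0]))
            model = train_svm(X, y, KernelSpec(kind, G=G), C)
            assert np.all(model.beta >= 0.0)
            assert np.all(model.beta <= C + 1e-12)
            assert abs(np.sum(model.beta * model.y)) <= 1e-6

    def test_agreement_with_reference_qp_implementation(self, rng):
        """Held-out label agreement with libsvm (via scikit-learn) on 20
        random small problems must reach 95% of points."""
        sklearn = pytest.importorskip("sklearn.svm")
        agreements = []
        for rep in range(20):
            X = rng.normal(size=(50, 6))
            y = np.where(rng.random(50) < 0.5, -1.0, 1.0)
            y[:2] = [-1.0, 1.0]
            X[y > 0] += 0.7
            kind, G, C = [("LINEAR", 1.0, 1.0), ("RBF", 0.5, 10.0),
                          ("POLY", 1.0, 1.0)][rep % 3]
            model = train_svm(X, y, KernelSpec(kind, G=G), C,
                              standardize=False)
            ref = sklearn.SVC(
                C=C, kernel=kind.lower() if kind != "LINEAR" else "linear",
                gamma=G, degree=3, coef0=1.0).fit(X, y)
            X_test = rng.normal(size=(40, 6))
            agreements.append(np.mean(predict(model, X_test)
                                      == ref.predict(X_test)))
        assert np.mean(agreements) >= 0.95

    def test_bad_inputs(self):
        X, y = _separable_toy()
        with pytest.raises(ValueError):
            train_svm(X, y, KernelSpec("LINEAR"), C=0.0)
        with pytest.raises(ValueError):
            train_svm(X, np.ones(6), KernelSpec("LINEAR"), C=1.0)


class TestPredict:
    def test_tie_at_zero_maps_to_plus_one(self):
        # perfectly symmetric pair: the midpoint has decision exactly 0
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = train_svm(X, y, KernelSpec("LINEAR"), C=1.0,
                          standardize=False)
        assert model.decision_function([[0.0]])[0] == pytest.approx(0.0,
                                                                    abs=1e-9)
        assert predict(model, [[0.0]])[0] == 1.0

    def test_repeat_prediction_identical(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.where(rng.random(20) < 0.5, -1.0, 1.0)
        y[:2] = [-1.0, 1.0]
        model = train_svm(X, y, KernelSpec("RBF", G=1.0), C=1.0)
        np.testing.assert_array_equal(predict(model, X), predict(model, X))

    def test_feature_length_mismatch(self):
        X, y = _separable_toy()
        model = train_svm(X, y, KernelSpec("LINEAR"), C=1.0)
        with pytest.raises(ValueError):
            predict(model, np.ones((3, 2)))


class TestEvaluate:
    def test_all_correct(self):
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        cm = evaluate(y, y)
        assert (cm.T1, cm.T2, cm.F1, cm.F2) == (2, 2, 0, 0)
        assert cm.acc == cm.sen == cm.sep == 1.0

    def test_published_grf_y_triple(self):
        cm = ConfusionMatrix(T1=16, T2=12, F1=1, F2=5)
        assert cm.acc == pytest.approx(28 / 34)
        assert cm.sen == pytest.approx(16 / 21)
        assert cm.sep == pytest.approx(12 / 13)

    def test_counts_assignment(self):
        true = np.array([-1.0, -1.0, -1.0, 1.0, 1.0])
        pred = np.array([-1.0, 1.0, 1.0, 1.0, -1.0])
        cm = evaluate(true, pred)
        assert (cm.T1, cm.T2, cm.F1, cm.F2) == (1, 1, 2, 1)

    def test_undefined_metrics_raise(self):
        cm = evaluate(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
        with pytest.raises(MetricUndefined):
            _ = cm.sen  # T1 + F2 = 0: nothing predicted as feature 1


class TestCrossValidation:
    def test_separable_data_perfect_cv(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-5, 0.3, (20, 3)),
                       rng.normal(5, 0.3, (20, 3))])
        y = np.r_[-np.ones(20), np.ones(20)]
        assert cross_validate(X, y, KernelSpec("LINEAR"), 1.0, seed=0) == 1.0

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.r_[-np.ones(20), np.ones(20)]
        a = cross_validate(X, y, KernelSpec("RBF", G=0.1), 1.0, seed=3)
        b = cross_validate(X, y, KernelSpec("RBF", G=0.1), 1.0, seed=3)
        assert a == b

    def test_stratified_folds_balance(self):
        y = np.r_[-np.ones(25), np.ones(15)]
        folds = stratified_folds(y, 5, seed=0)
        assert sorted(np.concatenate(folds).tolist()) == list(range(40))
        for f in folds:
            assert np.sum(y[f] == -1) == 5
            assert np.sum(y[f] == 1) == 3

    def test_class_too_small_to_stratify(self):
        y = np.r_[-np.ones(3), np.ones(30)]
        with pytest.raises(ValueError, match="too few"):
            stratified_folds(y, 5, seed=0)


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = _separable_toy()
        C, G, acc = grid_search(X, y, "RBF", C_grid=[2.0], G_grid=[0.25],
                                k=3, seed=0)
        assert (C, G) == (2.0, 0.25)

    def test_argmax_verified_by_brute_force(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        y[:4] = [-1, -1, 1, 1]
        X[y > 0, 0] += 1.5
        C_grid, G_grid = [0.5, 4.0], [0.05, 0.5]
        best_C, best_G, best_acc = grid_search(X, y, "RBF", C_grid, G_grid,
                                               k=3, seed=1)
        brute = {(C, G): cross_validate(X, y, KernelSpec("RBF", G=G), C,
                                        k=3, seed=1)
                 for C in C_grid for G in G_grid}
        assert best_acc == max(brute.values())
        assert brute[(best_C, best_G)] == best_acc

    def test_tie_broken_toward_smaller_c(self):
        X, y = _separable_toy()  # every C achieves CV accuracy 1.0
        best_C, best_G, acc = grid_search(X, y, "LINEAR",
                                          C_grid=[8.0, 0.5, 2.0],
                                          G_grid=[1.0], k=3, seed=0)
        assert acc == 1.0
        assert best_C == 0.5


class TestFeatureSets:
    def test_lr_task_row_counts(self, small_curves):
        X, y, groups = build_feature_sets(small_curves, "LR", "X")
        # 6 subjects x 2 trials x 2 conditions x 2 sides
        assert X.shape == (48, 101)
        assert np.sum(y == -1) == np.sum(y == 1) == 24
        assert len(set(groups)) == 6

    def test_fatigue_task_row_counts(self, small_sf):
        X, y, groups = build_feature_sets(small_sf, "fatigue", "Z")
        assert X.shape == (24, 101)
        assert np.sum(y == -1) == np.sum(y == 1) == 12

    def test_missing_side_raises(self, small_curves):
        broken = small_curves[small_curves["side"] == "L"]
        with pytest.raises(ValueError, match="missing"):
            build_feature_sets(broken, "LR", "X")

    def test_grouped_holdout_keeps_subjects_together(self, small_curves):
        X, y, groups = build_feature_sets(small_curves, "LR", "X")
        train, test = holdout_split(y, 0.3, seed=0, groups=groups)
        assert set(groups[train]).isdisjoint(set(groups[test]))


class TestConfusionRecovery:
    def test_fatigue_y_row_unique_with_two_metrics(self):
        cm, rest = recover_confusion_from_metrics(
            24, {"ACC": (0.54167, 5), "SEP": (0.522, 3)})
        assert (cm.T1, cm.T2, cm.F1, cm.F2) == (1, 12, 11, 0)
        assert rest["SEN"] == 1.0

    def test_fatigue_x_row_needs_full_triple(self):
        with pytest.raises(AmbiguousSolution) as exc:
            recover_confusion_from_metrics(
                24, {"ACC": (0.625, 3), "SEN": (0.667, 3)})
        assert len(exc.value.solutions) == 7
        cm, rest = recover_confusion_from_metrics(
            24, {"ACC": (0.625, 3), "SEN": (0.667, 3), "SEP": (0.6, 3)})
        assert (cm.T1, cm.T2, cm.F1, cm.F2) == (6, 9, 6, 3)

    def test_inconsistent_triple_has_no_solution(self):
        with pytest.raises(NoSolution):
            recover_confusion_from_metrics(
                34, {"ACC": (0.85294, 5), "SEN": (0.842, 3),
                     "SEP": (0.933, 3)})

    def test_needs_two_metrics(self):
        with pytest.raises(ValueError):
            recover_confusion_from_metrics(24, {"ACC": (0.5, 3)})
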