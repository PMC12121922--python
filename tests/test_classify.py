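"""Fold plans, the five classifiers, confusion metrics and the CV harness."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from thermocad.classify import (
    CLASSIFIER_NAMES,
    ConfusionCounts,
    cross_validate,
    encode_labels,
    holdout_evaluate,
    make_folds,
    metrics,
    run_experiment,
    train_predict,
)


def gaussian_pair(rng, n=100, d=2, gap=4.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, d))
    X[y == 1, 0] += gap
    return X, y


class TestFolds:
    def test_equal_fold_sizes(self):
        y = np.repeat([0, 1], 20)
        plan = make_folds(y, k=10, seed=0)
        sizes = [plan.test_indices(f).size for f in range(10)]
        assert sizes == [4] * 10

    def test_partition_exact(self):
        y = np.repeat([0, 1], 23)
        plan = make_folds(y, k=5, seed=1)
        all_test = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_test.tolist()) == list(range(46))

    def test_stratified_ratios(self):
        y = np.array([0] * 30 + [1] * 10)
        plan = make_folds(y, k=10, seed=0)
        for f in range(10):
            yt = y[plan.test_indices(f)]
            assert (yt == 0).sum() == 3 and (yt == 1).sum() == 1

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(np.array([0, 1, 0, 1]), k=10)

    def test_deterministic(self):
        y = np.repeat([0, 1], 15)
        a = make_folds(y, k=3, seed=9)
        b = make_folds(y, k=3, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestClassifiers:
    def test_knn_separable(self, rng):
        X, y = gaussian_pair(rng, gap=8.0)
        pred = train_predict("knn", X, y, X)
        assert (pred == y).mean() == 1.0

    def test_svm_agrees_with_brute_force_dual_on_xor(self):
        """RBF-SVM training predictions on the 4-point XOR match an
        independently solved kernel dual (small sigma regime)."""
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y01 = np.array([0, 0, 1, 1])
        ys = 2.0 * y01 - 1.0
        # replicate the fitted machine's kernel width (standardized inputs,
        # sigma = median pairwise distance) and solve the dual by optimization
        Xs = (X - X.mean(0)) / X.std(0)
        from scipy.spatial.distance import cdist

        D = cdist(Xs, Xs)
        sigma = np.median(D[np.triu_indices(4, k=1)])
        K = np.exp(-(D ** 2) / (2 * sigma ** 2))
        Q = (ys[:, None] * ys[None, :]) * K

        def neg_dual(a):
            return 0.5 * a @ Q @ a - a.sum()

        cons = {"type": "eq", "fun": lambda a: a @ ys}
        sol = minimize(neg_dual, x0=np.full(4, 0.5), bounds=[(0, 1.0)] * 4,
                       constraints=cons, method="SLSQP")
        a = sol.x
        free = [i for i in range(4) if 1e-6 < a[i] < 1 - 1e-6]
        if free:
            b = np.mean([ys[i] - (a * ys) @ K[:, i] for i in free])
        else:
            # all multipliers at bounds: b lies in the KKT-feasible interval
            # (alpha=0 pushes y(f+b) >= 1, alpha=C pushes y(f+b) <= 1)
            f = (a * ys) @ K
            lo = max(ys[i] - f[i] for i in range(4) if (ys[i] > 0) != (a[i] > 0.5))
            hi = min(ys[i] - f[i] for i in range(4) if (ys[i] > 0) == (a[i] > 0.5))
            b = 0.5 * (lo + hi)
        oracle = np.sign((a * ys) @ K + b)
        pred = train_predict("svm", X, y01, X)
        np.testing.assert_array_equal(2.0 * pred - 1.0, oracle)

    def test_lda_two_spherical_gaussians_low_error(self):
        """Pseudoquadratic discriminant approaches the ~2.3% Bayes error."""
        errs = []
        means = np.array([[-2.0, 0.0], [2.0, 0.0]])
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ytr = np.repeat([0, 1], 100)
            yte = np.repeat([0, 1], 100)
            Xtr = rng.standard_normal((200, 2)) + means[ytr]
            Xte = rng.standard_normal((200, 2)) + means[yte]
            pred = train_predict("lda", Xtr, ytr, Xte)
            errs.append((pred != yte).mean())
        assert np.mean(errs) <= 0.05

    def test_lda_singular_covariance_pseudoinverse(self, rng):
        X, y = gaussian_pair(rng)
        X = np.hstack([X, np.zeros((len(X), 1))])  # constant feature: singular cov
        pred = train_predict("lda", X, y, X)
        assert (pred == y).mean() > 0.9

    @pytest.mark.parametrize("net", ["patnet", "fitnet"])
    def test_nets_learn_separable_blobs(self, net, rng):
        X, y = gaussian_pair(rng, n=80, gap=6.0)
        pred = train_predict(net, X, y, X, seed=0)
        assert (pred == y).mean() >= 0.95

    @pytest.mark.parametrize("net", ["patnet", "fitnet"])
    def test_nets_seeded_determinism(self, net, rng):
        X, y = gaussian_pair(rng, n=60)
        a = train_predict(net, X, y, X, seed=2)
        b = train_predict(net, X, y, X, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_single_class_train_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="single class"):
            train_predict("svm", X, np.zeros(10, int), X)

    def test_unknown_classifier_rejected(self, rng):
        X, y = gaussian_pair(rng, n=20)
        with pytest.raises(ValueError, match="unknown"):
            train_predict("forest", X, y, X)


class TestMetrics:
    def test_hand_computed_confusion_table(self):
        m = metrics(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["precision"] == pytest.approx(100 * 8 / 9)

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert all(m[k] == 100.0 for k in m)

    def test_all_positive_predictor(self):
        m = metrics(ConfusionCounts(tp=10, fn=0, tn=0, fp=10))
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 50.0

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            m = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m["sensitivity"])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(0, 500)).filter(lambda t: sum(t) > 0))
    def test_matches_direct_formulas(self, counts):
        tp, fp, tn, fn = counts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert m["specificity"] == pytest.approx(100 * tn / (tn + fp))
        if tp + fp:
            assert m["precision"] == pytest.approx(100 * tp / (tp + fp))


class TestHarness:
    def test_each_sample_tested_once(self, rng):
        X, y = gaussian_pair(rng, n=60)
        plan = make_folds(y, k=5, seed=0)
        rep = cross_validate(X, y, plan, classifiers=("knn",))
        assert rep.pooled["knn"].total == 60

    def test_identical_seed_identical_report(self, rng):
        X, y = gaussian_pair(rng, n=60)
        plan = make_folds(y, k=5, seed=0)
        a = cross_validate(X, y, plan, classifiers=("svm", "lda"), seed=1)
        b = cross_validate(X, y, plan, classifiers=("svm", "lda"), seed=1)
        assert a.fold_counts == b.fold_counts

    def test_run_experiment_regime_containment(self, rng):
        X, y = gaussian_pair(rng, n=60, d=4)
        table = pd.DataFrame(X, columns=["t1", "t2", "n1", "n2"])
        subsets = {"texture_only": ["t1", "t2"], "combined": ["t1", "t2", "n1", "n2"]}
        assert set(subsets["texture_only"]) <= set(subsets["combined"])
        reps = run_experiment(table, y, subsets, k=5, seed=0, classifiers=("knn",))
        assert set(reps) == {"texture_only", "combined"}

    def test_run_experiment_unknown_column_rejected(self, rng):
        X, y = gaussian_pair(rng, n=40)
        table = pd.DataFrame(X, columns=["a", "b"])
        with pytest.raises(KeyError, match="unknown columns"):
            run_experiment(table, y, {"bad": ["zz"]}, k=5)

    def test_holdout_mode(self, rng):
        X, y = gaussian_pair(rng, n=80, gap=6.0)
        table = pd.DataFrame(X, columns=["a", "b"])
        rep = holdout_evaluate(table, y, ["a", "b"], seed=0, classifiers=("knn",))
        assert rep.mean_metrics("knn")["accuracy"] > 90.0

    def test_label_encoding_positive_class(self):
        y = encode_labels(pd.Series(["benign", "malignant", "sick", "healthy"]))
        np.testing.assert_array_equal(y, [0, 1, 1, 0])
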