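import numpy as np
import pandas as pd
import pytest

from aavep.encoding import FeatureMatrix
from aavep.modeling import (
    CVSpec,
    ModelSpec,
    PathogenicityClassifier,
    compute_metrics,
    fit_final,
    grid_search,
    predict,
    run_cv,
)


def blob_matrix(n=100, sep=6.0, seed=0, n_features=5, pos_fraction=0.5):
    """Two Gaussian classes separated by `sep` along every feature."""
    rng = np.random.default_rng(seed)
    n_pos = int(n * pos_fraction)
    y = np.array([0] * (n - n_pos) + [1] * n_pos)
    X = rng.normal(size=(n, n_features)) + sep * y[:, None]
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)],
                      index=[f"r{i}" for i in range(n)])
    return FeatureMatrix(df, pd.Series(y.astype(float), index=df.index))


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (rep.accuracy, rep.f1, rep.precision, rep.sensitivity) == (1, 1, 1, 1)

    def test_counts_and_formulas_hand_example(self):
        y_true = [1, 1, 1, 0, 0, 0]
        y_pred = [1, 0, 1, 1, 0, 0]
        rep = compute_metrics(y_true, y_pred)
        assert (rep.TP, rep.FP, rep.TN, rep.FN) == (2, 1, 2, 1)
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.f1 == pytest.approx(4 / 6)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.sensitivity == pytest.approx(2 / 3)

    def test_undefined_precision_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="precision undefined"):
            rep = compute_metrics([1, 0], [0, 0])
        assert np.isnan(rep.precision)

    def test_undefined_sensitivity_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="sensitivity undefined"):
            rep = compute_metrics([0, 0], [0, 1])
        assert np.isnan(rep.sensitivity)

    def test_auc_only_with_scores(self):
        assert compute_metrics([0, 1], [0, 1]).roc_auc is None
        rep = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        assert rep.roc_auc == pytest.approx(1.0)

    def test_agrees_with_brute_force_tally(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            yt, yp = rng.integers(0, 2, n), rng.integers(0, 2, n)
            rep = compute_metrics(yt, yp) if (yt == 1).any() and (yp == 1).any() else None
            if rep is None:
                continue
            tally = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
            for t, p in zip(yt, yp):
                tally[{(1, 1): "TP", (0, 1): "FP", (0, 0): "TN", (1, 0): "FN"}[(t, p)]] += 1
            assert (rep.TP, rep.FP, rep.TN, rep.FN) == (
                tally["TP"], tally["FP"], tally["TN"], tally["FN"]
            )
            assert rep.accuracy == pytest.approx((tally["TP"] + tally["TN"]) / n)


class TestRunCV:
    def test_separable_matrix_high_accuracy(self):
        m = blob_matrix(sep=6.0)
        res = run_cv(m, ModelSpec("random_forest", {"n_estimators": 50}), CVSpec(5, 2, seed=0))
        assert res.mean("accuracy") >= 0.95

    def test_shuffled_labels_near_chance(self):
        m = blob_matrix(sep=6.0, seed=1)
        rng = np.random.default_rng(2)
        shuffled = FeatureMatrix(
            m.data, pd.Series(rng.permutation(m.y), index=m.data.index)
        )
        res = run_cv(shuffled, ModelSpec("random_forest", {"n_estimators": 50}),
                     CVSpec(5, 2, seed=0))
        assert abs(res.mean("accuracy") - 0.5) <= 3 * res.sd("accuracy")

    def test_same_seed_identical(self):
        m = blob_matrix(sep=2.0, seed=3)
        spec = ModelSpec("xgboost", {"n_estimators": 20})
        a = run_cv(m, spec, CVSpec(4, 2, seed=9))
        b = run_cv(m, spec, CVSpec(4, 2, seed=9))
        assert np.array_equal(a.values("accuracy"), b.values("accuracy"))
        assert np.array_equal(a.values("roc_auc"), b.values("roc_auc"))

    def test_row_permutation_invariance_given_same_folds(self):
        m = blob_matrix(n=60, sep=2.0, seed=4)
        cv = CVSpec(4, 1, seed=5)
        splits = list(cv.splitter().split(m.X, m.y))
        perm = np.random.default_rng(6).permutation(len(m.data))
        inverse = np.argsort(perm)
        m_perm = FeatureMatrix(m.data.iloc[perm], m.labels.iloc[perm])
        mapped = [(inverse[tr], inverse[te]) for tr, te in splits]
        spec = ModelSpec("logistic_regression", {"C": 1.0})
        a = run_cv(m, spec, cv, splits=splits)
        b = run_cv(m_perm, spec, cv, splits=mapped)
        assert np.allclose(sorted(a.values("accuracy")), sorted(b.values("accuracy")))

    def test_class_too_small_for_folds_rejected(self):
        m = blob_matrix(n=20, pos_fraction=0.1)
        with pytest.raises(ValueError, match="members per class"):
            run_cv(m, ModelSpec("logistic_regression"), CVSpec(10, 1, seed=0))

    def test_paper_mode_runs(self):
        m = blob_matrix(n=60, sep=4.0, seed=7)
        res = run_cv(m, ModelSpec("svm", {"kernel": "rbf"}), CVSpec(3, 1, seed=0),
                     paper_mode=True)
        assert res.mean("accuracy") > 0.9


class TestGridSearch:
    def test_singleton_grid_returns_that_spec(self):
        m = blob_matrix(n=60, sep=4.0)
        spec = ModelSpec("logistic_regression", grid={"C": [0.5]})
        best, res, table = grid_search(m, spec, CVSpec(3, 1, seed=0))
        assert best.hyperparameters == {"C": 0.5}
        assert len(table) == 1

    def test_dominating_candidate_selected(self):
        # XOR labels: depth-1 stumps cannot express them, deep trees can
        rng = np.random.default_rng(8)
        a, b = rng.integers(0, 2, 120), rng.integers(0, 2, 120)
        X = np.column_stack([a, b]) + rng.normal(0, 0.1, size=(120, 2))
        y = (a ^ b).astype(float)
        df = pd.DataFrame(X, columns=["a", "b"], index=[f"r{i}" for i in range(120)])
        m = FeatureMatrix(df, pd.Series(y, index=df.index))
        spec = ModelSpec("random_forest",
                         grid={"max_depth": [1, None], "n_estimators": [50]})
        best, _, table = grid_search(m, spec, CVSpec(4, 1, seed=0))
        assert best.hyperparameters["max_depth"] is None
        assert len(table) == 2

    def test_one_row_per_grid_point(self):
        m = blob_matrix(n=60, sep=4.0)
        spec = ModelSpec("logistic_regression", grid={"C": [0.1, 1.0, 10.0]})
        _, _, table = grid_search(m, spec, CVSpec(3, 1, seed=0))
        assert list(table["grid_index"]) == [0, 1, 2]


class TestFitPredict:
    def test_overfit_capable_model_memorizes_training(self):
        m = blob_matrix(n=60, sep=6.0)
        model = fit_final(m, ModelSpec("random_forest", {"n_estimators": 100}))
        labels, proba = predict(model, m)
        assert np.array_equal(labels, m.y.astype(int))

    def test_probabilities_complementary(self):
        m = blob_matrix(n=60, sep=2.0)
        model = fit_final(m, ModelSpec("logistic_regression"))
        proba = model.predict_proba(m.data)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_label_is_probability_threshold(self):
        m = blob_matrix(n=60, sep=2.0, seed=9)
        model = fit_final(m, ModelSpec("logistic_regression"))
        labels, proba = predict(model, m)
        assert np.array_equal(labels, (proba >= 0.5).astype(int))

    def test_schema_mismatch_rejected(self):
        m = blob_matrix(n=40, sep=2.0)
        model = fit_final(m, ModelSpec("logistic_regression"))
        renamed = m.data.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="schema"):
            model.predict(renamed)

    def test_estimator_follows_sklearn_conventions(self):
        clf = PathogenicityClassifier(architecture="svm", hyperparameters={"C": 2.0})
        assert clf.get_params()["architecture"] == "svm"
        clf.set_params(architecture="random_forest", hyperparameters=None)
        m = blob_matrix(n=40, sep=4.0)
        clf.fit(m.data, m.y.astype(int))
        assert hasattr(clf, "pipeline_") and hasattr(clf, "feature_names_in_")
        assert list(clf.classes_) == [0, 1]
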