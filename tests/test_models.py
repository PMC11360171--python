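"""Nested cross-validation protocol: grid search, outer CV, model choice."""

import numpy as np
import pytest

from qgexar.models import (
    ALGORITHMS,
    CVReport,
    EndpointClassifier,
    FoldResult,
    ModelSpec,
    build_estimator,
    fit_final_and_predict,
    inner_grid_search,
    outer_repeated_cv,
    register_external_model,
    select_best_model,
)
from qgexar.metrics import MetricSet


def separable(n=80, p=8, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.binomial(1, 0.4, n)
    y[:2] = [0, 1]
    X[y == 1, :3] += shift
    return X, y


class TestInnerGridSearch:
    def test_single_point_returned_without_search(self):
        X, y = separable()
        spec = ModelSpec("random_forest", grid={"n_estimators": [17]})
        assert inner_grid_search(X, y, spec, k=3) == {"n_estimators": 17}

    def test_degenerate_setting_loses(self):
        # an unregularized vs an absurdly regularized linear model
        X, y = separable()
        spec = ModelSpec("svm_sgd", grid={"alpha": [1e-4, 1e6]})
        assert inner_grid_search(X, y, spec, k=3, seed=0) == {"alpha": 1e-4}

    def test_duplicate_grid_points_tie_to_first(self):
        X, y = separable()
        spec = ModelSpec("random_forest", grid={"n_estimators": [25, 25]})
        assert inner_grid_search(X, y, spec, k=3) == {"n_estimators": 25}

    def test_grid_order_preserved_in_points(self):
        spec = ModelSpec("random_forest", grid={"n_estimators": [5, 10], "max_depth": [2]})
        assert spec.grid_points() == [
            {"n_estimators": 5, "max_depth": 2},
            {"n_estimators": 10, "max_depth": 2},
        ]

    def test_minority_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        y = np.array([1, 1] + [0] * 18)
        with pytest.raises(ValueError, match="stratification"):
            inner_grid_search(X, y, ModelSpec("svm_sgd", grid={"alpha": [1e-4, 1e-3]}), k=5)


class TestOuterRepeatedCv:
    def test_separable_data_high_ba(self):
        X, y = separable(n=100, shift=3.0)
        report = outer_repeated_cv(
            X, y, ModelSpec("logistic_elasticnet", grid={"C": [1.0], "l1_ratio": [0.5]}),
            repeats=1, k=3, inner_k=3, seed=0,
        )
        assert report.mean_ba > 0.95
        assert len(report.folds) == 3

    def test_shuffled_labels_ba_near_half(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 10))
        y = rng.permutation(np.repeat([0, 1], 60))
        report = outer_repeated_cv(
            X, y, ModelSpec("svm_sgd", grid={"alpha": [1e-3]}),
            repeats=2, k=5, inner_k=3, seed=1,
        )
        assert abs(report.mean_ba - 0.5) <= 0.08

    def test_fixed_seed_deterministic(self):
        X, y = separable(n=60)
        kwargs = dict(repeats=1, k=2, inner_k=2, seed=9)
        spec = ModelSpec("random_forest", grid={"n_estimators": [30]})
        r1 = outer_repeated_cv(X, y, spec, **kwargs)
        r2 = outer_repeated_cv(X, y, spec, **kwargs)
        assert [f.metrics for f in r1.folds] == [f.metrics for f in r2.folds]

    def test_fold_count_is_repeats_times_k(self):
        X, y = separable(n=60)
        report = outer_repeated_cv(
            X, y, ModelSpec("svm_sgd", grid={"alpha": [1e-3]}),
            repeats=2, k=3, inner_k=2, seed=0,
        )
        assert len(report.folds) == 6

    def test_validation_only_signal_cannot_inflate_cv(self):
        # CV runs on training data alone: a separable validation set must
        # leave the null-level training CV untouched
        rng = np.random.default_rng(3)
        X_tr = rng.standard_normal((100, 8))
        y_tr = rng.permutation(np.repeat([0, 1], 50))
        spec = ModelSpec("svm_sgd", grid={"alpha": [1e-3]})
        report = outer_repeated_cv(X_tr, y_tr, spec, repeats=1, k=5, inner_k=3, seed=2)
        X_val, y_val = separable(n=40, shift=5.0, seed=4)
        _, probs = fit_final_and_predict(X_tr, y_tr, X_val, spec, seed=2)
        report_after = outer_repeated_cv(X_tr, y_tr, spec, repeats=1, k=5, inner_k=3, seed=2)
        assert [f.metrics for f in report.folds] == [f.metrics for f in report_after.folds]
        assert abs(report.mean_ba - 0.5) <= 0.1


class TestSelectBestModel:
    @staticmethod
    def _report(name, ba):
        ms = MetricSet(se=ba, sp=ba, ba=ba, mcc=0.0)
        return CVReport(algorithm=name, folds=[FoldResult(0, 0, ms, {})])

    def test_single_candidate(self):
        spec = ModelSpec("svm_sgd")
        assert select_best_model([(spec, self._report("svm_sgd", 0.6))]) is spec

    def test_max_ba_wins(self):
        a, b = ModelSpec("svm_sgd"), ModelSpec("random_forest")
        best = select_best_model([(a, self._report("svm_sgd", 0.62)),
                                  (b, self._report("random_forest", 0.67))])
        assert best is b

    def test_tie_resolves_to_declared_order(self):
        a, b = ModelSpec("svm_sgd"), ModelSpec("random_forest")
        best = select_best_model([(a, self._report("svm_sgd", 0.6)),
                                  (b, self._report("random_forest", 0.6))])
        assert best is a

    def test_linear_model_beats_degenerate_baseline_on_linear_data(self):
        register_external_model(
            "majority_vote",
            lambda seed=0, **kw: __import__("sklearn.dummy", fromlist=["DummyClassifier"])
            .DummyClassifier(strategy="most_frequent"),
        )
        X, y = separable(n=100, shift=2.5)
        lin = ModelSpec("logistic_elasticnet", grid={"C": [1.0], "l1_ratio": [0.5]})
        base = ModelSpec("majority_vote", grid={"_": [None]}, class_weighting=False)
        reports = [
            (s, outer_repeated_cv(X, y, s, repeats=1, k=3, inner_k=3, seed=0))
            for s in (base, lin)
        ]
        assert select_best_model(reports) is lin


class TestFinalFit:
    def test_training_replica_scores_high(self):
        X, y = separable(n=80, shift=3.0)
        clf, probs = fit_final_and_predict(X, y, X[y == 1][:3], "logistic_elasticnet", seed=0)
        assert (probs > 0.5).all()

    def test_empty_validation_empty_output(self):
        X, y = separable(n=60)
        _, probs = fit_final_and_predict(
            X, y, np.empty((0, X.shape[1])), ModelSpec("svm_sgd", grid={"alpha": [1e-3]}), seed=0
        )
        assert probs.shape == (0,)

    def test_probabilities_complementary(self):
        X, y = separable(n=60)
        clf = EndpointClassifier(
            algorithm="random_forest", grid={"n_estimators": [30]},
            select=False, inner_folds=2, random_state=0,
        ).fit(X, y)
        p = clf.predict_proba(X[:10])
        assert np.allclose(p.sum(axis=1), 1.0)
        assert ((p >= 0) & (p <= 1)).all()

    def test_feature_count_mismatch_rejected(self):
        X, y = separable(n=60)
        clf = EndpointClassifier(
            algorithm="svm_sgd", grid={"alpha": [1e-3]}, select=False,
            inner_folds=2, random_state=0,
        ).fit(X, y)
        with pytest.raises(ValueError, match="schema"):
            clf.predict_proba(X[:, :4])


@pytest.mark.parametrize("algorithm", ALGORITHMS)
def test_every_zoo_member_builds_and_predicts_proba(algorithm):
    X, y = separable(n=40, p=5)
    est = build_estimator(algorithm, seed=0)
    est.fit(X, y)
    p = est.predict_proba(X[:5])
    assert p.shape == (5, 2)


def test_dense_nn_depths_match_names():
    for depth in (1, 2, 3, 4):
        est = build_estimator(f"dense_nn_{depth}")
        assert len(est.hidden_layer_sizes) == depth
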