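"""Class-weighted classifier zoo and the nested cross-validation protocol.

Model selection follows a two-level scheme scored throughout by balanced
accuracy (BA), the right criterion under the strong class imbalance of
endocrine-activity data:

* an *inner* 5-fold grid search picks hyperparameters on the training
  part of each outer fold (ties broken by grid declaration order);
* an *outer* repeated stratified CV (10 repeats x 5 folds at full
  scale) measures each algorithm; within each outer fold, feature
  selection is refit on that fold's training part only, so no held-out
  information leaks into selection or tuning;
* the algorithm with the highest mean outer BA wins (ties by declared
  algorithm order), is refit on the entire training set, and predicts
  the untouched validation chemicals.

The zoo covers a gradient-boosting family (xgboost), random forest,
an SGD-trained SVM, elastic-net logistic regression, and small dense
feed-forward networks with 1-4 hidden ReLU layers. The five classical
families are fit with balanced sample weights (inverse class frequency
on the fit partition); additional sklearn-compatible classifiers can be
registered via :func:`register_external_model`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.utils.class_weight import compute_sample_weight
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from qgexar.metrics import MetricSet, aggregate_cv, confusion, metric_set
from qgexar.multisurf import MultiSURF
from qgexar.util import derive_seed

#: Declared order doubles as the tie-break for model selection.
ALGORITHMS = (
    "gradient_boosting",
    "random_forest",
    "svm_sgd",
    "logistic_elasticnet",
    "dense_nn_1",
    "dense_nn_2",
    "dense_nn_3",
    "dense_nn_4",
)

#: Families fit with balanced sample weights; the dense networks are not
#: (they take no sample weights and are not part of the weighted set).
CLASS_WEIGHTED = frozenset(
    {"gradient_boosting", "random_forest", "svm_sgd", "logistic_elasticnet"}
)

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gradient_boosting": {"n_estimators": [100, 300], "max_depth": [3, 6]},
    "random_forest": {"n_estimators": [200, 500], "max_features": ["sqrt", 0.1]},
    "svm_sgd": {"alpha": [1e-4, 1e-3, 1e-2]},
    "logistic_elasticnet": {"C": [0.1, 1.0], "l1_ratio": [0.2, 0.8]},
    "dense_nn_1": {"alpha": [1e-4, 1e-2]},
    "dense_nn_2": {"alpha": [1e-4, 1e-2]},
    "dense_nn_3": {"alpha": [1e-4, 1e-2]},
    "dense_nn_4": {"alpha": [1e-4, 1e-2]},
}

_EXTERNAL_MODELS: dict[str, Callable[..., BaseEstimator]] = {}


def register_external_model(name: str, factory: Callable[..., BaseEstimator]) -> None:
    """Register an extra sklearn-compatible classifier family.

    ``factory(seed=..., **params)`` must return an unfitted estimator
    exposing ``fit`` and ``predict_proba`` (the slot used for AutoML-style
    externals).
    """
    _EXTERNAL_MODELS[name] = factory


@dataclass
class ModelSpec:
    """One algorithm family with its hyperparameter grid."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    class_weighting: bool | None = None  # None -> family default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS and self.algorithm not in _EXTERNAL_MODELS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS.get(self.algorithm, {"_": [None]}).items()}
        if self.class_weighting is None:
            self.class_weighting = self.algorithm in CLASS_WEIGHTED

    def grid_points(self) -> list[dict]:
        """Cartesian product of the grid in declared key order."""
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


def build_estimator(algorithm: str, params: Mapping | None = None, seed: int = 0) -> BaseEstimator:
    """Instantiate an unfitted classifier for one grid point."""
    params = {k: v for k, v in (params or {}).items() if k != "_"}
    if algorithm in _EXTERNAL_MODELS:
        return _EXTERNAL_MODELS[algorithm](seed=seed, **params)
    if algorithm == "gradient_boosting":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", tree_method="hist",
            verbosity=0, **params,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm_sgd":
        # modified_huber = smoothed hinge; keeps the SVM geometry while
        # providing the predicted probabilities consensus and AUC require
        return SGDClassifier(loss="modified_huber", random_state=seed, **params)
    if algorithm == "logistic_elasticnet":
        # elastic-net penalty via l1_ratio in (0, 1) with the saga solver
        return LogisticRegression(
            solver="saga", max_iter=5000, random_state=seed, **params
        )
    if algorithm.startswith("dense_nn_"):
        depth = int(algorithm.rsplit("_", 1)[1])
        return MLPClassifier(
            hidden_layer_sizes=(64,) * depth, activation="relu", max_iter=400,
            random_state=seed, **params,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _fit(est: BaseEstimator, X, y, class_weighting: bool) -> BaseEstimator:
    if class_weighting:
        sw = compute_sample_weight("balanced", y)
        try:
            est.fit(X, y, sample_weight=sw)
            return est
        except TypeError:
            pass
    est.fit(X, y)
    return est


def _proba(est: BaseEstimator, X) -> np.ndarray:
    return est.predict_proba(X)[:, list(est.classes_).index(1)]


def inner_grid_search(X, y, spec: ModelSpec, k: int = 5, seed: int | None = None):
    """Pick the grid point with the highest mean inner-CV balanced accuracy.

    Ties keep the first point in grid declaration order. Requires every
    class to appear at least ``k`` times so stratified folds never lose
    a class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present in the training fold")
    if counts.min() < k:
        raise ValueError(
            f"stratification error: minority class has {counts.min()} members < {k} folds"
        )
    points = spec.grid_points()
    if len(points) == 1:
        return points[0]
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_point, best_score = None, -math.inf
    for point in points:
        scores = []
        for tr, te in splits:
            est = build_estimator(spec.algorithm, point, seed=seed)
            _fit(est, X[tr], y[tr], spec.class_weighting)
            scores.append(balanced_accuracy_score(y[te], est.predict(X[te])))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first point wins ties
            best_point, best_score = point, score
    return best_point


class EndpointClassifier(ClassifierMixin, BaseEstimator):
    """Feature selection + inner grid search + class-weighted final fit.

    The unit of the outer protocol: ``fit`` optionally runs MultiSURF on
    the training data, grid-searches hyperparameters by inner stratified
    CV, and refits the winning configuration on all training rows.

    Parameters
    ----------
    algorithm : str
        One of :data:`ALGORITHMS` or a registered external model.
    grid : dict or None
        Hyperparameter grid; ``None`` uses the family default.
    select : bool
        Run MultiSURF and keep positive-weight features.
    inner_folds : int
        Folds of the inner grid-search CV.
    class_weighting : bool or None
        Balanced sample weights on fit; ``None`` = family default.
    random_state : int
        Seed for folds and stochastic learners.

    Attributes
    ----------
    selector_ : MultiSURF or None
    support_ : boolean mask of retained feature columns
    best_params_ : chosen grid point
    estimator_ : the fitted final model
    """

    def __init__(self, algorithm="random_forest", grid=None, select=True,
                 inner_folds=5, class_weighting=None, random_state=0):
        self.algorithm = algorithm
        self.grid = grid
        self.select = select
        self.inner_folds = inner_folds
        self.class_weighting = class_weighting
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            algorithm=self.algorithm,
            grid=dict(self.grid) if self.grid else {},
            class_weighting=self.class_weighting,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        spec = self._spec()
        if self.select:
            self.selector_ = MultiSURF().fit(X, y)
            self.support_ = self.selector_.get_support()
        else:
            self.selector_ = None
            self.support_ = np.ones(X.shape[1], dtype=bool)
        Xs = X[:, self.support_]
        self.best_params_ = inner_grid_search(
            Xs, y, spec, k=self.inner_folds, seed=self.random_state
        )
        est = build_estimator(spec.algorithm, self.best_params_, seed=self.random_state)
        self.estimator_ = _fit(est, Xs, y, spec.class_weighting)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"schema error: expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        p1 = _proba(self.estimator_, X[:, self.support_])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class FoldResult:
    repeat: int
    fold: int
    metrics: MetricSet
    params: dict


@dataclass
class CVReport:
    """Per-fold metrics and chosen hyperparameters for one algorithm."""

    algorithm: str
    folds: list[FoldResult]

    def aggregate(self) -> pd.DataFrame:
        return aggregate_cv(f.metrics for f in self.folds)

    @property
    def mean_ba(self) -> float:
        return float(np.mean([f.metrics.ba for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"algorithm": self.algorithm, "repeat": f.repeat, "fold": f.fold}
            row.update(f.metrics.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def outer_repeated_cv(
    X,
    y,
    spec: ModelSpec | str,
    repeats: int = 10,
    k: int = 5,
    feature_selector: bool = True,
    inner_k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified outer CV around selection + inner grid search.

    Within every outer fold, MultiSURF (when enabled) and the grid
    search see only that fold's training part; the held-out part is
    scored once with SE/SP/BA/MCC/AUC.
    """
    if isinstance(spec, str):
        spec = ModelSpec(algorithm=spec)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"stratification error: minority class has {counts.min()} members < {k} folds"
        )
    rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    folds = []
    for idx, (tr, te) in enumerate(rskf.split(X, y)):
        clf = EndpointClassifier(
            algorithm=spec.algorithm,
            grid=spec.grid,
            select=feature_selector,
            inner_folds=inner_k,
            class_weighting=spec.class_weighting,
            random_state=derive_seed(seed, f"outer_fold:{idx}"),
        ).fit(X[tr], y[tr])
        p = clf.predict_proba(X[te])[:, 1]
        ms = metric_set(confusion(p, y[te]), probabilities=p, labels=y[te])
        folds.append(
            FoldResult(repeat=idx // k, fold=idx % k, metrics=ms, params=clf.best_params_)
        )
    return CVReport(algorithm=spec.algorithm, folds=folds)


def select_best_model(reports: Sequence[tuple[ModelSpec, CVReport]] | Mapping[str, CVReport]):
    """Spec (or algorithm name) with the highest mean outer-CV BA.

    Ties resolve to the earliest entry in the given order.
    """
    if isinstance(reports, Mapping):
        items = [(name, rep) for name, rep in reports.items()]
    else:
        items = list(reports)
    if not items:
        raise ValueError("need at least one CV report")
    best_key, best_ba = None, -math.inf
    for key, report in items:
        if report.mean_ba > best_ba:
            best_key, best_ba = key, report.mean_ba
    return best_key


def fit_final_and_predict(
    X_train,
    y_train,
    X_validation,
    spec: ModelSpec | str,
    feature_selector: bool = True,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[EndpointClassifier, np.ndarray]:
    """Refit the winning configuration on all training data; predict probs.

    The validation matrix must present the same gene columns the model
    was trained on; selection learned on training data is applied to it
    unchanged. Returns the fitted classifier and P(active) per
    validation chemical (empty input -> empty output).
    """
    if isinstance(spec, str):
        spec = ModelSpec(algorithm=spec)
    clf = EndpointClassifier(
        algorithm=spec.algorithm,
        grid=spec.grid,
        select=feature_selector,
        inner_folds=inner_k,
        class_weighting=spec.class_weighting,
        random_state=seed,
    ).fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=int))
    X_validation = np.asarray(X_validation, dtype=float)
    if X_validation.shape[0] == 0:
        return clf, np.empty(0)
    return clf, clf.predict_proba(X_validation)[:, 1]
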