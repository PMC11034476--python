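"""Classifier training, repeated stratified cross-validation, and metrics.

Four architectures are supported — support vector machine, logistic
regression, random forest and gradient-boosted trees — each wrapped in
:class:`PathogenicityClassifier`, a scikit-learn estimator whose internal
pipeline standardizes features on the training rows only, so that
cross-validation is leakage-safe by construction. A ``paper_mode`` switch
on :func:`run_cv` instead standardizes once on the full matrix before
splitting, reproducing the common (leaky) fit-once-on-everything protocol;
it is off by default.

Performance is estimated with repeated stratified k-fold cross-validation
(default 10 folds x 10 repeats) and summarized as mean +/- sample standard
deviation over folds for accuracy, F1, precision, sensitivity (recall of
the pathogenic class, the positive label) and ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .encoding import FeatureMatrix

__all__ = [
    "Architecture",
    "CVSpec",
    "ModelSpec",
    "MetricsReport",
    "CVResult",
    "PathogenicityClassifier",
    "compute_metrics",
    "run_cv",
    "grid_search",
    "fit_final",
    "predict",
    "DEFAULT_GRIDS",
]

Architecture = Literal["svm", "logistic_regression", "random_forest", "xgboost"]

ARCHITECTURES: tuple[str, ...] = ("svm", "logistic_regression", "random_forest", "xgboost")

# Default hyperparameter grids. The search protocol (exhaustive grid +
# repeated stratified CV) is fixed; these candidate values are package
# defaults chosen to span the usual operating ranges of each learner.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {
        "kernel": ["rbf", "poly"],
        "C": [0.1, 1.0, 10.0],
        "gamma": ["scale", 0.01, 0.1],
    },
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    "xgboost": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
}


@dataclass(frozen=True)
class CVSpec:
    """Repeated stratified k-fold settings (stratification is always on)."""

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(
            n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed
        )


@dataclass(frozen=True)
class ModelSpec:
    """One architecture with fixed hyperparameters and an optional grid."""

    architecture: Architecture
    hyperparameters: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )


def _make_estimator(architecture: str, params: dict, random_state: int | None):
    params = dict(params)
    if architecture == "svm":
        return SVC(probability=True, random_state=random_state, **params)
    if architecture == "logistic_regression":
        params.setdefault("max_iter", 5000)
        return LogisticRegression(random_state=random_state, **params)
    if architecture == "random_forest":
        return RandomForestClassifier(random_state=random_state, **params)
    if architecture == "xgboost":
        params.setdefault("n_jobs", 1)
        return XGBClassifier(
            random_state=random_state, eval_metric="logloss", **params
        )
    raise ValueError(f"unknown architecture {architecture!r}")


class PathogenicityClassifier(BaseEstimator, ClassifierMixin):
    """Binary pathogenicity classifier (pathogenic = positive class 1).

    A thin scikit-learn estimator over the four supported architectures.
    Features are standardized inside the estimator's own pipeline (fit on
    training rows only) unless ``scale=False``. Fitted attributes follow
    the scikit-learn convention (trailing underscore); predicting on a
    DataFrame whose columns differ from the training schema raises.

    Parameters
    ----------
    architecture : str
        One of ``svm``, ``logistic_regression``, ``random_forest``,
        ``xgboost``.
    hyperparameters : dict, optional
        Passed through to the underlying learner.
    scale : bool
        Standardize features within the pipeline (default True).
    random_state : int, optional
        Seeds every stochastic component of the learner.
    """

    def __init__(
        self,
        architecture: Architecture = "random_forest",
        hyperparameters: dict | None = None,
        scale: bool = True,
        random_state: int | None = None,
    ):
        self.architecture = architecture
        self.hyperparameters = hyperparameters
        self.scale = scale
        self.random_state = random_state

    def _as_array(self, X, check_schema: bool) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.data
        if isinstance(X, pd.DataFrame):
            if check_schema:
                got = list(X.columns)
                if got != list(self.feature_names_in_):
                    raise ValueError(
                        "feature-name schema mismatch: model was trained on "
                        f"{list(self.feature_names_in_)[:4]}... but got {got[:4]}..."
                    )
            return X.to_numpy()
        return np.asarray(X)

    def fit(self, X, y=None):
        if isinstance(X, FeatureMatrix) and y is None:
            y = X.y
        names = None
        if isinstance(X, FeatureMatrix):
            names = X.feature_names
        elif isinstance(X, pd.DataFrame):
            names = list(X.columns)
        Xa = self._as_array(X, check_schema=False)
        ya = np.asarray(y, dtype=int)
        if set(np.unique(ya)) - {0, 1}:
            raise ValueError("labels must be binary 0/1 (pathogenic = 1)")
        steps = []
        if self.scale:
            steps.append(("scale", StandardScaler()))
        steps.append(
            (
                "clf",
                _make_estimator(
                    self.architecture, self.hyperparameters or {}, self.random_state
                ),
            )
        )
        self.pipeline_ = Pipeline(steps).fit(Xa, ya)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        self.feature_names_in_ = np.asarray(
            names if names is not None else [f"x{i}" for i in range(Xa.shape[1])],
            dtype=object,
        )
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._as_array(X, check_schema=True))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(self._as_array(X, check_schema=True))

    def pathogenic_proba(self, X) -> np.ndarray:
        """Probability of the pathogenic (positive) class."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]


@dataclass
class MetricsReport:
    """Confusion counts and the five summary statistics.

    ``accuracy = (TP+TN)/n``, ``f1 = 2TP/(2TP+FP+FN)``,
    ``precision = TP/(TP+FP)``, ``sensitivity = TP/(TP+FN)`` with the
    pathogenic class as positive; undefined ratios are NaN (warned).
    """

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    f1: float
    precision: float
    sensitivity: float
    roc_auc: float | None = None

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "accuracy": self.accuracy, "f1": self.f1, "precision": self.precision,
            "sensitivity": self.sensitivity, "roc_auc": self.roc_auc,
        }


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], y_score: Sequence[float] | None = None
) -> MetricsReport:
    """Confusion counts and summary statistics, pathogenic (1) as positive.

    ROC AUC is included only when scores are supplied and both classes are
    present in ``y_true``.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    acc = (tp + tn) / yt.size
    if tp + fp == 0:
        warnings.warn("precision undefined: no positive predictions", RuntimeWarning, stacklevel=2)
        prec = float("nan")
    else:
        prec = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("sensitivity undefined: no positive truths", RuntimeWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    f1 = float("nan") if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    auc = None
    if y_score is not None:
        ys = np.asarray(y_score, dtype=float)
        if ys.shape != yt.shape:
            raise ValueError("y_score must match y_true length")
        if len(np.unique(yt)) == 2:
            auc = float(roc_auc_score(yt, ys))
        else:
            warnings.warn("ROC AUC undefined: single-class truth", RuntimeWarning, stacklevel=2)
            auc = float("nan")
    return MetricsReport(tp, fp, tn, fn, acc, f1, prec, sens, auc)


_METRICS = ("accuracy", "f1", "precision", "sensitivity", "roc_auc")


@dataclass
class CVResult:
    """Per-fold reports plus mean +/- sample sd aggregates."""

    fold_reports: list[MetricsReport]
    seed: int

    def values(self, metric: str) -> np.ndarray:
        vals = [getattr(r, metric) for r in self.fold_reports]
        return np.asarray([np.nan if v is None else v for v in vals], dtype=float)

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.values(metric)))

    def sd(self, metric: str) -> float:
        v = self.values(metric)
        return float(np.nanstd(v[~np.isnan(v)], ddof=1)) if np.sum(~np.isnan(v)) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in _METRICS}
        ).T

    def table(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.fold_reports):
            d = r.as_dict()
            d["fold"] = i
            rows.append(d)
        return pd.DataFrame(rows)


def _check_cv_feasible(y: np.ndarray, cv: CVSpec) -> None:
    pos, neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if pos < cv.n_folds or neg < cv.n_folds:
        raise ValueError(
            f"stratified {cv.n_folds}-fold CV needs >= {cv.n_folds} members per class "
            f"(got pathogenic={pos}, benign={neg})"
        )


def run_cv(
    matrix: FeatureMatrix,
    model: ModelSpec,
    cv: CVSpec = CVSpec(),
    paper_mode: bool = False,
    splits: Iterable[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of one model spec on a labeled matrix.

    Standardization is fit inside each training fold (leakage-safe). With
    ``paper_mode=True`` the whole matrix is standardized once up front
    instead. Deterministic for a given ``cv.seed``.
    """
    matrix = matrix.labeled()
    X, y = matrix.X, matrix.y.astype(int)
    _check_cv_feasible(y, cv)
    if paper_mode:
        from .encoding import standardize

        matrix, _ = standardize(matrix)
        X = matrix.X
    clf = PathogenicityClassifier(
        architecture=model.architecture,
        hyperparameters=dict(model.hyperparameters),
        scale=not paper_mode,
        random_state=cv.seed,
    )
    reports: list[MetricsReport] = []
    split_iter = splits if splits is not None else cv.splitter().split(X, y)
    for train_idx, test_idx in split_iter:
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("stratification violation: a fold is missing a class")
        fold_clf = clone(clf).fit(X[train_idx], y[train_idx])
        pred = fold_clf.predict(X[test_idx])
        score = fold_clf.pathogenic_proba(X[test_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reports.append(compute_metrics(y[test_idx], pred, score))
    return CVResult(reports, cv.seed)


def grid_search(
    matrix: FeatureMatrix,
    model: ModelSpec,
    cv: CVSpec = CVSpec(),
    paper_mode: bool = False,
) -> tuple[ModelSpec, CVResult, pd.DataFrame]:
    """Exhaustive grid search scored by mean CV accuracy.

    Ties break by higher mean ROC AUC, then first-in-grid order. Returns
    the winning spec (grid cleared, hyperparameters fixed), its CV result,
    and the full results table (one row per grid point).
    """
    grid = model.grid or DEFAULT_GRIDS[model.architecture]
    candidates = list(ParameterGrid(grid))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    rows, results = [], []
    for i, params in enumerate(candidates):
        merged = {**model.hyperparameters, **params}
        res = run_cv(matrix, replace(model, hyperparameters=merged, grid={}), cv, paper_mode)
        results.append((res.mean("accuracy"), res.mean("roc_auc"), -i, merged, res))
        rows.append(
            {
                "grid_index": i,
                **{f"param_{k}": v for k, v in params.items()},
                "mean_accuracy": res.mean("accuracy"),
                "sd_accuracy": res.sd("accuracy"),
                "mean_roc_auc": res.mean("roc_auc"),
            }
        )
    best_acc, best_auc, neg_i, best_params, best_res = max(results)
    best_spec = ModelSpec(model.architecture, best_params, {})
    return best_spec, best_res, pd.DataFrame(rows)


def fit_final(
    matrix: FeatureMatrix, model: ModelSpec, seed: int = 0, paper_mode: bool = False
) -> PathogenicityClassifier:
    """Fit the selected spec on the whole labeled matrix."""
    matrix = matrix.labeled()
    clf = PathogenicityClassifier(
        architecture=model.architecture,
        hyperparameters=dict(model.hyperparameters),
        scale=not paper_mode,
        random_state=seed,
    )
    return clf.fit(matrix.data, matrix.y.astype(int))


def predict(model: PathogenicityClassifier, rows) -> tuple[np.ndarray, np.ndarray]:
    """Labels (pathogenic=1) and pathogenic-class probabilities."""
    if isinstance(rows, FeatureMatrix):
        rows = rows.data
    return model.predict(rows), model.pathogenic_proba(rows)
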