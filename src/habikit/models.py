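"""Classifier training: six algorithms, many-fold CV tuning, Youden cutoff.

Each model is tuned by stratified k-fold cross-validation over a modest
hyperparameter grid (winner by mean CV AUC), refit on the full training
split, and given a fixed operating point: the training-score threshold
maximizing Youden's J (sensitivity + specificity - 1).  The nominal fold
count (default 50) is capped at the minority-class count so stratification
stays possible; predictions call positive at score > cutoff (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .selection import NormalizationParams, apply_normalizer, fit_normalizer

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "TrainedModel",
    "PredictionSet",
    "youden_cutoff",
    "tune_and_train",
    "predict",
]

DEFAULT_CV_FOLDS = 50


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """RBF-SVM whose probabilities come from an explicit Platt fit.

    scikit-learn's built-in ``probability=True`` calibrates with internal CV
    and can invert the ranking on small cohorts; fitting the sigmoid
    directly on the training decision values keeps the probability scores
    strictly rank-preserving with respect to the SVM margin.
    """

    def __init__(self, C: float = 1.0, gamma="scale", random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        self.svc_ = SVC(
            kernel="rbf", C=self.C, gamma=self.gamma, random_state=self.random_state
        ).fit(X, y)
        d = self.svc_.decision_function(X).reshape(-1, 1)
        self.platt_ = LogisticRegression(max_iter=1000).fit(d, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        return self.platt_.predict_proba(self.svc_.decision_function(X).reshape(-1, 1))

    def predict(self, X):
        return self.svc_.predict(X)


def _algorithm(name: str, seed: int):
    """Estimator factory + hyperparameter grid for each supported algorithm."""
    if name == "svm":
        return PlattScaledSVC(random_state=seed), {
            "C": [0.1, 1.0, 10.0, 100.0],
            "gamma": ["scale", 0.01, 0.1],
        }
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed), {
            "n_estimators": [100, 300],
            "max_depth": [None, 4, 8],
        }
    if name == "extra_trees":
        return ExtraTreesClassifier(random_state=seed), {
            "n_estimators": [100, 300],
            "max_depth": [None, 4, 8],
        }
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0
        ), {
            "n_estimators": [100, 300],
            "max_depth": [2, 4],
            "learning_rate": [0.05, 0.2],
        }
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1), {
            "n_estimators": [100, 300],
            "max_depth": [2, 4],
            "learning_rate": [0.05, 0.2],
        }
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed), {
            "C": [0.01, 0.1, 1.0, 10.0],
        }
    raise ValueError(f"unknown algorithm {name!r}")


ALGORITHMS = (
    "svm",
    "random_forest",
    "extra_trees",
    "xgboost",
    "lightgbm",
    "logistic_regression",
)


@dataclass
class ModelSpec:
    algorithm: str = "svm"
    grid: Optional[dict] = None          # overrides the default grid
    cv_folds: int = DEFAULT_CV_FOLDS
    seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    estimator: object
    params: NormalizationParams
    features: list[str]
    cutoff: float
    feature_set: str = "HR"
    algorithm: str = "svm"
    seed: int = 42
    grid_winner: dict = field(default_factory=dict)
    cv_folds_used: int = 0
    cutoff_flag: Optional[str] = None

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in table.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = apply_normalizer(self.params, table[self.features]).values
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class PredictionSet:
    case_ids: list
    scores: np.ndarray
    calls: np.ndarray
    cohort: str = "validation"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": self.case_ids, "score": self.scores,
             "call": self.calls, "cohort": self.cohort}
        )


def youden_cutoff(scores, labels) -> tuple[float, Optional[str]]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints of adjacent sorted unique scores; the call
    rule is strict (score > cutoff).  Ties take the lowest threshold.
    Constant score vectors return the constant itself, flagged.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0]), "constant_scores"
    midpoints = (uniq[:-1] + uniq[1:]) / 2.0
    # extremes cover the call-all / call-none operating points (J = 0);
    # they are visited last so a midpoint wins any tie
    candidates = np.concatenate([midpoints, [uniq[-1], uniq[0] - 1.0]])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        call = scores > t
        sens = (call & (labels == 1)).sum() / n_pos
        spec = (~call & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j:  # strict: earlier (lower) midpoint wins ties
            best_j, best_t = j, t
    return float(best_t), None


def tune_and_train(
    table: pd.DataFrame,
    labels,
    spec: ModelSpec = ModelSpec(),
    features: Optional[list[str]] = None,
    normalization: str = "minmax",
    feature_set: str = "HR",
) -> TrainedModel:
    """Grid-search CV on the training table, refit, fix the Youden cutoff.

    ``table`` holds raw (unnormalized) training features; normalization is
    fit here on the training rows and stored with the model.
    """
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 cases per class")
    features = list(features) if features is not None else list(table.columns)
    params = fit_normalizer(table[features], normalization)
    X = apply_normalizer(params, table[features]).values

    folds = min(spec.cv_folds, int(counts.min()))
    if folds < spec.cv_folds:
        warnings.warn(
            f"cv_folds reduced from {spec.cv_folds} to {folds} "
            "(minority-class count)", stacklevel=2
        )
    estimator, default_grid = _algorithm(spec.algorithm, spec.seed)
    grid = spec.grid if spec.grid is not None else default_grid
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(estimator, grid, scoring="roc_auc", cv=cv, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate folds may lack a class
        search.fit(X, labels)

    scores = search.best_estimator_.predict_proba(X)[:, 1]
    cutoff, flag = youden_cutoff(scores, labels)
    return TrainedModel(
        estimator=search.best_estimator_,
        params=params,
        features=features,
        cutoff=cutoff,
        feature_set=feature_set,
        algorithm=spec.algorithm,
        seed=spec.seed,
        grid_winner=dict(search.best_params_),
        cv_folds_used=folds,
        cutoff_flag=flag,
    )


def predict(model: TrainedModel, table: pd.DataFrame, cohort: str = "validation") -> PredictionSet:
    """Score a cohort with stored normalization; call positive at score > cutoff."""
    scores = model.score(table)
    calls = (scores > model.cutoff).astype(int)
    return PredictionSet(
        case_ids=list(table.index), scores=scores, calls=calls, cohort=cohort
    )
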