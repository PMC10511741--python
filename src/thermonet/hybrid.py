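"""Hybrid deep-feature pipeline: random-forest feature selection + classical ML.

The 32-dimensional activations of RANet's third fully connected layer are
treated as a feature matrix.  A random forest (100 trees, Gini impurity)
supplies mean-decrease-in-impurity importances (normalised to sum to one)
with their across-tree standard deviations; the top-k features (default
k = 12, the elbow of the importance curve) are selected on the training fold
only, and SVM (C = 1, RBF), k-NN (k = 5, Euclidean) and gradient boosting
(100 stumps, learning rate 1, depth 1) are each trained twice — on all
features and on the selected subset — after standardisation with
training-fold statistics.  Nothing from the evaluation fold ever touches the
importances or the scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .datapipe import split_indices
from .evalrep import ClassificationReport, confusion_matrix, classification_metrics, roc_auc

__all__ = [
    "ImportanceVector",
    "SelectionResult",
    "MLConfig",
    "rf_feature_importance",
    "select_top_features",
    "TopKImportanceSelector",
    "train_ml_classifier",
    "run_hybrid_experiment",
]


@dataclass(frozen=True)
class ImportanceVector:
    mean_importance: np.ndarray
    std_importance: np.ndarray

    def __post_init__(self):
        if (self.mean_importance < 0).any() or (self.std_importance < 0).any():
            raise ValueError("importances must be non-negative")


@dataclass(frozen=True)
class SelectionResult:
    selected_indices: tuple[int, ...]
    k: int


@dataclass(frozen=True)
class MLConfig:
    model: str = "svm"
    svm_C: float = 1.0
    svm_kernel: str = "rbf"
    knn_k: int = 5
    gb_estimators: int = 100
    gb_learning_rate: float = 1.0
    gb_max_depth: int = 1
    seed: int = 0

    def validate(self):
        if self.model not in ("svm", "knn", "gradient_boosting"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.svm_C, self.knn_k, self.gb_estimators,
               self.gb_learning_rate, self.gb_max_depth) <= 0:
            raise ValueError("hyperparameters must be positive")


def _check_features(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be n x d with n matching labels")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite entries")
    return X, y


def rf_feature_importance(
    X, y, n_trees: int = 100, seed: int = 0
) -> ImportanceVector:
    """Normalised mean-decrease-in-impurity importances plus across-tree sd."""
    X, y = _check_features(X, y)
    if len(X) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least two samples and both classes present")
    # all features considered at every split: importance should measure each
    # feature's impurity decrease, not its luck in the candidate subsampling
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features=None, random_state=seed
    ).fit(X, y)
    mean = forest.feature_importances_
    std = np.std([t.feature_importances_ for t in forest.estimators_], axis=0)
    return ImportanceVector(mean_importance=mean, std_importance=std)


def select_top_features(importances: ImportanceVector, k: int = 12) -> SelectionResult:
    """Indices of the k largest mean importances, descending; ties broken by
    lower index; k larger than d is clipped with a warning."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d = len(importances.mean_importance)
    if k > d:
        import warnings

        warnings.warn(f"k={k} exceeds feature count {d}; clipping to {d}")
        k = d
    order = np.argsort(-importances.mean_importance, kind="stable")
    return SelectionResult(selected_indices=tuple(int(i) for i in order[:k]), k=k)


class TopKImportanceSelector(BaseEstimator, TransformerMixin):
    """Transformer view of RF importance ranking + top-k column selection."""

    def __init__(self, k: int = 12, n_trees: int = 100, seed: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        imp = rf_feature_importance(X, y, self.n_trees, self.seed)
        self.importances_ = imp
        sel = select_top_features(imp, self.k)
        self.selected_indices_ = sel.selected_indices
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        return np.asarray(X)[:, list(self.selected_indices_)]


def train_ml_classifier(X, y, config: MLConfig | None = None) -> Pipeline:
    """Standardise (training statistics) then fit the configured model.

    The returned sklearn Pipeline exposes ``predict`` and a decision-score
    interface (``decision_function`` for SVM, ``predict_proba`` otherwise).
    """
    config = config or MLConfig()
    config.validate()
    X, y = _check_features(X, y)
    if config.model == "svm":
        model = SVC(C=config.svm_C, kernel=config.svm_kernel, gamma="scale",
                    random_state=config.seed)
    elif config.model == "knn":
        model = KNeighborsClassifier(n_neighbors=config.knn_k, metric="euclidean",
                                     weights="uniform")
    else:
        model = GradientBoostingClassifier(
            n_estimators=config.gb_estimators,
            learning_rate=config.gb_learning_rate,
            max_depth=config.gb_max_depth,
            random_state=config.seed,
        )
    pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
    return pipe.fit(X, y)


def _scores(pipe: Pipeline, X) -> np.ndarray:
    model = pipe.named_steps["model"]
    if hasattr(model, "decision_function"):
        return pipe.decision_function(X)
    return pipe.predict_proba(X)[:, 1]


def _evaluate(pipe, X_test, y_test, positive) -> ClassificationReport:
    pred = pipe.predict(X_test)
    cm = confusion_matrix(y_test == positive, pred == positive)
    report = classification_metrics(cm)
    try:
        curve = roc_auc((y_test == positive).astype(int), _scores(pipe, X_test))
        report.auc = curve.auc
    except ValueError:
        pass
    return report


def run_hybrid_experiment(
    X,
    y,
    k: int = 12,
    ml_configs: tuple[MLConfig, ...] | None = None,
    split_seed: int = 0,
    groups=None,
    test_fraction: float = 0.3,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """70-30 stratified split of feature rows; each model is trained and
    evaluated twice (all features / top-k selected on the training fold only).

    ``groups`` (e.g. subject ids) forces group-wise splitting; ``split``
    supplies explicit (train, test) row indices instead.  Returns
    {model: {"all": report, "selected": report, "selected_indices": (...)}}.
    """
    X, y = _check_features(X, y)
    if ml_configs is None:
        ml_configs = (
            MLConfig(model="gradient_boosting"),
            MLConfig(model="knn"),
            MLConfig(model="svm"),
        )
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    positive = classes[-1]
    if split is None:
        train_idx, test_idx = split_indices(y, test_fraction, groups=groups,
                                            seed=split_seed)
    else:
        train_idx, test_idx = (np.asarray(s, dtype=int) for s in split)
    Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]
    selector = TopKImportanceSelector(k=k, seed=split_seed).fit(Xtr, ytr)
    results: dict = {"selected_indices": selector.selected_indices_,
                     "importances": selector.importances_,
                     "train_index": train_idx, "test_index": test_idx}
    for cfg in ml_configs:
        full = train_ml_classifier(Xtr, ytr, cfg)
        sel = train_ml_classifier(selector.transform(Xtr), ytr, cfg)
        results[cfg.model] = {
            "all": _evaluate(full, Xte, yte, positive),
            "selected": _evaluate(sel, selector.transform(Xte), yte, positive),
        }
    return results
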