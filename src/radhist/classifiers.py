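"""The three classifiers, each emitting a continuous positive-class score.

* Gaussian naive Bayes (implemented here): class-conditional independent
  Gaussians per feature, posterior computed in log space, per-class standard
  deviations floored at 1e-9 so constant features cannot produce infinities.
* Random forest: 100 bootstrap trees, sqrt(p) candidate features per split,
  Gini criterion, grown to purity; the positive score is the fraction of
  trees voting positive (with pure leaves, averaged tree probabilities are
  exactly the vote fraction).  An optional locally-weighted voting mode
  weights each tree by its accuracy on the training instances nearest the
  query (30 by default); it is OFF by default.
* K-nearest neighbors with k = 9 and Euclidean distance; the score is the
  fraction of positive labels among the k nearest training samples.

Naive Bayes and KNN operate on features standardized by training-cohort
mean/sd (applied leakage-free to any evaluation cohort through the fitted
pipeline).  Labels may be strings ("ADENO"/"SQUAMOUS") or {0, 1}; the
positive class is ADENO / 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .simulate import POSITIVE_LABEL

__all__ = [
    "CLASSIFIER_KINDS", "GaussianNaiveBayes", "make_classifier",
    "train_classifier", "positive_scores", "encode_labels",
    "train_naive_bayes", "train_random_forest", "train_knn",
]

CLASSIFIER_KINDS = ("naive_bayes", "random_forest", "knn")
SD_FLOOR = 1e-9


def encode_labels(labels) -> np.ndarray:
    """Map labels to {0, 1} with ADENO (or 1/True) as the positive class."""
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_LABEL).astype(int)
    return y.astype(int)


class GaussianNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with Gaussian class-conditionals.

    The positive-class score is the exact posterior
    p(+|x) = 1 / (1 + exp(-logodds)) with
    logodds = log p(+)/p(-) + sum_i log N(x_i; mu_i+, sd_i+)/N(x_i; mu_i-, sd_i-),
    evaluated in log space.  Per-class sds are floored at ``sd_floor``.
    """

    def __init__(self, sd_floor: float = SD_FLOOR):
        self.sd_floor = sd_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = encode_labels(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        self.classes_ = np.array([0, 1])
        self.theta_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        self.sigma_ = np.stack([
            np.maximum(X[y == c].std(axis=0, ddof=0), self.sd_floor)
            for c in (0, 1)
        ])
        counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
        self.class_prior_ = counts / counts.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], 2))
        for c in (0, 1):
            z = (X - self.theta_[c]) / self.sigma_[c]
            jll[:, c] = (
                np.log(self.class_prior_[c])
                - 0.5 * np.sum(z ** 2 + np.log(2.0 * np.pi * self.sigma_[c] ** 2),
                               axis=1)
            )
        return jll

    def predict_proba(self, X):
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        probs = np.exp(jll)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class LocalAccuracyForest(ClassifierMixin, BaseEstimator):
    """Random forest with optional locally-weighted tree voting.

    With ``local_k`` set, each tree's vote on a query is weighted by the
    tree's accuracy on the ``local_k`` training instances nearest the query
    (Euclidean distance on the raw inputs); with ``local_k=None`` it is a
    plain vote-fraction forest.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, local_k: int | None = None):
        self.n_trees = n_trees
        self.seed = seed
        self.local_k = local_k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = encode_labels(y)
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError("each class needs at least 2 training samples")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, criterion="gini", max_features="sqrt",
            min_samples_leaf=1, bootstrap=True, random_state=self.seed,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.X_train_ = X
        self.y_train_ = y
        if self.local_k is not None:
            self.nn_ = NearestNeighbors(
                n_neighbors=min(self.local_k, len(y))).fit(X)
        return self

    @property
    def trees_(self):
        return self.forest_.estimators_

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if self.local_k is None:
            return self.forest_.predict_proba(X)
        votes = np.stack([t.predict(X) for t in self.forest_.estimators_])
        train_votes = np.stack(
            [t.predict(self.X_train_) for t in self.forest_.estimators_])
        _, idx = self.nn_.kneighbors(X)
        pos = np.empty(X.shape[0])
        for q in range(X.shape[0]):
            acc = (train_votes[:, idx[q]] == self.y_train_[idx[q]]).mean(axis=1)
            if acc.sum() == 0:
                acc = np.ones_like(acc)
            pos[q] = np.sum(acc * votes[:, q]) / acc.sum()
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_classifier(kind: str, seed: int = 0, *, n_trees: int = 100, k: int = 9,
                    rf_local_k: int | None = None):
    """Unfitted estimator (a Pipeline where standardization is required)."""
    if kind == "naive_bayes":
        return Pipeline([("scale", StandardScaler()),
                         ("model", GaussianNaiveBayes())])
    if kind == "random_forest":
        return LocalAccuracyForest(n_trees=n_trees, seed=seed, local_k=rf_local_k)
    if kind == "knn":
        return Pipeline([("scale", StandardScaler()),
                         ("model", KNeighborsClassifier(n_neighbors=k))])
    raise ValueError(f"unknown classifier kind {kind!r}; one of {CLASSIFIER_KINDS}")


def train_classifier(X, y, kind: str, seed: int = 0, **kwargs):
    """Fit one of the three classifiers on a feature frame.

    KNN requires at least k training samples; the others need both classes
    with >= 2 members.
    """
    X = pd.DataFrame(X)
    y = encode_labels(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = make_classifier(kind, seed, **kwargs)
    if kind == "knn":
        n_neighbors = model.named_steps["model"].n_neighbors
        if len(y) < n_neighbors:
            raise ValueError(f"KNN needs at least k={n_neighbors} training samples")
    model.fit(X.to_numpy(dtype=float), y)
    model.feature_names_ = list(map(str, X.columns))
    return model


def positive_scores(model, X) -> np.ndarray:
    """Positive-class (ADENO) scores in [0, 1] for a fitted model."""
    X = pd.DataFrame(X)
    expected = getattr(model, "feature_names_", None)
    if expected is not None:
        got = list(map(str, X.columns))
        if got != expected:
            raise ValueError("prediction features differ from training features")
    proba = model.predict_proba(X.to_numpy(dtype=float))
    classes = getattr(model, "classes_", None)
    if classes is None:
        classes = model.named_steps["model"].classes_
    return proba[:, list(classes).index(1)]


def train_naive_bayes(X, y):
    return train_classifier(X, y, "naive_bayes")


def train_random_forest(X, y, n_trees: int = 100, seed: int = 0,
                        local_k: int | None = None):
    return train_classifier(X, y, "random_forest", seed,
                            n_trees=n_trees, rf_local_k=local_k)


def train_knn(X, y, k: int = 9):
    return train_classifier(X, y, "knn", k=k)
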