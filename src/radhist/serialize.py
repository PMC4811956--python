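"""Versioned JSON serialization of trained models.

Every container carries ``format`` and ``version`` keys plus the classifier
kind, feature names and any standardization statistics.  Random-forest trees
are stored as nested node records; loading returns a :class:`LoadedModel`
that replays predictions from the stored records (bit-identical scores for
naive Bayes and the forest; KNN re-runs the neighbor search on the stored
training matrix).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classifiers import GaussianNaiveBayes, LocalAccuracyForest

__all__ = ["save_model", "load_model", "LoadedModel"]

FORMAT = "radhist-model"
VERSION = 1


def _tree_to_records(tree) -> dict:
    t = tree.tree_
    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            counts = t.value[i][0]
            return {"leaf": True, "value": [float(v) for v in counts]}
        return {
            "leaf": False,
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(int(t.children_left[i])),
            "right": node(int(t.children_right[i])),
        }
    return node(0)


def _predict_record(node: dict, x: np.ndarray) -> np.ndarray:
    while not node["leaf"]:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    v = np.asarray(node["value"], dtype=float)
    return v / v.sum()


def save_model(model, path) -> None:
    """Serialize a model trained by :func:`radhist.classifiers.train_classifier`."""
    payload: dict = {"format": FORMAT, "version": VERSION,
                     "feature_names": getattr(model, "feature_names_", None)}
    est = model
    if hasattr(model, "named_steps"):
        scaler = model.named_steps["scale"]
        payload["scaler"] = {"mean": scaler.mean_.tolist(),
                             "scale": scaler.scale_.tolist()}
        est = model.named_steps["model"]
    if isinstance(est, GaussianNaiveBayes):
        payload["kind"] = "naive_bayes"
        payload["model"] = {
            "theta": est.theta_.tolist(), "sigma": est.sigma_.tolist(),
            "prior": est.class_prior_.tolist(), "sd_floor": est.sd_floor,
        }
    elif isinstance(est, LocalAccuracyForest):
        payload["kind"] = "random_forest"
        payload["model"] = {
            "trees": [_tree_to_records(t) for t in est.trees_],
            "classes": est.classes_.tolist(),
        }
    elif est.__class__.__name__ == "KNeighborsClassifier":
        payload["kind"] = "knn"
        payload["model"] = {
            "k": int(est.n_neighbors),
            "X": est._fit_X.tolist(),
            "y": np.asarray(est._y).tolist(),
        }
    else:
        raise TypeError(f"cannot serialize estimator {est!r}")
    Path(path).write_text(json.dumps(payload))


class LoadedModel:
    """A deserialized model; exposes predict_proba / feature_names_."""

    def __init__(self, payload: dict):
        if payload.get("format") != FORMAT:
            raise ValueError("not a radhist model file")
        self.kind = payload["kind"]
        self.feature_names_ = payload.get("feature_names")
        self._scaler = payload.get("scaler")
        self._model = payload["model"]
        self.classes_ = np.array([0, 1])

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            return X
        return (X - np.asarray(self._scaler["mean"])) / np.asarray(self._scaler["scale"])

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "naive_bayes":
            nb = GaussianNaiveBayes(sd_floor=self._model["sd_floor"])
            nb.theta_ = np.asarray(self._model["theta"])
            nb.sigma_ = np.asarray(self._model["sigma"])
            nb.class_prior_ = np.asarray(self._model["prior"])
            nb.classes_ = self.classes_
            return nb.predict_proba(self._scaled(X))
        if self.kind == "random_forest":
            probs = np.stack([
                np.stack([_predict_record(tree, x) for tree in self._model["trees"]]).mean(axis=0)
                for x in X
            ])
            return probs
        if self.kind == "knn":
            Xs = self._scaled(X)
            train = np.asarray(self._model["X"])
            y = np.asarray(self._model["y"])
            k = self._model["k"]
            pos = np.empty(len(Xs))
            for q, x in enumerate(Xs):
                d = np.sqrt(((train - x) ** 2).sum(axis=1))
                near = np.lexsort((np.arange(len(d)), d))[:k]
                pos[q] = y[near].mean()
            return np.column_stack([1.0 - pos, pos])
        raise ValueError(f"unknown kind {self.kind!r}")

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def load_model(path) -> LoadedModel:
    return LoadedModel(json.loads(Path(path).read_text()))
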