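"""Classifier adapters: five algorithm families behind one contract.

The harness treats the algorithm as a categorical factor with five levels:
gradient-boosted trees (XGBoost), Gaussian naive Bayes (NB), RBF-kernel
support vector machine (SVM), a backpropagation multilayer perceptron (NN),
and a probabilistic neural network (PNN).  The first four delegate to
xgboost / scikit-learn with library defaults (no tuning -- the benchmark
compares algorithms as shipped); the PNN is a Parzen/Gaussian-kernel
classifier implemented here: the class score of a query is the log of the
mean Gaussian kernel density of that class's training points at the query,
with a single shared bandwidth (default: median pairwise training distance
divided by sqrt(K)).

Every adapter returns a :class:`~qsarbench.metrics.PredictionSet` whose
predicted label is the argmax of its score row, and is deterministic given
(spec, data, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import logsumexp
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import InputError, PredictionSet
from .synthetic import DescriptorTable

ALGORITHM_NAMES: tuple[str, ...] = ("XGBoost", "NB", "SVM", "NN", "PNN")


class SchemaError(ValueError):
    """Train/eval descriptor column mismatch."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """One factor level of the ML factor: a named algorithm plus optional
    settings passed through opaquely to the underlying implementation."""

    name: str
    settings: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise InputError(f"unknown algorithm {self.name!r}; "
                             f"choose from {ALGORITHM_NAMES}")

    def with_seed(self, seed: int) -> "AlgorithmSpec":
        return AlgorithmSpec(self.name, dict(self.settings), int(seed))


class ParzenPNN:
    """Probabilistic neural network as a Parzen-window classifier.

    Class score of query q: ``log mean_i N(q; x_i, sigma^2 I)`` over training
    points x_i of that class (log-density up to the shared Gaussian
    normalization constant, which cancels across classes).  ``bandwidth=None``
    uses median pairwise training distance / sqrt(K).
    """

    def __init__(self, bandwidth: float | None = None):
        self.bandwidth = bandwidth

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ParzenPNN":
        self.classes_ = np.unique(y)
        self._groups = [x[y == c] for c in self.classes_]
        if self.bandwidth is None:
            d = pdist(x) if len(x) <= 1500 else pdist(x[:: max(1, len(x) // 1500)])
            med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
            self.bandwidth_ = med / np.sqrt(len(self.classes_))
        else:
            self.bandwidth_ = float(self.bandwidth)
        return self

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        s2 = 2.0 * self.bandwidth_ ** 2
        cols = [
            logsumexp(-cdist(x, g, "sqeuclidean") / s2, axis=1) - np.log(len(g))
            for g in self._groups
        ]
        return np.column_stack(cols)

    # sklearn-ish aliases so the dispatch below stays uniform
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.score_samples(x)


def _build_model(spec: AlgorithmSpec):
    s = dict(spec.settings)
    if spec.name == "XGBoost":
        return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0, **s)
    if spec.name == "NB":
        return GaussianNB(**s)
    if spec.name == "SVM":
        s.setdefault("kernel", "rbf")
        return SVC(probability=True, random_state=spec.seed, **s)
    if spec.name == "NN":
        return MLPClassifier(random_state=spec.seed, **s)
    if spec.name == "PNN":
        return ParzenPNN(**s)
    raise InputError(f"unknown algorithm {spec.name!r}")  # pragma: no cover


def train_and_score(spec: AlgorithmSpec, train: DescriptorTable,
                    eval_table: DescriptorTable) -> PredictionSet:
    """Fit the named algorithm on ``train`` and score ``eval_table``.

    Returns predicted labels and an N x K score matrix in sorted-class
    column order; the predicted label is always the argmax of the score row.
    """
    if list(train.descriptor_names) != list(eval_table.descriptor_names):
        raise SchemaError("train and eval descriptor columns differ")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise InputError("training set must contain at least 2 classes")

    model = _build_model(spec)
    if spec.name == "XGBoost":
        # xgboost wants integer-coded targets
        code = {c: i for i, c in enumerate(classes.tolist())}
        y = np.array([code[v] for v in train.labels.tolist()])
        model.fit(train.values, y)
        model_classes = classes  # proba columns follow the integer coding
        scores = model.predict_proba(eval_table.values)
    else:
        model.fit(train.values, train.labels)
        model_classes = np.asarray(model.classes_)
        scores = model.predict_proba(eval_table.values)

    # align score columns to the sorted class order
    col = {c: j for j, c in enumerate(model_classes.tolist())}
    scores = scores[:, [col[c] for c in classes.tolist()]]
    predicted = classes[np.argmax(scores, axis=1)]

    return PredictionSet(
        true_labels=eval_table.labels,
        predicted_labels=predicted,
        class_scores=scores,
        classes=classes,
    )


__all__ = [
    "ALGORITHM_NAMES",
    "AlgorithmSpec",
    "ParzenPNN",
    "SchemaError",
    "train_and_score",
]
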