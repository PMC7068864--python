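"""Classical classifiers (k-NN, RBF-SVM) over 12-feature vectors.

Both classifiers emit a label plus a continuous malignancy score so ROC and
precision-recall analysis applies uniformly: the k-NN score is the fraction
of malignant neighbours among the k nearest; the SVM score is the signed
decision-function value oriented so larger means more malignant.

The k-NN neighbour search and vote are written out explicitly because the
contract fixes the tie-breaking rule (toward the single nearest neighbour's
label); the SVM optimisation is delegated to scikit-learn's SVC — only its
input/output contract is owned here.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .errors import (DegenerateTrainingError, DimensionError, ParameterError)
from .features import N_FEATURES, NormalizationParams, apply_normalizer
from .synthgen import BENIGN, MALIGNANT

CLASS_ORDER = (BENIGN, MALIGNANT)  # malignant is the positive class


def _encode_labels(labels) -> np.ndarray:
    labels = list(labels)
    bad = set(labels) - set(CLASS_ORDER)
    if bad:
        raise ParameterError(f"unknown labels {bad}")
    return np.array([CLASS_ORDER.index(l) for l in labels], dtype=int)


@dataclass
class TrainedModel:
    """A fitted classical model plus the normalization it was trained with."""

    kind: str  # "knn" | "svm"
    X: np.ndarray  # normalized training matrix (n, 12)
    y: np.ndarray  # encoded labels (0=benign, 1=malignant)
    normalization: NormalizationParams | None = None
    k: int = 5
    svc: SVC | None = None

    def __post_init__(self):
        if self.kind not in ("knn", "svm"):
            raise ParameterError(f"unknown model kind {self.kind!r}")
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise DimensionError(
                f"training matrix must be (n, {N_FEATURES})")

    def _check_vector(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != N_FEATURES:
            raise DimensionError(
                f"feature vector length {x.shape[0]} != {N_FEATURES}")
        if self.normalization is not None:
            x = apply_normalizer(x, self.normalization)
        return x

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise ParameterError(f"{path} does not hold a TrainedModel")
        return model


def knn_fit(X: np.ndarray, labels, k: int = 5,
            normalization: NormalizationParams | None = None) -> TrainedModel:
    """Store the (normalized) training set for k-NN prediction."""
    X = np.asarray(X, dtype=float)
    y = _encode_labels(labels)
    if k < 1 or k > len(X):
        raise ParameterError(f"k={k} outside [1, {len(X)}]")
    if normalization is not None:
        X = apply_normalizer(X, normalization)
    return TrainedModel(kind="knn", X=X, y=y, normalization=normalization, k=k)


def knn_predict(model: TrainedModel, x: np.ndarray) -> tuple[str, float]:
    """Majority vote among the k nearest training vectors.

    Score = fraction of malignant neighbours.  A tied vote (even k) goes to
    the single nearest neighbour's label.  Neighbour rank ties at equal
    distance resolve to the lower training-row index, which keeps the
    prediction independent of training-row order up to exact duplicates.
    """
    if model.kind != "knn":
        raise ParameterError("model is not a k-NN model")
    x = model._check_vector(x)
    d = np.linalg.norm(model.X - x, axis=1)
    order = np.argsort(d, kind="stable")[:model.k]
    votes = model.y[order]
    score = float(votes.mean())
    if score > 0.5:
        label_idx = 1
    elif score < 0.5:
        label_idx = 0
    else:
        label_idx = int(votes[0])  # tie -> nearest neighbour's label
    return CLASS_ORDER[label_idx], score


def svm_fit(X: np.ndarray, labels, C: float = 1.0, gamma="scale",
            normalization: NormalizationParams | None = None,
            seed: int = 0) -> TrainedModel:
    """Fit an RBF-kernel SVM (benign vs malignant).

    Default ``gamma='scale'`` is 1 / (12 * Var(X)); the optimizer is
    scikit-learn's SVC, fully determined by data, hyperparameters and seed.
    """
    X = np.asarray(X, dtype=float)
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training set contains a single class")
    if normalization is not None:
        X = apply_normalizer(X, normalization)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    svc.fit(X, y)
    return TrainedModel(kind="svm", X=X, y=y, normalization=normalization,
                        svc=svc)


def svm_predict(model: TrainedModel, x: np.ndarray) -> tuple[str, float]:
    """Label from the decision-function sign; score = signed margin
    (positive toward malignant)."""
    if model.kind != "svm" or model.svc is None:
        raise ParameterError("model is not a fitted SVM model")
    x = model._check_vector(x)
    score = float(model.svc.decision_function(x[None, :])[0])
    return CLASS_ORDER[int(score > 0)], score


def predict(model: TrainedModel, x: np.ndarray) -> tuple[str, float]:
    """Dispatch to the model kind's predictor."""
    return knn_predict(model, x) if model.kind == "knn" else svm_predict(model, x)


def predict_batch(model: TrainedModel, X: np.ndarray
                  ) -> tuple[list[str], np.ndarray]:
    """Vector of (label, score) predictions for a feature matrix."""
    labels, scores = [], []
    for row in np.atleast_2d(np.asarray(X, dtype=float)):
        lab, sc = predict(model, row)
        labels.append(lab)
        scores.append(sc)
    return labels, np.asarray(scores)
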