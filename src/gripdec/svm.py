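"""Linear one-vs-rest SVM on DTW-aligned, fixed-length feature vectors.

No hyperparameter search is performed; the box constraint defaults to the
SVM-light heuristic C = n (sum_i x_i . x_i)^-1, i.e. the reciprocal of the
mean squared feature norm, which makes the regularization scale-aware.
Multi-class decisions take the argmax of the per-class (uncalibrated)
decision values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

#: Convergence tolerance of the underlying quadratic-program solver.
SOLVER_TOL = 1e-6


def default_C(features: np.ndarray) -> float:
    """SVM-light default box constraint: reciprocal mean squared row norm."""
    features = np.asarray(features, dtype=float)
    sq = np.einsum("ij,ij->i", features, features)
    total = sq.sum()
    if total == 0:
        raise ValueError("all-zero feature matrix: default C undefined")
    return float(len(features) / total)


@dataclass
class OvrSvmModel:
    """One linear soft-margin binary SVM per class; argmax-decision OvR."""

    classes: list[str]
    C: float
    weights: np.ndarray = field(repr=False)   # (n_classes, d)
    biases: np.ndarray = field(repr=False)    # (n_classes,)

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {features.shape[1]} != {self.n_features}")
        return features @ self.weights.T + self.biases

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "classes": self.classes,
            "C": self.C,
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
        }))

    @classmethod
    def load(cls, path: str | Path) -> "OvrSvmModel":
        obj = json.loads(Path(path).read_text())
        return cls(classes=obj["classes"], C=obj["C"],
                   weights=np.array(obj["weights"]),
                   biases=np.array(obj["biases"]))


def train(features: np.ndarray, labels: np.ndarray,
          C: float | None = None) -> OvrSvmModel:
    """Fit one class-vs-rest linear SVM per class.

    ``C`` defaults to :func:`default_C` of the training features.  The
    problem is convex, so the fit is deterministic up to solver tolerance.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if C is None:
        C = default_C(features)
    weights = np.empty((len(classes), features.shape[1]))
    biases = np.empty(len(classes))
    for k, cls in enumerate(classes):
        y = np.where(labels == cls, 1.0, -1.0)
        clf = SVC(kernel="linear", C=C, tol=SOLVER_TOL)
        clf.fit(features, y)
        # libsvm orients the hyperplane by first-seen label; flip so that
        # positive decision values mean "this class"
        sign = clf.classes_[1]
        weights[k] = sign * clf.coef_.ravel()
        biases[k] = sign * clf.intercept_[0]
    return OvrSvmModel(classes=classes, C=float(C),
                       weights=weights, biases=biases)


def fit_predict_gram(gram_train: np.ndarray, labels: np.ndarray,
                     gram_test: np.ndarray, C: float | None = None,
                     ) -> np.ndarray:
    """OvR linear SVM from precomputed Gram matrices; returns test labels.

    Solves the same dual problem as :func:`train` (identical decisions up to
    solver tolerance) but reuses inner products across refits, which makes
    repeated relabelling — e.g. a permutation test on fixed features — cheap.
    ``C`` defaults to the SVM-light heuristic n / trace(gram_train).
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if C is None:
        C = float(len(gram_train) / np.trace(gram_train))
    dv = np.empty((len(gram_test), len(classes)))
    for k, cls in enumerate(classes):
        y = np.where(labels == cls, 1.0, -1.0)
        clf = SVC(kernel="precomputed", C=C, tol=SOLVER_TOL)
        clf.fit(gram_train, y)
        dv[:, k] = clf.classes_[1] * clf.decision_function(gram_test)
    idx = np.argmax(dv, axis=1)
    return np.array([classes[i] for i in idx])


def predict(model: OvrSvmModel, features: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels by maximal decision value (ties: first class in order).

    Returns (labels, decision value matrix of shape n x n_classes).
    """
    dv = model.decision_values(features)
    idx = np.argmax(dv, axis=1)
    return np.array([model.classes[i] for i in idx]), dv
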