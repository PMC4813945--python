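"""Pluggable supervised base classifiers for the M-training ensemble.

Four kinds are provided:

``svm_rbf``
    Support vector machine with an RBF kernel (the default base learner),
    at the study's tuned hyperparameters: kernel width gamma = 0.2749 and
    penalty C = 0.4848.  Multi-class handling is one-vs-one with majority
    aggregation (libsvm's native scheme).
``plsda``
    Partial least squares discriminant analysis: PLS regression onto
    one-hot class indicators, predicting by argmax of the fitted
    response.  Default 5 latent variables (clamped to the feature
    dimension when the data are narrower).
``rbf_network``
    A radial-basis-function network trained by greedy incremental center
    selection until a goal training MSE is reached (defaults: goal MSE
    0.4329, spread 0.0176).
``nearest_centroid``
    Euclidean nearest class centroid; trivially deterministic, used for
    fast exact tests.

``svm_rbf`` and ``rbf_network`` standardize features (training-pool mean
and variance) inside ``fit`` because RBF kernels at a fixed width are
scale sensitive; zero-variance features are left unscaled rather than
failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import LabeledSet

__all__ = ["ClassifierSpec", "make_classifier", "fit_classifier", "predict_labels",
           "PLSDAClassifier", "RBFNetworkClassifier", "DEFAULT_SPEC"]

_KINDS = ("svm_rbf", "plsda", "rbf_network", "nearest_centroid")

#: Tuned hyperparameters as printed for each classifier family.
_DEFAULT_HYPER: dict[str, dict[str, float]] = {
    "svm_rbf": {"kernel_width": 0.2749, "penalty": 0.4848},
    "plsda": {"latent_variables": 5},
    "rbf_network": {"goal_mse": 0.4329, "spread": 0.0176},
    "nearest_centroid": {},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Serializable description of a base classifier."""

    kind: str = "svm_rbf"
    hyperparameters: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {_KINDS}")
        merged = dict(_DEFAULT_HYPER[self.kind])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        for k, v in merged.items():
            if v <= 0:
                raise ValueError(f"hyperparameter {k} must be positive, got {v}")
        object.__setattr__(self, "hyperparameters", merged)

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, **self.hyperparameters, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ClassifierSpec":
        d = dict(d)
        kind = d.pop("kind")
        seed = int(d.pop("seed", 0))
        return cls(kind=kind, hyperparameters=d, seed=seed)


DEFAULT_SPEC = ClassifierSpec("svm_rbf")


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: PLS2 regression on one-hot class indicators, argmax decision.

    Ties pick the lowest label in sorted label order.  ``n_components``
    is clamped to the feature dimension at fit time (PLS cannot extract
    more latent variables than features).
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("PLSDAClassifier requires at least 2 classes")
        Y = np.eye(len(self.classes_))[y_idx]
        k = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        if k < self.n_components:
            warnings.warn(
                f"n_components clamped from {self.n_components} to {k} "
                f"(feature dimension {X.shape[1]})", UserWarning, stacklevel=2)
        self._pls = PLSRegression(n_components=k, scale=True)
        self._pls.fit(X, Y)
        return self

    def predict(self, X):
        check_is_fitted(self, "_pls")
        X = validate_data(self, X, reset=False)
        scores = self._pls.predict(X)
        # argmax takes the first (lowest sorted label) maximum on ties
        return self.classes_[np.argmax(scores, axis=1)]


class RBFNetworkClassifier(ClassifierMixin, BaseEstimator):
    """RBF network with greedy incremental center selection.

    Centers are training points, added one at a time (the candidate that
    most reduces the one-hot regression residual, ties to the lowest
    index) until the training MSE falls below ``goal_mse`` or
    ``max_neurons`` centers are placed.  Hidden activations are Gaussian,
    exp(-||x - c||^2 / (2 * spread^2)) on standardized features; output
    weights are the least-squares solution.
    """

    def __init__(self, goal_mse: float = 0.4329, spread: float = 0.0176,
                 max_neurons: int = 60):
        self.goal_mse = goal_mse
        self.spread = spread
        self.max_neurons = max_neurons

    def _activations(self, X, centers):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.spread ** 2))

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("RBFNetworkClassifier requires at least 2 classes")
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        Y = np.eye(len(self.classes_))[y_idx]
        n = len(Xs)
        cap = min(self.max_neurons, n)

        # Orthogonal least squares: greedily add the candidate center whose
        # activation column (orthogonalized against the selected basis)
        # explains the most residual one-hot variance; lowest index on ties.
        A = self._activations(Xs, Xs)          # candidate columns, (n, n)
        bias = np.ones(n) / np.sqrt(n)
        R = Y - np.outer(bias, bias @ Y)       # residual after bias
        A_perp = A - np.outer(bias, bias @ A)
        chosen: list[int] = []
        for _ in range(cap):
            norms2 = (A_perp ** 2).sum(axis=0)
            norms2[chosen] = 0.0
            proj = A_perp.T @ R                # (n_cand, n_classes)
            with np.errstate(divide="ignore", invalid="ignore"):
                reduction = np.where(norms2 > 1e-12,
                                     (proj ** 2).sum(axis=1) / norms2, 0.0)
            idx = int(np.argmax(reduction))
            if reduction[idx] <= 1e-12:
                break
            chosen.append(idx)
            q = A_perp[:, idx] / np.sqrt(norms2[idx])
            R = R - np.outer(q, q @ R)
            A_perp = A_perp - np.outer(q, q @ A_perp)
            if float((R ** 2).mean()) <= self.goal_mse:
                break
        if not chosen:  # degenerate activations: fall back to one center
            chosen = [0]
        H = np.column_stack([A[:, chosen], np.ones(n)])
        self.weights_, *_ = np.linalg.lstsq(H, Y, rcond=None)
        self.centers_ = Xs[chosen]
        self.train_mse_ = float(((Y - H @ self.weights_) ** 2).mean())
        return self

    def predict(self, X):
        check_is_fitted(self, "centers_")
        X = validate_data(self, X, reset=False)
        Xs = self._scaler.transform(X)
        H = np.column_stack([self._activations(Xs, self.centers_), np.ones(len(Xs))])
        scores = H @ self.weights_
        return self.classes_[np.argmax(scores, axis=1)]


def make_classifier(spec: ClassifierSpec | str | None = None) -> BaseEstimator:
    """Build an unfitted sklearn estimator from a :class:`ClassifierSpec`."""
    if spec is None:
        spec = DEFAULT_SPEC
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    hp = spec.hyperparameters
    if spec.kind == "svm_rbf":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", gamma=hp["kernel_width"], C=hp["penalty"],
                        random_state=spec.seed)),
        ])
    if spec.kind == "plsda":
        return PLSDAClassifier(n_components=int(hp["latent_variables"]))
    if spec.kind == "rbf_network":
        return RBFNetworkClassifier(goal_mse=hp["goal_mse"], spread=hp["spread"])
    return NearestCentroid()


def fit_classifier(spec: ClassifierSpec | BaseEstimator, train: LabeledSet) -> BaseEstimator:
    """Fit a fresh classifier on a labeled pool.

    ``spec`` may be a :class:`ClassifierSpec` (or kind string) or any
    sklearn classifier instance, which is cloned before fitting so the
    returned model's predict is a pure function of its training data.
    """
    if len(train) == 0:
        raise ValueError("cannot fit on an empty training set")
    if len(set(train.y.astype(str))) < 2:
        raise ValueError("training set contains a single class")
    model = (clone(spec) if isinstance(spec, BaseEstimator) else make_classifier(spec))
    model.fit(train.X, train.y.astype(str))
    return model


def predict_labels(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Predict one label per row, order preserved; empty input allowed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(X) == 0:
        return np.array([], dtype=object)
    return np.asarray(model.predict(X), dtype=object)
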