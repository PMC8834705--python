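"""Feature-vector classifiers for assessment and recognition.

Seven classifier kinds operate on DTW feature vectors: k-NN, SVM, naive
Bayes, logistic regression, decision tree, a back-propagation neural
network (BPNN) and a radial-basis-function network (RBFNN).  The classical
five are standard algorithms and are delegated to scikit-learn; the two
networks are implemented here because their form is pinned down exactly:

* BPNN: one hidden layer with tangent-sigmoid activation
  f(x) = 2/(1 + e^(-2x)) - 1 (algebraically tanh), softmax output,
  full-batch gradient descent on cross-entropy.
* RBFNN: one hidden layer of Gaussian units exp(-||x - c_i||^2 / d^2)
  with k-means centres and least-squares output weights.  (The exponent is
  negative; a positive exponent would diverge with distance.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "train",
    "predict",
    "tangent_sigmoid",
    "rbf_activations",
    "save_model",
    "load_model",
]

KINDS = ("knn", "svm", "nb", "logistic", "dtree", "bpnn", "rbfnn")

_DEFAULTS: dict[str, dict] = {
    "knn": {"k": 3},
    "svm": {"kernel": "rbf", "C": 1.0},
    "nb": {},
    "logistic": {"C": 1.0},
    "dtree": {"max_depth": None, "seed": 0},
    "bpnn": {"hidden_units": 16, "epochs": 500, "learning_rate": 0.01, "seed": 0},
    "rbfnn": {"n_centers": 8, "width": None, "seed": 0},
}


@dataclass
class ClassifierSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind '{self.kind}'")
        params = dict(_DEFAULTS[self.kind])
        unknown = set(self.hyperparams) - set(params)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        params.update(self.hyperparams)
        self.hyperparams = params


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    classes: np.ndarray
    parameters: dict
    n_features: int

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def tangent_sigmoid(x):
    """Hidden-layer activation f(x) = 2/(1 + e^(-2x)) - 1."""
    return 2.0 / (1.0 + np.exp(-2.0 * np.asarray(x, dtype=float))) - 1.0


def rbf_activations(X, centers, width: float) -> np.ndarray:
    """Gaussian radial-basis design matrix exp(-||x - c_i||^2 / d^2).

    The network output is these activations times the linear weights,
    f(x) = sum_i w_i exp(-||x - c_i||^2 / d^2).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    return np.exp(-cdist(X, centers) ** 2 / float(width) ** 2)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < 2:
        raise ValueError("at least two training samples required")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite (no NaN/inf)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels must contain at least two classes")
    return X, y, classes


def train(spec: ClassifierSpec, X, y) -> TrainedClassifier:
    """Fit a classifier of the requested kind; deterministic given the
    seed in the hyperparameters."""
    X, y, classes = _validate_xy(X, y)
    hp = spec.hyperparams
    params: dict

    if spec.kind == "knn":
        if not 1 <= hp["k"] <= len(X):
            raise ValueError("knn k out of range")
        params = {"X": X.copy(), "y": y.copy()}
    elif spec.kind == "svm":
        est = SVC(kernel=hp["kernel"], C=hp["C"])
        est.fit(X, y)
        params = {"est": est}
    elif spec.kind == "nb":
        est = GaussianNB()
        est.fit(X, y)
        params = {"est": est}
    elif spec.kind == "logistic":
        est = LogisticRegression(C=hp["C"], max_iter=1000)
        est.fit(X, y)
        params = {"est": est}
    elif spec.kind == "dtree":
        est = DecisionTreeClassifier(max_depth=hp["max_depth"], random_state=hp["seed"])
        est.fit(X, y)
        params = {"est": est}
    elif spec.kind == "bpnn":
        params = _train_bpnn(X, y, classes, hp)
    else:  # rbfnn
        params = _train_rbfnn(X, y, classes, hp)

    return TrainedClassifier(spec=spec, classes=classes, parameters=params, n_features=X.shape[1])


def _train_bpnn(X, y, classes, hp) -> dict:
    rng = np.random.default_rng(hp["seed"])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    n, d = Xs.shape
    h, C = hp["hidden_units"], len(classes)
    T = np.zeros((n, C))
    T[np.arange(n), np.searchsorted(classes, y)] = 1.0
    W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0, 1.0 / np.sqrt(h), size=(h, C))
    b2 = np.zeros(C)
    lr = hp["learning_rate"]
    losses = []
    for _ in range(hp["epochs"]):
        H = tangent_sigmoid(Xs @ W1 + b1)
        P = _softmax(H @ W2 + b2)
        losses.append(float(-np.log(np.clip(P[T == 1], 1e-300, None)).mean()))
        dZ2 = (P - T) / n
        dW2 = H.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dH = dZ2 @ W2.T
        dZ1 = dH * (1.0 - H**2)  # derivative of tangent sigmoid
        dW1 = Xs.T @ dZ1
        db1 = dZ1.sum(axis=0)
        W1 -= lr * dW1
        b1 -= lr * db1
        W2 -= lr * dW2
        b2 -= lr * db2
    return {"W1": W1, "b1": b1, "W2": W2, "b2": b2, "mu": mu, "sd": sd, "loss": losses}


def _train_rbfnn(X, y, classes, hp) -> dict:
    n_centers = min(hp["n_centers"], len(X))
    km = KMeans(n_clusters=n_centers, n_init=5, random_state=hp["seed"]).fit(X)
    centers = km.cluster_centers_
    d = hp["width"]
    if d is None:
        if n_centers > 1:
            pair = cdist(centers, centers)
            d = float(np.median(pair[np.triu_indices(n_centers, k=1)]))
        else:
            d = 1.0
        if d <= 0:
            d = 1.0
    Phi = rbf_activations(X, centers, d)
    T = np.zeros((len(X), len(classes)))
    T[np.arange(len(X)), np.searchsorted(classes, y)] = 1.0
    W, *_ = np.linalg.lstsq(Phi, T, rcond=None)
    return {"centers": centers, "width": d, "W": W}


def predict(model: TrainedClassifier, X) -> np.ndarray:
    """Predict one label per row of X (labels seen in training only)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, model.n_features) if X.size == 0 else X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.array([], dtype=model.classes.dtype)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    kind = model.spec.kind
    p = model.parameters
    if kind == "knn":
        return _predict_knn(model, X)
    if kind in ("svm", "nb", "logistic", "dtree"):
        return p["est"].predict(X)
    if kind == "bpnn":
        Xs = (X - p["mu"]) / p["sd"]
        H = tangent_sigmoid(Xs @ p["W1"] + p["b1"])
        scores = H @ p["W2"] + p["b2"]
        return model.classes[np.argmax(scores, axis=1)]
    # rbfnn
    Phi = rbf_activations(X, p["centers"], p["width"])
    return model.classes[np.argmax(Phi @ p["W"], axis=1)]


def _predict_knn(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Majority vote among the k nearest training points; vote ties are
    broken by smallest mean neighbour distance, then by lowest label."""
    p = model.parameters
    k = model.spec.hyperparams["k"]
    D = cdist(X, p["X"])
    out = []
    for row in D:
        nn = np.argsort(row, kind="stable")[:k]
        labels = p["y"][nn]
        dists = row[nn]
        cand = sorted(set(labels.tolist()))
        votes = {c: int((labels == c).sum()) for c in cand}
        best = max(votes.values())
        tied = [c for c in cand if votes[c] == best]
        if len(tied) > 1:
            means = {c: float(dists[labels == c].mean()) for c in tied}
            lo = min(means.values())
            tied = [c for c in tied if means[c] == lo]
        out.append(tied[0])
    return np.array(out, dtype=model.classes.dtype)


# ---------------------------------------------------------------------------
# persistence (bespoke network models only; versioned JSON container)

_FORMAT_VERSION = 1


def save_model(model: TrainedClassifier, path) -> None:
    """Serialise a bespoke (bpnn/rbfnn) model to a versioned JSON file."""
    if model.spec.kind not in ("bpnn", "rbfnn"):
        raise ValueError(
            "only bespoke network models (bpnn, rbfnn) support JSON persistence; "
            "scikit-learn-backed kinds are retrained per run"
        )
    payload = {
        "format_version": _FORMAT_VERSION,
        "kind": model.spec.kind,
        "hyperparams": {k: v for k, v in model.spec.hyperparams.items()},
        "classes": model.classes.tolist(),
        "n_features": model.n_features,
        "parameters": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in model.parameters.items()
            if k != "loss"
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model container version")
    params = {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
        for k, v in payload["parameters"].items()
    }
    return TrainedClassifier(
        spec=ClassifierSpec(payload["kind"], payload["hyperparams"]),
        classes=np.asarray(payload["classes"]),
        parameters=params,
        n_features=payload["n_features"],
    )
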