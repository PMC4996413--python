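"""Classifier suite and evaluation protocols.

Three classifier families evaluate candidate CpG panels: distance-
weighted k-nearest-neighbor (k = 1, 6, 12; vote weight 1/(d+ε)), a
CART-style classification tree with the Gini index as split criterion,
and a one-hidden-layer feed-forward neural network trained by classic
per-sample back-propagation with momentum (sigmoid hidden and output
units, squared-error on one-hot targets, learning rate 0.3, momentum
0.2, 1000 epochs, ⌊(F+C)/2⌋+1 hidden nodes).

Two evaluation protocols are provided: leave-one-out resampling on a
training set, and a single fit applied to an independent held-out set.
Both report total accuracy and per-class sensitivity from the pooled
confusion matrix.  Inputs are standardized per feature using training
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeClassifier

KNN_EPS = 1e-9


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str  # knn | tree | ann
    k: int = 12
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "tree", "ann"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.k}-nn" if self.kind == "knn" else self.kind


def hidden_nodes(n_features: int, n_classes: int) -> int:
    """⌊(F + C)/2⌋ + 1 hidden units."""
    return (n_features + n_classes) // 2 + 1


def knn_weighted_predict(train_X, train_y, query_X, k: int):
    """Distance-weighted k-NN: Euclidean distances, vote weight 1/(d+ε),
    predicted class = argmax of summed weights over the k nearest
    training points.  Vote ties are broken by the class of the single
    nearest neighbor."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_y = np.asarray(train_y)
    if k > len(train_X):
        raise ValueError(f"k={k} exceeds training-set size {len(train_X)}")
    classes, y_idx = np.unique(train_y, return_inverse=True)
    d = cdist(query_X, train_X)
    order = np.argsort(d, axis=1, kind="stable")
    nearest_k = order[:, :k]
    w = 1.0 / (np.take_along_axis(d, nearest_k, axis=1) + KNN_EPS)
    votes = np.zeros((len(query_X), len(classes)))
    for j in range(k):
        np.add.at(votes, (np.arange(len(query_X)), y_idx[nearest_k[:, j]]), w[:, j])
    best = votes.max(axis=1)
    tie = (votes == best[:, None]).sum(axis=1) > 1
    pred = votes.argmax(axis=1)
    pred[tie] = y_idx[order[tie, 0]]
    return classes[pred]


@dataclass
class TrainedModel:
    """Fitted classifier with the feature subset it was trained on."""

    spec: ClassifierSpec
    classes: np.ndarray
    feature_mask: np.ndarray | None = None
    _predict: callable = field(default=None, repr=False)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._predict(X)


def knn_fit(train_X, train_y, spec: ClassifierSpec, mask=None) -> TrainedModel:
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    return TrainedModel(
        spec=spec,
        classes=np.unique(train_y),
        feature_mask=mask,
        _predict=lambda X: knn_weighted_predict(train_X, train_y, X, spec.k),
    )


def gini_tree_fit(train_X, train_y, spec: ClassifierSpec, mask=None) -> TrainedModel:
    """CART binary tree, Gini impurity split criterion, thresholds at
    midpoints of sorted unique feature values, grown until nodes are
    pure or cannot be split; no pruning."""
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    if len(train_X) < 2:
        raise ValueError("tree needs at least 2 samples")
    tree = DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    tree.fit(train_X, train_y)
    return TrainedModel(
        spec=spec, classes=tree.classes_, feature_mask=mask, _predict=tree.predict
    )


@njit(cache=False)
def _ann_train(X, T, W1, b1, W2, b2, lr, mom, epochs):  # pragma: no cover - jitted
    n, F = X.shape
    H = W1.shape[1]
    C = W2.shape[1]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    for _ in range(epochs):
        for s in range(n):
            x = X[s]
            # forward
            h = 1.0 / (1.0 + np.exp(-(x @ W1 + b1)))
            o = 1.0 / (1.0 + np.exp(-(h @ W2 + b2)))
            # backward: squared error, sigmoid derivatives
            do = (o - T[s]) * o * (1.0 - o)
            dh = (do @ W2.T) * h * (1.0 - h)
            for i in range(H):
                for j in range(C):
                    vW2[i, j] = mom * vW2[i, j] - lr * h[i] * do[j]
                    W2[i, j] += vW2[i, j]
            for j in range(C):
                vb2[j] = mom * vb2[j] - lr * do[j]
                b2[j] += vb2[j]
            for i in range(F):
                for j in range(H):
                    vW1[i, j] = mom * vW1[i, j] - lr * x[i] * dh[j]
                    W1[i, j] += vW1[i, j]
            for j in range(H):
                vb1[j] = mom * vb1[j] - lr * dh[j]
                b1[j] += vb1[j]


def ann_fit(train_X, train_y, spec: ClassifierSpec, mask=None) -> TrainedModel:
    """One hidden sigmoid layer of ⌊(F+C)/2⌋+1 nodes, sigmoid outputs,
    one-hot targets, per-sample backprop with momentum for exactly
    ``spec.epochs`` epochs; small uniform seeded weight init; argmax
    output decision."""
    X = np.ascontiguousarray(np.atleast_2d(train_X), dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite input to ANN")
    y = np.asarray(train_y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, F = X.shape
    C = len(classes)
    H = hidden_nodes(F, C)
    T = np.zeros((n, C))
    T[np.arange(n), y_idx] = 1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    W1 = rng.uniform(-0.5, 0.5, size=(F, H))
    b1 = rng.uniform(-0.5, 0.5, size=H)
    W2 = rng.uniform(-0.5, 0.5, size=(H, C))
    b2 = rng.uniform(-0.5, 0.5, size=C)
    _ann_train(X, T, W1, b1, W2, b2, spec.learning_rate, spec.momentum, spec.epochs)

    def predict(Xq):
        h = 1.0 / (1.0 + np.exp(-(Xq @ W1 + b1)))
        o = 1.0 / (1.0 + np.exp(-(h @ W2 + b2)))
        return classes[o.argmax(axis=1)]

    return TrainedModel(spec=spec, classes=classes, feature_mask=mask, _predict=predict)


_FITTERS = {"knn": knn_fit, "tree": gini_tree_fit, "ann": ann_fit}


def fit_classifier(train_X, train_y, spec: ClassifierSpec, mask=None) -> TrainedModel:
    return _FITTERS[spec.kind](train_X, train_y, spec, mask=mask)


@dataclass(frozen=True)
class PerformanceReport:
    """Total accuracy (%) and per-class sensitivity (%) under one protocol."""

    protocol: str  # "LOO" | "independent"
    classifier: str
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows: true class, cols: predicted
    feature_set: str = ""

    @property
    def total_accuracy(self) -> float:
        total = self.confusion.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * np.trace(self.confusion) / total

    @property
    def sensitivities(self) -> dict[str, float]:
        out = {}
        for i, cls in enumerate(self.classes):
            row = self.confusion[i].sum()
            out[cls] = 100.0 * self.confusion[i, i] / row if row else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classifier": self.classifier,
            "feature_set": self.feature_set,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "total_accuracy": round(self.total_accuracy, 6),
            "sensitivity": {k: round(v, 6) for k, v in self.sensitivities.items()},
        }


def performance_metrics(confusion: np.ndarray) -> tuple[float, np.ndarray]:
    """(total accuracy %, per-class sensitivity % vector) from a
    confusion matrix with true classes on rows."""
    confusion = np.asarray(confusion)
    if confusion.size == 0:
        raise ValueError("empty confusion matrix")
    if (confusion < 0).any() or not np.issubdtype(confusion.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    total = confusion.sum()
    acc = 100.0 * np.trace(confusion) / total
    rows = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = 100.0 * np.diag(confusion) / rows
    return acc, sens


def _confusion(classes: np.ndarray, y_true, y_pred) -> np.ndarray:
    pos = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[pos[t], pos[p]] += 1
    return conf


class _Standardizer:
    """Per-feature mean/sd from training data only; constant features
    are left unscaled."""

    def fit(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X):
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.sd


def _apply_mask(X, mask):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mask is None:
        return X
    return X[:, np.asarray(mask, dtype=bool)]


def loo_evaluate(X, y, spec: ClassifierSpec, mask=None, feature_set: str = "") -> PerformanceReport:
    """Leave-one-out resampling: each sample predicted by a model
    trained on the remaining n−1, standardization refit per fold."""
    X = _apply_mask(X, mask)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("LOO needs at least 2 samples")
    classes = np.unique(y)
    preds = np.empty(n, dtype=classes.dtype)
    for i in range(n):
        keep = np.arange(n) != i
        scaler = _Standardizer().fit(X[keep])
        model = fit_classifier(scaler.transform(X[keep]), y[keep], spec)
        preds[i] = model.predict(scaler.transform(X[i : i + 1]))[0]
    conf = _confusion(classes, y, preds)
    return PerformanceReport(
        protocol="LOO",
        classifier=spec.name,
        classes=tuple(str(c) for c in classes),
        confusion=conf,
        feature_set=feature_set,
    )


def holdout_evaluate(
    train_X,
    train_y,
    test_X,
    test_y,
    spec: ClassifierSpec,
    mask=None,
    train_ids=None,
    test_ids=None,
    feature_set: str = "",
) -> PerformanceReport:
    """Single fit on the training set, single pass over the independent
    test set.  Train and test sample ids must be disjoint."""
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"train/test sample overlap: {sorted(overlap)[:5]}")
    Xtr = _apply_mask(train_X, mask)
    Xte = _apply_mask(test_X, mask)
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    classes = np.unique(np.concatenate([train_y, test_y]))
    scaler = _Standardizer().fit(Xtr)
    model = fit_classifier(scaler.transform(Xtr), train_y, spec)
    preds = model.predict(scaler.transform(Xte))
    conf = _confusion(classes, test_y, preds)
    return PerformanceReport(
        protocol="independent",
        classifier=spec.name,
        classes=tuple(str(c) for c in classes),
        confusion=conf,
        feature_set=feature_set,
    )


def default_suite(seed: int = 0) -> list[ClassifierSpec]:
    """The five classifiers of the study: 1-nn, 6-nn, 12-nn, Gini tree, ANN."""
    return [
        ClassifierSpec(kind="knn", k=1, seed=seed),
        ClassifierSpec(kind="knn", k=6, seed=seed),
        ClassifierSpec(kind="knn", k=12, seed=seed),
        ClassifierSpec(kind="tree", seed=seed),
        ClassifierSpec(kind="ann", seed=seed),
    ]
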