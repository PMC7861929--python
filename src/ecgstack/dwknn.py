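"""Distance-weighted k-nearest-neighbor classifier.

A lazy learner: ``fit`` stores the training data; ``predict`` finds the k
nearest rows by Euclidean distance and tallies one weight per neighbor into
its own label's bin, with weight 1/(distance + const). The argmax class
wins; ties break by the fixed class order N, S, V, F.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CLASS_ORDER = {"N": 0, "S": 1, "V": 2, "F": 3}


def _canonical_classes(labels: np.ndarray) -> tuple[str, ...]:
    uniq = [str(u) for u in np.unique(labels)]
    return tuple(sorted(uniq, key=lambda c: (_CLASS_ORDER.get(c, len(_CLASS_ORDER)), c)))


@dataclass
class DwknnModel:
    X: np.ndarray
    y: np.ndarray
    k: int
    const: float
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if not 1 <= self.k <= len(self.X):
            raise ValueError(f"k must be in [1, {len(self.X)}]")
        if self.const <= 0:
            raise ValueError("const must be positive")
        if not self.classes:
            self.classes = _canonical_classes(self.y)
        self._y_codes = np.array(
            [self.classes.index(str(v)) for v in self.y], dtype=int)


@dataclass(frozen=True)
class Prediction:
    label: str
    class_weights: dict[str, float]


def fit(X, y, k: int = 4, const: float = 1.0) -> DwknnModel:
    """Store the training set verbatim (no fitting computation)."""
    return DwknnModel(X=X, y=y, k=k, const=const)


def neighbor_weights(distances, const: float) -> np.ndarray:
    """w_i = 1/(d_i + const); strictly decreasing in distance."""
    distances = np.asarray(distances, dtype=float)
    if const <= 0:
        raise ValueError("const must be positive")
    if (distances < 0).any():
        raise ValueError("distances must be nonnegative")
    return 1.0 / (distances + const)


def _vote(model: DwknnModel, dist_row: np.ndarray) -> tuple[int, np.ndarray]:
    # stable argsort: equal distances at the k-th slot resolve to the
    # lexicographically-first training index
    order = np.argsort(dist_row, kind="stable")[: model.k]
    w = neighbor_weights(dist_row[order], model.const)
    tally = np.zeros(len(model.classes))
    np.add.at(tally, model._y_codes[order], w)
    return int(np.argmax(tally)), tally


def predict(model: DwknnModel, x) -> Prediction:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.X.shape[1]:
        raise ValueError("query dimension mismatch")
    d = np.sqrt(np.maximum(((model.X - x) ** 2).sum(axis=1), 0.0))
    code, tally = _vote(model, d)
    return Prediction(label=model.classes[code],
                      class_weights={c: float(t) for c, t in zip(model.classes, tally)})


def predict_batch(model: DwknnModel, X_query, block_size: int = 1024) -> np.ndarray:
    """Row-wise predict, computed in blocks of pairwise distances."""
    X_query = np.asarray(X_query, dtype=float)
    if X_query.ndim != 2:
        X_query = X_query.reshape(-1, model.X.shape[1])
    if X_query.shape[0] == 0:
        return np.array([], dtype=model.y.dtype)
    if X_query.shape[1] != model.X.shape[1]:
        raise ValueError("query dimension mismatch")
    train_sq = (model.X ** 2).sum(axis=1)
    out = np.empty(len(X_query), dtype=object)
    for start in range(0, len(X_query), block_size):
        B = X_query[start : start + block_size]
        d2 = train_sq[None, :] - 2.0 * B @ model.X.T + (B ** 2).sum(axis=1)[:, None]
        d = np.sqrt(np.maximum(d2, 0.0))
        for i in range(len(B)):
            code, _ = _vote(model, d[i])
            out[start + i] = model.classes[code]
    return out.astype(str)
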