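"""Stacked ensemble of distance-weighted KNN classifiers.

First layer: S base DWKNN configurations, each trained with stratified
ten-fold cross-training. Out-of-fold predictions (one-hot encoded, one block
per base configuration) form the meta training set; the meta-classifier is
itself a DWKNN. At test time every fold model of a configuration predicts,
the ten one-hot outputs are averaged uniformly, and the concatenated blocks
feed the meta-classifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dwknn
from .dwknn import DwknnModel, _canonical_classes


@dataclass
class StackingConfig:
    base_params: tuple[tuple[int, float], ...] = ((3, 1.0), (4, 1.0), (5, 1.0), (6, 1.0))
    n_folds: int = 10
    seed: int = 0
    meta_params: tuple[int, float] = (4, 1.0)

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.base_params:
            raise ValueError("need at least one base configuration")


@dataclass
class StackingModel:
    fold_models: list[list[DwknnModel]]  # [fold][base_config]
    meta_model: DwknnModel
    fold_assignment: np.ndarray          # per-training-row fold id
    classes: tuple[str, ...]
    config: StackingConfig


def stratified_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def one_hot(labels, classes: tuple[str, ...]) -> np.ndarray:
    labels = np.asarray(labels)
    out = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        out[labels == c, j] = 1.0
    return out


def fit_stacking(X, y, cfg: StackingConfig | None = None) -> StackingModel:
    cfg = cfg or StackingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < cfg.n_folds:
        raise ValueError("fewer training rows than folds")
    classes = _canonical_classes(y)
    folds = stratified_folds(y, cfg.n_folds, cfg.seed)
    if np.bincount(folds, minlength=cfg.n_folds).min() == 0:
        raise ValueError("empty fold; reduce n_folds")

    n, S = len(X), len(cfg.base_params)
    fold_models: list[list[DwknnModel]] = []
    meta_X = np.zeros((n, S * len(classes)))
    for f in range(cfg.n_folds):
        in_fold = folds == f
        train_X, train_y = X[~in_fold], y[~in_fold]
        models_f: list[DwknnModel] = []
        for s, (k, const) in enumerate(cfg.base_params):
            m = dwknn.fit(train_X, train_y, k=min(k, len(train_X)), const=const)
            models_f.append(m)
            oof = dwknn.predict_batch(m, X[in_fold])
            meta_X[np.flatnonzero(in_fold), s * len(classes):(s + 1) * len(classes)] = \
                one_hot(oof, classes)
        fold_models.append(models_f)

    mk, mconst = cfg.meta_params
    meta = dwknn.fit(meta_X, y, k=min(mk, n), const=mconst)
    return StackingModel(fold_models=fold_models, meta_model=meta,
                         fold_assignment=folds, classes=classes, config=cfg)


def meta_features(model: StackingModel, X_test) -> np.ndarray:
    """Fold-averaged one-hot base predictions, one block per base config."""
    X_test = np.asarray(X_test, dtype=float)
    C = len(model.classes)
    S = len(model.config.base_params)
    out = np.zeros((len(X_test), S * C))
    for models_f in model.fold_models:
        for s, m in enumerate(models_f):
            pred = dwknn.predict_batch(m, X_test)
            out[:, s * C:(s + 1) * C] += one_hot(pred, model.classes)
    out /= len(model.fold_models)
    return out


def predict_stacking(model: StackingModel, X_test) -> np.ndarray:
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        return np.array([], dtype=str)
    return dwknn.predict_batch(model.meta_model, meta_features(model, X_test))
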