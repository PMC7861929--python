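"""End-to-end orchestration: signal -> beats -> features -> model -> metrics.

Also hosts the experiment harnesses (feature-combination sweep and K sweep),
which share one frozen dataset/split per seed so combinations are compared
without leakage.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dwknn, stacking
from .dataio import BeatAnnotation, EcgSignal, read_annotations, read_record, split_dataset
from .delineate import DelineateConfig, delineate_record
from .evaluate import (ConfusionMatrix, confusion_matrix, overall_accuracy,
                       report, round2)
from .features import (FeatureGroupSelection, Normalizer, apply_imputer,
                       build_feature_table, combine, fit_imputer)
from .preprocess import DenoiseConfig, denoise, segment_beats
from .stacking import StackingConfig
from .synth import SynthEcgConfig, balanced_class_sequence, synth_ecg

UNWEIGHTED_CONST = 1e9  # "knn" = distance weighting flattened to uniform


@dataclass
class RunConfig:
    # data source: a WFDB record + annotations, or a synthetic generator
    record_path: str | None = None
    annotation_path: str | None = None
    synthetic: bool = True
    n_beats: int = 400
    bpm: float = 72.0
    noise_sd: float = 0.0
    baseline_amp: float = 0.0
    class_weights: tuple[float, ...] = (0.55, 0.15, 0.2, 0.1)
    # stages
    denoise_cfg: DenoiseConfig = field(default_factory=DenoiseConfig)
    apply_denoise: bool = True
    selection: FeatureGroupSelection = field(default_factory=FeatureGroupSelection)
    classifier: str = "dwknn"  # knn | dwknn | stacking
    k: int = 4
    const: float = 1.0
    stacking_cfg: StackingConfig = field(default_factory=StackingConfig)
    train_frac: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in ("knn", "dwknn", "stacking"):
            raise ValueError("classifier must be knn, dwknn, or stacking")


@dataclass
class PreparedDataset:
    table: pd.DataFrame
    train_ids: np.ndarray
    test_ids: np.ndarray
    n_dropped: int


@dataclass
class PipelineResult:
    cm: ConfusionMatrix
    metrics: pd.DataFrame
    accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    n_train: int
    n_test: int


def _load_signal(cfg: RunConfig) -> tuple[EcgSignal, list[BeatAnnotation]]:
    if cfg.synthetic or cfg.record_path is None:
        seq = balanced_class_sequence(cfg.n_beats, seed=cfg.seed,
                                      weights=cfg.class_weights)
        sig, truth = synth_ecg(SynthEcgConfig(
            n_beats=cfg.n_beats, bpm=cfg.bpm, noise_sd=cfg.noise_sd,
            baseline_amp=cfg.baseline_amp, class_sequence=seq, seed=cfg.seed))
        return sig, truth.annotations()
    sig = read_record(cfg.record_path)
    ann_path = cfg.annotation_path or cfg.record_path + ".atr"
    return sig, read_annotations(ann_path)


def prepare_dataset(cfg: RunConfig) -> PreparedDataset:
    """Stages: load -> denoise -> segment -> delineate -> features -> split."""
    sig, anns = _load_signal(cfg)
    clean = denoise(sig, cfg.denoise_cfg) if cfg.apply_denoise else sig
    beats, n_dropped = segment_beats(clean, anns)
    r_list = [b.source[1] for b in beats]
    fids = delineate_record(clean, r_list)
    table = build_feature_table(beats, fids, clean.fs)
    split = split_dataset(table["label"].to_numpy(), cfg.train_frac, cfg.seed)
    return PreparedDataset(table=table, train_ids=split.train_ids,
                           test_ids=split.test_ids, n_dropped=n_dropped)


def _train_predict(cfg: RunConfig, X_train, y_train, X_test) -> np.ndarray:
    if cfg.classifier == "stacking":
        model = stacking.fit_stacking(X_train, y_train, cfg.stacking_cfg)
        return stacking.predict_stacking(model, X_test)
    const = UNWEIGHTED_CONST if cfg.classifier == "knn" else cfg.const
    model = dwknn.fit(X_train, y_train, k=min(cfg.k, len(X_train)), const=const)
    return dwknn.predict_batch(model, X_test)


def evaluate_selection(cfg: RunConfig, data: PreparedDataset,
                       sel: FeatureGroupSelection) -> PipelineResult:
    """Train/evaluate one feature selection on the frozen split."""
    X = combine(data.table, sel)
    y = data.table["label"].to_numpy()
    X_train, y_train = X[data.train_ids], y[data.train_ids]
    X_test, y_test = X[data.test_ids], y[data.test_ids]
    medians = fit_imputer(X_train)
    X_train = apply_imputer(medians, X_train)
    X_test = apply_imputer(medians, X_test)
    norm = Normalizer().fit(X_train)
    X_train, X_test = norm.transform(X_train), norm.transform(X_test)
    y_pred = _train_predict(cfg, X_train, y_train, X_test)
    classes = tuple(sorted(np.unique(y).tolist(),
                           key=lambda c: "NSVF".index(c) if c in "NSVF" else 9))
    cm = confusion_matrix(y_test, y_pred, classes)
    return PipelineResult(cm=cm, metrics=report(cm),
                          accuracy=overall_accuracy(cm),
                          y_true=y_test, y_pred=np.asarray(y_pred),
                          n_train=len(y_train), n_test=len(y_test))


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    data = prepare_dataset(cfg)
    return evaluate_selection(cfg, data, cfg.selection)


def write_artifacts(result: PipelineResult, out_dir: str) -> None:
    """Byte-stable report.json, confusion.csv, metrics.csv."""
    os.makedirs(out_dir, exist_ok=True)
    result.cm.to_csv(os.path.join(out_dir, "confusion.csv"))
    result.metrics.to_csv(os.path.join(out_dir, "metrics.csv"),
                          float_format="%.2f", index_label="class")
    payload = {
        "overall_accuracy": round2(result.accuracy),
        "n_train": result.n_train,
        "n_test": result.n_test,
        "confusion": result.cm.counts.tolist(),
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


ALL_GROUP_COMBOS: tuple[FeatureGroupSelection, ...] = tuple(
    FeatureGroupSelection(use_morph=m, use_inter=i, use_amp=a)
    for m, i, a in [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
)


def sweep_feature_combinations(cfg: RunConfig,
                               combos=ALL_GROUP_COMBOS) -> pd.DataFrame:
    """Accuracy per feature-group combination on one frozen split."""
    combos = list(combos)
    if not combos:
        raise ValueError("need at least one combination")
    data = prepare_dataset(cfg)
    rows = [{"combo": sel.name, "dims": len(sel.columns()),
             "acc": round2(evaluate_selection(cfg, data, sel).accuracy)}
            for sel in combos]
    return pd.DataFrame(rows)


def sweep_k(cfg: RunConfig, ks) -> pd.DataFrame:
    """Accuracy per neighbor count k on one frozen split."""
    ks = list(ks)
    if not ks:
        raise ValueError("need at least one k")
    data = prepare_dataset(cfg)
    rows = []
    for k in ks:
        cfg_k = RunConfig(**{**cfg.__dict__, "k": int(k)})
        rows.append({"k": int(k),
                     "acc": round2(evaluate_selection(cfg_k, data, cfg.selection).accuracy)})
    return pd.DataFrame(rows)
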