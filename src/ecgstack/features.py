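"""Feature extraction, feature-group combination, and min-max normalization.

Ten features per beat: the 235-sample morphology, three wave lengths
(P/QRS/T), four intervals (RR, PR, ST segment, QT), and two amplitudes
(R, T). Missing fiducials yield NaN features that are imputed with
training-set medians before classification.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delineate import Fiducials
from .preprocess import BEAT_LEN, Beat

MORPH_NAMES = tuple(f"morph_{i:03d}" for i in range(BEAT_LEN))
PQRST_NAMES = ("p_len", "qrs_len", "t_len")
INTERVAL_NAMES = ("rr_inter", "pr_inter", "st_seg", "qt_inter")
INTER_NAMES = PQRST_NAMES + INTERVAL_NAMES
AMP_NAMES = ("r_amp", "t_amp")
SCALAR_NAMES = INTER_NAMES + AMP_NAMES
FEATURE_NAMES = MORPH_NAMES + SCALAR_NAMES


@dataclass
class FeatureGroupSelection:
    """Which feature groups (and members) to stitch together.

    Order is frozen: Morph || Inter || Amp. ``pqrst`` in ``inter_members``
    toggles the three wave lengths as one unit.
    """

    use_morph: bool = True
    use_inter: bool = True
    use_amp: bool = True
    inter_members: tuple[str, ...] = ("pqrst",) + INTERVAL_NAMES
    amp_members: tuple[str, ...] = ("r_amp",)

    def columns(self) -> list[str]:
        cols: list[str] = []
        if self.use_morph:
            cols.extend(MORPH_NAMES)
        if self.use_inter:
            for m in self.inter_members:
                cols.extend(PQRST_NAMES if m == "pqrst" else (m,))
        if self.use_amp:
            cols.extend(self.amp_members)
        if not cols:
            raise ValueError("at least one feature group must be selected")
        return cols

    @property
    def name(self) -> str:
        parts = []
        if self.use_morph:
            parts.append("morph")
        if self.use_inter:
            parts.append("inter")
        if self.use_amp:
            parts.append("amp")
        return "+".join(parts) or "none"


def extract_features(beat: Beat, fid: Fiducials, prev_r: int | None,
                     fs: float) -> dict[str, float]:
    """Compute the named scalar features plus morphology for one beat.

    Durations are in seconds, amplitudes in mV. A feature whose fiducials
    are missing is NaN (to be imputed downstream).
    """
    if fid.r_peak != beat.source[1]:
        raise ValueError("beat and fiducials refer to different R peaks")

    def dur(a: int | None, b: int | None) -> float:
        return (b - a) / fs if a is not None and b is not None else np.nan

    r = fid.r_peak
    vals: dict[str, float] = {}
    for name, v in zip(MORPH_NAMES, beat.samples):
        vals[name] = float(v)
    vals["p_len"] = dur(fid.p_on, fid.p_off)
    vals["qrs_len"] = dur(fid.qrs_on, fid.qrs_off)
    vals["t_len"] = dur(fid.t_on, fid.t_off)
    vals["rr_inter"] = (r - prev_r) / fs if prev_r is not None else np.nan
    vals["pr_inter"] = dur(fid.p_on, fid.qrs_on)
    vals["st_seg"] = dur(fid.qrs_off, fid.t_on)
    vals["qt_inter"] = dur(fid.qrs_on, fid.t_off)
    vals["r_amp"] = float(np.max(beat.samples))
    if fid.t_peak is not None:
        vals["t_amp"] = float(beat.samples[np.clip(fid.t_peak - r + beat.r_offset,
                                                   0, BEAT_LEN - 1)])
    else:
        vals["t_amp"] = np.nan
    return vals


def build_feature_table(beats: list[Beat], fiducials: list[Fiducials],
                        fs: float) -> pd.DataFrame:
    """One row per beat; columns FEATURE_NAMES + label.

    A beat with no preceding beat in its record gets NaN RR, filled by the
    same training-median imputation as missing fiducials.
    """
    if len(beats) != len(fiducials):
        raise ValueError("beats and fiducials must align")
    rows = []
    prev_by_record: dict[str, int] = {}
    for beat, fid in zip(beats, fiducials):
        rec, r = beat.source
        prev_r = prev_by_record.get(rec)
        rows.append(extract_features(beat, fid, prev_r, fs) | {"label": beat.label})
        prev_by_record[rec] = r
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])
    return df


def combine(table: pd.DataFrame, sel: FeatureGroupSelection) -> np.ndarray:
    """Stitch the selected feature groups into a (beats x dims) matrix."""
    return table[sel.columns()].to_numpy(dtype=float)


def fit_imputer(train: np.ndarray) -> np.ndarray:
    """Per-column medians over finite training values (0 for all-NaN columns)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(train, axis=0)
    return np.where(np.isfinite(med), med, 0.0)


def apply_imputer(medians: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.array(X, dtype=float)
    mask = ~np.isfinite(X)
    if mask.any():
        X[mask] = np.broadcast_to(medians, X.shape)[mask]
    return X


@dataclass
class Normalizer:
    """Min-max scaler fit on training statistics only.

    Scales each dimension to [0,1] on the training set; transformed values
    are clipped to [-0.5, 1.5] so unseen extremes stay bounded. Zero-range
    dimensions map to 0.
    """

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, train: np.ndarray) -> "Normalizer":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ValueError("empty training matrix")
        self.mins = train.min(axis=0)
        self.maxs = train.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer has not been fit")
        X = np.asarray(X, dtype=float)
        rng = self.maxs - self.mins
        out = np.zeros_like(X)
        nz = rng > 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / rng[nz]
        return np.clip(out, -0.5, 1.5)

    def to_json(self) -> str:
        if not self.fitted:
            raise RuntimeError("normalizer has not been fit")
        return json.dumps({"mins": self.mins.tolist(), "maxs": self.maxs.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "Normalizer":
        d = json.loads(s)
        return cls(mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))
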