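"""Wavelet denoising and fixed-window beat segmentation.

A beat segment spans the inclusive window [r-90, r+144]: 90 samples before
the R peak, the R sample itself, and 144 after, i.e. 235 samples with the R
peak at offset 90.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _wavelets as wav
from .dataio import BeatAnnotation, EcgSignal

PRE_R = 90
POST_R = 144
BEAT_LEN = PRE_R + 1 + POST_R  # 235


@dataclass
class DenoiseConfig:
    """Discrete-wavelet denoising recipe.

    The deepest approximation band carries baseline wander and is zeroed;
    the finest detail bands carry high-frequency noise and are thresholded
    with the universal threshold sigma*sqrt(2 ln n), sigma estimated from
    the finest detail band via MAD/0.6745.
    """

    wavelet_name: str = "db6"
    levels: int = 9
    drop_approximation: bool = True
    baseline_detail_levels: frozenset[int] = frozenset({9})
    detail_threshold_levels: frozenset[int] = frozenset({1, 2})
    threshold_rule: str = "soft"  # or "hard"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        self.detail_threshold_levels = frozenset(self.detail_threshold_levels)
        self.baseline_detail_levels = frozenset(self.baseline_detail_levels)
        valid = set(range(1, self.levels + 1))
        if not self.detail_threshold_levels <= valid:
            raise ValueError("detail_threshold_levels must be within 1..levels")
        if not self.baseline_detail_levels <= valid:
            raise ValueError("baseline_detail_levels must be within 1..levels")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError("threshold_rule must be 'soft' or 'hard'")

    def to_dict(self) -> dict:
        return {
            "wavelet_name": self.wavelet_name,
            "levels": self.levels,
            "drop_approximation": self.drop_approximation,
            "baseline_detail_levels": sorted(self.baseline_detail_levels),
            "detail_threshold_levels": sorted(self.detail_threshold_levels),
            "threshold_rule": self.threshold_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiseConfig":
        d = dict(d)
        d["detail_threshold_levels"] = frozenset(d.get("detail_threshold_levels", {1, 2}))
        d["baseline_detail_levels"] = frozenset(d.get("baseline_detail_levels", {9}))
        return cls(**d)


@dataclass
class Beat:
    """Fixed 235-sample segment centered on an annotated R peak."""

    samples: np.ndarray
    label: str
    source: tuple[str, int]  # (record_id, r_index)
    r_offset: int = PRE_R

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LEN,):
            raise ValueError(f"beat must have exactly {BEAT_LEN} samples")
        if self.r_offset != PRE_R:
            raise ValueError(f"r_offset must be {PRE_R}")


def _ricker(t: np.ndarray) -> np.ndarray:
    # Mexican-hat mother wavelet, unit scale, L2-normalized.
    a = 2.0 / (np.sqrt(3.0) * np.pi ** 0.25)
    return a * (1.0 - t ** 2) * np.exp(-(t ** 2) / 2.0)


def wavelet_transform(signal: EcgSignal, scales) -> np.ndarray:
    """Continuous wavelet transform W(m, tau) by discretized convolution.

    W(m, tau) = m^(-1/2) * sum_t f(t) * psi((t - tau)/m), one row per scale,
    one column per sample (Mexican-hat mother wavelet, unit sample step).
    """
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if scales.size == 0 or np.any(scales <= 0):
        raise ValueError("scales must be non-empty and positive")
    x = signal.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    out = np.empty((len(scales), len(x)))
    for i, m in enumerate(scales):
        half = int(np.ceil(8.0 * m))
        j = np.arange(-half, half + 1)
        kernel = _ricker(j / m)
        # correlation: out[tau] = sum_j x[tau + j] * psi(j/m)
        out[i] = m ** -0.5 * np.correlate(
            np.pad(x, half, mode="constant"), kernel, mode="valid")
    return out


def denoise(signal: EcgSignal, cfg: DenoiseConfig | None = None) -> EcgSignal:
    """Remove baseline wander and high-frequency noise via the DWT."""
    cfg = cfg or DenoiseConfig()
    x = signal.samples
    if len(x) < (1 << cfg.levels):
        raise ValueError(
            f"signal length {len(x)} too short for {cfg.levels} levels")
    block = 1 << cfg.levels
    pad = (-len(x)) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = wav.wavedec(xp, cfg.wavelet_name, cfg.levels)
    # coeffs = [a_L, d_L, ..., d_1]; detail level j sits at index len-j.
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(len(xp)))
    shrink = wav.soft_threshold if cfg.threshold_rule == "soft" else wav.hard_threshold
    if cfg.drop_approximation:
        coeffs[0] = np.zeros_like(coeffs[0])
    for j in cfg.baseline_detail_levels:
        coeffs[len(coeffs) - j] = np.zeros_like(coeffs[len(coeffs) - j])
    for j in cfg.detail_threshold_levels:
        coeffs[len(coeffs) - j] = shrink(coeffs[len(coeffs) - j], thr)
    y = wav.waverec(coeffs, cfg.wavelet_name)[: len(x)]
    return EcgSignal(samples=y, fs=signal.fs,
                     record_id=signal.record_id, lead=signal.lead)


def segment_beats(signal: EcgSignal,
                  annotations: list[BeatAnnotation]) -> tuple[list[Beat], int]:
    """Cut one 235-sample Beat per annotation; returns (beats, n_dropped).

    Annotations whose window [r-90, r+144] falls outside the record, or
    whose class is EXCLUDED, are dropped and counted.
    """
    x = signal.samples
    beats: list[Beat] = []
    dropped = 0
    for ann in annotations:
        r = ann.r_index
        if not 0 <= r < len(x):
            raise ValueError(f"annotation index {r} outside record")
        if ann.aami_class == "EXCLUDED" or r - PRE_R < 0 or r + POST_R >= len(x):
            dropped += 1
            continue
        beats.append(Beat(samples=x[r - PRE_R : r + POST_R + 1].copy(),
                          label=ann.aami_class,
                          source=(signal.record_id, r)))
    return beats, dropped
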