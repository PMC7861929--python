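"""Synthetic annotated ECG and labeled feature-table generators.

Each beat is a sum of three Gaussian bumps (P, QRS, T) with class-specific
amplitudes, offsets, and widths, plus optional sinusoidal baseline wander
and white noise. Ground truth (R positions, planted wave parameters,
labels) is recorded so every downstream stage can be tested against a
constructible oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import BeatAnnotation, EcgSignal, map_symbol_to_aami


@dataclass(frozen=True)
class WaveParams:
    amp: float      # mV
    offset: float   # s relative to R
    width: float    # s (Gaussian sigma)


# Class-conditional morphologies: V has a wide QRS and no P; F sits between
# N and V; S resembles N but arrives early (short preceding RR).
DEFAULT_WAVE_PARAMS: dict[str, dict[str, WaveParams]] = {
    "N": {"P": WaveParams(0.15, -0.170, 0.025),
          "QRS": WaveParams(1.00, 0.0, 0.012),
          "T": WaveParams(0.30, 0.290, 0.055)},
    "S": {"P": WaveParams(0.10, -0.150, 0.020),
          "QRS": WaveParams(0.95, 0.0, 0.012),
          "T": WaveParams(0.28, 0.280, 0.050)},
    "V": {"P": WaveParams(0.0, -0.170, 0.025),
          "QRS": WaveParams(1.30, 0.0, 0.045),
          "T": WaveParams(-0.40, 0.300, 0.060)},
    "F": {"P": WaveParams(0.08, -0.170, 0.025),
          "QRS": WaveParams(0.80, 0.0, 0.028),
          "T": WaveParams(0.20, 0.290, 0.055)},
}
# RR multiplier applied to the interval preceding a beat of each class.
DEFAULT_RR_SCALE = {"N": 1.0, "S": 0.70, "V": 1.0, "F": 1.0}


@dataclass
class SynthEcgConfig:
    fs: float = 360.0
    n_beats: int = 10
    bpm: float = 72.0
    class_sequence: tuple[str, ...] | None = None  # default: all N
    wave_params: dict[str, dict[str, WaveParams]] = field(
        default_factory=lambda: DEFAULT_WAVE_PARAMS)
    rr_scale: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RR_SCALE))
    baseline_amp: float = 0.0   # mV
    baseline_freq: float = 0.3  # Hz
    noise_sd: float = 0.0       # mV
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.bpm <= 0:
            raise ValueError("fs and bpm must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.class_sequence is not None:
            if len(self.class_sequence) != self.n_beats:
                raise ValueError("class_sequence length must equal n_beats")
            unknown = set(self.class_sequence) - set(self.wave_params)
            if unknown:
                raise ValueError(f"no wave parameters for classes {unknown}")


@dataclass
class SynthTruth:
    r_indices: np.ndarray
    labels: tuple[str, ...]
    wave_truth: list[dict[str, WaveParams]]  # planted params per beat

    def annotations(self) -> list[BeatAnnotation]:
        return [BeatAnnotation(int(r), lab, map_symbol_to_aami(lab))
                for r, lab in zip(self.r_indices, self.labels)]


def synth_ecg(cfg: SynthEcgConfig) -> tuple[EcgSignal, SynthTruth]:
    """Generate a single-lead trace with planted beats and full ground truth."""
    rng = np.random.default_rng(cfg.seed)
    labels = tuple(cfg.class_sequence) if cfg.class_sequence else ("N",) * cfg.n_beats
    base_rr = 60.0 / cfg.bpm

    # R times: class-dependent scaling of the preceding interval
    r_times = [1.0]
    for lab in labels[1:]:
        r_times.append(r_times[-1] + base_rr * cfg.rr_scale.get(lab, 1.0))
    r_times = np.array(r_times)
    duration = r_times[-1] + 1.0
    n = int(np.ceil(duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    x = np.zeros(n)
    wave_truth: list[dict[str, WaveParams]] = []
    for rt, lab in zip(r_times, labels):
        params = cfg.wave_params[lab]
        wave_truth.append(dict(params))
        for wp in params.values():
            if wp.amp == 0.0:
                continue
            c = rt + wp.offset
            lo = max(0, int((c - 5 * wp.width) * cfg.fs))
            hi = min(n, int((c + 5 * wp.width) * cfg.fs) + 1)
            x[lo:hi] += wp.amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * wp.width ** 2))
    if cfg.baseline_amp:
        x += cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq * t)
    if cfg.noise_sd:
        x += rng.normal(0.0, cfg.noise_sd, size=n)

    r_indices = np.round(r_times * cfg.fs).astype(int)
    sig = EcgSignal(samples=x, fs=cfg.fs, record_id=f"syn{cfg.seed}", lead="SYN")
    return sig, SynthTruth(r_indices=r_indices, labels=labels, wave_truth=wave_truth)


def balanced_class_sequence(n_beats: int, seed: int = 0,
                            classes: tuple[str, ...] = ("N", "S", "V", "F"),
                            weights: tuple[float, ...] | None = None) -> tuple[str, ...]:
    """Random class-per-beat sequence; uniform weights unless given."""
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    return tuple(rng.choice(classes, size=n_beats, p=p))


DEFAULT_CLASS_MEANS = {
    "N": np.array([0.0, 0.0, 0.0, 0.0]),
    "S": np.array([3.0, 0.0, 0.0, 0.0]),
    "V": np.array([0.0, 3.0, 0.0, 0.0]),
    "F": np.array([0.0, 0.0, 3.0, 0.0]),
}


def synth_feature_table(n_per_class: dict[str, int],
                        class_means: dict[str, np.ndarray] | None = None,
                        spread: float = 0.1,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters in feature space; returns (X, labels)."""
    if spread < 0:
        raise ValueError("spread must be nonnegative")
    means = class_means or DEFAULT_CLASS_MEANS
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for cls, count in n_per_class.items():
        mu = np.asarray(means[cls], dtype=float)
        X_parts.append(mu + spread * rng.standard_normal((count, len(mu))))
        y_parts.extend([cls] * count)
    return np.vstack(X_parts), np.array(y_parts)
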