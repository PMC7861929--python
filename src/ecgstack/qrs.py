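"""Pan-Tompkins R-peak detection and detection scoring.

Pipeline: 5-15 Hz band-pass (zero-phase) -> five-point derivative ->
squaring -> 150 ms moving-window integration -> dual adaptive thresholds
with search-back and a 200 ms refractory period. Each accepted peak is
refined to the local absolute maximum of the input trace within +/-40 ms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dataio import EcgSignal

REFRACTORY_S = 0.200
INTEGRATION_S = 0.150
REFINE_S = 0.040
SEARCHBACK_FACTOR = 1.66


@dataclass(frozen=True)
class DetectionScore:
    tp: int
    fp: int
    fn: int

    @property
    def n_ref(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class DetectionMetrics:
    fdr: float
    se: float
    ppv: float | None
    acc: float


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def pan_tompkins(signal: EcgSignal) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices."""
    fs = signal.fs
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    x = signal.samples
    if len(x) < int(2 * fs):
        raise ValueError("need at least 2 s of signal")

    bp = _bandpass(x, fs)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    sq = deriv ** 2
    win = max(1, int(round(INTEGRATION_S * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # adaptive thresholds seeded from the first two seconds
    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(head.mean())
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rejected: list[int] = []
    rr_hist: list[int] = []

    def rr_avg() -> float:
        return float(np.mean(rr_hist[-8:])) if rr_hist else 0.0

    for p in cand:
        # search-back: a long gap means a beat was probably missed
        if accepted and rr_hist:
            gap_limit = SEARCHBACK_FACTOR * rr_avg()
            if p - accepted[-1] > gap_limit:
                thr2 = 0.5 * thr1
                back = [q for q in rejected
                        if accepted[-1] + refractory <= q < p - refractory
                        and mwi[q] > thr2]
                if back:
                    q = max(back, key=lambda i: mwi[i])
                    rr_hist.append(q - accepted[-1])
                    accepted.append(q)
                    spki = 0.25 * mwi[q] + 0.75 * spki
        if mwi[p] > thr1:
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            rejected.append(p)
            npki = 0.125 * mwi[p] + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

    # refine each detection to the local absolute maximum of the input
    half = int(round(REFINE_S * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = sorted(set(refined))
    # enforce the refractory period after refinement
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if np.abs(x[p]) > np.abs(x[out[-1]]):
                out[-1] = p
            continue
        out.append(p)
    return np.array(out, dtype=int)


def match_detections(detected, reference, fs: float,
                     tol_ms: float = 150.0) -> DetectionScore:
    """Greedy one-to-one nearest matching within ``tol_ms``.

    Matched pairs count as TP; unmatched detections as FP; unmatched
    reference marks as FN. Ties break toward the earlier reference.
    """
    detected = np.asarray(detected, dtype=int)
    reference = np.asarray(reference, dtype=int)
    tol = tol_ms / 1000.0 * fs
    pairs = []
    for di, d in enumerate(detected):
        for ri, r in enumerate(reference):
            dt = abs(int(d) - int(r))
            if dt <= tol:
                pairs.append((dt, ri, di))
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, ri, di in pairs:
        if ri in used_r or di in used_d:
            continue
        used_r.add(ri)
        used_d.add(di)
        tp += 1
    return DetectionScore(tp=tp, fp=len(detected) - tp, fn=len(reference) - tp)


def detection_metrics(score: DetectionScore) -> DetectionMetrics:
    """Fdr/Se/+p/Acc with Fdr = 100*(FP+FN)/n_ref and Acc = 100 - Fdr."""
    if score.n_ref == 0:
        raise ValueError("no reference beats")
    se = 100.0 * score.tp / score.n_ref
    ppv = (None if score.tp + score.fp == 0
           else 100.0 * score.tp / (score.tp + score.fp))
    fdr = 100.0 * (score.fp + score.fn) / score.n_ref
    return DetectionMetrics(fdr=fdr, se=se, ppv=ppv, acc=100.0 - fdr)
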