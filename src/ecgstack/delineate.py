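"""P/QRS/T fiducial-point delineation around a detected R peak.

Wave boundaries are found by a slope-threshold rule: scanning outward from a
wave's peak, the onset/offset is the first sample past the flank's steepest
point where the smoothed absolute slope falls below a fixed fraction
(default 12.5%) of the flank maximum. Search windows are clipped to the
neighboring beats when their R positions are known. Any fiducial that cannot
be located is reported as None (missing).
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .dataio import EcgSignal


@dataclass(frozen=True)
class Fiducials:
    r_peak: int
    p_on: int | None = None
    p_peak: int | None = None
    p_off: int | None = None
    qrs_on: int | None = None
    qrs_off: int | None = None
    t_on: int | None = None
    t_peak: int | None = None
    t_off: int | None = None

    def shifted(self, k: int) -> "Fiducials":
        vals = {f.name: (getattr(self, f.name) + k
                         if getattr(self, f.name) is not None else None)
                for f in fields(self)}
        return Fiducials(**vals)

    def ordering_ok(self) -> bool:
        seq = [self.p_on, self.p_peak, self.p_off, self.qrs_on]
        seq2 = [self.qrs_off, self.t_on, self.t_peak, self.t_off]
        present = [v for v in seq if v is not None]
        if any(a > b for a, b in zip(present, present[1:])):
            return False
        if self.qrs_on is not None and not self.qrs_on < self.r_peak:
            return False
        if self.qrs_off is not None and not self.r_peak < self.qrs_off:
            return False
        present2 = [v for v in seq2 if v is not None]
        return not any(a > b for a, b in zip(present2, present2[1:]))


@dataclass
class DelineateConfig:
    slope_frac: float = 0.125     # boundary threshold vs flank max slope
    qrs_halfwin_s: float = 0.150
    t_gap_s: float = 0.060        # T search starts this far after qrs_off
    t_max_s: float = 0.400        # ... and ends this far after R
    p_lo_s: float = 0.160         # P search window before qrs_on
    p_hi_s: float = 0.020
    p_halfwin_s: float = 0.150    # boundary search half-window around P peak
    t_halfwin_s: float = 0.200
    min_wave_amp: float = 0.02    # mV; smaller P/T excursions count as absent
    smooth_s: float = 0.010


def _smooth_slope(x: np.ndarray, fs: float, cfg: DelineateConfig) -> np.ndarray:
    w = max(3, int(round(cfg.smooth_s * fs)) | 1)
    sm = np.convolve(x, np.ones(w) / w, mode="same")
    return np.gradient(sm)


def _boundary(slope: np.ndarray, peak: int, lo: int, hi: int,
              frac: float, side: str) -> int | None:
    """First sample past the flank's steepest point where |slope| < frac*max."""
    a = np.abs(slope)
    if side == "left":
        seg = a[lo:peak + 1]
        if len(seg) <= 2:
            return None
        flank = lo + int(np.argmax(seg))
        thr = frac * a[flank]
        for i in range(flank, lo - 1, -1):
            if a[i] < thr:
                return i
        return lo
    seg = a[peak:hi]
    if len(seg) <= 2:
        return None
    flank = peak + int(np.argmax(seg))
    thr = frac * a[flank]
    for i in range(flank, hi):
        if a[i] < thr:
            return i
    return hi - 1


def _wave_peak(x: np.ndarray, lo: int, hi: int, min_amp: float) -> int | None:
    """Largest |excursion from the window's endpoint chord|, or None if small.

    The chord (straight line between the window's endpoints) serves as the
    local baseline, which stays valid when the wave fills most of the window
    or the baseline is slanted.
    """
    if hi - lo <= 2:
        return None
    seg = x[lo:hi]
    chord = np.linspace(seg[0], seg[-1], len(seg))
    dev = seg - chord
    i = int(np.argmax(np.abs(dev)))
    if np.abs(dev[i]) < min_amp or i in (0, len(seg) - 1):
        return None
    return lo + i


def delineate_record(signal: EcgSignal, r_indices,
                     cfg: DelineateConfig | None = None) -> list[Fiducials]:
    """Delineate every beat of a record, sharing one slope computation."""
    cfg = cfg or DelineateConfig()
    slope = _smooth_slope(signal.samples, signal.fs, cfg)
    r_indices = list(r_indices)
    out = []
    for i, r in enumerate(r_indices):
        prev_r = r_indices[i - 1] if i > 0 else None
        next_r = r_indices[i + 1] if i + 1 < len(r_indices) else None
        out.append(delineate_beat(signal, int(r), prev_r, next_r, cfg,
                                  _slope=slope))
    return out


def delineate_beat(signal: EcgSignal, r_peak: int,
                   prev_r: int | None = None, next_r: int | None = None,
                   cfg: DelineateConfig | None = None,
                   _slope: np.ndarray | None = None) -> Fiducials:
    """Locate P/QRS/T onsets, peaks, and offsets around ``r_peak``."""
    cfg = cfg or DelineateConfig()
    x = signal.samples
    fs = signal.fs
    n = len(x)
    if not 0 <= r_peak < n:
        raise ValueError("r_peak outside signal")
    slope = _slope if _slope is not None else _smooth_slope(x, fs, cfg)

    # --- QRS boundaries: slope rule within +/-100 ms of R
    halfwin = int(round(cfg.qrs_halfwin_s * fs))
    q_lo = max(0, r_peak - halfwin)
    q_hi = min(n, r_peak + halfwin + 1)
    if prev_r is not None:
        q_lo = max(q_lo, (prev_r + r_peak) // 2)
    if next_r is not None:
        q_hi = min(q_hi, (r_peak + next_r) // 2 + 1)
    qrs_on = _boundary(slope, r_peak, q_lo, q_hi, cfg.slope_frac, "left")
    qrs_off = _boundary(slope, r_peak, q_lo, q_hi, cfg.slope_frac, "right")
    if qrs_on is not None and qrs_on >= r_peak:
        qrs_on = max(q_lo, r_peak - 1)
    if qrs_off is not None and qrs_off <= r_peak:
        qrs_off = min(q_hi - 1, r_peak + 1)

    # --- T wave: search (qrs_off + 60 ms, min(next beat, R + 400 ms))
    t_on = t_peak = t_off = None
    if qrs_off is not None:
        t_lo = qrs_off + int(round(cfg.t_gap_s * fs))
        t_hi = r_peak + int(round(cfg.t_max_s * fs))
        if next_r is not None:
            t_hi = min(t_hi, next_r - int(round(0.100 * fs)))
        t_hi = min(t_hi, n)
        t_peak = _wave_peak(x, t_lo, t_hi, cfg.min_wave_amp) if t_lo < t_hi else None
        if t_peak is not None:
            w = int(round(cfg.t_halfwin_s * fs))
            b_lo = max(qrs_off + 1, t_peak - w)
            b_hi = min(n, t_peak + w + 1)
            if next_r is not None:
                b_hi = min(b_hi, next_r)
            t_on = _boundary(slope, t_peak, b_lo, b_hi, cfg.slope_frac, "left")
            t_off = _boundary(slope, t_peak, b_lo, b_hi, cfg.slope_frac, "right")
            if t_on is None or t_off is None:
                t_on = t_peak = t_off = None

    # --- P wave: search (qrs_on - 200 ms, qrs_on - 20 ms)
    p_on = p_peak = p_off = None
    if qrs_on is not None:
        p_lo = qrs_on - int(round(cfg.p_lo_s * fs))
        p_hi = qrs_on - int(round(cfg.p_hi_s * fs))
        if prev_r is not None:
            p_lo = max(p_lo, prev_r + int(round(0.100 * fs)))
        p_lo = max(0, p_lo)
        p_peak = _wave_peak(x, p_lo, p_hi, cfg.min_wave_amp) if p_lo < p_hi else None
        if p_peak is not None:
            w = int(round(cfg.p_halfwin_s * fs))
            b_lo = max(0, p_peak - w)
            if prev_r is not None:
                b_lo = max(b_lo, prev_r)
            b_hi = min(qrs_on, p_peak + w + 1)
            p_on = _boundary(slope, p_peak, b_lo, b_hi, cfg.slope_frac, "left")
            p_off = _boundary(slope, p_peak, b_lo, b_hi, cfg.slope_frac, "right")
            if p_on is None or p_off is None:
                p_on = p_peak = p_off = None

    fid = Fiducials(r_peak=r_peak, p_on=p_on, p_peak=p_peak, p_off=p_off,
                    qrs_on=qrs_on, qrs_off=qrs_off,
                    t_on=t_on, t_peak=t_peak, t_off=t_off)
    if not fid.ordering_ok():
        # degenerate geometry: keep QRS, drop the offending outer waves
        fid = Fiducials(r_peak=r_peak, qrs_on=qrs_on, qrs_off=qrs_off)
    return fid
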