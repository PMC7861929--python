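"""Record and annotation I/O, AAMI class mapping, and train/test splitting.

A self-contained reader/writer for the WFDB file family is included so the
package has no hard dependency on external waveform tooling: formats 212 and
16 for signals, plus the standard binary annotation stream and a plain-CSV
alternative used by the synthetic workflow.
"""
from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AAMI_CLASSES = ("N", "S", "V", "F")
EXCLUDED = "EXCLUDED"

# AAMI EC57 grouping of beat annotation symbols into the four studied classes.
_AAMI_MAP = {
    **{s: "N" for s in ("N", "L", "R", "e", "j")},
    **{s: "S" for s in ("A", "a", "J", "S")},
    **{s: "V" for s in ("V", "E")},
    "F": "F",
}

# Standard annotation-code <-> mnemonic table (beat and non-beat codes).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class EcgSignal:
    """Uniformly sampled single-lead voltage trace."""

    samples: np.ndarray  # mV
    fs: float            # Hz
    record_id: str = ""
    lead: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("signal must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BeatAnnotation:
    r_index: int
    symbol: str
    aami_class: str

    def is_beat(self) -> bool:
        return self.aami_class != EXCLUDED


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int


def map_symbol_to_aami(symbol: str) -> str:
    """Total mapping of an annotation symbol to {N,S,V,F} or EXCLUDED."""
    return _AAMI_MAP.get(symbol, EXCLUDED)


# ---------------------------------------------------------------------------
# WFDB header + signal files
# ---------------------------------------------------------------------------

def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec_tokens = lines[0].split()
    record_name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            gspec = tok[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gspec, bl = gspec.split("(")
                baseline = int(bl.rstrip(")"))
            gain = float(gspec) if float(gspec) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(dict(file=fname, fmt=int(fmt), gain=gain,
                            baseline=baseline, description=desc))
    return record_name, n_sig, fs, n_samples, signals


def _read_dat(path: str, fmt: int, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if fmt == 16:
        data = raw[: (len(raw) // 2) * 2].view("<i2").astype(np.int64)
        n = len(data) // n_sig
        return data[: n * n_sig].reshape(n, n_sig)
    if fmt == 212:
        raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int64)
        first = raw[:, 0] + ((raw[:, 1] & 0x0F) << 8)
        second = raw[:, 2] + ((raw[:, 1] & 0xF0) << 4)
        first -= (first & 0x800) << 1   # sign-extend 12-bit
        second -= (second & 0x800) << 1
        data = np.empty(raw.shape[0] * 2, dtype=np.int64)
        data[0::2], data[1::2] = first, second
        n = len(data) // n_sig
        return data[: n * n_sig].reshape(n, n_sig)
    raise ValueError(f"unsupported WFDB signal format {fmt}")


def read_record(path: str, lead: str | None = None) -> EcgSignal:
    """Read one lead of a WFDB record (``path`` with or without ``.hea``).

    ``lead`` is matched against the per-signal description; ``None`` selects
    the first lead.
    """
    base = path[:-4] if path.endswith(".hea") else path
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    record_name, n_sig, fs, n_samples, signals = _parse_header(hea)
    names = [s["description"] for s in signals]
    if lead is None:
        idx = 0
    else:
        if lead not in names:
            raise KeyError(f"lead {lead!r} not in record (leads: {names})")
        idx = names.index(lead)
    sig = signals[idx]
    dat = os.path.join(os.path.dirname(base), sig["file"])
    digital = _read_dat(dat, sig["fmt"], n_sig)[:, idx]
    if n_samples:
        digital = digital[:n_samples]
    samples = (digital - sig["baseline"]) / sig["gain"]
    return EcgSignal(samples=samples, fs=fs, record_id=record_name, lead=names[idx])


def write_record(base_path: str, signal: EcgSignal, gain: float = 200.0) -> None:
    """Write a single-lead format-16 WFDB record (``.hea`` + ``.dat``)."""
    record_name = os.path.basename(base_path)
    digital = np.round(signal.samples * gain).astype("<i2")
    with open(base_path + ".dat", "wb") as fh:
        fh.write(digital.tobytes())
    lead = signal.lead or "SYN"
    with open(base_path + ".hea", "w") as fh:
        fh.write(f"{record_name} 1 {signal.fs:g} {len(signal)}\n")
        fh.write(f"{record_name}.dat 16 {gain:g}(0)/mV 16 0 "
                 f"{int(digital[0])} 0 0 {lead}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str) -> list[BeatAnnotation]:
    """Read beat annotations from a binary ``.atr``-style stream or CSV.

    CSV files need columns ``r_index`` and ``symbol``. Only annotations whose
    symbol is a beat mark get a class; everything else maps to EXCLUDED.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        anns = [BeatAnnotation(int(r), str(s), map_symbol_to_aami(str(s)))
                for r, s in zip(df["r_index"], df["symbol"])]
    else:
        anns = _read_atr(path)
    return sorted(anns, key=lambda a: a.r_index)


def _read_atr(path: str) -> list[BeatAnnotation]:
    data = open(path, "rb").read()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == _SKIP:
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval & 0x80000000:
                interval -= 1 << 32
            t += interval
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += interval
        symbol = _CODE_TO_SYMBOL.get(code, "Q")
        anns.append(BeatAnnotation(t, symbol, map_symbol_to_aami(symbol)))
    return anns


def write_annotations(path: str, annotations: list[BeatAnnotation]) -> None:
    """Write annotations as a binary stream (non-CSV path) or CSV."""
    annotations = sorted(annotations, key=lambda a: a.r_index)
    if path.endswith(".csv"):
        pd.DataFrame(
            {"r_index": [a.r_index for a in annotations],
             "symbol": [a.symbol for a in annotations],
             "aami_class": [a.aami_class for a in annotations]}
        ).to_csv(path, index=False)
        return
    with open(path, "wb") as fh:
        t = 0
        for a in annotations:
            dt = a.r_index - t
            if dt < 0:
                raise ValueError("annotations must be sorted")
            if dt > 1023:
                fh.write(struct.pack("<H", (_SKIP << 10)))
                fh.write(struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF))
                dt = 0
            code = _SYMBOL_TO_CODE.get(a.symbol, 13)
            fh.write(struct.pack("<H", (code << 10) | dt))
            t = a.r_index
        fh.write(struct.pack("<H", 0))


def annotations_to_frame(annotations: list[BeatAnnotation],
                         record_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {"record_id": record_id,
         "r_index": [a.r_index for a in annotations],
         "symbol": [a.symbol for a in annotations],
         "aami_class": [a.aami_class for a in annotations]}
    )


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_dataset(labels, train_frac: float = 0.9, seed: int = 0) -> DatasetSplit:
    """Per-class stratified random split over beat indices.

    Within each class ``round(train_frac * n)`` beats go to train; a class
    with fewer than two members goes entirely to train (with a warning).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            warnings.warn(f"class {cls!r} has < 2 members; all to train")
            train.extend(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return DatasetSplit(train_ids=np.sort(np.array(train, dtype=int)),
                        test_ids=np.sort(np.array(test, dtype=int)),
                        seed=seed)
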