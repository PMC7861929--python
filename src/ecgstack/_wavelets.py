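"""Orthogonal discrete wavelet transform with periodic boundary handling.

Implements a multilevel DWT/IDWT for orthonormal Daubechies filters using
circular convolution, so the forward transform is an orthogonal matrix and
reconstruction is exact (up to float rounding) for even-length inputs.
"""
from __future__ import annotations

import numpy as np

# Orthonormal Daubechies scaling filters (sum = sqrt(2)).
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "db4": np.array(
        [
            0.2303778133088965,
            0.7148465705529157,
            0.6308807679298589,
            -0.027983769416859854,
            -0.18703481171909309,
            0.030841381835560764,
            0.0328830116668852,
            -0.010597401785069032,
        ]
    ),
    "db6": np.array(
        [
            0.11154074335008017,
            0.4946238903983854,
            0.7511339080215775,
            0.3152503517092432,
            -0.22626469396516913,
            -0.12976686756709563,
            0.09750160558707936,
            0.02752286553001629,
            -0.031582039318031156,
            0.0005538422009938016,
            0.004777257511010651,
            -0.0010773010849955799,
        ]
    ),
}


def scaling_filter(name: str) -> np.ndarray:
    try:
        return _SCALING_FILTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None


def _qmf(h: np.ndarray) -> np.ndarray:
    # g[k] = (-1)^k h[L-1-k]; together with h this forms an orthonormal pair.
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def _analysis(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-level periodized analysis; len(x) must be even."""
    n, L = len(x), len(h)
    ext = np.concatenate([x, x[np.arange(L - 1) % n]])
    # y[m] = sum_k f[k] x[(m+k) mod n]  (circular cross-correlation)
    lo = np.correlate(ext, h, mode="valid")[:n:2]
    hi = np.correlate(ext, g, mode="valid")[:n:2]
    return lo, hi


def _synthesis(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_analysis` (transpose of the orthogonal analysis map)."""
    n = 2 * len(a)
    L = len(h)
    out = np.zeros(n)
    for coef, f in ((a, h), (d, g)):
        u = np.zeros(n)
        u[0::2] = coef
        ext = np.concatenate([u[np.arange(-(L - 1), 0) % n], u])
        # circular convolution u * f
        out += np.correlate(ext, f[::-1], mode="valid")
    return out


def wavedec(x: np.ndarray, wavelet: str, levels: int) -> list[np.ndarray]:
    """Multilevel DWT. Returns [a_L, d_L, d_{L-1}, ..., d_1].

    len(x) must be divisible by 2**levels.
    """
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(x) % (1 << levels):
        raise ValueError(f"signal length {len(x)} not divisible by 2^{levels}")
    h = scaling_filter(wavelet)
    g = _qmf(h)
    details = []
    a = x
    for _ in range(levels):
        a, d = _analysis(a, h, g)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str) -> np.ndarray:
    h = scaling_filter(wavelet)
    g = _qmf(h)
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _synthesis(a, d, h, g)
    return a


def soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def hard_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.where(np.abs(x) >= thr, x, 0.0)
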