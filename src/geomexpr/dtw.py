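"""Dynamic time warping between two-channel feature vectors.

Classic dynamic-programming DTW with steps {(1,0), (0,1), (1,1)}, anchored
endpoints, no slope weights, and Euclidean local cost on the 2-vector
elements. Sequences may differ in length, which is what lets the weak
classifiers compare unresampled test sequences against fixed-length
prototypes. An optional Sakoe-Chiba band is available as a speed
optimization; with a radius at least max(len(a), len(b)) it is exact.

The inner dynamic program is numba-compiled: the boosting stage evaluates
millions of small DTW problems (every sequence against every class
prototype for every pool descriptor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["DtwConfig", "dtw_distance", "dtw_matrix_resampled", "dtw_matrix_single"]


@dataclass(frozen=True)
class DtwConfig:
    """DTW options. ``band_radius=None`` means unconstrained alignment."""

    band_radius: int | None = None

    def __post_init__(self) -> None:
        if self.band_radius is not None and self.band_radius < 0:
            raise ValueError("band_radius must be nonnegative")


@njit(cache=True)
def _dtw_core(a, b, band):  # pragma: no cover - exercised through wrappers
    n = a.shape[0]
    m = b.shape[0]
    INF = np.inf
    prev = np.full(m + 1, INF)
    curr = np.full(m + 1, INF)
    prev[0] = 0.0
    for i in range(1, n + 1):
        curr[0] = INF
        if band >= 0:
            lo = max(1, i - band)
            hi = min(m, i + band)
        else:
            lo = 1
            hi = m
        for j in range(1, lo):
            curr[j] = INF
        for j in range(hi + 1, m + 1):
            curr[j] = INF
        for j in range(lo, hi + 1):
            dx = a[i - 1, 0] - b[j - 1, 0]
            dy = a[i - 1, 1] - b[j - 1, 1]
            cost = np.sqrt(dx * dx + dy * dy)
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = cost + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(a: np.ndarray, b: np.ndarray, cfg: DtwConfig | None = None) -> float:
    """Minimal cumulative Euclidean cost over monotone alignments of a and b.

    Parameters
    ----------
    a, b
        Feature vectors of shape ``(n, 2)`` and ``(m, 2)``; lengths may
        differ.
    cfg
        Optional :class:`DtwConfig`; the default is unconstrained DTW.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("dtw_distance expects (n, 2) arrays")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("dtw_distance requires nonempty sequences")
    band = -1 if cfg is None or cfg.band_radius is None else int(cfg.band_radius)
    if band >= 0:
        # an admissible banded path must reach cell (n, m)
        band = max(band, abs(a.shape[0] - b.shape[0]))
    return float(_dtw_core(a, b, band))


@njit(cache=True)
def _dtw_single_vs_bank(x, protos, band):  # pragma: no cover
    # x: (D, n, 2); protos: (K, D, m, 2) -> (D, K)
    D = x.shape[0]
    K = protos.shape[0]
    out = np.empty((D, K))
    for f in range(D):
        for c in range(K):
            out[f, c] = _dtw_core(x[f], protos[c, f], band)
    return out


@njit(cache=True, parallel=False)
def _dtw_many_vs_bank(X, protos, band):  # pragma: no cover
    # X: (n_seq, D, n, 2); protos: (K, D, m, 2) -> (n_seq, D, K)
    n_seq = X.shape[0]
    D = X.shape[1]
    K = protos.shape[0]
    out = np.empty((n_seq, D, K))
    for s in range(n_seq):
        for f in range(D):
            for c in range(K):
                out[s, f, c] = _dtw_core(X[s, f], protos[c, f], band)
    return out


def dtw_matrix_single(x: np.ndarray, protos: np.ndarray, cfg: DtwConfig | None = None) -> np.ndarray:
    """DTW distances of one sequence's feature stack against a prototype bank.

    ``x`` has shape ``(D, n, 2)`` and ``protos`` ``(K, D, m, 2)``; the result
    is ``(D, K)``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    protos = np.ascontiguousarray(protos, dtype=np.float64)
    band = -1 if cfg is None or cfg.band_radius is None else int(cfg.band_radius)
    if band >= 0:
        band = max(band, abs(x.shape[1] - protos.shape[2]))
    return _dtw_single_vs_bank(x, protos, band)


def dtw_matrix_resampled(X: np.ndarray, protos: np.ndarray, cfg: DtwConfig | None = None) -> np.ndarray:
    """DTW distances of many equal-length sequences against a prototype bank.

    ``X`` has shape ``(n_seq, D, n, 2)``; the result is ``(n_seq, D, K)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    protos = np.ascontiguousarray(protos, dtype=np.float64)
    band = -1 if cfg is None or cfg.band_radius is None else int(cfg.band_radius)
    if band >= 0:
        band = max(band, abs(X.shape[2] - protos.shape[2]))
    return _dtw_many_vs_bank(X, protos, band)
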