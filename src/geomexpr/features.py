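"""Geometric feature vectors from normalized landmark trajectories.

Two feature families are built from a sequence of F frames:

* type-1 — per landmark i, the time series of displacements
  ``(dx_l, dy_l) = coords[i, l] - coords[i, 0]`` for l = 1..F-1 (pixels);
* type-2 — per ordered pair i < j, the time series of change in
  Euclidean distance and inter-landmark angle relative to frame 0,
  ``(dd_l, dtheta_l)`` (pixels, radians, angle difference wrapped to
  (-pi, pi]).

The neutral-frame element (always zero) is excluded, so a feature vector
has F-1 two-channel elements. The full pool over L landmarks holds
L type-1 + L(L-1)/2 type-2 descriptors (1378 for L = 52).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequences import LandmarkSequence

__all__ = [
    "FeatureDescriptor",
    "FeatureSet",
    "build_feature_pool",
    "type1_feature",
    "type2_feature",
    "extract_all",
    "region_summary",
    "wrap_angle",
]


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (-pi, pi]."""
    return -(np.mod(-np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi)


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """Identifies one feature-pool entry.

    ``kind`` is ``"type1"`` (single landmark ``i``; channels dx, dy) or
    ``"type2"`` (pair ``i < j``; channels dd, dtheta).
    """

    kind: str
    i: int
    j: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("type1", "type2"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.i < 0:
            raise ValueError("landmark index must be nonnegative")
        if self.kind == "type2" and self.j <= self.i:
            raise ValueError("type-2 descriptors require i < j")
        if self.kind == "type1" and self.j != -1:
            raise ValueError("type-1 descriptors take a single landmark index")

    def __repr__(self) -> str:
        if self.kind == "type1":
            return f"type1({self.i})"
        return f"type2({self.i},{self.j})"


def build_feature_pool(L: int) -> list[FeatureDescriptor]:
    """Enumerate the full descriptor pool for L landmarks.

    All L type-1 descriptors first, then the L(L-1)/2 type-2 pairs in
    lexicographic (i, j) order with i < j.
    """
    if L < 2:
        raise ValueError("the feature pool requires at least 2 landmarks")
    pool = [FeatureDescriptor("type1", i) for i in range(L)]
    pool.extend(
        FeatureDescriptor("type2", i, j) for i in range(L) for j in range(i + 1, L)
    )
    return pool


def type1_feature(seq: LandmarkSequence, i: int) -> np.ndarray:
    """Displacement time series of landmark i relative to the neutral frame.

    Returns an array of shape ``(F-1, 2)`` with channels (dx, dy).
    """
    if not 0 <= i < seq.n_landmarks:
        raise IndexError(f"landmark index {i} out of range [0, {seq.n_landmarks})")
    return seq.coords[i, 1:, :] - seq.coords[i, 0, :]


def _pair_distance_angle(seq: LandmarkSequence, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    diff = seq.coords[j] - seq.coords[i]  # (F, 2)
    d = np.hypot(diff[:, 0], diff[:, 1])
    theta = np.arctan2(diff[:, 1], diff[:, 0])
    coincident = d == 0.0
    if coincident[0]:
        raise ValueError(
            f"landmarks {i} and {j} coincide in frame 0; pair angle undefined"
        )
    if coincident.any():
        # carry the angle over from the previous frame
        import warnings

        warnings.warn(
            f"landmarks {i} and {j} coincide in some frame; carrying angle forward",
            RuntimeWarning,
            stacklevel=3,
        )
        for l in np.flatnonzero(coincident):
            theta[l] = theta[l - 1]
    return d, theta


def type2_feature(seq: LandmarkSequence, i: int, j: int) -> np.ndarray:
    """Pairwise distance/angle change time series for landmarks i < j.

    Returns an array of shape ``(F-1, 2)`` with channels
    (d_l - d_0, wrap(theta_l - theta_0)).

    Swapping i and j offsets every frame's angle by pi, which cancels in
    the wrapped difference, so the i < j ordering convention does not
    change the feature.
    """
    if not 0 <= i < j < seq.n_landmarks:
        raise IndexError(f"invalid pair ({i}, {j}) for L={seq.n_landmarks}")
    d, theta = _pair_distance_angle(seq, i, j)
    dd = d[1:] - d[0]
    dtheta = wrap_angle(theta[1:] - theta[0])
    return np.stack([dd, dtheta], axis=1)


class FeatureSet:
    """All pool feature vectors of one sequence, pool-aligned.

    Stores a dense array of shape ``(D, F-1, 2)`` whose first axis follows
    the descriptor pool order, plus a descriptor index for mapping-style
    access (``fs[descriptor]`` returns that descriptor's ``(F-1, 2)``
    feature vector).
    """

    def __init__(self, pool: Sequence[FeatureDescriptor], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[0] != len(pool) or values.shape[2] != 2:
            raise ValueError(
                f"values must have shape (len(pool), F-1, 2), got {values.shape}"
            )
        self.pool = list(pool)
        self.values = values
        self._index = {f: k for k, f in enumerate(self.pool)}

    def __len__(self) -> int:
        return len(self.pool)

    def __contains__(self, f: FeatureDescriptor) -> bool:
        return f in self._index

    def __getitem__(self, f: FeatureDescriptor) -> np.ndarray:
        try:
            return self.values[self._index[f]]
        except KeyError:
            raise KeyError(f"descriptor {f!r} not in this feature set") from None

    def index_of(self, f: FeatureDescriptor) -> int:
        return self._index[f]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]


def extract_all(seq: LandmarkSequence, pool: Sequence[FeatureDescriptor]) -> FeatureSet:
    """Extract every pool feature vector of a (normalized) sequence at once.

    Vectorized over landmarks and pairs; equivalent to calling
    :func:`type1_feature` / :func:`type2_feature` per descriptor.
    """
    L, F = seq.n_landmarks, seq.n_frames
    for f in pool:
        hi = max(f.i, f.j)
        if hi >= L:
            raise IndexError(f"descriptor {f!r} out of range for L={L}")

    t1 = seq.coords[:, 1:, :] - seq.coords[:, 0:1, :]  # (L, F-1, 2)

    # pairwise distance/angle for all i<j in one shot
    diff = seq.coords[None, :, :, :] - seq.coords[:, None, :, :]  # (L, L, F, 2): j - i
    d = np.hypot(diff[..., 0], diff[..., 1])
    theta = np.arctan2(diff[..., 1], diff[..., 0])
    iu, ju = np.triu_indices(L, k=1)
    d_p = d[iu, ju]  # (P, F)
    th_p = theta[iu, ju]
    zero = d_p == 0.0
    if zero.any():
        if zero[:, 0].any():
            bad = np.flatnonzero(zero[:, 0])[0]
            raise ValueError(
                f"landmarks {iu[bad]} and {ju[bad]} coincide in frame 0"
            )
        import warnings

        warnings.warn(
            "coincident landmark pairs found; carrying angles forward",
            RuntimeWarning,
            stacklevel=2,
        )
        for p, l in zip(*np.nonzero(zero)):
            th_p[p, l] = th_p[p, l - 1]
    t2 = np.stack(
        [d_p[:, 1:] - d_p[:, 0:1], wrap_angle(th_p[:, 1:] - th_p[:, 0:1])], axis=2
    )  # (P, F-1, 2)

    pair_index = {}
    for k in range(len(iu)):
        pair_index[(int(iu[k]), int(ju[k]))] = k
    values = np.empty((len(pool), F - 1, 2))
    for k, f in enumerate(pool):
        if f.kind == "type1":
            values[k] = t1[f.i]
        else:
            values[k] = t2[pair_index[(f.i, f.j)]]
    return FeatureSet(pool, values)


def region_summary(
    selected: Sequence[FeatureDescriptor], regions: Mapping[int, str]
) -> Counter:
    """Count selected descriptors per face region / unordered region pair.

    type-1 descriptors are counted under their landmark's region id;
    type-2 descriptors under the unordered pair of region ids
    (a single id when both landmarks share a region).
    """
    counts: Counter = Counter()
    for f in selected:
        if f.i not in regions:
            raise KeyError(f"landmark {f.i} has no region assignment")
        if f.kind == "type1":
            counts[(regions[f.i],)] += 1
        else:
            if f.j not in regions:
                raise KeyError(f"landmark {f.j} has no region assignment")
            ri, rj = regions[f.i], regions[f.j]
            key = (ri,) if ri == rj else tuple(sorted((ri, rj)))
            counts[key] += 1
    return counts
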