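"""Per-class median prototypes and the DTW nearest-prototype weak classifier.

Each expression class is summarized, per pool descriptor, by the
elementwise median of its training feature vectors (median rather than
mean, for outlier robustness; the class-conditional distributions are
assumed unimodal). A weak classifier looks at a single descriptor and
votes for the class whose prototype is DTW-nearest to the input's
feature vector for that descriptor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dtw import DtwConfig, dtw_distance, dtw_matrix_single
from .features import FeatureDescriptor, FeatureSet, extract_all
from .sequences import LandmarkSequence

__all__ = [
    "PrototypeBank",
    "build_prototypes",
    "weak_classify",
    "weak_classify_binary",
    "weak_votes",
]


@dataclass
class PrototypeBank:
    """Median prototype feature vectors, one per (class, descriptor).

    ``values`` has shape ``(K, D, N, 2)`` with the class axis following
    ``classes`` (sorted labels) and the descriptor axis following ``pool``.
    """

    classes: list[int]
    pool: list[FeatureDescriptor]
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K, D = len(self.classes), len(self.pool)
        if self.values.shape[:2] != (K, D) or self.values.ndim != 4:
            raise ValueError(
                f"values must have shape (K={K}, D={D}, N, 2), got {self.values.shape}"
            )
        self._index = {f: k for k, f in enumerate(self.pool)}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def prototype(self, label: int, f: FeatureDescriptor) -> np.ndarray:
        return self.values[self.classes.index(label), self._index[f]]

    def descriptor_index(self, f: FeatureDescriptor) -> int:
        return self._index[f]

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format": "geomexpr-prototypes",
            "version": 1,
            "classes": self.classes,
            "pool": [[f.kind, f.i, f.j] for f in self.pool],
            "values": self.values.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PrototypeBank":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "geomexpr-prototypes":
            raise ValueError("not a geomexpr prototype-bank file")
        pool = [FeatureDescriptor(k, i, j) for k, i, j in payload["pool"]]
        return cls(payload["classes"], pool, np.asarray(payload["values"]))

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(repr(self.classes).encode())
        return h.hexdigest()[:16]


def build_prototypes(
    train: Sequence[LandmarkSequence],
    pool: Sequence[FeatureDescriptor],
    K: int | None = None,
    *,
    features: np.ndarray | None = None,
    labels: Sequence[int] | None = None,
) -> PrototypeBank:
    """Build the per-class median prototype bank from training sequences.

    Sequences must be normalized and resampled to a common frame count so
    the elementwise median is defined. If the feature stack was already
    extracted, pass it via ``features`` (shape ``(n, D, N, 2)``) together
    with ``labels`` to avoid recomputation.

    Even-cardinality medians use the mean-of-middle-two convention
    (numpy's default).
    """
    if features is None:
        if not train:
            raise ValueError("cannot build prototypes from zero sequences")
        lengths = {s.n_frames for s in train}
        if len(lengths) != 1:
            raise ValueError(
                f"training sequences must share a frame count, got {sorted(lengths)}"
            )
        labels = [s.label for s in train]
        features = np.stack([extract_all(s, pool).values for s in train])
    labels_arr = np.asarray(labels)
    if np.any(labels_arr == None):  # noqa: E711 - catches python None in object arrays
        raise ValueError("all training sequences must be labeled")
    labels_arr = labels_arr.astype(int)
    classes = sorted(np.unique(labels_arr).tolist())
    if K is not None and len(classes) != K:
        raise ValueError(f"expected {K} classes, found {len(classes)}: {classes}")
    values = np.empty((len(classes), len(pool)) + features.shape[2:])
    for c, lab in enumerate(classes):
        members = features[labels_arr == lab]
        if members.shape[0] == 0:
            raise ValueError(f"class {lab} has no training sequences")
        values[c] = np.median(members, axis=0)
    return PrototypeBank(classes, list(pool), values)


def weak_votes(
    x: FeatureSet | np.ndarray, bank: PrototypeBank, cfg: DtwConfig | None = None
) -> np.ndarray:
    """Weak-classifier votes of one sequence for every pool descriptor.

    Returns an integer array of length D with the class label whose
    prototype is DTW-nearest per descriptor (ties go to the smaller class
    index).
    """
    values = x.values if isinstance(x, FeatureSet) else np.asarray(x)
    dist = dtw_matrix_single(values, bank.values, cfg)  # (D, K)
    return np.asarray(bank.classes)[np.argmin(dist, axis=1)]


def weak_classify(
    x_features: FeatureSet,
    bank: PrototypeBank,
    f: FeatureDescriptor,
    cfg: DtwConfig | None = None,
) -> int:
    """Class vote of the single-descriptor DTW nearest-prototype rule.

    Ties in DTW distance go to the smallest class index.
    """
    xv = x_features[f]
    k = bank.descriptor_index(f)
    dists = [dtw_distance(xv, bank.values[c, k], cfg) for c in range(bank.n_classes)]
    return bank.classes[int(np.argmin(dists))]


def weak_classify_binary(
    x_features: FeatureSet,
    bank: PrototypeBank,
    f: FeatureDescriptor,
    positive_class: int,
    cfg: DtwConfig | None = None,
) -> bool:
    """One-vs-all weak rule: keep all K class prototypes and call the input
    positive iff the positive class attains the minimum DTW distance."""
    return weak_classify(x_features, bank, f, cfg) == positive_class
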