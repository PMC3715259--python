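"""Fixed-length collapsed features from boosted descriptors + RBF SVM.

Each selected descriptor's feature vector (a time series of 2-vectors)
is collapsed to its per-channel signed maximum over the sequence — the
maximum displacement in x and y for type-1, the maximum change in
distance and angle for type-2 — giving a 2x|selected| vector per
sequence. The collapse is frame-count independent, so it is applied to
original-length (unresampled) sequences. Classification is a one-vs-one
multi-class SVM with RBF kernel; (C, gamma) are picked by cross-validated
grid search, with per-dimension [-1, 1] scaling fit on the training fold
inside the search.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .features import FeatureDescriptor, FeatureSet

__all__ = ["collapse_features", "train_svm", "predict_svm", "default_grid"]


def collapse_features(
    x_features: FeatureSet, selected: Sequence[FeatureDescriptor]
) -> np.ndarray:
    """Per-channel signed maxima of the selected feature vectors.

    Returns a vector of length ``2 * len(selected)``, ordered by selection
    with the x/distance channel before the y/angle channel for each
    descriptor. The maximum is the signed maximum of the raw channel
    values; pass each channel through ``abs`` beforehand if magnitude
    maxima are wanted instead (see ``abs_max``).
    """
    if not selected:
        raise ValueError("collapse_features needs a nonempty selection")
    out = np.empty(2 * len(selected))
    for s, f in enumerate(selected):
        v = x_features[f]  # (N_f, 2)
        out[2 * s] = v[:, 0].max()
        out[2 * s + 1] = v[:, 1].max()
    return out


def collapse_features_abs(
    x_features: FeatureSet, selected: Sequence[FeatureDescriptor]
) -> np.ndarray:
    """Magnitude variant: per-channel maximum of absolute values.

    Signed maxima truncate downward/leftward motion; this variant keeps
    such motion visible but departs from the plain-max collapse that is
    the default.
    """
    if not selected:
        raise ValueError("collapse_features needs a nonempty selection")
    out = np.empty(2 * len(selected))
    for s, f in enumerate(selected):
        v = np.abs(x_features[f])
        out[2 * s] = v[:, 0].max()
        out[2 * s + 1] = v[:, 1].max()
    return out


def default_grid() -> dict:
    """Exponential (C, gamma) grid: C in 2^-5..2^15, gamma in 2^-15..2^3,
    step 2 in the exponent."""
    return {
        "svc__C": [2.0**e for e in range(-5, 16, 2)],
        "svc__gamma": [2.0**e for e in range(-15, 4, 2)],
    }


def train_svm(
    features: np.ndarray,
    labels: Sequence[int],
    grid: dict | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> GridSearchCV:
    """Grid-searched RBF SVM on collapsed features.

    Scaling to [-1, 1] per dimension happens inside the CV pipeline so the
    scaler only ever sees training folds. Returns the fitted search object
    (use :func:`predict_svm` or ``.predict``).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix (n_samples, n_dims)")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train an SVM")
    pipe = Pipeline(
        [("scale", MinMaxScaler(feature_range=(-1, 1))), ("svc", SVC(kernel="rbf"))]
    )
    counts = np.bincount(y)
    folds = int(min(cv_folds, counts[counts > 0].min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid or default_grid(), cv=cv, n_jobs=None)
        search.fit(X, y)
        return search
    # degenerate: too few samples per class for CV; fit defaults directly
    pipe.fit(X, y)
    return pipe


def predict_svm(handle, features: np.ndarray) -> np.ndarray:
    """Predict class ids for a matrix of collapsed features."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    return np.asarray(handle.predict(X), dtype=int)
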