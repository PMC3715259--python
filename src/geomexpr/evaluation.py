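"""Stratified five-fold evaluation of the full pipeline.

Per fold, everything is fit on the training folds only — the reference
frame, the prototype bank, the boosted descriptor selection, and (on the
SVM path) the collapsed-feature scaler and grid-searched SVM — and the
held-out fold is predicted. Training sequences are resampled to a common
frame count so the elementwise prototype median is defined; test
sequences stay at their original length on the AdaBoost path because DTW
absorbs length differences, and the collapsed max features of the SVM
path are frame-count independent anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .boosting import (
    BoostTrace,
    StrongClassifier,
    samme_train,
    strong_classify_batch,
    vote_matrix,
)
from .dtw import DtwConfig
from .features import build_feature_pool, extract_all
from .prototypes import build_prototypes
from .sequences import LandmarkSequence, compute_reference, normalize_sequence, resample_sequence
from .svm import collapse_features, predict_svm, train_svm

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "PipelineConfig",
    "CVResult",
    "make_folds",
    "confusion_from_predictions",
    "run_cv",
]


@dataclass
class FoldPlan:
    """Stratified partition into k disjoint test folds."""

    test_indices: list[np.ndarray]
    seed: int

    @property
    def k(self) -> int:
        return len(self.test_indices)

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.test_indices[fold].tolist())
        n = sum(len(t) for t in self.test_indices)
        return np.array([i for i in range(n) if i not in test])


def make_folds(labels: Sequence[int], k_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition, reproducible per seed."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    small = np.flatnonzero((counts > 0) & (counts < k_folds))
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than {k_folds} sequences"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    tests = [test for _, test in skf.split(np.zeros(len(y)), y)]
    return FoldPlan(test_indices=tests, seed=seed)


@dataclass
class ConfusionMatrix:
    """Raw counts and row percentages; rows = actual, columns = predicted."""

    counts: np.ndarray
    classes: list[int]

    @property
    def percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return 100.0 * self.counts / totals

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_text(self) -> str:
        header = "actual\\pred " + " ".join(f"{c:>8}" for c in self.classes)
        lines = [header]
        pct = self.percentages
        for r, c in enumerate(self.classes):
            lines.append(
                f"{c:>11} " + " ".join(f"{pct[r, k]:8.2f}" for k in range(len(self.classes)))
            )
        return "\n".join(lines)


def confusion_from_predictions(
    true_labels: Sequence[int], predicted: Sequence[int], classes: Sequence[int] | None = None
) -> ConfusionMatrix:
    y, p = np.asarray(true_labels, dtype=int), np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValueError("true and predicted label lists must have equal length")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y, p])).tolist())
    classes = list(classes)
    pos = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for yi, pi in zip(y, p):
        counts[pos[yi], pos[pi]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings for :func:`run_cv`."""

    classifier: str = "adaboost"  # "adaboost" | "svm" | "both"
    n_resample: int = 16  # training frame count (15 feature elements)
    boost_rounds: int = 60
    k_folds: int = 5
    seed: int = 0
    dtw: DtwConfig = field(default_factory=DtwConfig)
    svm_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.classifier not in ("adaboost", "svm", "both"):
            raise ValueError(f"unknown classifier path {self.classifier!r}")


@dataclass
class CVResult:
    """Cross-validation outputs per classifier path."""

    fold_accuracies: dict[str, list[float]]
    confusion: dict[str, ConfusionMatrix]
    traces: list[BoostTrace]
    config: PipelineConfig

    def mean_accuracy(self, path: str) -> float:
        return float(np.mean(self.fold_accuracies[path]))


@dataclass
class FittedFold:
    """Everything fit on one training fold."""

    reference: "object"
    bank: "object"
    classifier: StrongClassifier
    trace: BoostTrace
    pool: list
    svm_handle: object | None = None

    def predict(self, test: Sequence[LandmarkSequence], path: str, dtw: DtwConfig | None = None) -> np.ndarray:
        test_n = [normalize_sequence(s, self.reference) for s in test]
        test_fs = [extract_all(s, self.pool) for s in test_n]
        if path == "adaboost":
            votes = vote_matrix(test_fs, self.bank, dtw)
            sel = [self.bank.descriptor_index(f) for f in self.classifier.descriptors]
            return strong_classify_batch(votes, sel, self.classifier.alphas, self.bank.classes)
        if path == "svm":
            if self.svm_handle is None:
                raise ValueError("this fold was fit without the SVM path")
            X = np.stack([collapse_features(fs, self.classifier.descriptors) for fs in test_fs])
            return predict_svm(self.svm_handle, X)
        raise ValueError(f"unknown path {path!r}")


def fit_fold(train: Sequence[LandmarkSequence], config: PipelineConfig | None = None) -> FittedFold:
    """Fit the full pipeline on one training fold.

    Only ``train`` is consulted: the reference frame, prototypes, boosted
    selection and (for the SVM path) scaler + grid search all come from
    these sequences alone.
    """
    config = config or PipelineConfig()
    train = list(train)
    y_tr = np.array([s.label for s in train], dtype=int)
    pool = build_feature_pool(train[0].n_landmarks)
    ref = compute_reference(train)
    train_n = [normalize_sequence(s, ref) for s in train]
    train_r = [resample_sequence(s, config.n_resample) for s in train_n]
    train_stack = np.stack([extract_all(s, pool).values for s in train_r])
    bank = build_prototypes(train_r, pool, features=train_stack, labels=y_tr)
    votes = vote_matrix(train_stack, bank, config.dtw)
    clf, trace = samme_train(
        train_stack, y_tr, bank, pool, config.boost_rounds, config.dtw, votes=votes
    )
    handle = None
    if config.classifier in ("svm", "both"):
        train_fs = [extract_all(s, pool) for s in train_n]  # original length
        X_tr = np.stack([collapse_features(fs, clf.descriptors) for fs in train_fs])
        handle = train_svm(X_tr, y_tr, grid=config.svm_grid, seed=config.seed)
    return FittedFold(ref, bank, clf, trace, pool, handle)


def run_cv(dataset: Sequence[LandmarkSequence], config: PipelineConfig | None = None) -> CVResult:
    """Run the five-fold protocol on a labeled dataset.

    Returns per-fold and mean accuracies, pooled confusion matrices (one
    per classifier path), and the per-fold boosting traces.
    """
    config = config or PipelineConfig()
    dataset = list(dataset)
    labels = np.array([s.label for s in dataset], dtype=int)
    plan = make_folds(labels, config.k_folds, config.seed)

    paths = ["adaboost", "svm"] if config.classifier == "both" else [config.classifier]
    fold_acc: dict[str, list[float]] = {p: [] for p in paths}
    all_true: list[int] = []
    all_pred: dict[str, list[int]] = {p: [] for p in paths}
    traces: list[BoostTrace] = []

    for fold in range(plan.k):
        tr_idx = plan.train_indices(fold)
        te_idx = plan.test_indices[fold]
        train = [dataset[i] for i in tr_idx]
        test = [dataset[i] for i in te_idx]
        y_te = labels[te_idx]

        fitted = fit_fold(train, config)
        traces.append(fitted.trace)
        for p in paths:
            pred = fitted.predict(test, p, config.dtw)
            fold_acc[p].append(float(np.mean(pred == y_te)))
            all_pred[p].extend(pred.tolist())
        all_true.extend(y_te.tolist())

    classes = sorted(np.unique(labels).tolist())
    confusion = {
        p: confusion_from_predictions(all_true, all_pred[p], classes) for p in paths
    }
    return CVResult(fold_accuracies=fold_acc, confusion=confusion, traces=traces, config=config)
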