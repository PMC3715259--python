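"""Multi-class AdaBoost (SAMME) over DTW nearest-prototype weak classifiers.

Boosting here is a feature-selection device: every weak classifier is
fully determined by a single pool descriptor (no learning inside the
weak rule), so each boosting round picks the descriptor with the
smallest weighted training error, weights it by

    alpha = log((1 - err) / err) + log(K - 1),

and up-weights the samples it misclassified. The log(K - 1) term is what
lets weak classifiers that are merely better than random K-class
guessing (accuracy > 1/K) receive positive weight; with K = 2 the
procedure is exactly the classic discrete binary AdaBoost.

Weak outputs do not depend on the sample weights, so all votes are
precomputed once into an (n_samples, D) matrix and every round is a
weighted column scan. Descriptors are selected without replacement, so
"number of selected features" equals the number of rounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dtw import DtwConfig
from .features import FeatureDescriptor, FeatureSet
from .prototypes import PrototypeBank, weak_votes

__all__ = [
    "StrongClassifier",
    "BoostTrace",
    "samme_train",
    "strong_classify",
    "select_features_ova",
    "weak_confusion_scores",
    "vote_matrix",
]

_ERR_FLOOR = 1e-10
_RANDOM_GUESS_MARGIN = 1e-12


@dataclass
class StrongClassifier:
    """Weighted vote of the boosted single-descriptor weak classifiers."""

    rounds: list[tuple[FeatureDescriptor, float]]
    K: int
    bank: PrototypeBank
    exhausted: bool = False  # True if the pool ran out of useful candidates early

    @property
    def descriptors(self) -> list[FeatureDescriptor]:
        return [f for f, _ in self.rounds]

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for _, a in self.rounds])

    def truncated(self, M: int) -> "StrongClassifier":
        """The strong classifier using only the first M rounds."""
        return StrongClassifier(self.rounds[:M], self.K, self.bank, self.exhausted)

    def to_json(self, path) -> None:
        payload = {
            "format": "geomexpr-strong-classifier",
            "version": 1,
            "K": self.K,
            "rounds": [[f.kind, f.i, f.j, a] for f, a in self.rounds],
            "bank_checksum": self.bank.checksum(),
            "exhausted": self.exhausted,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class BoostTrace:
    """Per-round diagnostics of a boosting run."""

    errors: list[float] = field(default_factory=list)
    descriptors: list[FeatureDescriptor] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "round": np.arange(1, len(self.errors) + 1),
                "descriptor": [repr(f) for f in self.descriptors],
                "err": self.errors,
                "alpha": self.alphas,
                "train_accuracy": self.train_accuracy,
            }
        ).to_csv(path, index=False)


def vote_matrix(
    feature_sets: Sequence[FeatureSet] | np.ndarray,
    bank: PrototypeBank,
    cfg: DtwConfig | None = None,
) -> np.ndarray:
    """Precompute weak votes: entry (s, f) is the class voted for sample s
    by the descriptor-f weak classifier. Sequences may differ in length."""
    if isinstance(feature_sets, np.ndarray):
        from .dtw import dtw_matrix_resampled

        dist = dtw_matrix_resampled(feature_sets, bank.values, cfg)  # (n, D, K)
        return np.asarray(bank.classes)[np.argmin(dist, axis=2)]
    return np.stack([weak_votes(fs, bank, cfg) for fs in feature_sets])


def _boost_rounds(
    votes: np.ndarray,
    labels: np.ndarray,
    K: int,
    M: int,
) -> tuple[list[int], list[float], BoostTrace, bool]:
    """Shared SAMME loop on a precomputed vote matrix.

    Returns selected descriptor column indices, alphas, the trace, and an
    ``exhausted`` flag set when no remaining candidate beats random
    guessing before M rounds complete.
    """
    n, D = votes.shape
    incorrect = votes != labels[:, None]  # (n, D)
    w = np.full(n, 1.0 / n)
    selected: list[int] = []
    alphas: list[float] = []
    trace = BoostTrace()
    available = np.ones(D, dtype=bool)
    # running class scores for the training-accuracy curve
    class_ids = np.unique(np.concatenate([labels, votes.ravel()]))
    scores = np.zeros((n, len(class_ids)))
    exhausted = False
    for _ in range(M):
        w = w / w.sum()
        errs = w @ incorrect  # (D,)
        errs_masked = np.where(available, errs, np.inf)
        best = int(np.argmin(errs_masked))  # ties -> lowest descriptor index
        err = float(errs_masked[best])
        if not np.isfinite(err) or err >= (K - 1) / K - _RANDOM_GUESS_MARGIN:
            exhausted = True
            break
        err_c = max(err, _ERR_FLOOR)
        alpha = math.log((1.0 - err_c) / err_c) + math.log(K - 1)
        selected.append(best)
        alphas.append(alpha)
        available[best] = False
        w = w * np.exp(alpha * incorrect[:, best])
        # trace
        scores[np.arange(n), np.searchsorted(class_ids, votes[:, best])] += alpha
        pred = class_ids[np.argmax(scores, axis=1)]
        trace.errors.append(err)
        trace.alphas.append(alpha)
        trace.train_accuracy.append(float(np.mean(pred == labels)))
    return selected, alphas, trace, exhausted


def samme_train(
    train_features: Sequence[FeatureSet] | np.ndarray,
    labels: Sequence[int],
    bank: PrototypeBank,
    pool: Sequence[FeatureDescriptor],
    M: int,
    cfg: DtwConfig | None = None,
    votes: np.ndarray | None = None,
) -> tuple[StrongClassifier, BoostTrace]:
    """Run M rounds of SAMME feature selection.

    Parameters
    ----------
    train_features
        Per-sequence feature sets (or a dense ``(n, D, N, 2)`` stack when
        all training sequences share a frame count), pool-aligned.
    labels
        Class labels, one per training sequence.
    bank
        Prototype bank built on the same training fold.
    pool
        Descriptor pool; must match the bank's pool.
    M
        Number of boosting rounds (= number of selected descriptors).
    votes
        Optional precomputed vote matrix from :func:`vote_matrix`.

    Training stops early (with ``exhausted=True`` on the classifier) if no
    remaining descriptor classifies better than random guessing under the
    current weights.
    """
    labels = np.asarray(labels, dtype=int)
    if M < 1:
        raise ValueError("M must be at least 1")
    K = bank.n_classes
    if labels.shape[0] < K:
        raise ValueError("need at least one training sample per class")
    if list(pool) != bank.pool:
        raise ValueError("pool does not match the prototype bank's pool")
    if votes is None:
        votes = vote_matrix(train_features, bank, cfg)
    selected, alphas, trace, exhausted = _boost_rounds(votes, labels, K, M)
    rounds = [(pool[k], a) for k, a in zip(selected, alphas)]
    trace.descriptors = [pool[k] for k in selected]
    return StrongClassifier(rounds, K, bank, exhausted), trace


def strong_classify(
    x_features: FeatureSet,
    clf: StrongClassifier,
    cfg: DtwConfig | None = None,
) -> int:
    """Predict with the boosted strong classifier.

    The class with the largest sum of alphas over agreeing weak
    classifiers wins; ties go to the smallest class index.
    """
    bank = clf.bank
    classes = np.asarray(bank.classes)
    scores = np.zeros(len(classes))
    from .prototypes import weak_classify

    for f, alpha in clf.rounds:
        vote = weak_classify(x_features, bank, f, cfg)
        scores[np.searchsorted(classes, vote)] += alpha
    return int(classes[int(np.argmax(scores))])


def strong_classify_batch(
    votes: np.ndarray,
    descriptor_indices: Sequence[int],
    alphas: Sequence[float],
    classes: Sequence[int],
) -> np.ndarray:
    """Vectorized strong-classifier prediction from a precomputed vote matrix."""
    classes = np.asarray(classes)
    n = votes.shape[0]
    scores = np.zeros((n, len(classes)))
    for k, alpha in zip(descriptor_indices, alphas):
        col = np.searchsorted(classes, votes[:, k])
        scores[np.arange(n), col] += alpha
    return classes[np.argmax(scores, axis=1)]


def select_features_ova(
    train_features: Sequence[FeatureSet] | np.ndarray,
    labels: Sequence[int],
    bank: PrototypeBank,
    pool: Sequence[FeatureDescriptor],
    positive_class: int,
    M: int,
    cfg: DtwConfig | None = None,
    votes: np.ndarray | None = None,
) -> tuple[list[FeatureDescriptor], list[float], BoostTrace]:
    """One-vs-all descriptor ranking for a single expression class.

    The weak rule keeps all K class prototypes and calls a sample positive
    iff the positive class attains the minimum DTW distance; boosting then
    runs with binary labels (K = 2 in the alpha formula, i.e. classic
    AdaBoost). Returns descriptors in selection order with their alphas.
    """
    labels = np.asarray(labels, dtype=int)
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class} has no training samples")
    if votes is None:
        votes = vote_matrix(train_features, bank, cfg)
    bin_votes = (votes == positive_class).astype(int)
    bin_labels = (labels == positive_class).astype(int)
    selected, alphas, trace, _ = _boost_rounds(bin_votes, bin_labels, 2, M)
    trace.descriptors = [pool[k] for k in selected]
    return [pool[k] for k in selected], alphas, trace


def weak_confusion_scores(
    clf: StrongClassifier,
    test_features: Sequence[FeatureSet],
    labels: Sequence[int],
    cfg: DtwConfig | None = None,
) -> np.ndarray:
    """Confusion scores of the selected weak classifiers, in percent.

    Entry (c, k) is the percentage of (weak classifier, test sample of true
    class c) pairs voting class k; each row sums to 100.
    """
    labels = np.asarray(labels, dtype=int)
    if len(test_features) == 0:
        raise ValueError("need a nonempty test set")
    bank = clf.bank
    classes = np.asarray(bank.classes)
    K = len(classes)
    sel = [bank.descriptor_index(f) for f in clf.descriptors]
    counts = np.zeros((K, K))
    for fs, lab in zip(test_features, labels):
        v = weak_votes(fs, bank, cfg)[sel]
        row = np.searchsorted(classes, lab)
        for vote in v:
            counts[row, np.searchsorted(classes, vote)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return 100.0 * counts / totals
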