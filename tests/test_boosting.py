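import math

import numpy as np
import pytest

from geomexpr import (
    GenConfig,
    build_feature_pool,
    build_prototypes,
    default_class_models,
    extract_all,
    generate_dataset,
    samme_train,
    select_features_ova,
    strong_classify,
    weak_confusion_scores,
)
from geomexpr.boosting import _boost_rounds, strong_classify_batch, vote_matrix
from geomexpr.features import FeatureDescriptor
from geomexpr.prototypes import PrototypeBank
from geomexpr.sequences import compute_reference, normalize_sequence, resample_sequence

from test_prototypes import make_seq


def make_bank_from_displacements(protos_by_class, L=2):
    """Bank whose class prototypes equal the given per-landmark displacements."""
    pool = build_feature_pool(L)
    seqs = [
        make_seq(disp, label=c, L=L, sequence_id=f"p{c}")
        for c, disp in protos_by_class.items()
    ]
    return build_prototypes(seqs, pool), pool


class TestAlphaFormula:
    def test_half_error_six_classes(self):
        # err = 0.5, K = 6: alpha = log(5)
        votes = np.array([[1], [1], [2], [2]])  # two of four wrong
        labels = np.array([1, 1, 1, 1])
        sel, alphas, trace, _ = _boost_rounds(votes, labels, K=6, M=1)
        assert alphas[0] == pytest.approx(math.log(1.0) + math.log(5), abs=1e-12)
        assert trace.errors[0] == pytest.approx(0.5)

    def test_binary_reduces_to_classic_weight(self):
        votes = np.array([[1], [1], [1], [0]])
        labels = np.array([1, 1, 0, 0])  # err = 0.25
        _, alphas, _, _ = _boost_rounds(votes, labels, K=2, M=1)
        assert alphas[0] == pytest.approx(math.log(0.75 / 0.25), abs=1e-12)


class TestHandSimulatedRound:
    """One round of the boosting loop against a hand-computed ledger.

    Setup (K=3, n=4, two candidate descriptors):
      descriptor A votes [1, 2, 3, 3] on labels [1, 2, 3, 1] -> err 1/4
      descriptor B votes [1, 1, 1, 1]                        -> err 2/4
    Round 1 must select A with alpha = log(3) + log(2) = log 6, and
    multiply sample 4's weight by 6, so round 2 sees B's error as
    2/9 and selects it with alpha = log(3.5) + log(2) = log 7.
    """

    def test_two_round_ledger(self):
        votes = np.array([[1, 1], [2, 1], [3, 1], [3, 1]])
        labels = np.array([1, 2, 3, 1])
        sel, alphas, trace, exhausted = _boost_rounds(votes, labels, K=3, M=2)
        assert sel == [0, 1]
        assert alphas[0] == pytest.approx(math.log(6), abs=1e-12)
        assert trace.errors == pytest.approx([0.25, 2.0 / 9.0], abs=1e-12)
        assert alphas[1] == pytest.approx(math.log(3.5) + math.log(2), abs=1e-12)
        assert not exhausted

    def test_same_ledger_through_full_api(self):
        # the same toy driven end to end through DTW weak classifiers:
        # prototypes at well-separated values, samples placed to vote as above
        bank, pool = make_bank_from_displacements(
            {1: [[1, 0], [1, 0]], 2: [[2, 0], [1, 0]], 3: [[3, 0], [1, 0]]}
        )
        # descriptor type1(0) votes [1,2,3,3]; type1(1) votes [1,1,1,1]
        samples = [
            make_seq([[1, 0], [1, 0]], label=1, sequence_id="s1"),
            make_seq([[2, 0], [1, 0]], label=2, sequence_id="s2"),
            make_seq([[3, 0], [1, 0]], label=3, sequence_id="s3"),
            make_seq([[3, 0], [1, 0]], label=1, sequence_id="s4"),
        ]
        labels = [s.label for s in samples]
        feats = [extract_all(s, pool) for s in samples]
        votes = vote_matrix(feats, bank)
        np.testing.assert_array_equal(votes[:, 0], [1, 2, 3, 3])
        np.testing.assert_array_equal(votes[:, 1], [1, 1, 1, 1])
        clf, trace = samme_train(feats, labels, bank, pool, M=2, votes=votes)
        assert clf.descriptors[0] == pool[0]
        assert clf.alphas[0] == pytest.approx(math.log(6), abs=1e-12)
        assert trace.errors[0] == pytest.approx(0.25, abs=1e-12)


class TestBinaryReduction:
    def test_matches_reference_binary_adaboost(self, rng):
        """With K=2 the loop must agree exactly with classic discrete
        AdaBoost run on the same fixed weak outputs."""
        n, D, M = 30, 12, 6
        votes = rng.integers(0, 2, size=(n, D))
        labels = rng.integers(0, 2, size=n)
        sel, alphas, trace, _ = _boost_rounds(votes, labels, K=2, M=M)

        # independent reference implementation (Freund-Schapire discrete
        # AdaBoost, selection without replacement)
        w = np.full(n, 1.0 / n)
        remaining = list(range(D))
        ref_sel, ref_alpha, ref_err = [], [], []
        for _ in range(M):
            w = w / w.sum()
            errs = [(w * (votes[:, f] != labels)).sum() for f in remaining]
            b = int(np.argmin(errs))
            err = errs[b]
            if err >= 0.5 - 1e-12:
                break
            f = remaining.pop(b)
            a = math.log((1 - err) / err)
            ref_sel.append(f)
            ref_alpha.append(a)
            ref_err.append(err)
            w = w * np.exp(a * (votes[:, f] != labels))
        assert sel == ref_sel
        np.testing.assert_allclose(alphas, ref_alpha, atol=1e-12)
        np.testing.assert_allclose(trace.errors, ref_err, atol=1e-12)


class TestStrongClassify:
    def test_single_round_equals_weak(self):
        bank, pool = make_bank_from_displacements(
            {1: [[1, 0], [0, 0]], 2: [[5, 0], [0, 0]], 3: [[9, 0], [0, 0]]}
        )
        feats = [extract_all(make_seq([[v, 0], [0, 0]], label=None), pool) for v in (1, 5, 9)]
        votes = vote_matrix(feats, bank)
        clf, _ = samme_train(
            [extract_all(make_seq([[v, 0], [0, 0]], label=c), pool) for v, c in ((1, 1), (5, 2), (9, 3))],
            [1, 2, 3], bank, pool, M=1,
        )
        assert len(clf.rounds) == 1
        for fs, expect in zip(feats, (1, 2, 3)):
            assert strong_classify(fs, clf) == expect

    def test_alpha_sums_decide(self):
        # votes {A: 1.0} vs {B: 0.5 + 0.4} -> A wins
        bank, pool = make_bank_from_displacements(
            {1: [[1, 0], [0, 0]], 2: [[9, 0], [9, 0]]}
        )
        clf_rounds = [(pool[0], 1.0), (pool[1], 0.5), (pool[2], 0.4)]
        from geomexpr.boosting import StrongClassifier

        clf = StrongClassifier(clf_rounds, K=2, bank=bank)
        # sample votes class 1 on descriptor 0, class 2 on the others
        fs = extract_all(make_seq([[1, 0], [9, 0]], label=None), pool)
        assert strong_classify(fs, clf) == 1

    def test_batch_matches_summation_oracle(self, rng):
        bank, pool = make_bank_from_displacements(
            {1: [[1, 0], [2, 0]], 2: [[4, 2], [0, 3]], 3: [[0, 6], [6, 0]]}
        )
        feats = [
            extract_all(make_seq(rng.normal(0, 3, (2, 2)), label=None), pool)
            for _ in range(15)
        ]
        votes = vote_matrix(feats, bank)
        alphas = rng.uniform(0.1, 2.0, size=3)
        sel = [0, 1, 2]
        batch = strong_classify_batch(votes, sel, alphas, bank.classes)
        for s, fs in enumerate(feats):
            scores = {c: 0.0 for c in bank.classes}
            for k, a in zip(sel, alphas):
                scores[votes[s, k]] += a
            expect = min(
                (c for c in bank.classes),
                key=lambda c: (-scores[c], c),
            )
            assert batch[s] == expect


class TestOvaSelection:
    def _planted(self, seed, K=3, n_per=10, D=15, N=8, planted=7):
        """Feature stack where only one descriptor carries class signal."""
        rng = np.random.default_rng(seed)
        n = K * n_per
        labels = np.repeat(np.arange(1, K + 1), n_per)
        feats = rng.normal(0.0, 1.0, size=(n, D, N, 2))
        ramp = np.linspace(0, 1, N)
        for s in range(n):
            target = 5.0 if labels[s] == 1 else -5.0
            feats[s, planted, :, 0] = target * ramp + rng.normal(0, 0.3, N)
            feats[s, planted, :, 1] = rng.normal(0, 0.3, N)
        pool = build_feature_pool(5)
        assert len(pool) == D
        # prototypes: per-class elementwise medians of the planted stack
        classes = [1, 2, 3]
        values = np.stack([np.median(feats[labels == c], axis=0) for c in classes])
        bank = PrototypeBank(classes, pool, values)
        return feats, labels, bank, pool, planted

    def test_planted_descriptor_selected_first(self):
        feats, labels, bank, pool, planted = self._planted(seed=0)
        selected, alphas, _ = select_features_ova(feats, labels, bank, pool, 1, M=3)
        assert selected[0] == pool[planted]
        assert alphas[0] > 0

    def test_zero_error_terminates_cleanly(self):
        feats, labels, bank, pool, planted = self._planted(seed=1)
        # the planted descriptor separates perfectly -> err floor engages,
        # selection continues over the remaining pool without blowing up
        selected, alphas, trace = select_features_ova(feats, labels, bank, pool, 1, M=5)
        assert selected[0] == pool[planted]
        assert all(np.isfinite(alphas))

    def test_indistinguishable_classes_select_nothing(self):
        rng = np.random.default_rng(3)
        pool = build_feature_pool(2)
        D, N = len(pool), 6
        feats = np.zeros((8, D, N, 2))  # all samples identical
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        values = np.stack([np.median(feats[labels == c], axis=0) for c in (1, 2)])
        bank = PrototypeBank([1, 2], pool, values)
        selected, alphas, _ = select_features_ova(feats, labels, bank, pool, 1, M=4)
        assert selected == [] and alphas == []

    def test_missing_positive_class(self):
        feats, labels, bank, pool, _ = self._planted(seed=2)
        with pytest.raises(ValueError):
            select_features_ova(feats, labels, bank, pool, positive_class=9, M=2)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    train = small_dataset
    ref = compute_reference(train)
    res = [resample_sequence(normalize_sequence(s, ref), 16) for s in train]
    pool = build_feature_pool(52)
    labels = np.array([s.label for s in train])
    feats = np.stack([extract_all(s, pool).values for s in res])
    bank = build_prototypes(res, pool, features=feats, labels=labels)
    votes = vote_matrix(feats, bank)
    clf, trace = samme_train(feats, labels, bank, pool, M=25, votes=votes)
    return clf, trace, votes, labels, bank


class TestTrainingDynamics:
    def test_alphas_positive_and_descriptors_distinct(self, fitted):
        clf, trace, *_ = fitted
        assert all(a > 0 for a in clf.alphas)
        assert len(set(clf.descriptors)) == len(clf.descriptors)

    def test_training_accuracy_reaches_saturation(self, fitted):
        _, trace, *_ = fitted
        # monotone up to saturation on separable synthetic data
        acc = np.array(trace.train_accuracy)
        assert acc[-1] >= acc[0]
        assert acc[-1] >= 0.99

    def test_confusion_scores_rows_sum_to_100(self, fitted, small_dataset):
        clf, _, votes, labels, bank = fitted
        ref = compute_reference(small_dataset)
        # two test sequences per class so every confusion row is populated
        subset = [s for c in range(1, 7) for s in [t for t in small_dataset if t.label == c][:2]]
        fs = [extract_all(normalize_sequence(s, ref), bank.pool) for s in subset]
        scores = weak_confusion_scores(clf, fs, [s.label for s in subset])
        np.testing.assert_allclose(scores.sum(axis=1), 100.0, atol=1e-9)

    def test_confusion_scores_counting_oracle(self):
        bank, pool = make_bank_from_displacements(
            {1: [[1, 0], [0, 0]], 2: [[9, 0], [0, 0]]}
        )
        from geomexpr.boosting import StrongClassifier

        clf = StrongClassifier([(pool[0], 1.0), (pool[1], 0.7)], K=2, bank=bank)
        feats = [
            extract_all(make_seq([[1, 0], [0, 0]], label=None), pool),
            extract_all(make_seq([[9, 0], [0, 0]], label=None), pool),
        ]
        labels = [1, 2]
        scores = weak_confusion_scores(clf, feats, labels)
        # double-loop oracle
        from geomexpr.prototypes import weak_classify

        counts = np.zeros((2, 2))
        for fs, lab in zip(feats, labels):
            for f in clf.descriptors:
                v = weak_classify(fs, bank, f)
                counts[lab - 1, v - 1] += 1
        expect = 100.0 * counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(scores, expect, atol=1e-9)
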