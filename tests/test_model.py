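import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtqsar.errors import DegenerateLabelsError, LengthMismatchError
from mtqsar.model import (
    ConfusionStats,
    InteractionMLPClassifier,
    confusion_stats,
    per_class_report,
    roc_auc,
    split_dataset,
    train_mlp,
)
from mtqsar.pipeline import repeat_model_search


class TestSplit:
    def test_70_30_exact_on_100(self):
        split = split_dataset(100, 0.70, seed=1)
        assert len(split.train_indices) == 70 and len(split.valid_indices) == 30

    def test_deterministic(self):
        assert split_dataset(57, seed=9) == split_dataset(57, seed=9)

    def test_partitions_disjoint_and_exhaustive(self):
        split = split_dataset(101, seed=2)
        tr, va = set(split.train_indices), set(split.valid_indices)
        assert tr.isdisjoint(va) and tr | va == set(range(101))

    def test_different_seeds_differ(self):
        assert split_dataset(100, seed=0) != split_dataset(100, seed=1)


class TestConfusionStats:
    def test_perfect_predictions(self):
        cs = confusion_stats([1, 1, 0, 0], [1, 1, 0, 0])
        assert cs.mcc == 1.0 and cs.accuracy == 1.0

    def test_degenerate_all_one_class(self):
        cs = confusion_stats([1, 1, 1], [1, 0, 1])
        assert cs.mcc == 0.0 and cs.mcc_degenerate

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            confusion_stats([1, 0], [1])

    def test_counts_exact(self):
        cs = confusion_stats([1, 0, 1, 0, 1], [1, 1, 0, 0, 1])
        assert (cs.tp, cs.tn, cs.fp, cs.fn) == (2, 1, 1, 1)
        assert cs.accuracy * cs.total == cs.tp + cs.tn

    @given(
        st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mcc_swap_and_negation_invariants(self, tp, tn, fp, fn):
        cs = ConfusionStats(tp=tp, tn=tn, fp=fp, fn=fn)
        swapped = ConfusionStats(tp=tn, tn=tp, fp=fn, fn=fp)
        inverted = ConfusionStats(tp=fn, tn=fp, fp=tn, fn=tp)
        assert cs.mcc == pytest.approx(swapped.mcc, abs=1e-12)
        assert cs.mcc == pytest.approx(-inverted.mcc, abs=1e-12)
        assert -1.0 <= cs.mcc <= 1.0


def _mann_whitney_auc(scores, labels):
    """Brute-force pairwise comparison oracle for the AUC."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, area = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert area == 1.0

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, size=80)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=80)
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(scores, 1 - labels)
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(20, 200))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.uniform(size=n) + 0.3 * labels
            _, area = roc_auc(scores, labels)
            assert area == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        _, area = roc_auc(scores, labels)
        assert area == pytest.approx(0.5, abs=0.02)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_auc([0.1, 0.9], [1, 1])


def _two_gaussians(seed=0, n=500, d=3.0, p=6):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] += d * y  # class shift on the first feature
    return X, y


class TestMlpTraining:
    def test_separable_data_high_training_accuracy(self):
        X, y = _two_gaussians()
        # brute-force linear scan: verify a threshold on feature 0 separates well
        best = max(
            np.mean((X[:, 0] > t) == y) for t in np.linspace(X[:, 0].min(), X[:, 0].max(), 200)
        )
        assert best >= 0.90
        clf = train_mlp(X, y, n_hidden=10, seed=0)
        assert np.mean(clf.predict(X) == y) >= 0.90

    def test_seed_determinism_identical_weights(self):
        X, y = _two_gaussians(seed=4, n=200)
        a = train_mlp(X, y, n_hidden=8, seed=5)
        b = train_mlp(X, y, n_hidden=8, seed=5)
        np.testing.assert_array_equal(a.weights_.w1, b.weights_.w1)
        np.testing.assert_array_equal(a.weights_.w2, b.weights_.w2)

    def test_different_seeds_differ(self):
        X, y = _two_gaussians(seed=4, n=200)
        a = train_mlp(X, y, n_hidden=8, seed=1)
        b = train_mlp(X, y, n_hidden=8, seed=2)
        assert not np.array_equal(a.weights_.w1, b.weights_.w1)

    def test_zero_hidden_rejected(self):
        X, y = _two_gaussians(n=50)
        with pytest.raises(ValueError):
            InteractionMLPClassifier(n_hidden=0).fit(X, y)

    def test_probability_pair_sums_to_one(self):
        X, y = _two_gaussians(seed=2, n=150)
        clf = train_mlp(X, y, n_hidden=6, seed=0)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((proba >= 0) & (proba <= 1))


class TestPerClassReport:
    def test_three_class_fixture(self):
        fams = ["1.1"] * 4 + ["2.7"] * 4 + ["3.2"] * 4
        true = [1, 1, 0, 0] * 3
        pred = [1, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 1]
        rep = per_class_report(true, pred, fams).rows
        assert len(rep) == 3
        assert rep["acc_interacting"].between(0, 1).all()
        row27 = rep[rep["ec_family"] == "2.7"].iloc[0]
        assert row27["acc_interacting"] == 1.0 and row27["acc_non_interacting"] == 1.0

    def test_ec_numeric_sort_order(self):
        fams = ["1.11", "1.2", "7.2", "1.1"]
        rep = per_class_report([1, 1, 1, 1], [1, 1, 1, 1], fams).rows
        assert rep["ec_family"].tolist() == ["1.1", "1.2", "1.11", "7.2"]


class TestRepeatSearch:
    def test_ranked_entries(self, small_dataset):
        pairs, _ = small_dataset
        entries = repeat_model_search(
            pairs, n_models=3, hidden_range=(10, 10), seed=0, max_features=4, max_iter=150
        )
        assert len(entries) == 3
        assert all(e.n_hidden == 10 for e in entries)
        accs = [e.stats_overall.accuracy for e in entries]
        assert accs == sorted(accs, reverse=True)
        # fresh split per model
        assert len({e.split for e in entries}) == 3
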