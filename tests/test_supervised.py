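"""Fold construction, oversampling, classifiers, permutation null, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emocat import supervised
from emocat.supervised import (
    ClassifierConfig,
    build_folds,
    crossval_classifier,
    oversample_minority,
    permutation_null,
    t_test_vs_chance,
    top_labels_filter,
)

FAST_MLP = ClassifierConfig(hidden=(16,), dropout=0.1, max_epochs=40, lr=1e-2, seed=0)


def separable_data(n_per_class=30, n_classes=3, d=6, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.eye(n_classes, d) * 12.0
    labels = np.repeat(np.arange(n_classes), n_per_class)
    X = centers[labels] + rng.normal(size=(len(labels), d))
    return X, labels


class TestBuildFolds:
    def test_leave_one_run_out_matches_runs(self):
        labels = np.repeat([0, 1, 2], 60)
        run_ids = np.tile(np.arange(6), 30)
        folds = build_folds(labels, run_ids, scheme="leave-one-run-out")
        assert folds.k == 6
        sizes = [len(test) for _, test in folds.split()]
        assert sizes == [30] * 6

    def test_k_equals_n_is_leave_one_out(self):
        labels = np.tile([0, 1], 5)
        folds = build_folds(labels, scheme="k-fold", k=10, seed=0)
        assert all(len(test) == 1 for _, test in folds.split())

    @given(
        n=st.integers(10, 60),
        k=st.integers(2, 8),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_partition_law(self, n, k, seed):
        labels = np.random.default_rng(seed).integers(0, 3, size=n)
        folds = build_folds(labels, scheme="k-fold", k=min(k, n), seed=seed)
        all_test = np.concatenate([test for _, test in folds.split()])
        assert sorted(all_test) == list(range(n))  # disjoint + exhaustive
        sizes = [len(test) for _, test in folds.split()]
        assert max(sizes) - min(sizes) <= 1

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_folds(np.zeros(5), scheme="k-fold", k=6)


class TestOversampleMinority:
    def test_minority_raised_to_majority(self):
        labels = np.array(["A"] * 50 + ["B"] * 10)
        out = oversample_minority(np.arange(60), labels, seed=0)
        values, counts = np.unique(labels[out], return_counts=True)
        assert dict(zip(values, counts)) == {"A": 50, "B": 50}

    def test_balanced_unchanged(self):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        out = oversample_minority(np.arange(20), labels, seed=0)
        assert sorted(out) == list(range(20))

    def test_only_training_indices_used(self):
        labels = np.array(["A"] * 20 + ["B"] * 20)
        train = np.arange(25)  # test indices 25..39 withheld
        out = oversample_minority(train, labels, seed=1)
        assert set(out) <= set(train)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oversample_minority(np.arange(5), np.zeros(5), seed=0)


class TestCrossvalClassifier:
    def test_separable_data_perfect_accuracy(self):
        X, labels = separable_data()
        folds = build_folds(labels, scheme="k-fold", k=3, seed=0)
        res = crossval_classifier(X, labels, folds, FAST_MLP)
        assert res.mean_accuracy == 1.0
        assert res.chance_level == pytest.approx(1 / 3)

    def test_null_labels_within_binomial_interval(self):
        from scipy.stats import binom

        rng = np.random.default_rng(3)
        X = rng.normal(size=(90, 5))
        labels = np.tile([0, 1, 2], 30)  # independent of X
        folds = build_folds(labels, scheme="k-fold", k=3, seed=0)
        res = crossval_classifier(X, labels, folds, FAST_MLP)
        n = len(labels)
        lo = binom.ppf(0.025, n, 1 / 3) / n
        hi = binom.ppf(0.975, n, 1 / 3) / n
        assert lo <= res.mean_accuracy <= hi

    def test_mean_is_average_of_folds(self):
        X, labels = separable_data(n_per_class=10)
        folds = build_folds(labels, scheme="k-fold", k=5, seed=1)
        res = crossval_classifier(X, labels, folds, FAST_MLP)
        assert res.mean_accuracy == pytest.approx(res.per_fold_accuracy.mean(), abs=1e-12)

    def test_deterministic_given_seed(self):
        X, labels = separable_data(n_per_class=8, seed=5)
        folds = build_folds(labels, scheme="k-fold", k=2, seed=0)
        a = crossval_classifier(X, labels, folds, FAST_MLP)
        b = crossval_classifier(X, labels, folds, FAST_MLP)
        assert np.array_equal(a.per_fold_accuracy, b.per_fold_accuracy)

    def test_no_leakage_from_test_labels(self):
        # randomising test-fold labels must not change trained predictions
        X, labels = separable_data(n_per_class=10, seed=2)
        folds = build_folds(labels, scheme="k-fold", k=2, seed=0)
        train, test = next(folds.split())
        y_enc = labels.copy()
        rng_a = np.random.default_rng(np.random.SeedSequence([0, 0]))
        pred_a = supervised._fit_predict_fold(X, y_enc, 3, train, test, FAST_MLP, rng_a)
        y_mangled = y_enc.copy()
        y_mangled[test] = np.random.default_rng(9).permutation(y_mangled[test])
        rng_b = np.random.default_rng(np.random.SeedSequence([0, 0]))
        pred_b = supervised._fit_predict_fold(X, y_mangled, 3, train, test, FAST_MLP, rng_b)
        assert np.array_equal(pred_a, pred_b)

    def test_nonfinite_features_rejected(self):
        X, labels = separable_data(n_per_class=5)
        X[0, 0] = np.nan
        folds = build_folds(labels, scheme="k-fold", k=2, seed=0)
        with pytest.raises(ValueError):
            crossval_classifier(X, labels, folds, FAST_MLP)

    def test_volumetric_model_on_small_volumes(self, rng):
        # two categories with distinct spatial patterns on an 8^3 grid
        n = 24
        labels = np.tile([0, 1], n // 2)
        X = rng.normal(scale=0.3, size=(n, 8, 8, 8))
        X[labels == 0, :4] += 2.0
        X[labels == 1, 4:] += 2.0
        folds = build_folds(labels, scheme="k-fold", k=2, seed=0)
        cfg = ClassifierConfig(model="volumetric-conv", max_epochs=20, batch_size=8, seed=0)
        res = crossval_classifier(X, labels, folds, cfg)
        assert res.mean_accuracy == 1.0


class TestPermutationNull:
    def test_tail_p_formula_when_observed_beats_all(self):
        X, labels = separable_data(n_per_class=12, seed=1)
        folds = build_folds(labels, scheme="k-fold", k=2, seed=0)
        null = permutation_null(X, labels, folds, FAST_MLP, n_permutations=19, seed=0)
        assert null.observed == 1.0
        assert np.all(null.null_means < 1.0)
        assert null.tail_p == pytest.approx(1 / 20)

    def test_null_mean_near_class_weighted_chance(self):
        # imbalanced labels independent of features: null centred near the
        # frequency-weighted chance level sum_c p_c^2
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4))
        labels = np.array([0] * 80 + [1] * 40)
        folds = build_folds(labels, scheme="k-fold", k=3, seed=0)
        null = permutation_null(X, labels, folds, FAST_MLP, n_permutations=30, seed=1)
        weighted_chance = (80 / 120) ** 2 + (40 / 120) ** 2
        assert abs(null.null_means.mean() - weighted_chance) < 0.1


class TestTTestVsChance:
    def test_all_at_chance(self):
        t, p, df = t_test_vs_chance([0.5, 0.5, 0.5], 0.5)
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_worked_example(self):
        t, p, df = t_test_vs_chance([0.4, 0.5, 0.3, 0.6], 1 / 3)
        # oracle: t = (mean - chance) / (sd / sqrt(n))
        acc = np.array([0.4, 0.5, 0.3, 0.6])
        expected = (acc.mean() - 1 / 3) / (acc.std(ddof=1) / 2)
        assert t == pytest.approx(expected, abs=1e-12)
        assert t == pytest.approx(1.807, abs=0.001)
        assert df == 3

    def test_scale_invariance_of_deviations(self):
        # scaling every deviation from chance by c scales mean and sd alike,
        # leaving t unchanged
        acc = np.array([0.4, 0.5, 0.3, 0.6])
        chance = 1 / 3
        t1, _, _ = t_test_vs_chance(acc, chance)
        t2, _, _ = t_test_vs_chance(chance + 2 * (acc - chance), chance)
        assert t2 == pytest.approx(t1, abs=1e-12)

    def test_zero_variance_off_chance_rejected(self):
        with pytest.raises(ValueError):
            t_test_vs_chance([0.6, 0.6, 0.6], 0.5)


class TestTopLabelsFilter:
    def test_top_three_by_frequency(self):
        labels = np.array(["a"] * 5 + ["b"] * 4 + ["c"] * 3 + ["d"] * 2)
        idx, top = top_labels_filter(labels, top_n=3)
        assert top == ["a", "b", "c"]
        assert len(idx) == 12

    def test_rank_tie_broken_by_first_occurrence(self):
        labels = np.array(["x"] * 3 + ["y"] * 2 + ["z"] * 2 + ["w"])
        _, top = top_labels_filter(labels, top_n=2)
        assert top == ["x", "y"]  # y seen before z
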