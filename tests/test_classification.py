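import math

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from hamqa.classification import (
    PNNModel,
    loo_evaluate,
    normalize,
    pnn_classify,
    pnn_score,
    subset_search,
)


def two_gaussian_classes(rng, n=20, separation=10.0, p=2):
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n, p)), rng.normal(separation, 1.0, size=(n, p))]
    )
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.normal(3.0, 5.0, size=(40, 6))
        Xn, mu, sd, kept = normalize(X)
        assert np.allclose(Xn.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Xn.std(axis=0), 1.0, atol=1e-10)
        assert kept.tolist() == list(range(6))

    def test_constant_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            Xn, _, _, kept = normalize(X)
        assert kept.tolist() == [0, 2] and Xn.shape == (10, 2)

    def test_antisymmetric_pair_maps_to_unit_points(self):
        X = np.array([[2.0, -3.0], [-2.0, 3.0]])
        Xn, *_ = normalize(X)
        assert np.allclose(np.abs(Xn), 1.0)


class TestPnnScore:
    def test_hand_computed_three_class_scores(self):
        model = PNNModel(
            {
                "a": np.array([[0.0, 0.0], [1.0, 0.0]]),
                "b": np.array([[4.0, 0.0]]),
                "c": np.array([[0.0, 3.0]]),
            },
            sigma=1.0,
        )
        q = np.array([1.0, 1.0])
        s = pnn_score(model, q)
        # exact kernel sums: class a averages exp(-2/2) and exp(-1/2)
        assert s["a"] == pytest.approx((math.exp(-1.0) + math.exp(-0.5)) / 2, abs=1e-12)
        assert s["b"] == pytest.approx(math.exp(-10.0 / 2), abs=1e-12)
        assert s["c"] == pytest.approx(math.exp(-5.0 / 2), abs=1e-12)

    def test_query_at_training_point_wins(self):
        model = PNNModel(
            {"a": np.array([[0.0, 0.0]]), "b": np.array([[10.0, 10.0]])}, sigma=1.0
        )
        assert pnn_classify(model, np.array([0.0, 0.0])) == "a"

    def test_exact_midpoint_tie_breaks_to_first_class(self):
        model = PNNModel(
            {"first": np.array([[0.0]]), "second": np.array([[2.0]])}, sigma=1.0
        )
        assert pnn_classify(model, np.array([1.0])) == "first"

    def test_missing_feature_rejected(self):
        model = PNNModel({"a": np.array([[0.0]])}, sigma=1.0)
        with pytest.raises(ValueError, match="missing"):
            pnn_score(model, np.array([np.nan]))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            PNNModel({"a": np.array([[0.0]])}, sigma=0.0)


class TestPnnNearestNeighbourLimit:
    def test_sigma_to_zero_matches_1nn(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array(["u", "v", "w"] * 10)
        Xn, *_ = normalize(X)
        knn = KNeighborsClassifier(n_neighbors=1).fit(Xn, y)
        model = PNNModel({c: Xn[y == c] for c in ("u", "v", "w")}, sigma=1e-6)
        queries = rng.normal(size=(20, 3))
        for q in queries:
            assert pnn_classify(model, q) == knn.predict(q[None, :])[0]


class TestLooEvaluate:
    def test_well_separated_classes_perfect(self, rng):
        X, y = two_gaussian_classes(rng)
        tt, sigma = loo_evaluate(X, y, sigma=0.5)
        assert tt.accuracy == 1.0
        assert tt.counts.sum() == 40
        assert list(tt.per_class_recall.values()) == [1.0, 1.0]

    def test_label_symmetric_distribution_near_chance(self, rng):
        n = 50
        X = rng.normal(size=(2 * n, 3))
        y = np.array(["A"] * n + ["B"] * n)
        tt, _ = loo_evaluate(X, y, sigma=1.0)
        # binomial 99% bounds around 0.5 for 100 trials
        assert 0.5 - 0.129 <= tt.accuracy <= 0.5 + 0.129

    def test_exact_duplicates_under_different_labels_flip(self, rng):
        # the held-out pattern's exact duplicate sits in the other class at
        # distance zero, so every assignment flips: documented behaviour
        X0 = rng.normal(size=(10, 2))
        X = np.vstack([X0, X0])
        y = np.array(["A"] * 10 + ["B"] * 10)
        tt, _ = loo_evaluate(X, y, sigma=0.3)
        assert tt.accuracy == 0.0

    def test_row_sums_equal_class_sizes(self, rng):
        X, y = two_gaussian_classes(rng, n=7, separation=1.0)
        tt, _ = loo_evaluate(X, y, sigma="grid")
        assert tt.counts.sum(axis=1).tolist() == [7, 7]

    def test_singleton_class_rejected(self):
        X = np.zeros((3, 1))
        with pytest.raises(ValueError, match="2 patterns"):
            loo_evaluate(X, np.array(["A", "A", "B"]), sigma=1.0)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="2 classes"):
            loo_evaluate(X, np.array(["A"] * 4), sigma=1.0)
        with pytest.raises(ValueError, match="2 classes"):
            subset_search(X, np.array(["A"] * 4), max_size=1)

    def test_affine_rescaling_invariance(self, rng):
        X, y = two_gaussian_classes(rng, n=10, separation=2.0)
        tt1, _ = loo_evaluate(X, y, sigma=0.5)
        X2 = X * np.array([100.0, 0.01]) + np.array([-7.0, 3.0])
        tt2, _ = loo_evaluate(X2, y, sigma=0.5)
        assert np.array_equal(tt1.counts, tt2.counts)

    def test_pattern_order_invariance(self, rng):
        X, y = two_gaussian_classes(rng, n=10, separation=2.0)
        perm = rng.permutation(len(y))
        tt1, _ = loo_evaluate(X, y, sigma=0.5)
        tt2, _ = loo_evaluate(X[perm], y[perm], classes=("A", "B"), sigma=0.5)
        assert np.array_equal(tt1.counts, tt2.counts)

    def test_nested_sigma_policy_runs(self, rng):
        X, y = two_gaussian_classes(rng, n=8)
        tt, sigma = loo_evaluate(X, y, sigma="nested")
        assert tt.accuracy == 1.0 and math.isnan(sigma)

    def test_pooled_vs_fold_normalization_modes(self, rng):
        X, y = two_gaussian_classes(rng, n=10)
        for norm in ("fold", "pooled"):
            tt, _ = loo_evaluate(X, y, sigma=0.5, norm=norm)
            assert tt.accuracy == 1.0


class TestSubsetSearch:
    def test_single_informative_feature_wins(self, rng):
        n = 15
        informative = np.concatenate([rng.normal(0, 0.3, n), rng.normal(8, 0.3, n)])
        noise = rng.normal(size=(2 * n, 4))
        X = np.column_stack([noise[:, :2], informative, noise[:, 2:]])
        y = np.array(["A"] * n + ["B"] * n)
        res = subset_search(X, y, max_size=2, sigma=0.5)
        assert res.subset == (2,)
        assert res.truth_table.accuracy == 1.0

    def test_redundant_perfect_features_prefer_smaller_subset(self, rng):
        n = 12
        f = np.concatenate([rng.normal(0, 0.2, n), rng.normal(6, 0.2, n)])
        X = np.column_stack([f, f * 2.0])
        y = np.array(["A"] * n + ["B"] * n)
        res = subset_search(X, y, max_size=2, sigma=0.5)
        assert len(res.subset) == 1

    def test_max_size_one_equals_direct_scan(self, rng):
        X, y = two_gaussian_classes(rng, n=8, separation=1.5, p=4)
        res = subset_search(X, y, max_size=1, sigma=0.5)
        accs = [loo_evaluate(X, y, subset=[j], sigma=0.5)[0].accuracy for j in range(4)]
        assert res.truth_table.accuracy == max(accs)
        assert res.subset == (int(np.argmax(accs)),)

    def test_combinatorial_guard(self, rng):
        X, y = two_gaussian_classes(rng, n=5, p=8)
        with pytest.raises(ValueError, match="force"):
            subset_search(X, y, max_size=7)

    def test_ranked_list_sorted_by_accuracy(self, rng):
        X, y = two_gaussian_classes(rng, n=8, separation=1.0, p=3)
        res = subset_search(X, y, max_size=2, sigma=0.5)
        accs = res.ranked["accuracy"].to_numpy()
        assert np.all(np.diff(accs) <= 0)
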