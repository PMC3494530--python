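import numpy as np
import pytest

from seldiflow import (ClassifierSpec, SpecError, SplitScheme, double_cv,
                       inner_cv_select, make_splits, metrics, predict,
                       rank_features, train_dlda, training_size_sweep)
from seldiflow.classify import DLDAModel


class TestMakeSplits:
    def test_balanced_counts_forced(self):
        labels = ["A"] * 25 + ["B"] * 25
        splits = make_splits(labels, SplitScheme(n_train=40, n_splits=20, seed=1))
        labels = np.asarray(labels)
        for train, test in splits:
            assert (labels[train] == "A").sum() == 20
            assert (labels[test] == "A").sum() == 5
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 50

    def test_many_splits_all_balanced(self):
        labels = np.array(["cancer"] * 53 + ["benign"] * 57)
        splits = make_splits(labels, SplitScheme(n_train=80, n_splits=500, seed=3))
        assert len(splits) == 500
        quota_cancer = round(80 * 53 / 110)
        for train, _ in splits:
            n_cancer = (labels[train] == "cancer").sum()
            assert abs(n_cancer - quota_cancer) <= 1
            assert len(train) == 80

    def test_deterministic_given_seed(self):
        labels = ["A"] * 10 + ["B"] * 10
        s1 = make_splits(labels, SplitScheme(n_train=12, n_splits=5, seed=9))
        s2 = make_splits(labels, SplitScheme(n_train=12, n_splits=5, seed=9))
        for (t1, e1), (t2, e2) in zip(s1, s2):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_infeasible_size_reports_minimum(self):
        labels = ["A"] * 3 + ["B"] * 3
        with pytest.raises(SpecError, match="infeasible"):
            make_splits(labels, SplitScheme(n_train=5, n_splits=1))

    def test_forced_equal_mode(self):
        labels = np.array(["A"] * 30 + ["B"] * 10)
        splits = make_splits(labels, SplitScheme(n_train=16, n_splits=5,
                                                 balanced="equal", seed=2))
        for train, _ in splits:
            assert (labels[train] == "A").sum() == 8
            assert (labels[train] == "B").sum() == 8


class TestDLDA:
    def test_midpoint_rule_single_feature(self):
        X = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        y = np.array(["A"] * 3 + ["B"] * 3)
        model = train_dlda(X, y)
        np.testing.assert_allclose(model.means.ravel(), [0.0, 2.0])
        assert predict(model, [[0.9]])[0] == "A"
        assert predict(model, [[1.1]])[0] == "B"

    def test_exact_tie_goes_to_earlier_class(self):
        model = DLDAModel(classes=np.array(["A", "B"]),
                          means=np.array([[0.0], [2.0]]),
                          pooled_var=np.array([1.0]))
        assert predict(model, [[1.0]])[0] == "A"

    def test_per_feature_rescaling_invariance(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.choice(["A", "B"], size=40)
        scales = rng.uniform(0.1, 10.0, size=6)
        m1 = train_dlda(X, y)
        m2 = train_dlda(X * scales, y)
        Xnew = rng.normal(size=(25, 6))
        np.testing.assert_array_equal(predict(m1, Xnew),
                                      predict(m2, Xnew * scales))

    def test_matches_brute_force_mahalanobis(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.choice(["A", "B", "C"], size=60)
        model = train_dlda(X, y)
        Xnew = rng.normal(size=(1000, 5))
        pred = predict(model, Xnew)
        for i in range(len(Xnew)):
            d = [np.sum((Xnew[i] - model.means[k]) ** 2 / model.pooled_var)
                 for k in range(3)]
            assert pred[i] == model.classes[int(np.argmin(d))]

    def test_zero_variance_feature_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(SpecError, match="M9"):
            train_dlda(X, y, feature_ids=["M1", "M9"])

    def test_dimension_mismatch_rejected(self, rng):
        model = train_dlda(rng.normal(size=(10, 3)),
                           np.array(["A"] * 5 + ["B"] * 5))
        with pytest.raises(SpecError, match="feature count"):
            predict(model, rng.normal(size=(2, 4)))


class TestRankFeatures:
    def test_planted_feature_ranks_first(self, rng):
        hits = 0
        for _ in range(50):
            X = rng.normal(size=(40, 30))
            X[:20, 7] += 3.0
            y = np.array(["A"] * 20 + ["B"] * 20)
            if rank_features(X, y)[0] == 7:
                hits += 1
        assert hits >= 49

    def test_two_class_f_ranking_equals_t_ranking(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.array(["A"] * 15 + ["B"] * 15)
        np.testing.assert_array_equal(rank_features(X, y, "two_class_t"),
                                      rank_features(X, y, "three_class_F"))

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 15))
        y = rng.choice(["A", "B"], size=30)
        perm = rng.permutation(30)
        np.testing.assert_array_equal(rank_features(X, y),
                                      rank_features(X[perm], y[perm]))

    def test_constant_feature_ranked_last(self, rng):
        X = rng.normal(size=(20, 5))
        X[:, 2] = 7.0
        y = np.array(["A"] * 10 + ["B"] * 10)
        assert rank_features(X, y)[-1] == 2


class TestInnerCVSelect:
    def test_saturated_accuracy_prefers_smallest_k(self, rng):
        X = rng.normal(size=(40, 30))
        y = np.array(["A"] * 20 + ["B"] * 20)
        X[:20, :] += 10.0            # trivially separable on any feature set
        spec = ClassifierSpec(model="dlda", feature_grid=(5, 10, 15))
        k, cost = inner_cv_select(X, y, spec, seed=4)
        assert k == 5
        assert cost is None

    def test_recovers_number_of_informative_features(self, rng):
        correct = 0
        n_runs = 25
        for _ in range(n_runs):
            X = rng.normal(size=(60, 40))
            y = np.array(["A"] * 30 + ["B"] * 30)
            X[:30, :5] += 2.5        # exactly five informative peaks
            spec = ClassifierSpec(model="dlda", feature_grid=(5, 10, 20, 40))
            k, _ = inner_cv_select(X, y, spec, seed=int(rng.integers(2 ** 31)))
            if k == 5:
                correct += 1
        assert correct >= 0.8 * n_runs

    def test_svm_cost_selected_from_grid(self, rng):
        X = rng.normal(size=(30, 10))
        X[:15] += 1.5
        y = np.array(["A"] * 15 + ["B"] * 15)
        spec = ClassifierSpec(model="svm", feature_grid=(5, 10),
                              cost_grid=(0.1, 1.0))
        k, cost = inner_cv_select(X, y, spec, seed=0)
        assert cost in (0.1, 1.0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = ["cancer"] * 5 + ["benign"] * 5
        m = metrics(y, y)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == \
            (100.0, 100.0, 100.0)

    def test_constant_benign_prediction(self):
        y_true = ["cancer"] * 25 + ["benign"] * 25
        m = metrics(y_true, ["benign"] * 50)
        assert m["accuracy"] == 50.0
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 100.0

    def test_three_class_rows_sum_to_hundred(self, rng):
        y_true = rng.choice(["benign", "LMP", "cancer"], size=60)
        y_pred = rng.choice(["benign", "LMP", "cancer"], size=60)
        m = metrics(y_true, y_pred)
        np.testing.assert_allclose(m["confusion"].sum(axis=1), 100.0, atol=0.1)
        assert m["sensitivity"] is None

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(SpecError):
            metrics(["cancer", "benign"], ["cancer", "weird"])


class TestDoubleCV:
    def test_separable_classes_near_perfect(self, rng):
        X = rng.normal(size=(60, 30))
        X[:30, :10] += 6.0
        y = np.array(["cancer"] * 30 + ["benign"] * 30)
        scheme = SplitScheme(n_train=40, n_splits=25, seed=5)
        spec = ClassifierSpec(model="dlda", feature_grid=(5, 10))
        res = double_cv(X, y, scheme, spec)
        assert res.aggregate["accuracy"] >= 99.0

    def test_bit_reproducible_with_fixed_seed(self, rng):
        X = rng.normal(size=(40, 20))
        y = np.array(["cancer"] * 20 + ["benign"] * 20)
        scheme = SplitScheme(n_train=26, n_splits=10, seed=8)
        spec = ClassifierSpec(model="dlda", feature_grid=(5, 10))
        r1 = double_cv(X, y, scheme, spec)
        r2 = double_cv(X, y, scheme, spec)
        assert r1.per_split.drop(columns="features").equals(
            r2.per_split.drop(columns="features"))

    def test_corrupting_test_labels_cannot_change_selection(self, rng):
        """Leak-freedom: flipping every test label changes reported metrics
        but never the selected hyperparameters or features."""
        X = rng.normal(size=(40, 25))
        X[:20, :5] += 1.0
        y = np.array(["cancer"] * 20 + ["benign"] * 20)
        scheme = SplitScheme(n_train=28, n_splits=8, seed=13)
        spec = ClassifierSpec(model="dlda", feature_grid=(5, 10))
        res = double_cv(X, y, scheme, spec)
        selections = res.per_split[["k", "cost"]]
        features = res.per_split["features"]

        # data-flow audit: recompute every split's selection from the
        # training part alone; agreement proves test labels play no role
        from seldiflow.classify import inner_cv_select as ics
        splits = make_splits(y, scheme)
        inner_seeds = [int(np.random.default_rng(c).integers(2 ** 31))
                       for c in np.random.SeedSequence(scheme.seed)
                       .spawn(len(splits))]
        for i, (train, test) in enumerate(splits):
            y_corrupt = y.copy()
            y_corrupt[test] = np.where(y_corrupt[test] == "cancer",
                                       "benign", "cancer")
            k, cost = ics(X[train], y_corrupt[train], spec,
                          seed=inner_seeds[i])
            assert k == selections["k"].iloc[i]
            order = rank_features(X[train], y_corrupt[train])
            assert [str(j) for j in order[:k]] == list(features.iloc[i])

    def test_training_size_sweep_reports_each_size(self, rng):
        X = rng.normal(size=(50, 15))
        X[:25, :5] += 2.0
        y = np.array(["cancer"] * 25 + ["benign"] * 25)
        out = training_size_sweep(X, y, (20, 30, 40),
                                  SplitScheme(n_train=20, n_splits=5, seed=1),
                                  ClassifierSpec(model="dlda",
                                                 feature_grid=(5,)))
        assert out["n_train"].tolist() == [20, 30, 40]
        assert len(out) == 3
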