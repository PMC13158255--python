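import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import cohen_kappa_score

from spectradiet import (
    DataError,
    FeatureTable,
    RFConfig,
    StratificationError,
    clopper_pearson,
    cohen_kappa,
    evaluate,
    oob_error,
    permutation_importance,
    stratified_split,
    tune_and_train,
)
from spectradiet.classify import _make_forest, _tree_oob_masks

SMALL_CONFIG = RFConfig(
    cv_folds=3,
    mtry_grid=(2,),
    ntree_grid=(50,),
    maxnodes_grid=(50,),
    nodesize_grid=(1,),
    seed=0,
)


def separable_table(n_per_class=15, n_classes=3, n_features=5, seed=0):
    """Perfectly separable features: class k has feature k pushed far out."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.05, size=(n_per_class * n_classes, n_features))
    labels = []
    for k in range(n_classes):
        rows = slice(k * n_per_class, (k + 1) * n_per_class)
        X[rows, k] += 5.0
        labels += [f"class{k}"] * n_per_class
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(len(labels))],
        class_labels=labels,
        matrix=X,
        aggregate_names=[f"band{j}" for j in range(n_features)],
    )


class TestStratifiedSplit:
    def test_eighty_twenty_counts(self):
        labels = ["a"] * 10 + ["b"] * 10
        train, test = stratified_split(labels, 0.8, seed=1)
        assert len(train) == 16 and len(test) == 4
        for cls in ("a", "b"):
            assert sum(1 for i in train if labels[i] == cls) == 8

    def test_deterministic_given_seed(self):
        labels = ["a"] * 7 + ["b"] * 9 + ["c"] * 5
        s1 = stratified_split(labels, 0.8, seed=3)
        s2 = stratified_split(labels, 0.8, seed=3)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])
        s3 = stratified_split(labels, 0.8, seed=4)
        assert not np.array_equal(s1[0], s3[0])

    def test_partition_property(self):
        labels = ["a"] * 9 + ["b"] * 6 + ["c"] * 4
        train, test = stratified_split(labels, 0.75, seed=0)
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(19))
        assert set(train).isdisjoint(test)

    def test_proportion_within_one_sample_per_class(self):
        labels = ["a"] * 7 + ["b"] * 11
        train, _ = stratified_split(labels, 0.8, seed=0)
        for cls, n in (("a", 7), ("b", 11)):
            got = sum(1 for i in train if labels[i] == cls)
            assert abs(got - 0.8 * n) <= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(StratificationError, match="lonely"):
            stratified_split(["a", "a", "lonely"], 0.8, seed=0)


class TestTuneAndTrain:
    def test_separable_data_ties_break_to_cheapest(self):
        """Every grid point reaches CV accuracy 1 on separable data, so the
        deterministic tie-break must pick the cheapest combination."""
        cfg = RFConfig(
            cv_folds=3,
            mtry_grid=(2, 3),
            ntree_grid=(50, 100),
            maxnodes_grid=(50, 100),
            nodesize_grid=(1, 5),
            seed=0,
        )
        result = tune_and_train(separable_table(), cfg)
        assert result.cv_table["mean_cv_accuracy"].min() == 1.0
        chosen = result.chosen_hyperparameters
        assert (chosen["ntree"], chosen["mtry"], chosen["maxnodes"], chosen["nodesize"]) == (
            50, 2, 50, 1,
        )

    def test_cv_table_has_full_grid_cardinality(self):
        cfg = RFConfig(
            cv_folds=3, mtry_grid=(1, 2), ntree_grid=(20, 30), maxnodes_grid=(50,),
            nodesize_grid=(1, 5), seed=0,
        )
        result = tune_and_train(separable_table(), cfg)
        assert len(result.cv_table) == 2 * 2 * 1 * 2

    def test_mtry_clipped_to_feature_count(self):
        cfg = RFConfig(
            cv_folds=3, mtry_grid=(2, 99), ntree_grid=(20,), maxnodes_grid=(50,),
            nodesize_grid=(1,), seed=0,
        )
        result = tune_and_train(separable_table(n_features=4), cfg)
        assert set(result.cv_table["mtry_effective"]) == {2, 4}

    def test_deterministic_choice_across_runs(self):
        a = tune_and_train(separable_table(), SMALL_CONFIG)
        b = tune_and_train(separable_table(), SMALL_CONFIG)
        assert a.chosen_hyperparameters == b.chosen_hyperparameters
        np.testing.assert_array_equal(
            a.cv_table["mean_cv_accuracy"], b.cv_table["mean_cv_accuracy"]
        )

    def test_missing_values_rejected(self):
        ft = separable_table()
        ft.matrix[0, 0] = np.nan
        with pytest.raises(DataError):
            tune_and_train(ft, SMALL_CONFIG)


class TestCohenKappa:
    def test_diagonal_matrix_is_one(self):
        assert cohen_kappa(np.diag([5, 9, 3])) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        assert cohen_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        # p_o = 35/50 = 0.7; p_e = (25*30 + 25*20)/50^2 = 0.5 -> kappa = 0.4
        assert cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        y_true = rng.integers(0, k, size=200)
        y_pred = np.where(rng.random(200) < 0.6, y_true, rng.integers(0, k, size=200))
        conf = np.zeros((k, k), dtype=int)
        for t, p in zip(y_true, y_pred):
            conf[t, p] += 1
        assert cohen_kappa(conf) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    def test_degenerate_single_class_table(self):
        assert cohen_kappa([[10, 0], [0, 0]]) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            cohen_kappa([[1, -1], [0, 2]])

    def test_kappa_one_iff_diagonal_with_multiple_classes(self):
        assert cohen_kappa(np.diag([4, 4])) == pytest.approx(1.0)
        off = np.array([[4, 1], [0, 4]])
        assert cohen_kappa(off) < 1.0


class TestClopperPearson:
    def test_boundary_cases(self):
        lo, _ = clopper_pearson(0, 20)
        assert lo == 0.0
        _, hi = clopper_pearson(20, 20)
        assert hi == 1.0

    @pytest.mark.parametrize("k,n", [(58, 60), (1, 10), (7, 13), (0, 5), (5, 5)])
    def test_matches_binomial_tail_bisection_oracle(self, k, n):
        """Independent oracle: invert the binomial tail probabilities by
        bisection (the defining property of the exact interval)."""

        def bisect(fn, lo, hi, tol=1e-12):
            for _ in range(100):
                mid = (lo + hi) / 2
                if fn(mid):
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        alpha = 0.05
        got_lo, got_hi = clopper_pearson(k, n, alpha)
        if 0 < k:
            # smallest p with P[X >= k] >= alpha/2
            exp_lo = bisect(lambda p: 1 - binom.cdf(k - 1, n, p) >= alpha / 2, 0.0, 1.0)
            assert got_lo == pytest.approx(exp_lo, abs=1e-9)
        if k < n:
            # largest p with P[X <= k] >= alpha/2
            exp_hi = bisect(lambda p: binom.cdf(k, n, p) < alpha / 2, 0.0, 1.0)
            assert got_hi == pytest.approx(exp_hi, abs=1e-9)

    def test_interval_brackets_point_estimate(self):
        lo, hi = clopper_pearson(58, 60)
        assert lo < 58 / 60 < hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(Exception):
            clopper_pearson(5, 3)


class TestOOBError:
    def test_reconstructed_oob_votes_match_sklearn_records(self):
        ft = separable_table(n_per_class=20)
        model = _make_forest(80, 2, 50, 1, seed=5, oob=True)
        model.fit(ft.matrix, ft.class_labels)
        n = ft.n_samples
        votes = np.zeros((n, len(model.classes_)))
        for est, mask in zip(model.estimators_, _tree_oob_masks(model, n)):
            votes[mask] += est.predict_proba(ft.matrix[mask])
        mine = votes / np.maximum(votes.sum(axis=1, keepdims=True), 1e-300)
        np.testing.assert_allclose(mine, model.oob_decision_function_, atol=1e-12)

    def test_separable_data_near_zero(self):
        ft = separable_table(n_per_class=20)
        model = _make_forest(100, 2, 50, 1, seed=0, oob=True)
        model.fit(ft.matrix, ft.class_labels)
        assert oob_error(model, ft.matrix, ft.class_labels) < 5.0
        assert oob_error(model) < 5.0

    def test_permuted_labels_near_chance(self):
        """With labels shuffled, OOB error sits near 1 - 1/K."""
        rng = np.random.default_rng(0)
        n_per, k = 30, 5
        X = rng.normal(size=(n_per * k, 6))
        y = np.repeat([f"c{i}" for i in range(k)], n_per)
        y = rng.permutation(y)
        model = _make_forest(300, 2, 50, 1, seed=1, oob=True)
        model.fit(X, y)
        err = oob_error(model, X, y)
        assert 0.0 <= err <= 100.0
        assert abs(err - 80.0) <= 10.0

    def test_model_without_oob_records_rejected(self):
        ft = separable_table()
        model = _make_forest(10, 2, 50, 1, seed=0, oob=False)
        model.fit(ft.matrix, ft.class_labels)
        with pytest.raises(DataError):
            oob_error(model)


@pytest.fixture(scope="module")
def two_class_fit():
    """One discriminating feature flanked by two pure-noise features."""
    rng = np.random.default_rng(7)
    n = 120
    signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(4, 1, n // 2)])
    noise = rng.normal(size=n)
    X = np.column_stack([noise, signal, rng.normal(size=n)])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    model = _make_forest(100, 2, 50, 1, seed=2, oob=True)
    model.fit(X, y)
    return model, X, y


class TestPermutationImportance:
    @pytest.mark.parametrize("mode", ["oob", "holdout"])
    def test_noise_feature_near_zero_signal_largest(self, two_class_fit, mode):
        model, X, y = two_class_fit
        imps = permutation_importance(
            model, X, y, n_repeats=20, seed=0, mode=mode,
            feature_names=["noise1", "signal", "noise2"],
        )
        assert abs(imps["noise1"]) < 0.05
        assert abs(imps["noise2"]) < 0.05
        assert max(imps, key=imps.get) == "signal"

    def test_sorted_descending_and_deterministic(self, two_class_fit):
        model, X, y = two_class_fit
        a = permutation_importance(model, X, y, n_repeats=3, seed=9)
        b = permutation_importance(model, X, y, n_repeats=3, seed=9)
        assert a == b
        assert list(a.values()) == sorted(a.values(), reverse=True)


class TestEvaluate:
    def test_perfect_predictions(self):
        ft = separable_table(n_per_class=20)
        model = _make_forest(100, 2, 50, 1, seed=0, oob=True)
        model.fit(ft.matrix, ft.class_labels)
        report = evaluate(model, ft, ft.class_labels)
        assert report.overall_accuracy == 1.0
        assert report.kappa == pytest.approx(1.0)
        for stats in report.per_class.values():
            assert stats["balanced_accuracy"] == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_two_classes(self):
        """A predictor that always answers one class scores accuracy 1/2 and
        kappa 0 on a balanced two-class test set."""
        ft = separable_table(n_per_class=30, n_classes=2)
        # train on data where class0's signature also covers class1's rows
        X_train = np.zeros((20, 5))
        X_train[:10, 0] = 5.0
        X_train[10:, 0] = 4.9  # nearly identical -> predicts the same class
        y_train = ["class0"] * 10 + ["class1"] * 10
        model = _make_forest(10, 1, 50, 10, seed=0, oob=False)
        model.fit(X_train, y_train)
        X_test = np.full((40, 5), 4.95)
        X_test[:, 0] = 4.95
        y_test = ["class0"] * 20 + ["class1"] * 20
        report = evaluate(model, X_test, y_test)
        preds = model.predict(X_test)
        if len(set(preds)) == 1:  # constant predictor realized
            assert report.overall_accuracy == pytest.approx(0.5)
            assert report.kappa == pytest.approx(0.0)

    def test_sensitivities_recombine_to_overall_accuracy(self):
        """Prevalence-weighted per-class sensitivities equal overall accuracy
        (algebraic identity on the confusion matrix)."""
        ft = separable_table(n_per_class=12, n_classes=4)
        rng = np.random.default_rng(0)
        model = _make_forest(30, 2, 50, 1, seed=0, oob=False)
        model.fit(ft.matrix + rng.normal(scale=2.0, size=ft.matrix.shape), ft.class_labels)
        report = evaluate(model, ft, ft.class_labels)
        n = report.confusion.sum()
        weighted = sum(
            report.per_class[c]["sensitivity"] * report.confusion[i].sum() / n
            for i, c in enumerate(report.labels)
        )
        assert weighted == pytest.approx(report.overall_accuracy, abs=1e-12)

    def test_unknown_test_label_rejected(self):
        ft = separable_table()
        model = _make_forest(10, 2, 50, 1, seed=0, oob=False)
        model.fit(ft.matrix, ft.class_labels)
        with pytest.raises(DataError, match="unseen"):
            evaluate(model, ft.matrix[:2], ["unseen", "class0"])

    def test_ci_brackets_accuracy(self):
        ft = separable_table(n_per_class=20)
        model = _make_forest(50, 2, 50, 1, seed=0, oob=True)
        model.fit(ft.matrix, ft.class_labels)
        report = evaluate(model, ft, ft.class_labels)
        assert report.ci95[0] <= report.overall_accuracy <= report.ci95[1]
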