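import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinsig.learn import (
    FoldError,
    ModelSpec,
    SmallClassError,
    UndefinedMetricError,
    auc,
    build_estimator,
    classify_by_regression,
    confusion_metrics,
    confusion_metrics_from_table,
    cross_validate,
    greedy_select,
    regression_metrics,
    remove_outliers,
    train_type_classifiers,
    type_vote,
)

from oracles import auc_concordance, confusion_formula

FAST = (("n_estimators", 50),)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = [0, 1, 0, 1, 1]
        m = confusion_metrics(y, y)
        assert m == {"MCC": 1.0, "F1": 1.0, "BACC": 1.0}

    def test_all_positive_predictions_degenerate_mcc(self):
        m = confusion_metrics([0, 1, 0, 1], [1, 1, 1, 1])
        assert m["MCC"] == 0.0

    def test_hand_computed_table(self):
        # TP=8 FP=2 FN=1 TN=9
        m = confusion_metrics_from_table(8, 2, 1, 9)
        assert m["MCC"] == pytest.approx((8 * 9 - 2 * 1) / math.sqrt(10 * 9 * 11 * 10))
        assert m["F1"] == pytest.approx(16 / 19)
        assert m["BACC"] == pytest.approx(0.5 * (8 / 9 + 9 / 11))

    def test_non_binary_input_rejected(self):
        with pytest.raises(UndefinedMetricError):
            confusion_metrics([0, 1, 2], [0, 1, 1])

    @given(
        st.tuples(
            st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_matches_formula_oracle(self, table):
        tp, fp, fn, tn = table
        got = confusion_metrics_from_table(tp, fp, fn, tn)
        want = confusion_formula(tp, fp, fn, tn)
        for k in ("MCC", "F1", "BACC"):
            assert got[k] == pytest.approx(want[k], abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 1, 1], [0.2, 0.5, 0.9])

    def test_matches_concordance_oracle(self, rng):
        for _ in range(20):
            y = np.array([0] * 4 + [1] * 4)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=8)
            assert auc(y, scores) == pytest.approx(auc_concordance(y, scores))


class TestRegressionMetrics:
    def test_identity_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["Pearson"] == pytest.approx(1.0)
        assert m["MSE"] == 0.0

    def test_sign_flip(self):
        y = np.array([-1.0, 0.0, 1.0])
        assert regression_metrics(y, -y)["Pearson"] == pytest.approx(-1.0)

    def test_six_point_hand_dataset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        yhat = np.array([1.5, 1.8, 3.4, 3.9, 5.5, 5.6])
        m = regression_metrics(y, yhat)
        # direct formula evaluation
        mse = float(np.mean((y - yhat) ** 2))
        assert m["MSE"] == pytest.approx(mse)
        assert m["RMSE"] == pytest.approx(math.sqrt(mse))
        pearson = float(
            np.sum((y - y.mean()) * (yhat - yhat.mean()))
            / math.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((yhat - yhat.mean()) ** 2))
        )
        assert m["Pearson"] == pytest.approx(pearson)
        # yhat is monotone in y, so both rank correlations are exactly 1
        assert m["Spearman"] == pytest.approx(1.0)
        assert m["Kendall"] == pytest.approx(1.0)

    def test_constant_input_raises_but_carries_errors(self):
        with pytest.raises(UndefinedMetricError) as exc:
            regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert exc.value.mse == pytest.approx(2 / 3)


class TestCrossValidate:
    def test_separable_data_reaches_perfect_mcc(self, rng):
        y = np.array([0, 1] * 50)
        X = np.column_stack([y * 2.0 + rng.uniform(0, 0.5, 100), rng.normal(size=100)])
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        report = cross_validate(spec, X, y, k=10)
        assert report.pooled["MCC"] == 1.0

    def test_permuted_labels_give_null_mcc(self, rng):
        X = rng.normal(size=(500, 10))
        y = rng.permutation([0, 1] * 250)
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        report = cross_validate(spec, X, y, k=5)
        assert abs(report.pooled["MCC"]) < 0.15

    def test_same_seed_identical_reports(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        spec = ModelSpec("random_forest", "classification", seed=3, overrides=FAST)
        a = cross_validate(spec, X, y, k=5)
        b = cross_validate(spec, X, y, k=5)
        assert a.pooled == b.pooled
        assert a.per_fold == b.per_fold
        assert (a.oof_prediction == b.oof_prediction).all()

    def test_rmse_is_sqrt_mse(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 50)
        spec = ModelSpec("random_forest", "regression", seed=0, overrides=FAST)
        report = cross_validate(spec, X, y, k=5)
        assert report.pooled["RMSE"] == pytest.approx(math.sqrt(report.pooled["MSE"]))

    def test_small_class_raises_fold_error(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 3 + [0] * 27)
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        with pytest.raises(FoldError, match="smaller k"):
            cross_validate(spec, X, y, k=10)

    @pytest.mark.parametrize("family", ["random_forest", "extra_trees", "mlp", "svm"])
    def test_all_families_instantiate_and_fit(self, family, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        est = build_estimator(ModelSpec(family, "classification", seed=0))
        est.fit(X, y)
        assert est.predict(X).shape == (40,)


class TestGreedySelect:
    def test_planted_signal_selected_first(self, rng):
        X = rng.normal(size=(80, 10))
        y = (X[:, 6] > 0).astype(int)
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        selected = greedy_select(X, y, spec, k=4, patience=2, max_features=4)
        assert selected[0] == 6

    def test_all_noise_stops_early(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.permutation([0, 1] * 30)
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        selected = greedy_select(X, y, spec, k=4, patience=2)
        assert len(selected) <= 2

    def test_duplicate_feature_tie_broken_by_column_order(self, rng):
        base = rng.normal(size=80)
        y = (base > 0).astype(int)
        X = rng.normal(size=(80, 8)) * 0.01
        X[:, 3] = base
        X[:, 7] = base  # identical signal, later column
        spec = ModelSpec("extra_trees", "classification", seed=0, overrides=FAST)
        selected = greedy_select(X, y, spec, k=4, patience=1, max_features=1)
        assert selected[0] == 3


class TestRemoveOutliers:
    def test_removes_exactly_floor_fraction(self):
        y = np.arange(10, dtype=float)
        yhat = y.copy()
        yhat[4] += 5.0  # the single gross error
        trim = remove_outliers(y, yhat, fraction=0.10)
        assert trim.removed.tolist() == [4]
        assert trim.retained.size == 9

    def test_fraction_zero_is_identity(self):
        y = np.arange(5, dtype=float)
        trim = remove_outliers(y, y + 0.1, fraction=0.0)
        assert trim.removed.size == 0
        assert trim.retained.tolist() == list(range(5))

    def test_ties_broken_by_original_index(self):
        y = np.zeros(10)
        yhat = np.ones(10)  # all residuals equal
        trim = remove_outliers(y, yhat, fraction=0.2)
        assert trim.removed.tolist() == [0, 1]

    def test_planted_gross_errors_recovered_and_pearson_increases(self, rng):
        n = 50
        y = rng.normal(size=n)
        yhat = y + rng.normal(0, 0.05, n)
        planted = rng.choice(n, size=5, replace=False)
        yhat[planted] += rng.choice([-1, 1], 5) * rng.uniform(3, 5, 5)
        trim = remove_outliers(y, yhat, fraction=0.10)
        assert sorted(trim.removed.tolist()) == sorted(planted.tolist())
        assert trim.metrics_after["Pearson"] > trim.metrics_before["Pearson"]


class TestClassifyByRegression:
    def test_boundary_is_inclusive(self):
        assert classify_by_regression([6.0])[0] == 1
        assert classify_by_regression([5.99])[0] == 0

    def test_counts_match_threshold_scan(self, rng):
        yhat = rng.uniform(4, 8, 200)
        for cutoff in (5.0, 5.5, 6.0, 6.5):
            assert classify_by_regression(yhat, cutoff).sum() == np.sum(yhat >= cutoff)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    types = np.array(["I"] * 80 + ["I1/2"] * 40 + ["II"] * 30 + ["allosteric"] * 12)
    X = rng.normal(size=(types.size, 6))
    for i, cls in enumerate(["I", "I1/2", "II", "allosteric"]):
        X[types == cls, i] += 6.0
    perm = rng.permutation(types.size)
    return X[perm], types[perm]


class TestTypeClassifiers:

    def test_separable_classes_recovered(self, separable):
        X, types = separable
        half = X.shape[0] // 2
        models = train_type_classifiers(X[:half], types[:half], seed=0)
        preds = models.predict(X[half:])
        for name, (a, b) in (
            ("I_vs_II", ("I", "II")),
            ("I_vs_I1/2", ("I", "I1/2")),
            ("I1/2_vs_II", ("I1/2", "II")),
        ):
            mask = np.isin(types[half:], (a, b))
            y = (types[half:][mask] == a).astype(int)
            yhat = np.array(
                [1 if p.votes[name] == a else 0 for p, m in zip(preds, mask) if m]
            )
            assert confusion_metrics(y, yhat)["MCC"] >= 0.9, name
        allo_true = (types[half:] == "allosteric").astype(int)
        allo_pred = np.array([int(p.votes["allosteric_vs_rest"]) for p in preds])
        assert confusion_metrics(allo_true, allo_pred)["MCC"] >= 0.9

    def test_missing_class_raises(self, separable):
        X, types = separable
        mask = types != "II"
        with pytest.raises(SmallClassError, match="'II'"):
            train_type_classifiers(X[mask], types[mask])

    def test_default_family_is_mlp_for_middle_contrast(self, separable):
        X, types = separable
        models = train_type_classifiers(X, types, seed=0)
        assert models.families["I1/2_vs_II"] == "mlp"
        assert models.families["I_vs_II"] == "extra_trees"


class TestTypeVote:
    def _votes(self, a, b, c, allo=False):
        return {
            "I_vs_II": a,
            "I_vs_I1/2": b,
            "I1/2_vs_II": c,
            "allosteric_vs_rest": allo,
        }

    def test_unanimous_winner(self):
        assert type_vote(self._votes("I", "I", "I1/2")) == ("I", False)

    def test_allosteric_precedence(self):
        assert type_vote(self._votes("II", "I1/2", "II", allo=True)) == (
            "allosteric",
            False,
        )

    def test_cyclic_votes_fall_back_to_majority_class(self):
        final, tie = type_vote(self._votes("I", "I1/2", "II"))
        assert final == "I" and tie

    def test_missing_prediction_raises(self):
        with pytest.raises(ValueError, match="missing"):
            type_vote({"I_vs_II": "I"})
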