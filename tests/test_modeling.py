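"""Classifier harness: metrics, ROC/AUC oracle, CV partition properties,
baseline table consistency."""

import numpy as np
import pytest
from scipy import stats

from myoscreen import (
    ConfigError,
    ConfusionCounts,
    ModelConfig,
    compute_metrics,
    confusion,
    kfold_cv,
    predict_labels,
    roc_auc,
    run_baselines,
    train_classifier,
)
from myoscreen.transform import FeatureMatrix
from myoscreen.reference_tables import baseline_metrics_table


def make_features(X, y):
    return FeatureMatrix(
        student_ids=np.array([f"S{i}" for i in range(len(y))], dtype=object),
        feature_names=[f"x{j}" for j in range(X.shape[1])],
        values=np.asarray(X, float),
        label=np.asarray(y, int),
        normalization_params={f"x{j}": (0.0, 1.0) for j in range(X.shape[1])},
        train_mask=np.ones(len(y), dtype=bool),
    )


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) * 0.3 + np.where(y[:, None] == 1, 2.0, -2.0)
    return make_features((X - X.min()) / (X.max() - X.min()), y)


class TestClassifier:
    def test_separable_data_fits_perfectly(self, separable):
        clf = train_classifier(separable, ModelConfig(seed=1))
        _, labels = predict_labels(clf, separable, 0.5)
        assert (labels == separable.label).mean() == 1.0

    def test_single_class_rejected(self):
        fm = make_features(np.random.default_rng(1).random((20, 2)), np.zeros(20))
        with pytest.raises(ConfigError, match="single class"):
            train_classifier(fm, ModelConfig())

    def test_threshold_is_strict(self):
        class Stub:
            _n_features = 1

            def predict_proba(self, X):
                p = np.array([0.5, 0.2, 0.7])
                return np.column_stack([1 - p, p])

        probs, labels = predict_labels(Stub(), np.zeros((3, 1)), threshold=0.5)
        assert labels.tolist() == [0, 0, 1]
        probs, labels = predict_labels(Stub(), np.zeros((3, 1)), threshold=0.0)
        assert labels.tolist() == [1, 1, 1]

    def test_null_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(7)
        n = 500
        X = rng.random((n, 3))
        y = (rng.random(n) < 0.5).astype(int)
        fm = make_features(X, y)
        cv_mean, _ = kfold_cv(fm, ModelConfig(seed=3))
        prior = max(y.mean(), 1 - y.mean())
        se = np.sqrt(prior * (1 - prior) / n)
        assert cv_mean < prior + 2.576 * se + 0.02

    def test_duplicated_rows_leave_decision_function_unchanged(self):
        """In the hard-margin regime (wide-margin separable data, no active
        slack) duplicating every row cannot move the solution."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 2)) * 0.2 + np.where(y[:, None] == 1, 3.0, -3.0)
        a = SVC(kernel="linear", C=1.0).fit(X, y)
        b = SVC(kernel="linear", C=1.0).fit(np.vstack([X, X]), np.concatenate([y, y]))
        grid = rng.normal(size=(50, 2)) * 3
        assert np.allclose(a.decision_function(grid), b.decision_function(grid), atol=1e-6)


class TestConfusionAndMetrics:
    def test_perfect_and_inverted_predictions(self):
        t = [1, 1, 0, 0]
        assert confusion(t, t) == ConfusionCounts(2, 0, 2, 0)
        assert confusion(t, [0, 0, 1, 1]) == ConfusionCounts(0, 2, 0, 2)

    def test_mixed_tabulation(self):
        c = confusion([1, 0, 1, 0, 0], [1, 1, 0, 0, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 2)

    def test_non_binary_rejected(self):
        with pytest.raises(ConfigError, match="binary"):
            confusion([0, 2], [0, 1])

    def test_symmetric_counts_give_half_everywhere(self):
        rep = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        for v in (rep.accuracy, rep.precision, rep.sensitivity, rep.specificity, rep.f1):
            assert v == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "method,expected_f1",
        [("Logistic Regression", 0.85), ("Naive Bayes", 0.90),
         ("KNN", 0.69), ("Random Forest", 0.92)],
    )
    def test_f1_identity_on_published_precision_recall(self, method, expected_f1):
        row = baseline_metrics_table().set_index("method").loc[method]
        p, r = row["precision"], row["sensitivity"]
        f1 = 2 * p * r / (p + r)
        assert round(f1, 2) == expected_f1

    def test_zero_denominator_reports_zero_with_warning(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert rep.precision == 0.0
        assert any("precision" in w for w in rep.warnings)
        with pytest.raises(ConfigError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        y = [0, 0, 1, 1]
        points, auc = roc_auc([0.1, 0.2, 0.8, 0.9], y)
        assert auc == pytest.approx(1.0)
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_null_scores_give_chance_auc(self, rng):
        n = 2000
        y = (rng.random(n) < 0.5).astype(int)
        s = rng.random(n)
        _, auc = roc_auc(s, y)
        n1, n0 = y.sum(), n - y.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    def test_auc_equals_normalized_mann_whitney_u(self, rng):
        for _ in range(5):
            n = 80
            y = np.concatenate([np.zeros(40), np.ones(40)]).astype(int)
            s = rng.standard_normal(n) + y  # overlap with ties unlikely
            _, auc = roc_auc(s, y)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (40 * 40), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidation:
    def test_fold_partition_covers_all_rows(self, separable):
        from sklearn.model_selection import StratifiedKFold

        y = separable.label
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=4)
        seen = []
        for _, test_idx in skf.split(separable.values, y):
            assert set(seen).isdisjoint(test_idx)
            seen.extend(test_idx)
        assert sorted(seen) == list(range(len(y)))

    def test_same_seed_reproduces_cv_exactly(self, separable):
        a = kfold_cv(separable, ModelConfig(seed=9))
        b = kfold_cv(separable, ModelConfig(seed=9))
        assert a == b


@pytest.fixture(scope="module")
def table(separable):
    return run_baselines(separable, ModelConfig(seed=2))


class TestBaselines:
    def test_every_baseline_separates_the_separable_cohort(self, table):
        ok = table[table["Status"] == "ok"]
        assert len(ok) == len(table)
        non_knn = ok[ok["Method"] != "KNN"]
        assert (non_knn["Accuracy"] > 0.9).all()

    def test_f1_internally_consistent(self, table):
        for row in table.itertuples():
            p, r = row.Precision, row.Sensitivity
            if p + r > 0:
                assert row.f1 == pytest.approx(2 * p * r / (p + r), abs=1e-9)

    def test_fixed_seed_reproduces_table(self, separable, table):
        again = run_baselines(separable, ModelConfig(seed=2))
        assert table.drop(columns="Status").equals(again.drop(columns="Status"))
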