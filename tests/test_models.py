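import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from cc_organotrait.models import (
    CLASSIFIER_FAMILIES,
    REGRESSOR_FAMILIES,
    CVProtocol,
    RegressionProtocol,
    build_features,
    label_top_percentile,
    model_grid,
    run_classification_cv,
    run_regression_iters,
)


class TestLabelTopPercentile:
    def test_one_to_ten(self):
        values = np.arange(1.0, 11.0)
        labels = label_top_percentile(values, 70)
        assert np.percentile(values, 70) == pytest.approx(7.3)
        assert labels.sum() == 3
        assert list(np.flatnonzero(labels)) == [7, 8, 9]  # values 8, 9, 10

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            label_top_percentile(np.full(10, 3.0))

    def test_q_zero_strict_inequality(self):
        labels = label_top_percentile(np.arange(1.0, 11.0), 0)
        assert labels.sum() == 9
        assert labels[0] == 0  # the minimum ties the threshold -> 0

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 4"):
            label_top_percentile([1.0, 2.0, 3.0])


class TestClassificationCV:
    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_perfect_leak(self, family):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        X = np.column_stack([y.astype(float), rng.normal(size=60)])
        res = run_classification_cv(X, y, family, CVProtocol(seed=1))
        assert res.mean_roc_auc == pytest.approx(1.0)
        assert res.skipped_folds == 0

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.4).astype(int)
        r1 = run_classification_cv(X, y, "random_forest", CVProtocol(seed=7))
        r2 = run_classification_cv(X, y, "random_forest", CVProtocol(seed=7))
        assert r1.fold_scores == r2.fold_scores

    def test_single_class_flagged(self):
        X = np.zeros((20, 2))
        res = run_classification_cv(X, np.zeros(20, dtype=int), "knn")
        assert res.flags == "single_class"
        assert np.isnan(res.mean_roc_auc)

    def test_too_few_samples_flagged(self):
        X = np.zeros((6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        res = run_classification_cv(X, y, "knn", CVProtocol(k=4))
        assert "too_few_samples" in res.flags or "class_smaller_than_k" in res.flags

    def test_cv_partition_correctness(self):
        """Folds are disjoint, cover all samples, and test indices never
        appear in their own training fold."""
        rng = np.random.default_rng(3)
        y = (rng.random(37) < 0.4).astype(int)
        splitter = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = []
        for train, test in splitter.split(np.zeros((37, 1)), y):
            assert set(train).isdisjoint(test)
            seen.extend(test)
        assert sorted(seen) == list(range(37))

    def test_small_n_null_spread(self):
        """Features independent of labels at the largest per-line size:
        per-seed AUC varies but stays in a plausible null band."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(34, 6))
        y = label_top_percentile(rng.normal(size=34))
        for seed in range(5):
            res = run_classification_cv(X, y, "naive_bayes", CVProtocol(seed=seed))
            assert 0.2 <= res.mean_roc_auc <= 0.8

    def test_monotone_signal_response(self):
        """Stronger feature-label signal -> non-decreasing mean ROC-AUC."""
        means = []
        for effect in (0.0, 1.0, 3.0):
            rng = np.random.default_rng(10)
            aucs = []
            for rep in range(100):
                y = (rng.random(60) < 0.3).astype(int)
                X = rng.normal(size=(60, 4))
                X[:, 0] += effect * y
                res = run_classification_cv(X, y, "naive_bayes", CVProtocol(seed=rep))
                if not np.isnan(res.mean_roc_auc):
                    aucs.append(res.mean_roc_auc)
            means.append(np.mean(aucs))
        assert means[0] <= means[1] <= means[2]


class TestRegressionIters:
    def test_target_equals_feature(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        X = np.column_stack([t, rng.normal(size=50)])
        res = run_regression_iters(X, t, "linear", RegressionProtocol(iterations=20))
        assert res.mean_r2_raw == pytest.approx(1.0)
        assert res.mean_r2_floored == pytest.approx(1.0)

    def test_independent_noise_floors_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        t = rng.normal(size=60)
        res = run_regression_iters(X, t, "linear", RegressionProtocol(iterations=50))
        assert res.mean_r2_raw <= 0.0
        assert res.mean_r2_floored == 0.0

    def test_strong_signal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3))
        t = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.1, size=100)
        res = run_regression_iters(X, t, "linear", RegressionProtocol(iterations=50))
        assert res.mean_r2_raw > 0.9

    def test_holdout_r2_matches_direct_loop(self):
        """R^2 equals 1 - SSE/SST computed by explicit loops."""
        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import train_test_split

        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        t = X[:, 0] * 2 + rng.normal(size=80)
        X_tr, X_te, y_tr, y_te = train_test_split(X, t, train_size=0.7,
                                                  random_state=5)
        model = LinearRegression().fit(X_tr, y_tr)
        pred = model.predict(X_te)
        sse = sum((yi - pi) ** 2 for yi, pi in zip(y_te, pred))
        mean_y = sum(y_te) / len(y_te)
        sst = sum((yi - mean_y) ** 2 for yi in y_te)
        assert model.score(X_te, y_te) == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_too_small_flagged(self):
        res = run_regression_iters(np.zeros((5, 2)), np.arange(5.0), "linear")
        assert "too_few_samples" in res.flags


class TestFeatures:
    def test_feature_sets(self, trait_table):
        X, kept, dropped = build_features(trait_table, "paper-text")
        assert X.shape == (207, 6)
        assert dropped == 0
        X2, _, _ = build_features(trait_table, "table-caption")
        assert X2.shape == (207, 5)

    def test_missing_rows_dropped(self, trait_table):
        table = trait_table.copy()
        table.loc[table.index[:3], "auc_wk6"] = np.nan
        X, kept, dropped = build_features(table)
        assert dropped == 3
        assert len(kept) == 204


class TestModelGrid:
    def test_classification_grid_shape(self, trait_table):
        grid = model_grid(trait_table, "liver", "classify",
                          cv_protocol=CVProtocol(seed=0))
        assert grid.scores.shape == (4, 8)
        assert set(grid.scores.index) == set(CLASSIFIER_FAMILIES)
        assert len(grid.lines) == 8
        scored = grid.scores.to_numpy()
        finite = scored[~np.isnan(scored)]
        assert ((finite >= 0) & (finite <= 1)).all()
        assert grid.protocol["k"] == 4
        assert grid.protocol["label_percentile"] == 70.0

    def test_grid_determinism(self, trait_table):
        g1 = model_grid(trait_table, "spleen", "classify",
                        cv_protocol=CVProtocol(seed=5))
        g2 = model_grid(trait_table, "spleen", "classify",
                        cv_protocol=CVProtocol(seed=5))
        pd.testing.assert_frame_equal(g1.scores, g2.scores)

    def test_regression_grid(self, trait_table):
        grid = model_grid(
            trait_table, "liver", "regress",
            reg_protocol=RegressionProtocol(iterations=10, seed=0),
        )
        assert grid.scores.shape == (2, 8)
        assert set(grid.scores.index) == set(REGRESSOR_FAMILIES)
        assert (grid.scores.fillna(0.0) >= 0).all().all()  # floored scores

    def test_degenerate_line_flagged(self, trait_table):
        table = trait_table.copy()
        mask = table["line"] == "IL72"
        table.loc[mask, "pct_liver"] = 5.0  # constant target -> no labels
        grid = model_grid(table, "liver", "classify")
        assert all(np.isnan(grid.scores.loc[f, "IL72"])
                   for f in CLASSIFIER_FAMILIES)
        assert any("labels" in v for (f, line), v in grid.flags.items()
                   if line == "IL72")

    def test_pooled_mode(self, trait_table):
        grid = model_grid(trait_table, "liver", "classify", per_line=False)
        assert grid.lines == ("all",)
        assert grid.n["all"] == 207

    def test_json_round_trip(self, trait_table):
        import json

        grid = model_grid(
            trait_table, "heart", "regress",
            reg_protocol=RegressionProtocol(iterations=5),
        )
        blob = json.dumps(grid.to_json_dict())
        parsed = json.loads(blob)
        assert parsed["task"] == "regress"
        assert set(parsed["grid"]) == set(REGRESSOR_FAMILIES)
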