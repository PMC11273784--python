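import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hemocloud.classify import (
    ALGORITHMS,
    GROUP_DIMS,
    assemble_feature_group,
    auc_from_roc,
    cloud_features_frame,
    compute_metrics,
    normalize_features,
    roc_points,
    run_cv,
    run_experiment_grid,
)
from hemocloud.pointnet import CloudFeatureVector, ExtractorConfig
from hemocloud.types import ValidationError


class TestMetrics:
    def test_hand_counted_example(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1])
        assert m["accuracy"] == 0.75
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5
        assert m["auc"] == 1.0

    def test_all_scores_tied_auc_half(self):
        m = compute_metrics([1, 0, 1, 0, 0], [0.3] * 5)
        assert m["auc"] == pytest.approx(0.5, abs=1e-12)

    def test_auc_matches_mann_whitney_brute_force(self, rng):
        """Pairwise-comparison oracle with half-credit for ties, 50 random vectors."""
        for _ in range(50):
            n = int(rng.integers(8, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[y == 1]
            neg = scores[y == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            expected = wins / (len(pos) * len(neg))
            got = compute_metrics(y, scores)["auc"]
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 60)
        y[:5], y[5:10] = 1, 0
        s = rng.random(60)
        a1 = compute_metrics(y, s)["auc"]
        a2 = compute_metrics(y, np.exp(3 * s) - 1)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_metrics_invariant_to_case_order(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        perm = rng.permutation(50)
        m1 = compute_metrics(y, s)
        m2 = compute_metrics(y[perm], s[perm])
        assert m1 == m2

    def test_roc_shape_and_area_consistency(self, rng):
        y = rng.integers(0, 2, 80)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(80), 2)
        roc = roc_points(y, s)
        assert (roc[0] == [0, 0]).all() and (roc[-1] == [1, 1]).all()
        assert (np.diff(roc[:, 0]) >= 0).all()
        assert auc_from_roc(roc) == pytest.approx(
            compute_metrics(y, s)["auc"], abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics([1, 1, 1], [0.1, 0.2, 0.3])


class TestNormalize:
    def test_train_column_standardised(self, rng):
        X = rng.normal(3.0, 2.5, size=(40, 4))
        Z, _ = normalize_features(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z, _ = normalize_features(X)
        assert (Z[:, 0] == 0).all()

    def test_test_fold_uses_train_statistics(self, rng):
        train = rng.normal(size=(30, 3))
        test = rng.normal(size=(10, 3))
        _, Zte = normalize_features(train, test)
        mu, sd = train.mean(axis=0), train.std(axis=0)
        np.testing.assert_allclose(Zte, (test - mu) / sd, rtol=1e-12)


class TestRunCV:
    def separable(self, rng, n=60):
        y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n - n // 2, dtype=int)]
        X = rng.normal(size=(n, 3))
        X[:, 0] += 8.0 * y
        return X, y

    def test_perfectly_separable(self, rng):
        X, y = self.separable(rng)
        rec = run_cv(X, y, "LR", folds=5, seed=0)
        assert rec.accuracy == 1.0
        assert rec.auc == 1.0

    def test_every_case_scored_once(self, rng):
        X, y = self.separable(rng)
        rec = run_cv(X, y, "LR", folds=6, seed=1)
        counts = np.bincount(rec.fold_assignments)
        assert counts.sum() == len(y)
        assert (rec.fold_assignments >= 0).all()

    def test_shuffled_labels_are_chance_level(self, rng):
        """Permutation null: mean out-of-fold AUC near 0.5 over 10 repeats."""
        X = rng.normal(size=(60, 5))
        aucs = []
        for k in range(10):
            y = np.r_[np.zeros(40, dtype=int), np.ones(20, dtype=int)]
            np.random.default_rng(k).shuffle(y)
            aucs.append(run_cv(X, y, "LR", folds=5, seed=k).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_seeded_determinism(self, rng):
        X, y = self.separable(rng)
        X += rng.normal(size=X.shape)
        r1 = run_cv(X, y, "XGBoost", folds=5, seed=3)
        r2 = run_cv(X, y, "XGBoost", folds=5, seed=3)
        assert r1.auc == r2.auc and r1.accuracy == r2.accuracy
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_folds_exceeding_minority_rejected(self, rng):
        X, y = self.separable(rng, n=12)
        with pytest.raises(ValidationError):
            run_cv(X, y, "LR", folds=10, seed=0)

    def test_unknown_algorithm_rejected(self, rng):
        X, y = self.separable(rng)
        with pytest.raises(ValidationError):
            run_cv(X, y, "RandomForest", folds=3, seed=0)


class TestFeatureGroups:
    def make_tables(self, n=6, dim=16):
        tab = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(n)],
                "label": [i % 2 for i in range(n)],
                "aspect_ratio": np.linspace(1, 2, n),
                "wss_mean": np.linspace(3, 5, n),
            }
        )
        vecs = [
            CloudFeatureVector(f"c{i}", np.arange(dim, dtype=float) + i)
            for i in range(n)
        ]
        return tab, cloud_features_frame(vecs)

    def test_group_a_tabular_only(self):
        tab, _ = self.make_tables()
        X, y, cols = assemble_feature_group(tab, None, "A")
        assert X.shape == (6, 2)
        assert cols == ["aspect_ratio", "wss_mean"]

    def test_group_b4_appends_16(self):
        tab, feats = self.make_tables(dim=16)
        X, y, cols = assemble_feature_group(tab, feats, "B4")
        assert X.shape == (6, 2 + 16)

    def test_dimension_mismatch_rejected(self):
        tab, feats = self.make_tables(dim=8)
        with pytest.raises(ValidationError, match="16"):
            assemble_feature_group(tab, feats, "B4")

    def test_missing_case_named(self):
        tab, feats = self.make_tables()
        feats = feats[feats["case_id"] != "c3"]
        with pytest.raises(ValidationError, match="c3"):
            assemble_feature_group(tab, feats, "B4")

    def test_group_dimension_map(self):
        assert GROUP_DIMS == {"A": None, "B1": 1024, "B2": 64, "B3": 32, "B4": 16}


class TestGrid:
    def test_report_shape_and_ranges(self, small_cohort):
        cases, table = small_cohort
        clouds = [c.cloud for c in cases]
        cfg = ExtractorConfig(channels=(4, 4, 8, 16), epochs=2, seed=0)
        report, rocs = run_experiment_grid(
            table, clouds, groups=("A", "B4"), algorithms=("LR", "XGBoost"),
            extractor_config=cfg, folds=4, seed=0,
        )
        assert len(report) == 4  # 2 algorithms x 2 groups
        assert report["AUC"].between(0, 1).all()
        assert set(rocs) == {("LR", "A"), ("XGBoost", "A"), ("LR", "B4"), ("XGBoost", "B4")}
        assert list(report.columns) == [
            "Algorithm", "Feature", "Accuracy", "Sensitivity", "Specificity", "AUC"
        ]
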