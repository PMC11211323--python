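"""Risk-model stage: imputation, encoding, SMOTE, tuning, training, prediction."""

import numpy as np
import pandas as pd
import pytest

from deeprisk.metrics import auroc
from deeprisk.risk import (
    FeatureEncoder,
    SearchSpace,
    StratificationError,
    _cv_auroc,
    branch_columns,
    filter_missing_columns,
    impute_missing,
    latent_frame,
    predict_risk,
    smote_oversample,
    train_classifier,
    tune_hyperparameters,
)


class TestMissingData:
    def test_complete_table_unchanged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.integers(0, 2, 50)})
        out = impute_missing(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_over_30_percent_column_excluded(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        df.loc[: int(0.35 * 100), "b"] = np.nan  # 35% missing
        out = impute_missing(df, seed=0)
        assert "b" not in out.columns and "a" in out.columns

    def test_boundary_30_percent_kept(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        df.loc[:29, "b"] = np.nan  # exactly 30%
        assert "b" in filter_missing_columns(df).columns

    def test_imputation_recovers_duplicated_column(self, rng):
        a = rng.normal(size=300)
        b = a.copy()
        mask = rng.random(300) < 0.2
        b[mask] = np.nan
        df = pd.DataFrame({"a": a, "b": b, "noise": rng.normal(size=300)})
        out = impute_missing(df, seed=1)
        r = np.corrcoef(out.loc[mask, "b"], a[mask])[0, 1]
        assert r > 0.95

    def test_categorical_imputation(self, rng):
        n = 200
        cat = np.where(rng.random(n) < 0.5, "x", "y")
        linked = np.where(cat == "x", 1.0, -1.0) + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"cat": cat, "linked": linked})
        miss = rng.random(n) < 0.15
        df.loc[miss, "cat"] = np.nan
        out = impute_missing(df, seed=2)
        assert (out.loc[miss, "cat"] == cat[miss]).mean() > 0.9


class TestFeatureEncoder:
    def test_one_hot_columns_sum_to_one(self):
        df = pd.DataFrame({"c": ["a", "b", "c", "a"]})
        enc = FeatureEncoder().fit(df)
        out = enc.transform(df)
        assert out.shape[1] == 3
        assert np.all(out.sum(axis=1) == 1.0)

    def test_continuous_standardized_on_dev(self, rng):
        df = pd.DataFrame({"x": rng.normal(5.0, 2.0, 200)})
        out = FeatureEncoder().fit(df).transform(df)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["x"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_external_rows_use_development_statistics(self, rng):
        dev = pd.DataFrame({"x": rng.normal(0.0, 1.0, 100)})
        ext = pd.DataFrame({"x": rng.normal(3.0, 1.0, 100)})
        enc = FeatureEncoder().fit(dev)
        transformed = enc.transform(ext)
        refit = FeatureEncoder().fit(ext).transform(ext)
        assert transformed["x"].mean() == pytest.approx(3.0, abs=0.5)  # shift retained
        assert not np.allclose(transformed["x"], refit["x"])

    def test_unseen_category_maps_to_zero_with_warning(self):
        enc = FeatureEncoder().fit(pd.DataFrame({"c": ["a", "b"]}))
        with pytest.warns(UserWarning, match="unseen"):
            out = enc.transform(pd.DataFrame({"c": ["z"]}))
        assert np.all(out.to_numpy() == 0.0)


class TestSmote:
    def test_interpolation_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0], [8.0, 8.0]])
        y = np.array([1, 1, 0, 0, 0, 0])
        Xo, yo = smote_oversample(X, y, k=1, seed=0)
        synthetic = Xo[len(X):]
        assert np.allclose(synthetic[:, 0], synthetic[:, 1])  # on the diagonal segment
        assert np.all((synthetic >= 0.0) & (synthetic <= 1.0))

    def test_classes_balanced(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 10 + [0] * 50)
        _, yo = smote_oversample(X, y, seed=1)
        counts = np.bincount(yo)
        assert counts[0] == counts[1]

    def test_synthetic_nearest_original_is_minority(self, rng):
        from sklearn.neighbors import NearestNeighbors

        X = np.vstack([rng.normal(0, 1, size=(12, 4)), rng.normal(8, 1, size=(48, 4))])
        y = np.array([1] * 12 + [0] * 48)
        for seed in range(20):
            Xo, yo = smote_oversample(X, y, seed=seed)
            synthetic = Xo[len(X):]
            nn = NearestNeighbors(n_neighbors=1).fit(X)
            _, idx = nn.kneighbors(synthetic)
            assert np.all(y[idx.ravel()] == 1)

    def test_minority_too_small_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(np.zeros((5, 2)), np.array([1, 0, 0, 0, 0]))


class TestTuning:
    def test_collapsed_space_returns_point(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        space = SearchSpace(
            max_depth=(3, 3), learning_rate=(0.1, 0.1), n_estimators=(50, 50),
            subsample=(1.0, 1.0), min_child_weight=(1.0, 1.0),
            reg_alpha=(0.0, 0.0), reg_lambda=(0.0, 0.0),
        )
        cfg, log = tune_hyperparameters(X, y, space, k_folds=3, n_trials=5, seed=0)
        assert cfg["max_depth"] == 3 and cfg["n_estimators"] == 50
        assert len(log) == 1

    def test_planted_depth_optimum(self, rng):
        # three-way parity: a single tree needs depth >= 3 to model it
        n = 600
        X = rng.integers(0, 2, size=(n, 3)).astype(float)
        y = (X.sum(axis=1) % 2).astype(int)
        X += rng.normal(0, 0.01, X.shape)
        space = SearchSpace(
            max_depth=(1, 6), learning_rate=(0.3, 0.3), n_estimators=(60, 60),
            subsample=(1.0, 1.0), min_child_weight=(1.0, 1.0),
            reg_alpha=(0.0, 0.0), reg_lambda=(1.0, 1.0),
        )
        cfg, _ = tune_hyperparameters(X, y, space, k_folds=3, n_trials=10, seed=1)
        assert cfg["max_depth"] >= 3

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(max_depth=(8, 2))

    def test_single_class_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([1] + [0] * 9)  # cannot stratify into 3 folds
        with pytest.raises((StratificationError, ValueError)):
            _cv_auroc(X, y, {"max_depth": 2, "n_estimators": 10}, k_folds=3, seed=0)


class TestClassifier:
    def test_separable_data_perfect_training_auroc(self, rng):
        X = pd.DataFrame({"x": np.r_[rng.normal(-3, 0.2, 40), rng.normal(3, 0.2, 40)]})
        y = np.array([0] * 40 + [1] * 40)
        rm = train_classifier(X, y, seed=0)
        scores = [p.probability for p in predict_risk(rm, X)]
        assert auroc(scores, y) == 1.0

    def test_permuted_labels_chance_cv(self, rng):
        from sklearn.model_selection import StratifiedKFold

        X = rng.normal(size=(200, 8))
        y = rng.permutation(np.array([1] * 100 + [0] * 100))
        aucs = []
        for tr, va in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            rm = train_classifier(pd.DataFrame(X[tr]), y[tr], seed=0)
            aucs.append(auroc([p.probability for p in predict_risk(rm, pd.DataFrame(X[va]))], y[va]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(pd.DataFrame({"x": rng.normal(size=10)}), np.ones(10), seed=0)

    def test_duplicated_row_same_probability(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        rm = train_classifier(X, y, seed=1)
        X2 = pd.concat([X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
        p = [r.probability for r in predict_risk(rm, X2)]
        assert p[0] == p[1]
        assert all(0.0 <= v <= 1.0 for v in p)

    def test_missing_column_schema_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = np.array([0, 1] * 15)
        rm = train_classifier(X, y, seed=2)
        with pytest.raises(KeyError):
            predict_risk(rm, X[["a"]])


class TestBranches:
    def test_column_counts(self, rng):
        mri = latent_frame(rng.normal(size=(10, 256)), "mri")
        ecg = latent_frame(rng.normal(size=(10, 32)), "ecg")
        clin = pd.DataFrame(rng.normal(size=(10, 7)), columns=[f"c{i}" for i in range(7)])
        assert branch_columns(mri, ecg, clin, "mri").shape[1] == 256
        assert branch_columns(mri, ecg, clin, "ecg").shape[1] == 32
        assert branch_columns(mri, ecg, clin, "clinical").shape[1] == 7
        assert branch_columns(mri, ecg, clin, "multimodal").shape[1] == 256 + 32 + 7

    def test_unknown_branch_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            branch_columns(df, df, df, "imaging")
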