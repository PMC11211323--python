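"""Explainability: Shapley identities and oracles, traversal, attention maps."""

import numpy as np
import pandas as pd
import pytest
import xgboost

from deeprisk.explain import (
    AttentionMap,
    exact_shapley,
    gradient_attention_map,
    latent_traversal,
    overlay,
    shapley_attributions,
    shapley_matrix,
    top_latents,
)
from deeprisk.risk import train_classifier
from deeprisk.vae import ResidualVAE, VaeConfig


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"f{i}" for i in range(5)])
    y = (X["f0"] + 0.5 * X["f1"] + rng.normal(0, 0.3, 200) > 0).astype(int).to_numpy()
    return train_classifier(X, y, {"max_depth": 3, "n_estimators": 30, "learning_rate": 0.2},
                            seed=0, use_smote=False), X


class TestShapley:
    def test_local_accuracy_on_100_rows(self, toy_model):
        rm, X = toy_model
        margins = rm.model.get_booster().predict(
            xgboost.DMatrix(X.to_numpy(), feature_names=rm.feature_names), output_margin=True
        )
        for i in range(100):
            att = shapley_attributions(rm, X.iloc[i])
            # float32 tree contributions: identity holds to single precision
            assert att.prediction_margin == pytest.approx(float(margins[i]), rel=1e-6, abs=1e-6)

    def test_constant_model_all_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = np.array([0, 1] * 20)
        # an astronomically large min_child_weight forbids any split
        rm = train_classifier(X, y, {"max_depth": 2, "n_estimators": 3,
                                     "min_child_weight": 1e6}, seed=0, use_smote=False)
        att = shapley_attributions(rm, X.iloc[0])
        assert np.allclose(att.values, 0.0, atol=1e-9)

    def test_matches_exact_enumeration_on_toy_tree(self):
        # uniform background over all 2^3 binary feature combinations makes
        # path-dependent TreeSHAP coincide with interventional Shapley values
        from itertools import product

        grid = np.array(list(product([0.0, 1.0], repeat=3)))
        X = pd.DataFrame(np.tile(grid, (8, 1)), columns=["a", "b", "c"])
        y = ((X["a"] + X["b"] * X["c"]) > 0.5).astype(int).to_numpy()
        rm = train_classifier(X, y, {"max_depth": 3, "n_estimators": 1, "learning_rate": 1.0},
                              seed=0, use_smote=False)
        booster = rm.model.get_booster()

        def margin(arr):
            return booster.predict(xgboost.DMatrix(arr, feature_names=rm.feature_names),
                                   output_margin=True)

        for row in grid[:4]:
            att = shapley_attributions(rm, pd.Series(row, index=["a", "b", "c"]))
            phi, base = exact_shapley(margin, row, X.to_numpy())
            assert np.allclose(att.values, phi, atol=1e-5)
            assert att.base_value == pytest.approx(base, abs=1e-5)

    def test_matrix_matches_single_rows(self, toy_model):
        rm, X = toy_model
        frame, base = shapley_matrix(rm, X.iloc[:5])
        att0 = shapley_attributions(rm, X.iloc[0])
        assert np.allclose(frame.iloc[0].to_numpy(), att0.values, atol=1e-9)
        assert base == pytest.approx(att0.base_value, abs=1e-9)


class TestTopLatents:
    def test_all_zero_tie_break_by_index(self):
        s = pd.Series(np.zeros(8), index=[f"mri_{i:03d}" for i in range(8)])
        assert list(top_latents(s, m=3, latent_prefix="mri_")) == [0, 1, 2]

    def test_dominant_feature_first(self):
        s = pd.Series([0.1, -5.0, 0.2], index=["mri_000", "mri_001", "mri_002"])
        assert top_latents(s, m=2, latent_prefix="mri_")[0] == 1

    def test_matches_sort_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(size=30)
            ranked = top_latents(vals, m=30)
            oracle = sorted(range(30), key=lambda i: (-abs(vals[i]), i))
            assert list(ranked) == oracle

    def test_cohort_frame_aggregation(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 4)), columns=[f"mri_{i:03d}" for i in range(4)])
        frame["mri_002"] *= 10
        assert top_latents(frame, m=1, latent_prefix="mri_")[0] == 2


class TestTraversal:
    def test_zero_offset_equals_plain_decoding(self, tiny_ecg_vae, beat_bank):
        lat = tiny_ecg_vae.encode_dataset(beat_bank)
        trav = latent_traversal(tiny_ecg_vae, lat, latent_index=3)
        base_recon = tiny_ecg_vae.decode(lat.mean(axis=0))
        i0 = int(np.where(trav.offsets_sd == 0.0)[0][0])
        assert np.array_equal(trav.reconstructions[i0], base_recon)

    def test_degenerate_dimension_constant(self, tiny_ecg_vae, beat_bank):
        lat = tiny_ecg_vae.encode_dataset(beat_bank)
        lat[:, 5] = 0.7  # zero spread dimension
        trav = latent_traversal(tiny_ecg_vae, lat, latent_index=5)
        for rec in trav.reconstructions[1:]:
            assert np.array_equal(rec, trav.reconstructions[0])

    def test_out_of_range_index(self, tiny_ecg_vae, beat_bank):
        lat = tiny_ecg_vae.encode_dataset(beat_bank)
        with pytest.raises(IndexError):
            latent_traversal(tiny_ecg_vae, lat, latent_index=99)

    def test_planted_factor_varies_monotonically(self):
        # images whose single generative factor is blob size; the latent most
        # correlated with it should traverse monotonically in a size proxy
        rng = np.random.default_rng(3)
        rr, cc = np.mgrid[0:16, 0:16]
        X = np.zeros((120, 2, 16, 16, 2))
        sizes = rng.uniform(2.0, 7.0, 120)
        for i, s in enumerate(sizes):
            blob = (np.sqrt((rr - 8) ** 2 + (cc - 8) ** 2) <= s).astype(float)
            for sl in range(2):
                X[i, sl, :, :, 0] = blob
                X[i, sl, :, :, 1] = 1.0
        cfg = VaeConfig(modality="mri", input_shape=(2, 16, 16, 2), latent_dim=4,
                        hidden_dim=32, n_residual_blocks=1, beta=1e-5,
                        epochs=120, batch_size=32, seed=0)
        vae = ResidualVAE(cfg)
        vae.fit(X)
        lat = vae.encode_dataset(X)
        corr = [abs(np.corrcoef(lat[:, j], sizes)[0, 1]) for j in range(4)]
        j = int(np.argmax(corr))
        trav = latent_traversal(vae, lat, latent_index=j)
        proxy = trav.reconstructions[..., 0].sum(axis=(1, 2, 3))  # decoded blob area
        from scipy.stats import spearmanr

        rho = spearmanr(trav.offsets_sd, proxy).statistic
        assert abs(rho) > 0.8


class _LinearEncoderStub:
    """Analytic encoder mu = W @ x for closed-form attention-map checks."""

    def __init__(self, W, input_shape):
        self.W = W
        from types import SimpleNamespace

        self.config = SimpleNamespace(modality="ecg", input_shape=input_shape,
                                      latent_dim=W.shape[0])

    def input_gradient(self, x, latent_index):
        return self.W[latent_index].reshape(x.shape)


class TestAttentionMaps:
    def test_map_shape_matches_input(self, tiny_ecg_vae, beat_bank):
        amap = gradient_attention_map(tiny_ecg_vae, beat_bank[0], [0, 1, 2])
        assert amap.heatmap.shape == beat_bank[0].shape
        assert 0.0 <= amap.heatmap.min() and amap.heatmap.max() == pytest.approx(1.0)

    def test_zero_weight_latent_gives_zero_map(self, beat_bank):
        from deeprisk.vae import default_ecg_config

        vae = ResidualVAE(default_ecg_config(hidden_dim=16, n_residual_blocks=1, seed=0))
        vae.mu_head.W[:, 7] = 0.0  # silence latent 7
        vae.mu_head.b[7] = 0.0
        amap = gradient_attention_map(vae, beat_bank[0], [7])
        assert np.all(amap.heatmap == 0.0)

    def test_linear_encoder_matches_analytic_mean(self, rng):
        W = rng.normal(size=(6, 2 * 16))
        stub = _LinearEncoderStub(W, (2, 16))
        x = rng.normal(size=(2, 16))
        amap = gradient_attention_map(stub, x, [1, 3, 4])
        expected = np.abs(W[[1, 3, 4]]).mean(axis=0).reshape(2, 16)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(amap.heatmap, expected, atol=1e-12)

    def test_mri_map_restricted_to_scan_channel(self, rng):
        cfg = VaeConfig(modality="mri", input_shape=(2, 8, 8, 2), latent_dim=3,
                        hidden_dim=8, n_residual_blocks=1, seed=0)
        vae = ResidualVAE(cfg)
        amap = gradient_attention_map(vae, rng.normal(size=(2, 8, 8, 2)), [0, 1])
        assert amap.heatmap.shape == (2, 8, 8)

    def test_empty_indices_rejected(self, tiny_ecg_vae, beat_bank):
        with pytest.raises(ValueError):
            gradient_attention_map(tiny_ecg_vae, beat_bank[0], [])

    def test_invalid_map_values_rejected(self):
        with pytest.raises(ValueError):
            AttentionMap(heatmap=np.array([[0.2, -0.1]]), latent_indices=(0,))


class TestOverlay:
    def test_renders_deterministically(self, tmp_path, rng):
        heat = rng.random((8, 8))
        heat /= heat.max()
        amap = AttentionMap(heatmap=heat, latent_indices=(0,))
        orig = rng.random((8, 8))
        p1 = overlay(amap, orig, tmp_path / "a.png")
        p2 = overlay(amap, orig, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_map_renders(self, tmp_path, rng):
        amap = AttentionMap(heatmap=np.zeros((8, 8)), latent_indices=(0,))
        path = overlay(amap, rng.random((8, 8)), tmp_path / "z.png")
        assert path.exists() and path.stat().st_size > 0

    def test_hot_region_location(self, tmp_path):
        # single hot corner pixel must land in the matching image quadrant
        from PIL import Image

        heat = np.zeros((16, 16))
        heat[2, 13] = 1.0  # top-right
        amap = AttentionMap(heatmap=heat, latent_indices=(0,))
        path = overlay(amap, np.zeros((16, 16)), tmp_path / "h.png", alpha=1.0)
        img = np.asarray(Image.open(path).convert("RGB")).astype(float)
        redness = img[..., 0] - img[..., 2]
        r, c = np.unravel_index(np.argmax(redness), redness.shape)
        assert r < img.shape[0] / 2 and c > img.shape[1] / 2
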