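"""Residual β-VAE: ELBO identities, training behaviour, determinism, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deeprisk.vae import (
    ElboReport,
    ResidualVAE,
    ShapeError,
    VaeConfig,
    default_ecg_config,
    default_mri_config,
    elbo_loss,
    kl_divergence,
    reconstruction_metrics,
)


def tiny_config(**kw):
    kw.setdefault("modality", "ecg")
    kw.setdefault("input_shape", (2, 16))
    kw.setdefault("latent_dim", 4)
    kw.setdefault("hidden_dim", 16)
    kw.setdefault("n_residual_blocks", 1)
    kw.setdefault("seed", 0)
    return VaeConfig(**kw)


class TestShapes:
    def test_mri_latent_dimension_default_256(self):
        vae = ResidualVAE(default_mri_config(hidden_dim=16, n_residual_blocks=1))
        x = np.zeros((12, 64, 64, 2))
        assert vae.encode(x).mu.shape == (256,)

    def test_ecg_latent_dimension_default_32(self):
        vae = ResidualVAE(default_ecg_config(hidden_dim=16, n_residual_blocks=1))
        assert vae.encode(np.zeros((12, 150))).mu.shape == (32,)

    def test_encode_deterministic(self, rng):
        vae = ResidualVAE(tiny_config())
        x = rng.normal(size=(2, 16))
        a, b = vae.encode(x), vae.encode(x)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.logvar, b.logvar)

    def test_decode_roundtrip_shape(self, rng):
        vae = ResidualVAE(tiny_config())
        x = rng.normal(size=(2, 16))
        assert vae.decode(vae.encode(x).mu).shape == (2, 16)

    def test_shape_errors(self):
        vae = ResidualVAE(tiny_config())
        with pytest.raises(ShapeError):
            vae.encode(np.zeros((3, 16)))
        with pytest.raises(ShapeError):
            vae.decode(np.zeros(7))

    def test_sampled_z_uses_reparameterization(self, rng):
        vae = ResidualVAE(tiny_config())
        x = rng.normal(size=(2, 16))
        code = vae.encode(x, sample_seed=5)
        eps = np.random.default_rng(5).standard_normal((1, 4))[0]
        assert np.allclose(code.z, code.mu + np.exp(code.logvar / 2) * eps)


class TestElbo:
    def test_kl_standard_normal_is_zero(self):
        assert kl_divergence(np.zeros(4), np.zeros(4)) == 0.0

    def test_kl_unit_mean_is_half(self):
        mu = np.array([1.0, 0.0, 0.0])
        assert kl_divergence(mu, np.zeros(3)) == 0.5

    def test_beta_zero_total_is_recon(self, rng):
        x = rng.normal(size=(2, 16))
        xh = rng.normal(size=(2, 16))
        rep = elbo_loss(x, xh, rng.normal(size=4), rng.normal(size=4), beta=0.0)
        assert rep.total == rep.recon_loss

    def test_total_identity_exact(self, rng):
        rep = ElboReport(recon_loss=0.123, kl=4.56, beta=0.7)
        assert rep.total == 0.123 + 0.7 * 4.56

    def test_kl_closed_form_vs_monte_carlo(self):
        # KL(q||p) estimated by sampling z ~ q and averaging log q - log p
        rng = np.random.default_rng(0)
        mu = np.array([0.5, -1.0, 0.2])
        logvar = np.array([0.3, -0.5, 0.0])
        sd = np.exp(logvar / 2)
        z = mu + sd * rng.standard_normal((100_000, 3))
        log_q = -0.5 * (((z - mu) / sd) ** 2 + logvar + np.log(2 * np.pi)).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        assert kl_divergence(mu, logvar) == pytest.approx(mc, rel=0.01)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6),
           st.lists(st.floats(-4, 4), min_size=1, max_size=6))
    def test_kl_nonnegative(self, mu, logvar):
        n = min(len(mu), len(logvar))
        assert kl_divergence(np.array(mu[:n]), np.array(logvar[:n])) >= -1e-12


class TestTraining:
    def test_overfits_single_sample(self, rng):
        cfg = tiny_config(epochs=300, learning_rate=5e-3, beta=0.0, val_fraction=0.0)
        vae = ResidualVAE(cfg)
        x = rng.normal(size=(1, 2, 16))
        log = vae.fit(x)
        assert log[-1]["train_recon"] < 0.01 * log[0]["train_recon"]

    def test_learning_progress(self, beat_bank):
        cfg = default_ecg_config(hidden_dim=32, n_residual_blocks=1, epochs=40, seed=1)
        vae = ResidualVAE(cfg)
        log = vae.fit(beat_bank)
        assert log[-1]["val_recon"] < 0.5 * log[0]["val_recon"]

    def test_beta_monotonicity(self, beat_bank):
        # much larger beta pushes the posterior toward the prior (smaller KL)
        kls = {}
        for beta_mult in (1.0, 1000.0):
            cfg = default_ecg_config(
                hidden_dim=32, n_residual_blocks=1, epochs=15, seed=2, beta=1e-3 * beta_mult
            )
            vae = ResidualVAE(cfg)
            vae.fit(beat_bank)
            kls[beta_mult] = vae.evaluate(beat_bank).kl
        assert kls[1000.0] < kls[1.0]

    def test_training_determinism(self, beat_bank):
        losses = []
        for _ in range(2):
            vae = ResidualVAE(default_ecg_config(hidden_dim=16, n_residual_blocks=1, epochs=5, seed=7))
            log = vae.fit(beat_bank)
            losses.append(log[-1]["train_total"])
        assert losses[0] == losses[1]

    def test_nan_input_aborts_with_diagnostics(self, rng):
        vae = ResidualVAE(tiny_config(epochs=2))
        x = rng.normal(size=(8, 2, 16))
        x[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            vae.fit(x)

    def test_latent_extraction_order_invariant(self, beat_bank, tiny_ecg_vae):
        perm = np.random.default_rng(0).permutation(len(beat_bank))
        lat = tiny_ecg_vae.encode_dataset(beat_bank)
        lat_perm = tiny_ecg_vae.encode_dataset(beat_bank[perm])
        assert np.allclose(lat[perm], lat_perm, atol=1e-12)

    def test_decode_continuity(self, tiny_ecg_vae):
        z = np.zeros(32)
        base = tiny_ecg_vae.decode(z)
        for eps in (1e-2, 1e-4, 1e-6):
            delta = np.full(32, eps)
            diff = np.linalg.norm(tiny_ecg_vae.decode(z + delta) - base)
            assert diff < 100 * eps * np.sqrt(32)  # Lipschitz-bounded response


class TestElboDuringTraining:
    def test_identity_holds_each_epoch(self, beat_bank):
        cfg = default_ecg_config(hidden_dim=16, n_residual_blocks=1, epochs=4, seed=3)
        vae = ResidualVAE(cfg)
        log = vae.fit(beat_bank)
        for entry in log:
            assert entry["train_total"] == pytest.approx(
                entry["train_recon"] + cfg.beta * entry["train_kl"], abs=1e-12
            )


class TestReconstructionMetrics:
    def test_identity_reconstruction(self, rng):
        x = rng.normal(size=(12, 150))
        m = reconstruction_metrics(x, x.copy())
        assert m["pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert m["rmse"] == 0.0

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.normal(size=(12, 150))
        x -= x.mean(axis=1, keepdims=True)
        assert reconstruction_metrics(x, -x)["pearson_r"] == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.normal(size=(1, 60))
        y = rng.normal(size=(1, 60))
        expected = np.cov(x[0], y[0])[0, 1] / (x[0].std(ddof=1) * y[0].std(ddof=1))
        assert reconstruction_metrics(x, y)["pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged(self, rng):
        x = np.ones((2, 30))
        m = reconstruction_metrics(x, rng.normal(size=(2, 30)))
        assert m["undefined_correlation"]

    def test_ssim_identity_for_volumes(self, rng):
        x = rng.random((4, 16, 16))
        m = reconstruction_metrics(x, x.copy(), modality="mri")
        assert m["ssim"] == pytest.approx(1.0, abs=1e-9)


def test_checkpoint_roundtrip(tmp_path, tiny_ecg_vae, beat_bank):
    path = tmp_path / "vae.npz"
    tiny_ecg_vae.save(path)
    loaded = ResidualVAE.load(path)
    a = tiny_ecg_vae.encode_dataset(beat_bank[:4])
    b = loaded.encode_dataset(beat_bank[:4])
    assert np.array_equal(a, b)
    assert loaded.config == tiny_ecg_vae.config


def test_input_gradient_matches_finite_difference(rng):
    vae = ResidualVAE(tiny_config())
    x = rng.normal(size=(2, 16))
    g = vae.input_gradient(x, latent_index=1)
    h = 1e-6
    for idx in [(0, 3), (1, 10)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        num = (vae.encode(xp).mu[1] - vae.encode(xm).mu[1]) / (2 * h)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_input_gradient_through_pooling(rng):
    cfg = VaeConfig(modality="mri", input_shape=(2, 8, 8, 2), latent_dim=3,
                    hidden_dim=8, n_residual_blocks=1, pool=(1, 2, 2, 1), seed=0)
    vae = ResidualVAE(cfg)
    x = rng.normal(size=(2, 8, 8, 2))
    g = vae.input_gradient(x, 0)
    h = 1e-6
    xp, xm = x.copy(), x.copy()
    xp[1, 3, 4, 0] += h
    xm[1, 3, 4, 0] -= h
    num = (vae.encode(xp).mu[0] - vae.encode(xm).mu[0]) / (2 * h)
    assert g[1, 3, 4, 0] == pytest.approx(num, rel=1e-4, abs=1e-10)
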