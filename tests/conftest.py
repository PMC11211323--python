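import numpy as np
import pytest

from deeprisk.ecg import preprocess_ecg
from deeprisk.mri import AnalyticRingBackend, LgeVolume, preprocess_volume
from deeprisk.simulate import EcgSimParams, MriSimParams, generate_ecg, generate_lge_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_beats(n: int, seed: int = 0) -> np.ndarray:
    """Preprocessed mean-beat sets for n synthetic patients, shape (n, 12, 150)."""
    r = np.random.default_rng(seed)
    out = []
    for i in range(n):
        p = EcgSimParams(
            heart_rate_bpm=float(r.normal(70, 8)),
            qrs_width_ms=float(np.clip(r.normal(100, 18), 60, 160)),
            noise_sd_mv=0.02,
            wander_amp_mv=0.1,
            seed=int(r.integers(2**31)),
        )
        out.append(preprocess_ecg(generate_ecg(p)).beats)
    return np.stack(out)


def make_model_inputs(n: int, seed: int = 0, lesion_mean: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed (n, 12, 64, 64, 2) model inputs + realized lesion fractions."""
    r = np.random.default_rng(seed)
    vols, fracs = [], []
    for i in range(n):
        lf = float(0.5 * r.beta(2, 4)) if lesion_mean else 0.0
        p = MriSimParams(lesion_fraction=lf, seed=int(r.integers(2**31)))
        vol, mask, frac = generate_lge_volume(p)
        vols.append(preprocess_volume(LgeVolume(vol), AnalyticRingBackend(mask)).data)
        fracs.append(frac)
    return np.stack(vols), np.array(fracs)


@pytest.fixture(scope="session")
def beat_bank():
    """40 preprocessed synthetic mean-beat sets shared across tests."""
    return make_beats(40, seed=7)


@pytest.fixture(scope="session")
def tiny_ecg_vae(beat_bank):
    """A small trained ECG VAE shared by explainability/latent tests."""
    from deeprisk.vae import ResidualVAE, default_ecg_config

    vae = ResidualVAE(
        default_ecg_config(beat_length=150, hidden_dim=32, n_residual_blocks=1, epochs=10, seed=3)
    )
    vae.fit(beat_bank)
    return vae
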