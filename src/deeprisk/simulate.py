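"""Synthetic cohort generator: ECGs, LGE-like volumes, clinical tables, outcomes.

Emulates the data a multimodal arrhythmic-risk study collects before ICD
implantation, with known ground truth so every downstream stage is testable:

* 10-s 12-lead ECGs built from a per-lead 3-Gaussian P-QRS-T template, with
  additive Gaussian noise and sinusoidal baseline wander;
* short-axis LGE-like volumes containing an annular myocardium around a
  bright blood pool, with optional hyper-enhanced lesions inside the annulus;
* a clinical table mirroring the usual ICD-cohort roster (demographics,
  pathology class, history flags, labs, medication, device type) with
  missing-completely-at-random cells;
* a binary one-year ventricular-arrhythmia outcome drawn from a logistic
  model over standardized lesion burden, QRS width and a clinical score.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

# Relative amplitude of the P, QRS and T deflection per lead (mV); aVR is the
# classic inverted lead. These only need to look ECG-like and give every lead
# a detectable, lead-specific morphology.
_BASE_AMP = np.array(
    [
        [0.08, 0.9, 0.25],   # I
        [0.12, 1.2, 0.35],   # II
        [0.05, 0.6, 0.15],   # III
        [-0.09, -1.0, -0.28],  # aVR
        [0.03, 0.4, 0.10],   # aVL
        [0.08, 0.9, 0.25],   # aVF
        [0.05, -0.7, 0.12],  # V1
        [0.06, 0.8, 0.30],   # V2
        [0.07, 1.4, 0.40],   # V3
        [0.08, 1.6, 0.45],   # V4
        [0.08, 1.3, 0.38],   # V5
        [0.08, 1.0, 0.30],   # V6
    ]
)
# Offsets of the P and T wave centres relative to the R peak, and their widths.
_P_OFFSET_MS, _T_OFFSET_MS = -160.0, 250.0
_P_SIGMA_MS, _T_SIGMA_MS = 22.0, 55.0


class ParameterError(ValueError):
    """Invalid simulation parameter."""


@dataclass(frozen=True)
class EcgSimParams:
    heart_rate_bpm: float = 60.0
    duration_s: float = 10.0
    fs_hz: float = 500.0
    wave_amplitudes: np.ndarray = field(default_factory=lambda: _BASE_AMP.copy())
    qrs_width_ms: float = 100.0
    noise_sd_mv: float = 0.0
    wander_amp_mv: float = 0.0
    wander_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.heart_rate_bpm <= 0 or self.duration_s <= 0 or self.fs_hz <= 0:
            raise ParameterError("rate, duration and sampling frequency must be positive")
        if self.qrs_width_ms <= 0:
            raise ParameterError("qrs_width_ms must be positive")
        if self.noise_sd_mv < 0 or self.wander_amp_mv < 0:
            raise ParameterError("noise/wander amplitudes must be nonnegative")
        if not (0 < self.wander_freq_hz < 0.5):
            raise ParameterError("wander_freq_hz must lie in (0, 0.5)")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("duration_s * fs_hz must be an integer sample count")


def true_r_peak_times(p: EcgSimParams) -> np.ndarray:
    """Ground-truth R-peak times (s) used by :func:`generate_ecg`."""
    interval = 60.0 / p.heart_rate_bpm
    first = 0.5 * interval
    times = np.arange(first, p.duration_s, interval)
    return times


def true_r_peak_samples(p: EcgSimParams, fs_hz: Optional[float] = None) -> np.ndarray:
    fs = p.fs_hz if fs_hz is None else fs_hz
    return np.round(true_r_peak_times(p) * fs).astype(int)


def beat_template(p: EcgSimParams, fs_hz: Optional[float] = None, window_s=(0.2, 0.4)) -> np.ndarray:
    """Noise-free single-beat template per lead, sampled around the R peak.

    Returns a (12, L) array covering ``window_s[0]`` before to ``window_s[1]``
    after the R peak — the waveform the ECG preprocessing chain should recover.
    """
    fs = p.fs_hz if fs_hz is None else fs_hz
    t = np.arange(-int(round(window_s[0] * fs)), int(round(window_s[1] * fs))) / fs
    return _beat_waveform(t[None, :], p)


def _beat_waveform(dt_s: np.ndarray, p: EcgSimParams) -> np.ndarray:
    """Sum of 3 Gaussians (P, QRS, T) per lead evaluated at offsets dt_s (s)."""
    qrs_sigma = p.qrs_width_ms / 1000.0 / 4.0  # width ~ +/- 2 sigma
    centers = np.array([_P_OFFSET_MS / 1000.0, 0.0, _T_OFFSET_MS / 1000.0])
    sigmas = np.array([_P_SIGMA_MS / 1000.0, qrs_sigma, _T_SIGMA_MS / 1000.0])
    amp = np.asarray(p.wave_amplitudes, dtype=float)
    if amp.shape != (12, 3):
        raise ParameterError("wave_amplitudes must have shape (12, 3)")
    # dt_s is (B, T): per-beat sample offsets. basis: (3, B, T); result (12, T)
    basis = np.exp(-0.5 * ((dt_s[None, ...] - centers[:, None, None]) / sigmas[:, None, None]) ** 2)
    return np.einsum("lk,kbt->lt", amp, basis)


def generate_ecg(p: EcgSimParams):
    """Simulate a 12-lead ECG record.

    Beats are placed at exactly ``60 / heart_rate_bpm`` intervals; each beat is
    the 3-Gaussian P-QRS-T template, plus seeded Gaussian noise and a
    sinusoidal baseline wander common to all leads (scaled per lead).
    """
    from .ecg import EcgRecord  # local import to avoid a cycle

    n = int(round(p.duration_s * p.fs_hz))
    t = np.arange(n) / p.fs_hz
    r_times = true_r_peak_times(p)
    # offsets to the nearest beat centre: (n_beats, n) -> per-sample min offset
    dt = t[None, :] - r_times[:, None]  # (B, T)
    clean = _beat_waveform(dt, p)  # (12, T) summed over beats
    rng = np.random.default_rng(p.seed)
    signal = clean.copy()
    if p.wander_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = p.wander_amp_mv * np.sin(2 * np.pi * p.wander_freq_hz * t + phase)
        signal = signal + wander[None, :]
    if p.noise_sd_mv > 0:
        signal = signal + rng.normal(0.0, p.noise_sd_mv, size=signal.shape)
    return EcgRecord(signals=signal, fs_hz=p.fs_hz, lead_names=LEAD_NAMES)


# ---------------------------------------------------------------------------
# LGE-like volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MriSimParams:
    n_slices: int = 12
    height: int = 96
    width: int = 96
    spacing_mm: tuple[float, float, float] = (10.0, 1.8, 1.8)  # (depth, row, col)
    ring_inner_px: float = 12.0   # at the base; tapers toward the apex
    ring_outer_px: float = 22.0
    apex_taper: float = 0.45      # apex radii = taper * base radii
    lesion_count: int = 4
    lesion_fraction: float = 0.0  # target fraction of myocardium enhanced
    intensity_background: float = 0.05
    intensity_blood: float = 0.65
    intensity_myocardium: float = 0.30
    intensity_lesion: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.ring_inner_px >= self.ring_outer_px:
            raise ParameterError("inner radius must be below outer radius")
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ParameterError("lesion_fraction must lie in [0, 1]")
        if self.n_slices < 1 or self.height < 8 or self.width < 8:
            raise ParameterError("degenerate volume geometry")


def ring_radii(p: MriSimParams) -> np.ndarray:
    """Per-slice (inner, outer) radii in pixels; slice 0 is the apex."""
    scale = np.linspace(p.apex_taper, 1.0, p.n_slices)
    return np.stack([p.ring_inner_px * scale, p.ring_outer_px * scale], axis=1)


def generate_lge_volume(p: MriSimParams) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate one short-axis LGE-like volume.

    Returns ``(volume, true_mask, realized_lesion_fraction)`` with volume shape
    (n_slices, height, width), mask in {0,1} (1 = myocardium), slice 0 = apex.
    Lesion blobs are drawn strictly inside the annulus until the enhanced
    fraction of myocardium reaches ``lesion_fraction``.
    """
    rng = np.random.default_rng(p.seed)
    rr, cc = np.mgrid[0 : p.height, 0 : p.width]
    cy, cx = (p.height - 1) / 2.0, (p.width - 1) / 2.0
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    radii = ring_radii(p)
    mask = np.zeros((p.n_slices, p.height, p.width), dtype=np.uint8)
    blood = np.zeros_like(mask)
    for s in range(p.n_slices):
        inner, outer = radii[s]
        mask[s] = ((dist >= inner) & (dist < outer)).astype(np.uint8)
        blood[s] = (dist < inner).astype(np.uint8)

    lesion = np.zeros_like(mask, dtype=bool)
    myo_total = int(mask.sum())
    if p.lesion_fraction > 0 and myo_total > 0:
        coords = np.argwhere(mask > 0)
        target = p.lesion_fraction * myo_total
        # grow spherical-ish blobs seeded at random myocardium voxels; small
        # radii keep the overshoot well inside the +/-0.05 tolerance
        for _ in range(10_000):
            if lesion.sum() >= target:
                break
            s0, r0, c0 = coords[rng.integers(len(coords))]
            rad = rng.uniform(1.5, 3.5)
            s_lo, s_hi = max(0, s0 - 1), min(p.n_slices, s0 + 2)
            blob = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) <= rad
            for s in range(s_lo, s_hi):
                lesion[s] |= blob & (mask[s] > 0)
    realized = float(lesion.sum() / myo_total) if myo_total else 0.0

    vol = np.full((p.n_slices, p.height, p.width), p.intensity_background, dtype=float)
    vol[blood > 0] = p.intensity_blood
    vol[mask > 0] = p.intensity_myocardium
    vol[lesion] = p.intensity_lesion
    if p.noise_sd > 0:
        vol = vol + rng.normal(0.0, p.noise_sd, size=vol.shape)
    return vol, mask, realized


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CATEGORICAL_COLUMNS = ("sex", "pathology", "device")
CONTINUOUS_COLUMNS = ("age", "bmi", "sodium", "potassium", "creatinine")
FLAG_COLUMNS = (
    "atrial_arrhythmia", "cva", "copd", "hypertension", "diabetes", "prior_nsvt",
    "beta_blocker", "acei_arb", "vka", "sotalol", "digoxin", "amiodarone", "noac",
)
# Column forced above 30% missing when missing_rate > 0.3, to exercise the
# variable-exclusion rule downstream.
HIGH_MISSING_COLUMN = "potassium"

_PATHOLOGY_LEVELS = ("dilated", "genetic", "hypertrophic", "miscellaneous")
_PATHOLOGY_P = (0.63, 0.05, 0.16, 0.16)
_DEVICE_LEVELS = ("single_chamber", "dual_chamber", "crt_d", "subcutaneous")
_DEVICE_P = (0.29, 0.25, 0.34, 0.12)
_FLAG_P = {
    "atrial_arrhythmia": 0.28, "cva": 0.09, "copd": 0.09, "hypertension": 0.43,
    "diabetes": 0.17, "prior_nsvt": 0.28, "beta_blocker": 0.73, "acei_arb": 0.95,
    "vka": 0.23, "sotalol": 0.035, "digoxin": 0.08, "amiodarone": 0.07, "noac": 0.08,
}


def generate_clinical(n: int, missing_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Clinical table with MCAR missingness at ``missing_rate``.

    When ``missing_rate > 0.3`` the designated high-missing column is pushed
    above 30% missing so the exclusion rule has something to exclude.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0.0 <= missing_rate <= 0.6):
        raise ParameterError("missing_rate must lie in [0, 0.6]")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.normal(60.0, 14.0, n).clip(18, 95),
            "sex": rng.choice(["female", "male"], n, p=[0.32, 0.68]),
            "bmi": rng.normal(26.3, 4.7, n).clip(15, 50),
            "pathology": rng.choice(_PATHOLOGY_LEVELS, n, p=_PATHOLOGY_P),
            "sodium": rng.normal(139.8, 3.0, n),
            "potassium": rng.normal(4.35, 0.45, n),
            "creatinine": np.exp(rng.normal(np.log(95.0), 0.40, n)),
            "device": rng.choice(_DEVICE_LEVELS, n, p=_DEVICE_P),
        }
    )
    for col in FLAG_COLUMNS:
        df[col] = rng.binomial(1, _FLAG_P[col], n)
    df = df[list(CONTINUOUS_COLUMNS[:2]) + ["sex", "pathology"]
            + list(CONTINUOUS_COLUMNS[2:]) + list(FLAG_COLUMNS) + ["device"]]
    if missing_rate > 0:
        for col in df.columns:
            holes = rng.random(n) < missing_rate
            df.loc[holes, col] = np.nan
        if missing_rate > 0.3:
            extra = rng.random(n) < min(missing_rate + 0.15, 0.8)
            df.loc[extra, HIGH_MISSING_COLUMN] = np.nan
    return df


def clinical_risk_score(df: pd.DataFrame) -> np.ndarray:
    """Fixed linear clinical risk score: z(age) + z(log creatinine) + prior NSVT.

    Computed from the generator's population constants so the score is exact
    regardless of sample composition; gives the clinical branch recoverable
    signal.
    """
    age_z = (df["age"].to_numpy(float) - 60.0) / 14.0
    cre_z = (np.log(df["creatinine"].to_numpy(float)) - np.log(95.0)) / 0.40
    nsvt = df["prior_nsvt"].to_numpy(float)
    return age_z + cre_z + (nsvt - _FLAG_P["prior_nsvt"]) / np.sqrt(_FLAG_P["prior_nsvt"] * (1 - _FLAG_P["prior_nsvt"]))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

# Population constants for standardising the ground-truth risk factors.
# lesion_fraction ~ 0.5 * Beta(2, 4): mean 1/6, var 0.25 * 8/(36*7)
_LF_MEAN = 1.0 / 6.0
_LF_SD = float(np.sqrt(0.25 * 8.0 / (36.0 * 7.0)))
_QRS_MEAN, _QRS_SD = 100.0, 18.0
_CLIN_SD = np.sqrt(3.0)  # sum of three ~unit-variance components


@dataclass(frozen=True)
class CohortSimParams:
    n_patients: int = 200
    effect_intercept: float = float(np.log(0.09 / 0.91))  # ~9% baseline prevalence
    effect_lesion: float = 0.0
    effect_qrs: float = 0.0
    effect_clinical: float = 0.0
    missing_rate: float = 0.1
    ecg_fs_hz: float = 500.0
    ecg_noise_sd_mv: float = 0.02
    ecg_wander_amp_mv: float = 0.10
    mri: MriSimParams = field(default_factory=MriSimParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not (0.0 <= self.missing_rate <= 0.6):
            raise ParameterError("missing_rate must lie in [0, 0.6]")


@dataclass
class CohortDataset:
    """One synthetic study cohort with per-patient ground truth."""

    params: CohortSimParams
    patient_ids: list[str]
    ecgs: list  # list[EcgRecord]
    ecg_params: list[EcgSimParams]
    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    clinical: pd.DataFrame
    outcome: np.ndarray
    lesion_fraction: np.ndarray   # realized, per patient
    qrs_width_ms: np.ndarray
    clinical_score: np.ndarray
    linear_predictor: np.ndarray  # ground-truth logit of the event probability
    event_prob: np.ndarray

    def __len__(self) -> int:
        return len(self.patient_ids)


def generate_cohort(p: CohortSimParams, with_signals: bool = True) -> CohortDataset:
    """Simulate a full cohort.

    The binary outcome is Bernoulli(sigmoid(a + b1*z_lesion + b2*z_qrs +
    b3*z_clinical)) with all z-scores standardized by the generator's
    population constants; the true linear predictor is stored for oracle
    evaluation. ``with_signals=False`` skips the (slower) ECG/volume synthesis
    and keeps only the tabular truth.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    clinical = generate_clinical(n, missing_rate=0.0, seed=int(rng.integers(2**31)))
    clin_score = clinical_risk_score(clinical)

    lf_target = 0.5 * rng.beta(2.0, 4.0, n)
    qrs = rng.normal(_QRS_MEAN, _QRS_SD, n).clip(60, 160)
    heart_rate = rng.normal(70.0, 8.0, n).clip(45, 110)

    ecg_params: list[EcgSimParams] = []
    ecgs, volumes, masks = [], [], []
    lf_realized = np.empty(n)
    for i in range(n):
        amp = _BASE_AMP * rng.normal(1.0, 0.05, size=(12, 1))
        ep = EcgSimParams(
            heart_rate_bpm=float(heart_rate[i]),
            fs_hz=p.ecg_fs_hz,
            wave_amplitudes=amp,
            qrs_width_ms=float(qrs[i]),
            noise_sd_mv=p.ecg_noise_sd_mv,
            wander_amp_mv=p.ecg_wander_amp_mv,
            seed=int(rng.integers(2**31)),
        )
        ecg_params.append(ep)
        mp = replace(p.mri, lesion_fraction=float(lf_target[i]), seed=int(rng.integers(2**31)))
        if with_signals:
            ecgs.append(generate_ecg(ep))
            vol, mask, frac = generate_lge_volume(mp)
            volumes.append(vol)
            masks.append(mask)
            lf_realized[i] = frac
        else:
            _, _, frac = generate_lge_volume(replace(mp, noise_sd=0.0))
            lf_realized[i] = frac

    z_lf = (lf_realized - _LF_MEAN) / _LF_SD
    z_qrs = (qrs - _QRS_MEAN) / _QRS_SD
    z_clin = clin_score / _CLIN_SD
    lp = (
        p.effect_intercept
        + p.effect_lesion * z_lf
        + p.effect_qrs * z_qrs
        + p.effect_clinical * z_clin
    )
    prob = 1.0 / (1.0 + np.exp(-lp))
    outcome = (rng.random(n) < prob).astype(int)

    if p.missing_rate > 0:
        holes_rng = np.random.default_rng(int(rng.integers(2**31)))
        for col in clinical.columns:
            holes = holes_rng.random(n) < p.missing_rate
            clinical.loc[holes, col] = np.nan
        if p.missing_rate > 0.3:
            extra = holes_rng.random(n) < min(p.missing_rate + 0.15, 0.8)
            clinical.loc[extra, HIGH_MISSING_COLUMN] = np.nan

    ids = [f"P{i:04d}" for i in range(n)]
    return CohortDataset(
        params=p,
        patient_ids=ids,
        ecgs=ecgs,
        ecg_params=ecg_params,
        volumes=volumes,
        masks=masks,
        clinical=clinical,
        outcome=outcome,
        lesion_fraction=lf_realized,
        qrs_width_ms=qrs,
        clinical_score=clin_score,
        linear_predictor=lp,
        event_prob=prob,
    )


def write_cohort(dataset: CohortDataset, out_dir) -> pd.DataFrame:
    """Write a cohort to disk: per-patient ECG CSVs, NIfTI volumes/masks,
    clinical + outcome CSVs and a manifest linking patient id to file paths."""
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    (out / "ecg").mkdir(parents=True, exist_ok=True)
    (out / "mri").mkdir(parents=True, exist_ok=True)
    rows = []
    spacing = dataset.params.mri.spacing_mm
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    for i, pid in enumerate(dataset.patient_ids):
        ecg_path = out / "ecg" / f"{pid}.csv"
        rec = dataset.ecgs[i]
        pd.DataFrame(rec.signals.T, columns=list(rec.lead_names)).to_csv(ecg_path, index=False)
        vol_path = out / "mri" / f"{pid}_vol.nii.gz"
        mask_path = out / "mri" / f"{pid}_mask.nii.gz"
        nib.save(nib.Nifti1Image(dataset.volumes[i].astype(np.float32), affine), vol_path)
        nib.save(nib.Nifti1Image(dataset.masks[i].astype(np.uint8), affine), mask_path)
        rows.append({"patient_id": pid, "ecg": str(ecg_path), "volume": str(vol_path),
                     "mask": str(mask_path), "ecg_fs_hz": rec.fs_hz})
    clinical = dataset.clinical.copy()
    clinical.insert(0, "patient_id", dataset.patient_ids)
    clinical.to_csv(out / "clinical.csv", index=False)
    pd.DataFrame({"patient_id": dataset.patient_ids, "outcome": dataset.outcome}).to_csv(
        out / "outcomes.csv", index=False
    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
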