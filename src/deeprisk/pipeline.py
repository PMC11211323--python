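"""End-to-end orchestration: simulate -> preprocess -> VAEs -> risk -> explain.

A single hierarchical, schema-validated configuration drives the whole run;
per-stage seeds are derived from one master seed through
``numpy.random.SeedSequence.spawn`` (stage order fixed below). Heavy stages
cache their outputs in the run directory and are skipped on resume when the
configuration hash still matches. Every run emits one JSON manifest with the
config snapshot, stage seeds, output digests, package version and timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .ecg import preprocess_ecg
from .explain import (
    gradient_attention_map,
    latent_traversal,
    overlay,
    shapley_matrix,
    top_latents,
)
from .metrics import delong_test, evaluate_predictions
from .mri import AnalyticRingBackend, LgeVolume, preprocess_volume
from .risk import (
    BRANCHES,
    FeatureEncoder,
    SearchSpace,
    branch_columns,
    impute_missing,
    latent_frame,
    predict_risk,
    train_classifier,
    tune_hyperparameters,
)
from .simulate import CohortSimParams, generate_cohort
from .vae import ResidualVAE, default_ecg_config, default_mri_config

_STAGES = ("cohort", "ecg_prep", "mri_prep", "vae_ecg", "vae_mri", "risk", "evaluate", "explain")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_development: int = 120
    n_external: int = 60
    effect_intercept: float = float(np.log(0.09 / 0.91))
    effect_lesion: float = 0.0
    effect_qrs: float = 0.0
    effect_clinical: float = 0.0
    missing_rate: float = 0.1


class EcgPrepSection(_Strict):
    sg_window: int = 31
    sg_polyorder: int = 5
    baseline_cutoff_hz: float = 0.5
    normalization: str = "zscore"


class VaeSection(_Strict):
    latent_dim: int = 0  # 0 -> modality default
    hidden_dim: int = 64
    n_residual_blocks: int = 1
    beta: float = -1.0  # < 0 -> modality default
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3


class RiskSection(_Strict):
    n_trials: int = 0  # 0 -> skip tuning, use the default configuration
    k_folds: int = 5
    smote_k: int = 5
    default_max_depth: int = 3
    default_learning_rate: float = 0.1
    default_n_estimators: int = 200


class EvalSection(_Strict):
    n_bootstrap: int = 500


class PipelineConfig(_Strict):
    """Schema-validated run configuration; unknown keys are rejected."""

    seed: int = 0
    cohort: CohortSection = Field(default_factory=CohortSection)
    ecg: EcgPrepSection = Field(default_factory=EcgPrepSection)
    vae_ecg: VaeSection = Field(default_factory=VaeSection)
    vae_mri: VaeSection = Field(default_factory=lambda: VaeSection(hidden_dim=128))
    risk: RiskSection = Field(default_factory=RiskSection)
    evaluation: EvalSection = Field(default_factory=EvalSection)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage seeds spawned from the master seed (fixed stage order)."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(_STAGES, children)}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


class PipelineRun:
    """Executes the workflow stage by stage with file-level caching."""

    def __init__(self, config: PipelineConfig, out_dir, resume: bool = True):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.seeds = stage_seeds(config.seed)
        self.cfg_hash = _config_hash(config)
        self.timings: dict[str, float] = {}

    def _cache_ok(self, name: str) -> bool:
        marker = self.out / f"{name}.done.json"
        if not (self.resume and marker.exists()):
            return False
        return json.loads(marker.read_text()).get("config_hash") == self.cfg_hash

    def _mark(self, name: str) -> None:
        (self.out / f"{name}.done.json").write_text(
            json.dumps({"config_hash": self.cfg_hash, "stage": name})
        )

    def run(self) -> dict:
        t0 = time.time()
        cc = self.cfg.cohort
        n_total = cc.n_development + cc.n_external

        # -- cohort ---------------------------------------------------------
        params = CohortSimParams(
            n_patients=n_total,
            effect_intercept=cc.effect_intercept,
            effect_lesion=cc.effect_lesion,
            effect_qrs=cc.effect_qrs,
            effect_clinical=cc.effect_clinical,
            missing_rate=cc.missing_rate,
            seed=self.seeds["cohort"],
        )
        cohort = generate_cohort(params)
        dev = np.arange(cc.n_development)
        ext = np.arange(cc.n_development, n_total)
        y = cohort.outcome

        # -- ECG prep + VAE -------------------------------------------------
        ecg_path = self.out / "ecg_beats.npz"
        if self._cache_ok("ecg_prep"):
            beats = np.load(ecg_path)["beats"]
        else:
            ec = self.cfg.ecg
            beats = np.stack(
                [
                    preprocess_ecg(
                        rec, ec.sg_window, ec.sg_polyorder, ec.baseline_cutoff_hz, ec.normalization
                    ).beats
                    for rec in cohort.ecgs
                ]
            )
            np.savez_compressed(ecg_path, beats=beats)
            self._mark("ecg_prep")

        mri_path = self.out / "mri_inputs.npz"
        if self._cache_ok("mri_prep"):
            volumes = np.load(mri_path)["volumes"]
        else:
            volumes = np.stack(
                [
                    preprocess_volume(
                        LgeVolume(cohort.volumes[i], cohort.params.mri.spacing_mm),
                        AnalyticRingBackend(cohort.masks[i]),
                    ).data
                    for i in range(n_total)
                ]
            )
            np.savez_compressed(mri_path, volumes=volumes)
            self._mark("mri_prep")

        vaes: dict[str, ResidualVAE] = {}
        for modality, data, section in (
            ("ecg", beats, self.cfg.vae_ecg),
            ("mri", volumes, self.cfg.vae_mri),
        ):
            ckpt = self.out / f"vae_{modality}.npz"
            if self._cache_ok(f"vae_{modality}"):
                vaes[modality] = ResidualVAE.load(ckpt)
            else:
                maker = default_ecg_config if modality == "ecg" else default_mri_config
                kw = dict(
                    latent_dim=section.latent_dim,
                    hidden_dim=section.hidden_dim,
                    n_residual_blocks=section.n_residual_blocks,
                    beta=section.beta,
                    epochs=section.epochs,
                    batch_size=section.batch_size,
                    learning_rate=section.learning_rate,
                    seed=self.seeds[f"vae_{modality}"],
                )
                cfg = maker(beat_length=data.shape[-1], **kw) if modality == "ecg" else maker(**kw)
                vae = ResidualVAE(cfg)
                vae.fit(data[dev])
                vae.save(ckpt)
                self._mark(f"vae_{modality}")
                vaes[modality] = vae
        ecg_lat = latent_frame(vaes["ecg"].encode_dataset(beats), "ecg")
        mri_lat = latent_frame(vaes["mri"].encode_dataset(volumes), "mri")

        # -- clinical preparation (development-fitted) ------------------------
        clin_imputed = impute_missing(cohort.clinical, seed=self.seeds["risk"])
        encoder = FeatureEncoder().fit(clin_imputed.iloc[dev])
        clin_enc = encoder.transform(clin_imputed)

        # -- branches ---------------------------------------------------------
        rc = self.cfg.risk
        default_cfg = {
            "max_depth": rc.default_max_depth,
            "learning_rate": rc.default_learning_rate,
            "n_estimators": rc.default_n_estimators,
        }
        predictions: dict[str, np.ndarray] = {}
        models = {}
        reports = {}
        for branch in BRANCHES:
            X = branch_columns(mri_lat, ecg_lat, clin_enc, branch)
            X_dev, X_ext = X.iloc[dev], X.iloc[ext]
            if rc.n_trials > 0:
                best_cfg, _ = tune_hyperparameters(
                    X_dev.to_numpy(float), y[dev], SearchSpace(),
                    k_folds=rc.k_folds, n_trials=rc.n_trials, seed=self.seeds["risk"],
                )
            else:
                best_cfg = dict(default_cfg)
            rm = train_classifier(
                X_dev, y[dev], best_cfg, seed=self.seeds["risk"], branch=branch, smote_k=rc.smote_k
            )
            preds = predict_risk(rm, X_ext, [cohort.patient_ids[i] for i in ext])
            scores = np.array([p.probability for p in preds])
            predictions[branch] = scores
            models[branch] = rm
            reports[branch] = evaluate_predictions(
                scores, y[ext], n_bootstrap=self.cfg.evaluation.n_bootstrap,
                seed=self.seeds["evaluate"],
            )
            pd.DataFrame(
                {"patient_id": [p.patient_id for p in preds], "score": scores,
                 "label": y[ext], "branch": branch}
            ).to_csv(self.out / f"predictions_{branch}.csv", index=False)

        metrics = {b: r.to_dict() for b, r in reports.items()}
        if y[ext].min() != y[ext].max():
            dl = delong_test(predictions["multimodal"], predictions["mri"], y[ext])
            metrics["delong_multimodal_vs_mri"] = {
                "delta_auc": dl.delta, "z": dl.z, "p": dl.p, "degenerate": dl.degenerate,
            }
        (self.out / "metrics.json").write_text(json.dumps(metrics, indent=2))

        # -- explainability ---------------------------------------------------
        X_mm = branch_columns(mri_lat, ecg_lat, clin_enc, "multimodal")
        shap_frame, _base = shapley_matrix(models["multimodal"], X_mm.iloc[ext])
        shap_frame.to_csv(self.out / "shap_values.csv", index=False)
        top_mri = top_latents(shap_frame, m=10, latent_prefix="mri_")
        top_ecg = top_latents(shap_frame, m=10, latent_prefix="ecg_")
        patient = int(ext[0])
        amap = gradient_attention_map(vaes["mri"], volumes[patient], top_mri)
        overlay(amap, volumes[patient][..., 0], self.out / "attention_mri.png")
        trav = latent_traversal(vaes["mri"], mri_lat.to_numpy(), int(top_mri[0]))
        np.savez_compressed(
            self.out / "traversal_mri.npz",
            reconstructions=trav.reconstructions, offsets=trav.offsets_sd,
        )
        explain_summary = {
            "top_mri_latents": [int(i) for i in top_mri],
            "top_ecg_latents": [int(i) for i in top_ecg],
            "attention_patient": cohort.patient_ids[patient],
        }
        (self.out / "explain.json").write_text(json.dumps(explain_summary, indent=2))

        manifest = {
            "package_version": __version__,
            "config": json.loads(self.cfg.model_dump_json()),
            "config_hash": self.cfg_hash,
            "stage_seeds": self.seeds,
            "outputs": {
                p.name: _digest(p)
                for p in sorted(self.out.glob("*"))
                if p.is_file() and p.suffix in {".json", ".csv", ".npz"} and p.name != "manifest.json"
            },
            "elapsed_s": time.time() - t0,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"metrics": metrics, "manifest": manifest, "out_dir": str(self.out),
                "models": models, "vaes": vaes, "predictions": predictions,
                "labels_external": y[ext]}


def run_pipeline(config: PipelineConfig | dict, out_dir, resume: bool = True) -> dict:
    """Validate the configuration and execute the full workflow."""
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    return PipelineRun(config, out_dir, resume=resume).run()


def load_config(path) -> PipelineConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)
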