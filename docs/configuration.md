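# Pipeline configuration schema

`deeprisk run --config full.yaml` (or `run_pipeline(config, out_dir)` from
Python) takes one hierarchical configuration. Unknown keys anywhere in the
tree are rejected before any computation. All values below show the
defaults; every section may be omitted.

```yaml
seed: 0                      # master seed; per-stage seeds are spawned from
                             # it via numpy SeedSequence in a fixed order

cohort:
  n_development: 120         # patients used to fit VAEs, encoders, classifier
  n_external: 60             # held-out patients for evaluation
  effect_intercept: -2.3136  # logit of the baseline event rate (~9%)
  effect_lesion: 0.0         # log-odds per SD of lesion burden
  effect_qrs: 0.0            # log-odds per SD of QRS width
  effect_clinical: 0.0       # log-odds per SD of the clinical risk score
  missing_rate: 0.1          # MCAR cell-missingness in the clinical table

ecg:
  sg_window: 31              # Savitzky-Golay window (samples at 250 Hz)
  sg_polyorder: 5
  baseline_cutoff_hz: 0.5    # Fourier baseline terms strictly below this
  normalization: zscore      # or "minmax"

vae_ecg:                     # 32 latents (modality default)
  latent_dim: 0              # 0 = modality default (ECG 32, MRI 256)
  hidden_dim: 64
  n_residual_blocks: 1
  beta: -1.0                 # < 0 = modality default (ECG 1e-3, MRI 1e-5)
  epochs: 20
  batch_size: 32
  learning_rate: 0.001

vae_mri:                     # 256 latents; same keys as vae_ecg
  hidden_dim: 128

risk:
  n_trials: 0                # >0 enables GP-guided hyperparameter search
  k_folds: 5                 # stratified CV folds inside the search
  smote_k: 5                 # minority nearest neighbours for SMOTE
  default_max_depth: 3       # used when n_trials == 0
  default_learning_rate: 0.1
  default_n_estimators: 200

evaluation:
  n_bootstrap: 500           # percentile-bootstrap iterations for the CIs
```

Outputs in the run directory: `metrics.json` (per-branch point estimates +
CIs + the multimodal-vs-MRI DeLong comparison), `predictions_<branch>.csv`,
`ecg_beats.npz` / `mri_inputs.npz` (cached preprocessing), `vae_ecg.npz` /
`vae_mri.npz` (checkpoints with embedded config), `shap_values.csv`,
`attention_mri.png`, `traversal_mri.npz`, `explain.json`, and
`manifest.json` (config snapshot, stage seeds, output digests, package
version). Re-running with the same configuration reuses the cached stages;
`resume=False` (CLI `--no-resume`) forces a fresh run.
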