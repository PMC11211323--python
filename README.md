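# deeprisk

Multimodal prediction of one-year malignant ventricular arrhythmia in
non-ischaemic systolic heart failure, at desk scale.

Deciding who benefits from a prophylactic implantable
cardioverter-defibrillator (ICD) is hard: ejection fraction alone is a poor
predictor, while myocardial fibrosis seen on late gadolinium enhancement
(LGE) MRI and electrophysiological signatures in the 12-lead ECG carry
complementary risk information. `deeprisk` implements the full pipeline a
risk-stratification study of this kind needs — and, because no patient data
ship with it, a synthetic cohort generator with *known* effect sizes so that
every stage is testable end to end:

1. **Simulation** — 12-lead ECGs with P-QRS-T morphology, noise and baseline
   wander; 12-slice short-axis LGE-like volumes with an annular myocardium
   and hyper-enhanced lesions; clinical tables with controllable
   missingness; outcomes drawn from
   `P(event) = σ(α + β₁·z_lesion + β₂·z_QRS + β₃·z_clinical)`.
2. **ECG preprocessing** — 250 Hz, Savitzky-Golay smoothing, truncated-Fourier
   baseline removal, R-peak marking, aligned mean-beat averaging, z-scoring.
3. **MRI preprocessing** — pluggable myocardium segmentation, ROI crop,
   standardization to a 12×64×64×2 masked input (scan + mask channels).
4. **Residual β-VAE** feature extraction (NumPy, hand-backpropagated) —
   ECG → 32 latents, MRI → 256 latents, trained on the ELBO
   `recon + β·KL` with per-modality β.
5. **Risk model** — missForest-style imputation, one-hot + z-score encoding
   frozen on the development cohort, SMOTE balancing inside training data
   only, GP-guided Bayesian hyperparameter search, XGBoost; a `multimodal`
   branch plus single-modality `mri` / `ecg` / `clinical` branches.
6. **Explainability** — TreeSHAP attributions (local accuracy
   `Σφ + base = logit p̂`), latent traversals over ±3 SD, gradient-based
   attention maps averaged over the top-10 SHAP latents.
7. **Evaluation** — pair-counting AUROC, average precision, Youden
   cut-point, sensitivity/specificity/PPV/NPV/accuracy/F1, 95% percentile
   bootstrap CIs, DeLong's test for correlated AUROCs, calibration slope.

See `docs/methods.md` for the model details and design decisions, and
`examples/` for one short narrative script per capability.

## Worked example

`python examples/05_risk_model.py` simulates 300 patients with an
imaging-borne risk effect (lesion odds ratio e³ per SD, weaker ECG/clinical
effects), trains both VAEs on the 200 development patients, fits the four
branches, and scores the 100 external patients:

```
held-out AUROC per branch (100 external patients):
  mri          0.658
  multimodal   0.642
  ecg          0.609
  clinical     0.434
0.5 is chance; the imaging-informed branches should rank above the
ECG and clinical branches because the planted signal is imaging-borne.
```

The imaging-informed branches lead the board — the qualitative fingerprint
of an imaging-dominated risk substrate, recovered entirely through
unsupervised latent compression (the classifier never sees lesion fraction
directly). At the larger experiment scale used by `scripts/acceptance.py`
(400 development / 200 external patients) the same design reaches
multimodal AUROC ≈ 0.75 with the MRI branch out-ranking the ECG and
clinical branches in 10 of 10 replicates.

A full orchestrated run (`python examples/08_full_pipeline.py`, or
`deeprisk run --out run_dir`) adds bootstrap CIs, a DeLong comparison of the
multimodal and MRI branches, SHAP values, an attention-map PNG and a
reproducibility manifest.

## Command line

```
deeprisk simulate --n 100 --seed 0 --out cohort/     # synthetic study data
deeprisk prep-ecg --in cohort/ecg/P0000.csv --out prep/
deeprisk prep-mri --in vol.nii.gz --mask-backend file --mask-file map.nii.gz --out prep/
deeprisk train-vae --modality ecg --data beats.npz --out vae_ecg.npz
deeprisk encode --weights vae_ecg.npz --data beats.npz --out latents.csv
deeprisk evaluate --preds preds.csv --n-boot 3000 --seed 7 --out eval/
deeprisk compare --preds-a a.csv --preds-b b.csv     # DeLong test
deeprisk run --config full.yaml --out run_dir        # everything
```

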