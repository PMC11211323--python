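"""Train the four risk branches on a synthetic cohort with a planted effect.

Signal is planted mainly in lesion burden (odds ratio e^3 per SD), so the
MRI branch and the multimodal model should out-discriminate the ECG and
clinical branches on held-out patients.
"""

from deeprisk.experiments import run_branch_experiment

result = run_branch_experiment(
    seed=0,
    n_dev=200, n_ext=100,
    effect_lesion=3.0, effect_qrs=0.5, effect_clinical=0.5,
    vae_ecg_kw=dict(hidden_dim=32, n_residual_blocks=1, epochs=10),
    vae_mri_kw=dict(hidden_dim=128, n_residual_blocks=1, epochs=20),
)

print("held-out AUROC per branch (100 external patients):")
for branch, auc in sorted(result["auroc"].items(), key=lambda kv: -kv[1]):
    print(f"  {branch:12s} {auc:.3f}")
print("0.5 is chance; the imaging-informed branches should rank above the")
print("ECG and clinical branches because the planted signal is imaging-borne.")
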