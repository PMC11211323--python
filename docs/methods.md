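# Methods

`deeprisk` re-creates, at desk scale and on synthetic data, a multimodal
pipeline for predicting one-year malignant ventricular arrhythmia in
patients with non-ischaemic systolic heart failure: latent features are
extracted from short-axis LGE-MRI and 12-lead mean-beat ECGs with residual
β-VAEs, combined with clinical variables, and classified with a
SMOTE-balanced gradient-boosted model, followed by Shapley, latent-traversal
and gradient-attention explainability and a full ROC/bootstrap/DeLong
evaluation battery. This note records the model, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Synthetic cohort generator

The generator is first-class code, not a fixture: it defines the conditions
under which every downstream claim is tested.

**ECG.** Each patient's 10-s, 500 Hz, 12-lead ECG is a train of beats at
exactly `60/heart_rate` intervals. A beat is the sum of three Gaussian
deflections per lead — P (centre −160 ms, σ 22 ms), QRS (centre 0, σ =
`qrs_width_ms`/4), T (centre +250 ms, σ 55 ms) — scaled by a 12×3 amplitude
matrix (aVR inverted, precordial progression). Additive white Gaussian noise
(default 0.02 mV) and a common sinusoidal baseline wander (default 0.1 mV at
0.3 Hz, below the 0.5 Hz baseline-removal cutoff) complete the record. This
is deliberately not a dipole/torso forward model: downstream stages need
detectable R peaks and outcome-covarying morphology, nothing more.

**LGE-like volume.** 12 slices of 96×96 voxels (1.8 mm in-plane, 10 mm
depth); each slice holds an annular myocardium around a brighter blood pool,
with radii tapering toward the apex (slice 0). Lesions are small spheroidal
blobs seeded at random myocardium voxels and grown until the enhanced
fraction reaches the per-patient target (realized fraction returned; always
within ±0.05 of target). Intensity levels: background 0.05, myocardium 0.30,
blood 0.65, lesion 1.00, with σ = 0.02 noise. No MRI physics (no PSIR
contrast simulation) is attempted.

**Clinical table.** Mirrors a typical ICD-cohort roster: age, sex, BMI,
pathology class (dilated/genetic/hypertrophic/miscellaneous), six history
flags, three labs, seven medication flags, device type, with marginal
frequencies matching a two-hospital NICM population (e.g. 32% female, mean
age 60, 63% dilated, 9 % baseline event rate). Missingness is MCAR at a
configurable rate; the mechanism in real registries is unknown, and MCAR is
the weakest assumption that still exercises the imputation stage. When the
rate exceeds 0.3 one designated column (potassium) is pushed above 30 %
missing so the variable-exclusion rule has work to do.

**Outcome.** `P(event) = sigmoid(α + β₁·z(lesion fraction) + β₂·z(QRS
width) + β₃·z(clinical score))`, where the z-scores use the generator's
analytic population constants (lesion fraction ~ 0.5·Beta(2,4); QRS ~
N(100, 18) ms; clinical score = z(age) + z(log creatinine) + standardized
prior-NSVT flag). The default intercept corresponds to 9% prevalence, the
one-year arrhythmia rate typical of such cohorts. The true linear predictor
is stored per patient for oracle checks.

## ECG preprocessing

Downsample to 250 Hz (polyphase, linear-fit edge padding) → Savitzky-Golay
smoothing → subtraction of a truncated Fourier-series baseline (all bins
below 0.5 Hz, DC included) → R-peak marking on lead II (squared-derivative
energy, 120 ms integration, threshold at 25% of the 99.5th energy
percentile, 200 ms refractory, refinement to the local extremum) → 600 ms
windows (200 ms before / 400 ms after R, so L = 150 samples) →
cross-correlation alignment (±10 samples) to the first beat → per-lead
averaging → per-lead z-scoring (min-max available via `normalization=
"minmax"`; z-score is the default because the clinical variables are also
z-scored, and "normalize to [0, 1] with z-scores" is not a coherent single
operation).

The Savitzky-Golay window is 31 samples (~124 ms) with polynomial order 5.
Order 3 at this window measurably attenuates a ~100 ms QRS (template-recovery
Pearson drops below 0.99); order 5 preserves it while still suppressing
high-frequency noise. Both are configurable.

## MRI preprocessing

Segmentation is a pluggable interface with three backends: `analytic`
(returns the generator's true ring — synthetic data only), `file` (an
externally produced probability map), and a trainable backend — a 4-level
pooled feature pyramid (encoder: repeated 2× average pooling producing local
mean/spread at each scale; decoder: upsampling back to full resolution) with
a small random-forest pixel classifier, trained only on synthetic
(volume, mask) pairs. The forest's nonlinearity keeps hyper-enhanced lesion
voxels inside the myocardium class; it reaches Dice ≥ 0.9 on held-out
synthetic volumes.

Probability maps are thresholded at 0.5 (unstated in the field; declared
here), cropped to the all-slice 2D bounding box plus an 8-pixel margin,
harmonized to 12 slices (center crop if deeper, symmetric zero-pad with zero
mask if shallower), resized in-plane to 64×64 (bilinear for the scan,
nearest-neighbour then re-binarized for the mask), histogram-equalized
per volume (global, rank-preserving, constant volumes passed through) and
rescaled to [0, 1]. Channel order is fixed and recorded in the JSON sidecar:
index 0 = masked scan, index 1 = binary mask; off-mask scan voxels are
exactly zero by construction.

## Residual β-VAE

The autoencoder is a residual multilayer-perceptron VAE implemented directly
on NumPy with hand-written backpropagation (verified against finite
differences to ~1e-8 relative error): the input is average-pooled over its
spatial axes (MRI: 4×4 in-plane, giving 12×16×16×2), flattened, passed
through `Dense → tanh → n residual blocks` (a block is
`x + Dense(tanh(Dense(x)))`) to linear posterior heads (μ, log σ²); the
decoder mirrors the trunk and nearest-neighbour-unpools to the input shape.
Latent dimensionalities follow the modalities: 32 for ECG, 256 for MRI.

Training maximizes the β-weighted ELBO with Adam (default 1e-3, seeded
minibatches, best-validation-epoch weights retained, hard abort on
non-finite loss):

    total = recon + β · KL
    recon = mean squared reconstruction error (per element)
    KL    = ½ Σ (μ² + e^{logvar} − 1 − logvar)   per sample, batch-averaged

Because the reconstruction term is a per-element mean while the KL is a
per-sample sum over latent dimensions, the natural β scale depends on the
input dimensionality; the per-modality defaults are β = 1e-3 (ECG,
1 800-dimensional input) and β = 1e-5 (MRI, 98 304-dimensional input), each
chosen so the two terms are commensurate at initialization. Tuning explores
multipliers {0.5, 1, 2, 4} of the base. Downstream features are the
posterior means μ, not samples: deterministic features keep the classifier,
SHAP values and attention maps reproducible.

The log-variance head's bias initializes at −8 (posterior σ = e⁻⁴). This is
load-bearing: the encoder's μ spread across patients is small relative to a
unit-variance prior, so with σ ≈ 1 at initialization the reparameterized
sample is noise-dominated, the decoder settles on reconstructing the
population mean, and no gradient ever tightens the posterior — the classic
collapse equilibrium. Starting tight breaks the cycle; on mean-beat cohorts
the decoder then reconstructs patient-specific morphology well below the
mean-beat error floor.

## Risk model

Clinical columns with more than 30% missing values are excluded; the rest
are imputed missForest-style (mean/mode initialization, then per-column
random forests refitted for up to 10 rounds or until the largest relative
change falls below 1e-3). Categoricals are one-hot encoded and continuous
variables z-scored with statistics fitted on development rows only and
frozen for external rows; unseen categories map to all-zero indicators with
a warning. Class imbalance is addressed with SMOTE (synthetic minority rows
`x + λ(x_nn − x)`, λ ~ U(0,1), k = 5 minority neighbours, balanced 1:1),
applied only inside training data — never to validation folds or external
cohorts.

The classifier is XGBoost (`binary:logistic`, `hist`). Hyperparameters are
tuned by sequential model-based search — a Matern-kernel Gaussian-process
surrogate over the unit hypercube maximizing expected improvement of the
stratified 5-fold cross-validated AUROC, with SMOTE refitted inside each
training fold; the first third of the trial budget is random exploration.
Search space: depth 2–8, learning rate 0.01–0.3 (log), 50–500 estimators,
subsample 0.5–1, min-child-weight 1–10, L1/L2 0–5. After tuning, the best
configuration is refitted on the whole development cohort. Branches:
`multimodal` (256 MRI + 32 ECG + clinical columns) or any single block.

## Explainability

* **Shapley attributions** use the tree-path-dependent TreeSHAP algorithm of
  the fitted booster. Values live in margin (log-odds) space, so local
  accuracy reads `Σφᵢ + base = logit(p̂)` (held to single precision, 1e-6
  relative — the booster stores contributions as float32); a positive value
  raises the predicted probability. A brute-force interventional Shapley
  enumerator over all 2^p coalitions ships alongside as the independent
  small-p oracle.
* **Latent traversal** decodes the cohort-mean latent vector with one
  coordinate swept across −3…+3 SD (SD taken over the cohort's posterior
  means; per-patient base points available via `base=`). Offsets are decoded
  one vector at a time so the 0-offset frame is bit-identical to a plain
  decode.
* **Attention maps** are the mean absolute gradient of the selected
  posterior-mean coordinates (by default the ten latents with highest SHAP
  importance) with respect to the input — computed from the learned latent
  space directly, not by backpropagating a classification output — restricted
  to the scan channel for MRI and min-max normalized. Gradients are taken of
  μ, not a sampled z, for determinism; |gradient| (rather than
  gradient×input or signed gradients) is used because the maps are read as
  saliency magnitudes. Through the pooled front end the per-pixel gradient is
  block-uniform at the pooling resolution.

## Evaluation statistics

AUROC is the pair-counting (Mann–Whitney, midrank-tied) estimator, identical
to trapezoidal ROC integration; AUPRC is average precision. Confusion
metrics use `score ≥ threshold ⇒ positive` (ties predicted positive). The
Youden cut-point scans midpoints between adjacent unique scores plus
sentinels, ties broken toward higher specificity (fewer implants at equal
J). Confidence intervals are 95% percentile bootstrap (3 000 iterations by
default; replicates that lose a class are skipped and counted, >50%
degenerate replicates abort). DeLong's test uses placement-value structural
components for the correlated-AUC variance, with identical score vectors
reported as a degenerate comparison (p = 1) rather than a division by zero.
Calibration is reported both as the logistic-recalibration slope (primary:
logistic fit of outcomes on logit(score)) and as a straight-line fit through
the binned reliability points.

## Orchestration

One pydantic-validated hierarchical configuration drives simulate →
prep-ecg → prep-mri → train-vae ×2 → encode → train-risk (4 branches) →
predict → evaluate → explain. Per-stage seeds are spawned from the master
seed via `numpy.random.SeedSequence` in a fixed stage order; heavy stages
cache outputs keyed by a configuration hash and are skipped on resume; each
run writes a manifest (config snapshot, stage seeds, output digests, package
version, timestamp). Unknown configuration keys are rejected before any
computation.

## Validation experiments and problem sizes

The desk-scale experiments in `deeprisk.experiments` (also run by
`scripts/acceptance.py`) use: development 400 / external 200 patients for
signal recovery (lesion odds ratio e³ per SD, ECG and clinical effects e¹);
ten replicates of 150/100 with an MRI-only effect for branch ordering; 200
null datasets of n = 500 for DeLong type-I calibration; 100 cohorts of
n = 200 with 500-iteration bootstraps for CI coverage. These experiments
simulate a 20% event rate rather than the 9% cohort default: with 200
held-out patients, a 9% rate leaves ~18 events and a chance-level AUROC
standard error of ~0.075, too noisy to interpret; 20% gives usable
precision at the same scale. VAE sizes in the experiments (hidden 64–256,
15–30 epochs) are small enough to train in minutes on one CPU.

## What passing these tests does and does not show

The generator's lesions are bright, compact and noise-free relative to real
PSIR contrast; its ECGs have no muscle artifact, electrode drift, ectopy or
conduction abnormalities; its missingness is MCAR; its outcome model is
exactly logistic in three known factors. Passing therefore demonstrates that
the machinery is correct and that the chain can recover planted
morphology-linked risk signal through unsupervised latent compression — it
says nothing about the discrimination such a model would reach on real
patient cohorts, which cannot be assessed without clinical data.

## Known limitations

* The VAEs are dense residual networks on pooled inputs, not strided
  convolutional stacks; attention maps are block-uniform at the 4×4 pooling
  resolution for MRI.
* Latent compression is lossy: on the signal-recovery cohort a linear probe
  reads lesion burden from the 256 MRI latents with r ≈ 0.5–0.7 against
  truth, which bounds the MRI branch below the oracle AUROC of the true
  fraction. Notably, an *untrained* encoder (a random projection of the
  pooled masked scan) already carries most of this linearly-readable signal;
  at desk scale the VAE's contribution is reconstruction fidelity and a
  decoder for traversal/attention, not a large gain in downstream
  discrimination.
* Single-latent traversals produce visible transformations only when the
  data's variation is concentrated in few factors relative to the latent
  dimensionality (as in the factor-dominant traversal test); on cohorts
  whose inter-patient variance is a small fraction of the reconstruction
  floor, and with β too small to impose disentanglement, the information is
  spread across many latents and any single-coordinate sweep is subtle.
* TreeSHAP values are path-dependent; they coincide with interventional
  Shapley values only under balanced training cover (the toy-tree oracle
  test constructs exactly that case).
* The trainable segmentation backend is a feature-pyramid pixel classifier;
  it is not expected to transfer to real LGE-MRI.
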