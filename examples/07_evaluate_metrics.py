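"""Evaluate predictions the way a risk-stratification study reports them.

Full battery: AUROC/AUPRC, Youden-optimal cut-point, sensitivity/specificity/
PPV/NPV/accuracy/F1 with 95% bootstrap CIs, DeLong comparison of two models,
and the calibration slope.
"""

import numpy as np

from deeprisk.metrics import calibration, delong_test, evaluate_predictions

rng = np.random.default_rng(0)
n = 300
labels = (rng.random(n) < 0.15).astype(int)            # 15% event rate
good = 1 / (1 + np.exp(-(1.8 * labels + rng.normal(-2, 1, n))))
weak = 1 / (1 + np.exp(-(0.4 * labels + rng.normal(-2, 1, n))))

report = evaluate_predictions(good, labels, n_bootstrap=1000, seed=7)
print(f"AUROC {report.auroc:.3f} (95% CI {report.ci['auroc'][0]:.3f}-{report.ci['auroc'][1]:.3f})")
print(f"AUPRC {report.auprc:.3f}  (baseline = prevalence {labels.mean():.2f})")
print(f"Youden threshold {report.threshold:.3f}: sensitivity {report.sensitivity:.2f}, "
      f"specificity {report.specificity:.2f}, NPV {report.npv:.3f}")

dl = delong_test(good, weak, labels)
print(f"DeLong: dAUC {dl.delta:+.3f}, z {dl.z:.2f}, p {dl.p:.2g} "
      "(small p: the stronger model's AUROC is genuinely higher)")

cal = calibration(good, labels)
print(f"calibration slope {cal.slope:.2f} (1 = perfectly calibrated spread; "
      "<1 overconfident, >1 underconfident)")
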