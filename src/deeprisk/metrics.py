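"""Evaluation statistics for binary risk predictions.

Implements the evaluation battery used to report arrhythmic-risk models:
AUROC (pair-counting estimator), AUPRC (average precision), confusion-table
metrics at a threshold, the Youden-J optimal cut-point, percentile bootstrap
confidence intervals, DeLong's test for correlated AUROCs, and calibration
(logistic recalibration slope plus binned reliability).

Conventions
-----------
* A score greater than **or equal to** the threshold predicts the positive
  class (ties at the threshold count as positive).
* Bootstrap intervals are percentile intervals; replicates that lose one of
  the two classes are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given labels (e.g. one class)."""


class UnstableCIError(RuntimeError):
    """Raised when too many bootstrap replicates are degenerate to trust the CI."""


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the pair-counting (Mann-Whitney) estimator.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg); identical
    to trapezoidal integration of the empirical ROC curve.
    """
    scores, labels = _validate(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC requires both classes")
    ranks = rankdata(scores)  # midranks handle ties -> 0.5 credit per tied pair
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    ppv: Optional[float]  # None when nothing is predicted positive
    npv: Optional[float]
    accuracy: float
    f1: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


def threshold_metrics(scores, labels, threshold: float) -> ThresholdMetrics:
    """Confusion-table metrics with ``score >= threshold`` predicting positive."""
    scores, labels = _validate(scores, labels)
    n1 = int(labels.sum())
    if n1 == 0 or n1 == labels.size:
        raise UndefinedMetricError("threshold metrics require both classes")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    acc = (tp + tn) / labels.size
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) > 0 else None
    return ThresholdMetrics(sens, spec, ppv, npv, acc, f1, tp, fp, tn, fn)


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    j: float  # sensitivity + specificity - 1 at the threshold
    sensitivity: float
    specificity: float


def youden_cutpoint(scores, labels) -> CutpointResult:
    """Optimal cut-point maximising Youden's J = sensitivity + specificity - 1.

    Exhaustive scan over midpoints between adjacent unique scores plus one
    candidate above the maximum; ties in J are broken toward the higher
    threshold (higher specificity, fewer predicted positives).
    """
    scores, labels = _validate(scores, labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([uniq[:1] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1:] + 1.0])
    best: Optional[CutpointResult] = None
    for thr in candidates:
        m = threshold_metrics(scores, labels, thr)
        j = m.sensitivity + m.specificity - 1.0
        if best is None or j > best.j + 1e-12 or (abs(j - best.j) <= 1e-12 and m.specificity > best.specificity):
            best = CutpointResult(float(thr), float(j), m.sensitivity, m.specificity)
    assert best is not None
    return best


def bootstrap_ci(
    scores,
    labels,
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    n_iter: int = 3000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for ``metric_fn(scores, labels)``.

    Patients are resampled with replacement; replicates in which the resample
    contains a single outcome class are skipped (and counted). Returns
    ``(point, lo, hi)``.
    """
    scores, labels = _validate(scores, labels)
    if scores.size < 10:
        raise ValueError("bootstrap requires n >= 10")
    point = float(metric_fn(scores, labels))
    rng = np.random.default_rng(seed)
    stats = []
    n_degenerate = 0
    for _ in range(n_iter):
        idx = rng.integers(0, scores.size, scores.size)
        ls = labels[idx]
        if ls.min() == ls.max():
            n_degenerate += 1
            continue
        value = metric_fn(scores[idx], ls)
        if value is None or not np.isfinite(value):  # metric undefined on replicate
            n_degenerate += 1
            continue
        stats.append(value)
    if n_degenerate > n_iter / 2:
        raise UnstableCIError(f"{n_degenerate}/{n_iter} bootstrap replicates were degenerate")
    alpha = (1.0 - level) / 2.0
    stats_arr = np.asarray(stats, dtype=float)
    lo, hi = np.percentile(stats_arr, [100 * alpha, 100 * (1 - alpha)])
    return point, float(lo), float(hi)


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative).

    V10_i = P-hat(score of positive i exceeds a random negative), with ties
    counted 1/2; V01_j analogously per negative. mean(V10) = mean(V01) = AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 0.5 if x == y, else 0 -- vectorised n1 x n0 table
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's test comparing two correlated AUROCs on the same patients.

    Uses placement-value structural components to estimate var(AUC_a - AUC_b);
    z = delta / sqrt(var), two-sided normal p-value. Identical score vectors
    (or zero estimated variance) yield a degenerate result with p = 1.
    """
    scores_a, labels = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("DeLong test requires both classes")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    n1, n0 = v10a.size, v01a.size
    v10 = np.stack([v10a, v10b])
    v01 = np.stack([v01a, v01b])
    s10 = np.cov(v10) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n0 > 1 else np.zeros((2, 2))
    cov = s10 / n1 + s01 / n0
    c = np.array([1.0, -1.0])
    var = float(c @ cov @ c)
    delta = auc_a - auc_b
    if var <= 0:
        return DelongResult(auc_a, auc_b, delta, 0.0, 0.0, 1.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, delta, var, float(z), p)


@dataclass(frozen=True)
class CalibrationResult:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    predicted_rate: np.ndarray  # mean score per non-empty bin (NaN if empty)
    observed_rate: np.ndarray   # event rate per non-empty bin (NaN if empty)
    slope: float                # logistic recalibration slope (primary)
    intercept: float
    binned_slope: float         # straight-line fit to the non-empty bin points


def calibration(scores, labels, n_bins: int = 10) -> CalibrationResult:
    """Calibration curve and slope.

    Primary slope is the logistic-recalibration convention: fit
    ``label ~ logit(score)`` by logistic regression; slope 1 means perfectly
    calibrated spread. A straight-line fit through the binned reliability
    points is reported alongside.
    """
    scores, labels = _validate(scores, labels)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("calibration requires scores in [0, 1]")
    if scores.size < n_bins:
        raise ValueError("need n >= n_bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if counts[b] > 0:
            pred[b] = scores[which == b].mean()
            obs[b] = labels[which == b].mean()
    eps = 1e-7
    lo = np.log(np.clip(scores, eps, 1 - eps) / np.clip(1 - scores, eps, 1 - eps))
    import statsmodels.api as sm

    fit = sm.GLM(labels, sm.add_constant(lo), family=sm.families.Binomial()).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    ok = counts > 0
    if ok.sum() >= 2 and np.ptp(pred[ok]) > 0:
        binned_slope = float(np.polyfit(pred[ok], obs[ok], 1)[0])
    else:
        binned_slope = float("nan")
    return CalibrationResult(edges, counts, pred, obs, slope, intercept, binned_slope)


@dataclass
class MetricsReport:
    """Point estimates with 95% percentile-bootstrap CIs at the Youden cut-point."""

    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    f1: Optional[float]
    threshold: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv", "accuracy", "f1", "threshold")
        }
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        out["n_bootstrap"] = self.n_bootstrap
        out["seed"] = self.seed
        return out


def evaluate_predictions(scores, labels, n_bootstrap: int = 3000, seed: int = 0) -> MetricsReport:
    """Full evaluation at the Youden-optimal threshold, with bootstrap CIs."""
    scores, labels = _validate(scores, labels)
    cut = youden_cutpoint(scores, labels)
    m = threshold_metrics(scores, labels, cut.threshold)
    report = MetricsReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        ppv=m.ppv,
        npv=m.npv,
        accuracy=m.accuracy,
        f1=m.f1,
        threshold=cut.threshold,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
    if n_bootstrap > 0:
        def at_cut(attr):
            # undefined replicates (e.g. PPV with no predicted positives)
            # contribute NaN and are dropped from the percentile
            def fn(s, l):
                v = getattr(threshold_metrics(s, l, cut.threshold), attr)
                return np.nan if v is None else v

            return fn

        fns: dict[str, Callable] = {
            "auroc": auroc,
            "auprc": auprc,
            "sensitivity": at_cut("sensitivity"),
            "specificity": at_cut("specificity"),
            "ppv": at_cut("ppv"),
            "npv": at_cut("npv"),
            "accuracy": at_cut("accuracy"),
            "f1": at_cut("f1"),
        }
        for i, (name, fn) in enumerate(fns.items()):
            _, lo, hi = bootstrap_ci(scores, labels, fn, n_iter=n_bootstrap, seed=seed + i)
            report.ci[name] = (lo, hi)
    return report
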