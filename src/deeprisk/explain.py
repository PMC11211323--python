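"""Explainability: Shapley attributions, latent traversal, attention maps.

* Shapley feature attributions for the gradient-boosted classifier use the
  tree-path-dependent TreeSHAP algorithm (xgboost's native implementation).
  Values live in margin (log-odds) space, so local accuracy reads
  ``sum(phi) + base = margin(x)`` — a positive value raises the predicted
  probability.
* Latent traversal decodes the cohort-mean latent vector with one coordinate
  swept across ``offset * SD`` steps, visualising the factor that coordinate
  encodes.
* Attention maps are the absolute input-gradients of selected posterior-mean
  coordinates, averaged and min-max normalized — computed from the learned
  latent space directly rather than by backpropagating a classification
  output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost

from .risk import RiskModel
from .vae import ResidualVAE


@dataclass(frozen=True)
class AttributionVector:
    """Per-feature Shapley values plus the expected-output base value (margin scale)."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    def __post_init__(self):
        if len(self.values) != len(self.feature_names):
            raise ValueError("one value per feature required")

    @property
    def prediction_margin(self) -> float:
        return float(self.values.sum() + self.base_value)


def shapley_attributions(rm: RiskModel, x_row: pd.Series | pd.DataFrame) -> AttributionVector:
    """Tree-path-dependent Shapley values for one explained row.

    Local accuracy: ``sum(values) + base_value`` equals the model's margin
    (log-odds) output for the row.
    """
    if isinstance(x_row, pd.Series):
        x_row = x_row.to_frame().T
    missing = [c for c in rm.feature_names if c not in x_row.columns]
    if missing:
        raise KeyError(f"row lacks features: {missing[:5]}")
    arr = x_row[rm.feature_names].to_numpy(float)
    dm = xgboost.DMatrix(arr, feature_names=rm.feature_names)
    contribs = rm.model.get_booster().predict(dm, pred_contribs=True)
    return AttributionVector(
        values=np.asarray(contribs[0, :-1], dtype=float),
        base_value=float(contribs[0, -1]),
        feature_names=list(rm.feature_names),
    )


def shapley_matrix(rm: RiskModel, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Shapley values for every row; returns (frame, base_value)."""
    dm = xgboost.DMatrix(X[rm.feature_names].to_numpy(float), feature_names=rm.feature_names)
    contribs = rm.model.get_booster().predict(dm, pred_contribs=True)
    frame = pd.DataFrame(contribs[:, :-1], columns=rm.feature_names, index=X.index)
    return frame, float(contribs[0, -1])


def top_latents(
    attributions: pd.DataFrame | pd.Series | np.ndarray,
    m: int = 10,
    latent_prefix: Optional[str] = None,
) -> np.ndarray:
    """Rank latent features by |Shapley value| (per patient or aggregated).

    A DataFrame is reduced to mean |value| per feature over the cohort; ties
    break deterministically toward the lower feature index. When
    ``latent_prefix`` is given, ranking is restricted to columns starting with
    it and positions are returned within that block.
    """
    if isinstance(attributions, pd.DataFrame):
        series = attributions.abs().mean(axis=0)
    elif isinstance(attributions, pd.Series):
        series = attributions.abs()
    else:
        series = pd.Series(np.abs(np.asarray(attributions, dtype=float)))
    if latent_prefix is not None:
        cols = [c for c in series.index if str(c).startswith(latent_prefix)]
        series = series[cols]
        positions = np.arange(len(cols))
    else:
        positions = np.arange(len(series))
    vals = series.to_numpy(float)
    order = np.lexsort((positions, -vals))  # descending |phi|, then low index
    return positions[order][:m]


@dataclass(frozen=True)
class TraversalSet:
    latent_index: int
    offsets_sd: np.ndarray
    reconstructions: np.ndarray  # (n_offsets, *input_shape)
    base_latent: np.ndarray
    sd: float

    def __post_init__(self):
        if 0.0 not in np.asarray(self.offsets_sd):
            raise ValueError("offset grid must contain 0")


def latent_traversal(
    vae: ResidualVAE,
    cohort_latents: np.ndarray,
    latent_index: int,
    offsets_sd: Sequence[float] = (-3, -2, -1, 0, 1, 2, 3),
    base: Optional[np.ndarray] = None,
) -> TraversalSet:
    """Decode the base latent with one coordinate swept across +/- SD steps.

    The per-dimension SD comes from the cohort's posterior means; the base
    point defaults to the cohort mean (pass ``base`` for a per-patient view).
    """
    lat = np.asarray(cohort_latents, dtype=float)
    if not (0 <= latent_index < lat.shape[1]):
        raise IndexError(f"latent index {latent_index} out of range")
    sd = float(lat[:, latent_index].std())
    base_vec = lat.mean(axis=0) if base is None else np.asarray(base, dtype=float).copy()
    offsets = np.asarray(offsets_sd, dtype=float)
    recons = []
    for off in offsets:
        z = base_vec.copy()
        z[latent_index] = base_vec[latent_index] + off * sd
        # decode one vector at a time so the 0-offset frame is bit-identical
        # to a plain decode of the base vector (batched BLAS rounds differently)
        recons.append(vae.decode(z))
    recon = np.stack(recons)
    return TraversalSet(latent_index, offsets, recon, base_vec, sd)


@dataclass(frozen=True)
class AttentionMap:
    heatmap: np.ndarray  # spatial shape of the input, in [0, 1]
    latent_indices: tuple[int, ...]

    def __post_init__(self):
        h = np.asarray(self.heatmap, dtype=float)
        object.__setattr__(self, "heatmap", h)
        if h.min() < 0:
            raise ValueError("attention map must be nonnegative")
        if h.max() > 0 and abs(h.max() - 1.0) > 1e-9:
            raise ValueError("non-zero attention map must be normalized to max 1")


def gradient_attention_map(
    vae: ResidualVAE, x: np.ndarray, latent_indices: Sequence[int]
) -> AttentionMap:
    """Mean |d mu_i / d input| over the selected latent dimensions.

    For the MRI modality the map is restricted to the scan channel. The
    result is min-max normalized to [0, 1] (all-zero maps stay zero).
    """
    indices = tuple(int(i) for i in latent_indices)
    if not indices:
        raise ValueError("latent_indices must be non-empty")
    grads = [np.abs(vae.input_gradient(x, i)) for i in indices]
    heat = np.mean(grads, axis=0)
    if vae.config.modality == "mri" and heat.ndim == 4:
        heat = heat[..., 0]  # scan channel
    lo, hi = heat.min(), heat.max()
    if hi > lo:
        heat = (heat - lo) / (hi - lo)
    elif hi > 0:
        heat = heat / hi
    return AttentionMap(heatmap=heat, latent_indices=indices)


# ---------------------------------------------------------------------------
# Exact Shapley enumeration (test oracle / small-feature reference)
# ---------------------------------------------------------------------------


def exact_shapley(predict_fn, x_row: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, float]:
    """Brute-force interventional Shapley values over all 2^p coalitions.

    ``predict_fn`` maps an (n, p) array to outputs; the value of a coalition S
    is the mean prediction with features in S taken from ``x_row`` and the
    rest marginalised over ``background`` rows. Exponential in p — intended
    as an independent oracle for small p, not production use.
    """
    from itertools import combinations
    from math import factorial

    x_row = np.asarray(x_row, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    p = x_row.size

    def value(S: frozenset) -> float:
        mixed = bg.copy()
        for j in S:
            mixed[:, j] = x_row[j]
        return float(np.mean(predict_fn(mixed)))

    cache = {frozenset(): value(frozenset())}
    for r in range(1, p + 1):
        for S in combinations(range(p), r):
            cache[frozenset(S)] = value(frozenset(S))
    phi = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in combinations(others, r):
                phi[j] += w * (cache[frozenset(S) | {j}] - cache[frozenset(S)])
    return phi, cache[frozenset()]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def overlay(
    amap: AttentionMap,
    original: np.ndarray,
    out_path,
    slice_index: Optional[int] = None,
    cmap: str = "inferno",
    alpha: float = 0.5,
) -> Path:
    """Alpha-blend a heatmap over the original slice (MRI) or lead panel (ECG).

    Deterministic rendering: fixed figure geometry and colormap, no
    timestamps in the written PNG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heat = amap.heatmap
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if heat.ndim == 3:  # volume: render one slice
        s = slice_index if slice_index is not None else heat.shape[0] // 2
        heat2d, orig2d = heat[s], np.asarray(original)[s]
    else:
        heat2d, orig2d = np.atleast_2d(heat), np.atleast_2d(original)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    ax.imshow(orig2d, cmap="gray", interpolation="nearest")
    if heat2d.max() > 0:
        ax.imshow(heat2d, cmap=cmap, interpolation="nearest", alpha=alpha * (heat2d > 0))
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight", pad_inches=0, metadata={"Software": None})
    plt.close(fig)
    return out_path
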