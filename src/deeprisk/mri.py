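"""Short-axis LGE volume preprocessing: segmentation, ROI crop, 12x64x64x2 input.

The myocardium segmentation is a pluggable backend:

* ``analytic``   — returns a known mask (synthetic data only, where the
  generator geometry is available);
* ``model``      — a trainable 4-scale encoder-decoder pixel classifier,
  trained on synthetic (volume, mask) pairs;
* ``file``       — an externally produced probability map loaded from NIfTI.

Downstream, the probability map drives an in-plane ROI crop, the crop is
standardized to 12 slices of 64 x 64 with per-volume histogram equalization,
and the mask is layered over the scan as a second channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from skimage import exposure
from skimage.transform import resize

TARGET_SLICES = 12
TARGET_SIZE = 64
DEFAULT_MARGIN = 8
DEFAULT_THRESHOLD = 0.5


class NoMyocardiumError(RuntimeError):
    """No voxel reached the probability threshold."""


@dataclass(frozen=True)
class LgeVolume:
    """Short-axis LGE intensities with voxel spacing (depth, row, col) in mm."""

    intensities: np.ndarray  # (S, H, W)
    spacing_mm: tuple[float, float, float] = (10.0, 1.8, 1.8)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError(f"volume must be (S, H, W) with S >= 1; got {arr.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass(frozen=True)
class MyocardiumMap:
    """Pixel-wise myocardium probabilities, same shape as its volume."""

    probabilities: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", arr)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ModelInputVolume:
    """12 x 64 x 64 x 2 model input: channel 0 = masked equalized scan, 1 = mask."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.shape != (TARGET_SLICES, TARGET_SIZE, TARGET_SIZE, 2):
            raise ValueError(f"expected (12, 64, 64, 2); got {arr.shape}")
        mask = arr[..., 1]
        if not np.isin(mask, [0.0, 1.0]).all():
            raise ValueError("mask channel must be binary")
        if np.any((mask == 0) & (arr[..., 0] != 0)):
            raise ValueError("scan channel must be zero outside the mask")

    @property
    def scan(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def mask(self) -> np.ndarray:
        return self.data[..., 1]


# ---------------------------------------------------------------------------
# Segmentation backends
# ---------------------------------------------------------------------------


class AnalyticRingBackend:
    """Returns a known myocardium mask (synthetic volumes only)."""

    def __init__(self, true_mask: np.ndarray):
        self.true_mask = np.asarray(true_mask)

    def __call__(self, vol: LgeVolume) -> MyocardiumMap:
        if self.true_mask.shape != vol.shape:
            raise ValueError("true mask shape does not match volume")
        return MyocardiumMap(self.true_mask.astype(float))


class FileBackend:
    """Loads an externally produced probability map from NIfTI."""

    def __init__(self, path):
        self.path = Path(path)

    def __call__(self, vol: LgeVolume) -> MyocardiumMap:
        import nibabel as nib

        arr = np.asarray(nib.load(self.path).dataobj, dtype=float)
        if arr.ndim == 3 and arr.shape[::-1] == vol.shape:
            arr = arr.transpose(2, 1, 0)  # stored col-row-slice -> slice-row-col
        if arr.shape != vol.shape:
            raise ValueError(f"probability map {arr.shape} does not match volume {vol.shape}")
        return MyocardiumMap(np.clip(arr, 0.0, 1.0))


class EncoderDecoderBackend:
    """Trainable multiscale pixel classifier with a 4-level pooled pyramid.

    Encoder: four successive 2x average-pooling levels of the slice, each
    yielding local mean and local spread features; decoder: nearest-neighbour
    upsampling of every level back to full resolution. The concatenated
    per-pixel feature vector feeds a small random-forest classifier trained on
    synthetic (volume, mask) pairs; the forest's nonlinearity lets it keep
    hyper-enhanced lesion pixels inside the myocardium class.
    """

    N_LEVELS = 4

    def __init__(self, seed: int = 0, max_pixels_per_volume: int = 20000):
        self.seed = seed
        self.max_pixels = max_pixels_per_volume
        self._clf = None

    @staticmethod
    def _features(vol: np.ndarray) -> np.ndarray:
        """Per-voxel features: intensity + (mean, spread) at 4 pooled scales."""
        from scipy.ndimage import uniform_filter, zoom

        feats = [vol]
        for level in range(1, EncoderDecoderBackend.N_LEVELS + 1):
            size = 2**level
            mean = uniform_filter(vol, size=(1, size, size), mode="nearest")
            sq = uniform_filter(vol**2, size=(1, size, size), mode="nearest")
            spread = np.sqrt(np.clip(sq - mean**2, 0.0, None))
            feats.extend([mean, spread])
        return np.stack(feats, axis=-1)  # (S, H, W, 9)

    def fit(self, volumes: list[np.ndarray], masks: list[np.ndarray]) -> "EncoderDecoderBackend":
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(self.seed)
        xs, ys = [], []
        for vol, mask in zip(volumes, masks):
            f = self._features(np.asarray(vol, dtype=float)).reshape(-1, 1 + 2 * self.N_LEVELS)
            y = np.asarray(mask).reshape(-1).astype(int)
            idx = rng.choice(y.size, size=min(self.max_pixels, y.size), replace=False)
            xs.append(f[idx])
            ys.append(y[idx])
        X = np.concatenate(xs)
        Y = np.concatenate(ys)
        self._clf = RandomForestClassifier(
            n_estimators=30, max_depth=14, random_state=self.seed, n_jobs=1
        ).fit(X, Y)
        return self

    def __call__(self, vol: LgeVolume) -> MyocardiumMap:
        if self._clf is None:
            raise RuntimeError("EncoderDecoderBackend must be fitted before use")
        f = self._features(vol.intensities).reshape(-1, 1 + 2 * self.N_LEVELS)
        prob = self._clf.predict_proba(f)[:, 1].reshape(vol.shape)
        return MyocardiumMap(prob)


def segment_myocardium(vol: LgeVolume, backend) -> MyocardiumMap:
    """Apply a segmentation backend (callable ``LgeVolume -> MyocardiumMap``)."""
    if not callable(backend):
        raise ValueError(f"unknown segmentation backend: {backend!r}")
    return backend(vol)


# ---------------------------------------------------------------------------
# Crop / standardize / assemble
# ---------------------------------------------------------------------------


def crop_roi(
    vol: LgeVolume,
    prob_map: MyocardiumMap,
    threshold: float = DEFAULT_THRESHOLD,
    margin: int = DEFAULT_MARGIN,
) -> tuple[LgeVolume, MyocardiumMap]:
    """Crop all slices to the 2D bounding box of the thresholded map + margin."""
    if prob_map.probabilities.shape != vol.shape:
        raise ValueError("probability map shape does not match volume")
    hits = prob_map.probabilities >= threshold
    if not hits.any():
        raise NoMyocardiumError(f"no voxel reaches probability {threshold}")
    rows = np.where(hits.any(axis=(0, 2)))[0]
    cols = np.where(hits.any(axis=(0, 1)))[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(vol.shape[1], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(vol.shape[2], cols[-1] + 1 + margin)
    return (
        LgeVolume(vol.intensities[:, r0:r1, c0:c1], vol.spacing_mm),
        MyocardiumMap(prob_map.probabilities[:, r0:r1, c0:c1]),
    )


def _harmonize_slices(arr: np.ndarray, n: int = TARGET_SLICES, fill: float = 0.0) -> np.ndarray:
    """Center-crop to n slices if deeper, symmetric zero-pad if shallower."""
    s = arr.shape[0]
    if s == n:
        return arr
    if s > n:
        start = (s - n) // 2
        return arr[start : start + n]
    pad_before = (n - s) // 2
    pad_after = n - s - pad_before
    pad = [(pad_before, pad_after)] + [(0, 0)] * (arr.ndim - 1)
    return np.pad(arr, pad, constant_values=fill)


def standardize(
    vol: LgeVolume,
    prob_map: MyocardiumMap,
    threshold: float = DEFAULT_THRESHOLD,
    equalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a cropped volume to (12, 64, 64) scan + binary mask.

    In-plane resize is bilinear for the scan and nearest-neighbour (then
    re-binarized) for the mask; slice count is harmonized to 12 (center crop /
    symmetric zero-pad with zero mask); the scan undergoes per-volume global
    histogram equalization (rank-preserving) and is rescaled to [0, 1].
    """
    scan = _harmonize_slices(vol.intensities)
    mask = _harmonize_slices((prob_map.probabilities >= threshold).astype(float))
    scan64 = np.stack(
        [resize(sl, (TARGET_SIZE, TARGET_SIZE), order=1, anti_aliasing=False) for sl in scan]
    )
    mask64 = np.stack(
        [resize(sl, (TARGET_SIZE, TARGET_SIZE), order=0, anti_aliasing=False) for sl in mask]
    )
    mask64 = (mask64 >= 0.5).astype(float)
    if equalize and np.ptp(scan64) > 0:
        scan64 = exposure.equalize_hist(scan64)
    rng = np.ptp(scan64)
    scan64 = (scan64 - scan64.min()) / rng if rng > 0 else np.zeros_like(scan64)
    return scan64, mask64


def assemble_input(vol64: np.ndarray, mask64: np.ndarray) -> ModelInputVolume:
    """Layer mask over scan: channel 0 = scan * mask, channel 1 = mask."""
    vol64 = np.asarray(vol64, dtype=float)
    mask64 = np.asarray(mask64, dtype=float)
    if vol64.shape != mask64.shape:
        raise ValueError(f"shape mismatch: {vol64.shape} vs {mask64.shape}")
    return ModelInputVolume(np.stack([vol64 * mask64, mask64], axis=-1))


def preprocess_volume(
    vol: LgeVolume,
    backend,
    threshold: float = DEFAULT_THRESHOLD,
    margin: int = DEFAULT_MARGIN,
) -> ModelInputVolume:
    """Full chain: segment -> crop ROI -> standardize -> assemble."""
    prob_map = segment_myocardium(vol, backend)
    cvol, cmap = crop_roi(vol, prob_map, threshold, margin)
    vol64, mask64 = standardize(cvol, cmap, threshold)
    return assemble_input(vol64, mask64)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_volume_nifti(path) -> LgeVolume:
    import nibabel as nib

    img = nib.load(path)
    arr = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    if arr.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume")
    # stored (col, row, slice) when written by write_cohort; heuristically put
    # the smallest axis (slice count) first
    slice_axis = int(np.argmin(arr.shape))
    arr = np.moveaxis(arr, slice_axis, 0)
    spacing = (float(zooms[slice_axis]),) + tuple(float(z) for i, z in enumerate(zooms) if i != slice_axis)
    return LgeVolume(arr, spacing_mm=spacing)  # type: ignore[arg-type]


def write_model_input(mi: ModelInputVolume, out_dir, stem: str) -> Path:
    """Store a ModelInputVolume as 4D NIfTI + JSON sidecar fixing channel order."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{stem}.nii.gz"
    nib.save(nib.Nifti1Image(mi.data.astype(np.float32), np.eye(4)), path)
    sidecar = {"channel_order": ["scan", "mask"], "shape": list(mi.data.shape)}
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return path
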