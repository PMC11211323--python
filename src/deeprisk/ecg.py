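"""12-lead ECG preprocessing: raw record -> normalized per-lead mean beat.

Chain: downsample to 250 Hz -> Savitzky-Golay smoothing + low-resolution
Fourier-series baseline removal -> R-peak detection on a reference lead ->
window extraction around each R peak -> cross-correlation alignment ->
per-lead averaging -> per-lead normalization (z-score by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly, savgol_filter

from .simulate import LEAD_NAMES

TARGET_FS = 250.0
#: beat window: 200 ms before to 400 ms after the R peak
BEAT_WINDOW_S = (0.2, 0.4)


class InsufficientBeatsError(RuntimeError):
    """Fewer than 3 usable beats available for averaging."""


@dataclass(frozen=True)
class EcgRecord:
    """A raw or preprocessed multichannel ECG (millivolts)."""

    signals: np.ndarray  # (12, T)
    fs_hz: float
    lead_names: Sequence[str] = LEAD_NAMES

    def __post_init__(self):
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "signals", sig)
        if sig.ndim != 2 or sig.shape[0] != len(self.lead_names):
            raise ValueError(f"signals must be (n_leads, T); got {sig.shape}")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class MeanBeatSet:
    """Per-lead mean P-QRS-T waveforms, aligned at the R peak."""

    beats: np.ndarray  # (12, L)
    fs_hz: float
    alignment_index: int  # sample index of the R peak within the window
    normalization: str = "zscore"

    def __post_init__(self):
        b = np.asarray(self.beats, dtype=float)
        object.__setattr__(self, "beats", b)
        if b.ndim != 2:
            raise ValueError("beats must be (n_leads, L)")
        if not (0 <= self.alignment_index < b.shape[1]):
            raise ValueError("alignment_index outside window")


def resample(rec: EcgRecord, target_fs: float = TARGET_FS) -> EcgRecord:
    """Anti-aliased downsampling to ``target_fs`` (polyphase filtering).

    Upsampling is refused: the pipeline only ever reduces the sampling rate.
    """
    if rec.fs_hz < target_fs:
        raise ValueError(f"refusing to upsample from {rec.fs_hz} to {target_fs} Hz")
    if rec.fs_hz == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs_hz).limit_denominator(1000)
    # linear-fit padding avoids edge transients on offset/wandering signals
    out = resample_poly(rec.signals, frac.numerator, frac.denominator, axis=1, padtype="line")
    return EcgRecord(signals=out, fs_hz=target_fs, lead_names=rec.lead_names)


def denoise_and_detrend(
    rec: EcgRecord, sg_window: int = 31, sg_polyorder: int = 5, baseline_cutoff_hz: float = 0.5
) -> EcgRecord:
    """Savitzky-Golay smoothing, then truncated-Fourier baseline subtraction.

    The baseline estimate per lead is the inverse FFT of the record restricted
    to frequency bins strictly below ``baseline_cutoff_hz`` (DC included) —
    a "low-resolution" Fourier-series fit of the slow wander.
    """
    if sg_window > rec.n_samples:
        raise ValueError("Savitzky-Golay window longer than signal")
    smoothed = savgol_filter(rec.signals, sg_window, sg_polyorder, axis=1)
    spectrum = np.fft.rfft(smoothed, axis=1)
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.fs_hz)
    low = np.zeros_like(spectrum)
    keep = freqs < baseline_cutoff_hz
    low[:, keep] = spectrum[:, keep]
    baseline = np.fft.irfft(low, n=rec.n_samples, axis=1)
    return EcgRecord(signals=smoothed - baseline, fs_hz=rec.fs_hz, lead_names=rec.lead_names)


def detect_r_peaks(
    rec: EcgRecord, reference_lead: str = "II", refractory_s: float = 0.2
) -> np.ndarray:
    """R-peak sample indices from squared-derivative energy on one lead.

    Pan-Tompkins-style: differentiate, square, integrate over a 120 ms moving
    window, threshold adaptively at a fraction of the upper energy quantile,
    enforce a refractory gap, then refine each detection to the local extremum
    of the reference lead. Indices are shared across leads.
    """
    lead = rec.signals[list(rec.lead_names).index(reference_lead)]
    fs = rec.fs_hz
    d = np.diff(lead, prepend=lead[:1])
    energy = d * d
    win = max(3, int(round(0.12 * fs)))
    kernel = np.ones(win) / win
    energy = np.convolve(energy, kernel, mode="same")
    top = np.quantile(energy, 0.995)
    if top <= 0:
        return np.array([], dtype=int)
    threshold = 0.25 * top
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(energy, height=threshold, distance=max(1, int(round(refractory_s * fs))))
    if peaks.size == 0:
        return np.array([], dtype=int)
    # refine: local |lead| maximum within +/-60 ms of the energy peak
    half = int(round(0.06 * fs))
    refined = []
    for pk in peaks:
        lo, hi = max(0, pk - half), min(lead.size, pk + half + 1)
        refined.append(lo + int(np.argmax(np.abs(lead[lo:hi]))))
    refined_arr = np.array(sorted(set(refined)), dtype=int)
    # re-enforce the refractory gap after refinement
    keep = [int(refined_arr[0])]
    for idx in refined_arr[1:]:
        if idx - keep[-1] >= refractory_s * fs:
            keep.append(int(idx))
    return np.array(keep, dtype=int)


def _window_lengths(fs: float, window_s=BEAT_WINDOW_S) -> tuple[int, int]:
    return int(round(window_s[0] * fs)), int(round(window_s[1] * fs))


def extract_mean_beats(
    rec: EcgRecord,
    peaks: np.ndarray,
    window_s: tuple[float, float] = BEAT_WINDOW_S,
    max_lag: int = 10,
    reference_lead: str = "II",
) -> MeanBeatSet:
    """Average cross-correlation-aligned beats per lead (pre-normalization).

    Each beat is a fixed window around its R peak; beats whose window would
    overrun the record are dropped. The first in-bounds beat (reference lead)
    is the alignment template; every other beat is shifted by the integer lag
    (within ``+/- max_lag`` samples) maximising its cross-correlation with the
    template, the same shift applied to all leads.
    """
    pre, post = _window_lengths(rec.fs_hz, window_s)
    L = pre + post
    peaks = np.asarray(peaks, dtype=int)
    usable = peaks[(peaks - pre - max_lag >= 0) & (peaks + post + max_lag <= rec.n_samples)]
    if usable.size < 3:
        raise InsufficientBeatsError(f"only {usable.size} usable beats (need >= 3)")
    ref_idx = list(rec.lead_names).index(reference_lead)
    template = rec.signals[ref_idx, usable[0] - pre : usable[0] + post]
    stacks = []
    for pk in usable:
        lags = np.arange(-max_lag, max_lag + 1)
        scores = [
            float(np.dot(template, rec.signals[ref_idx, pk + lag - pre : pk + lag + post]))
            for lag in lags
        ]
        best = int(lags[int(np.argmax(scores))])
        stacks.append(rec.signals[:, pk + best - pre : pk + best + post])
    mean = np.mean(np.stack(stacks), axis=0)
    assert mean.shape[1] == L
    return MeanBeatSet(beats=mean, fs_hz=rec.fs_hz, alignment_index=pre, normalization="none")


def normalize_beats(beats: MeanBeatSet, mode: str = "zscore") -> MeanBeatSet:
    """Per-lead normalization of a mean-beat set.

    ``zscore`` (default) maps each lead to mean 0 / SD 1; ``minmax`` maps to
    [0, 1]. A constant lead maps to all-zeros in either mode.
    """
    x = beats.beats
    if mode == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        out = np.where(sd > 1e-12, (x - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    elif mode == "minmax":
        lo = x.min(axis=1, keepdims=True)
        rng = x.max(axis=1, keepdims=True) - lo
        out = np.where(rng > 1e-12, (x - lo) / np.where(rng > 1e-12, rng, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return MeanBeatSet(out, beats.fs_hz, beats.alignment_index, normalization=mode)


def preprocess_ecg(
    rec: EcgRecord,
    sg_window: int = 31,
    sg_polyorder: int = 5,
    baseline_cutoff_hz: float = 0.5,
    normalization: str = "zscore",
) -> MeanBeatSet:
    """Full chain: resample -> denoise/detrend -> R peaks -> mean beats -> normalize."""
    rec = resample(rec)
    rec = denoise_and_detrend(rec, sg_window, sg_polyorder, baseline_cutoff_hz)
    peaks = detect_r_peaks(rec)
    beats = extract_mean_beats(rec, peaks)
    return normalize_beats(beats, normalization)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_ecg_csv(path, fs_hz: float, lead_names: Sequence[str] = LEAD_NAMES) -> EcgRecord:
    """Read a per-lead CSV (one column per lead, one row per sample)."""
    df = pd.read_csv(path)
    missing = [ln for ln in lead_names if ln not in df.columns]
    if missing:
        raise ValueError(f"CSV missing leads: {missing}")
    return EcgRecord(signals=df[list(lead_names)].to_numpy(float).T, fs_hz=fs_hz, lead_names=lead_names)


def write_mean_beats(beats: MeanBeatSet, out_dir, stem: str = "mean_beats") -> Path:
    """Write a MeanBeatSet as CSV (12 x L) plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    pd.DataFrame(beats.beats, index=list(LEAD_NAMES)).to_csv(csv_path, header=False)
    sidecar = {
        "fs_hz": beats.fs_hz,
        "alignment_index": beats.alignment_index,
        "normalization": beats.normalization,
        "n_samples": int(beats.beats.shape[1]),
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_mean_beats(csv_path) -> MeanBeatSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, header=None, index_col=0)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return MeanBeatSet(
        beats=df.to_numpy(float),
        fs_hz=sidecar["fs_hz"],
        alignment_index=sidecar["alignment_index"],
        normalization=sidecar["normalization"],
    )
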