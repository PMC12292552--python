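"""Baseline acoustic representations.

Two utterance-level feature sets back the classical baselines:

* **MFCC** — 13 mel-frequency cepstral coefficients (including c0) computed
  on 25 ms Hamming windows with a 5 ms shift, augmented with first and second
  temporal derivatives (delta, delta-delta) and averaged over frames, giving
  one 39-dimensional vector per utterance.
* **eGeMAPS** — the 88 standardized prosodic/phonatory/spectral functionals
  of the extended Geneva minimalistic acoustic parameter set.  These are
  produced by an external extractor (openSMILE eGeMAPSv02); this module only
  validates and ingests the resulting table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fftpack import dct

from .audio import AudioClip

__all__ = ["UtteranceFeatureVector", "mfcc_utterance_vector", "mfcc_frames",
           "ingest_egemaps", "EGEMAPS_DIM", "MFCC_DIM"]

MFCC_DIM = 39
EGEMAPS_DIM = 88

_LOG_FLOOR = 1e-10  # energy floor before the log step (silent / padded frames)


@dataclass
class UtteranceFeatureVector:
    values: np.ndarray
    feature_set: str  # "MFCC" | "eGeMAPS"
    speaker_id: str = ""
    label: str = ""
    sentence_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = {"MFCC": MFCC_DIM, "eGeMAPS": EGEMAPS_DIM}.get(self.feature_set)
        if expected is None:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.values.shape != (expected,):
            raise ValueError(f"{self.feature_set} vector must have length {expected}, "
                             f"got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _hz_to_mel(hz):
    return 2595.0 * np.log10(1.0 + np.asarray(hz) / 700.0)


def _mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, sr: int) -> np.ndarray:
    """Triangular mel filterbank over the rFFT bins (0 .. Nyquist)."""
    mel_points = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sr / 2.0), n_filters + 2)
    hz_points = _mel_to_hz(mel_points)
    bins = np.floor((n_fft + 1) * hz_points / sr).astype(int)
    fbank = np.zeros((n_filters, n_fft // 2 + 1))
    for m in range(1, n_filters + 1):
        left, centre, right = bins[m - 1], bins[m], bins[m + 1]
        for k in range(left, centre):
            if centre > left:
                fbank[m - 1, k] = (k - left) / (centre - left)
        for k in range(centre, right):
            if right > centre:
                fbank[m - 1, k] = (right - k) / (right - centre)
    return fbank


def _delta(feats: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-based temporal derivative along the frame axis."""
    denom = 2.0 * sum(i * i for i in range(1, width + 1))
    padded = np.pad(feats, ((width, width), (0, 0)), mode="edge")
    out = np.zeros_like(feats)
    for i in range(1, width + 1):
        out += i * (padded[width + i:padded.shape[0] - width + i]
                    - padded[width - i:padded.shape[0] - width - i])
    return out / denom


def mfcc_frames(clip: AudioClip, n_mfcc: int = 13, n_filters: int = 26,
                frame_seconds: float = 0.025, hop_seconds: float = 0.005) -> np.ndarray:
    """Frame-level MFCC matrix (n_frames x n_mfcc), Hamming-windowed."""
    sr = clip.sample_rate
    frame = int(round(frame_seconds * sr))
    hop = int(round(hop_seconds * sr))
    x = clip.samples
    if x.size < frame:
        raise ValueError("clip shorter than one analysis frame")
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame)
    n_fft = int(2 ** np.ceil(np.log2(frame)))
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2 / n_fft
    fbank = _mel_filterbank(n_filters, n_fft, sr)
    energies = np.maximum(power @ fbank.T, _LOG_FLOOR)
    return dct(np.log(energies), type=2, axis=1, norm="ortho")[:, :n_mfcc]


def mfcc_utterance_vector(clip: AudioClip) -> UtteranceFeatureVector:
    """39-dim utterance vector: frame-mean of 13 MFCCs + deltas + delta-deltas."""
    static = mfcc_frames(clip)
    d1 = _delta(static)
    d2 = _delta(d1)
    per_frame = np.hstack([static, d1, d2])  # n_frames x 39
    return UtteranceFeatureVector(values=per_frame.mean(axis=0), feature_set="MFCC",
                                  speaker_id=clip.speaker_id, label=clip.label,
                                  sentence_id=clip.sentence_id)


def ingest_egemaps(table: pd.DataFrame, id_columns: tuple[str, ...] = ("speaker_id", "label", "sentence_id")) -> list[UtteranceFeatureVector]:
    """Validate and ingest an externally-extracted 88-feature table.

    Every non-id column is treated as a feature; there must be exactly 88 of
    them, all finite numerics.  Raises with an explicit message on a wrong
    column count or on rows containing missing / non-finite entries.
    """
    feature_cols = [c for c in table.columns if c not in id_columns]
    if len(feature_cols) != EGEMAPS_DIM:
        raise ValueError(f"eGeMAPS table must carry exactly {EGEMAPS_DIM} feature columns, "
                         f"found {len(feature_cols)}")
    values = table[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad_rows = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    if bad_rows.size:
        raise ValueError(f"eGeMAPS table has non-finite or missing entries in rows "
                         f"{bad_rows.tolist()}")
    vectors = []
    for i in range(len(table)):
        meta = {col: str(table.iloc[i][col]) for col in id_columns if col in table.columns}
        vectors.append(UtteranceFeatureVector(
            values=values[i], feature_set="eGeMAPS",
            speaker_id=meta.get("speaker_id", ""), label=meta.get("label", ""),
            sentence_id=meta.get("sentence_id", "")))
    return vectors
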