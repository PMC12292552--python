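"""Standardisation of raw recordings to the fixed model input.

Pipeline order: resample to the target rate, trim leading/trailing silence by
an energy frame scan, then pad/truncate to the fixed clip length.  A low-pass
filter augmentation is provided for training data only; the training loader
is the single call site, so evaluation data can never pass through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioClip

__all__ = ["PreprocessConfig", "trim_silence", "standardize", "augment_lowpass",
           "split_train_test", "prepare_clip", "assert_speaker_disjoint",
           "EmptyAfterTrimError"]


class EmptyAfterTrimError(ValueError):
    """The whole clip fell below the silence threshold."""


@dataclass
class PreprocessConfig:
    target_rate: int = 16000
    target_seconds: float = 5.0
    trim_threshold_db: float = 40.0     # below the clip's max frame RMS
    trim_frame_seconds: float = 0.025
    trim_hop_seconds: float = 0.010
    augment_probability: float = 0.5
    lowpass_cutoff_range: tuple[float, float] = (2000.0, 7000.0)

    def __post_init__(self):
        if self.target_rate <= 0 or self.target_seconds <= 0:
            raise ValueError("target_rate and target_seconds must be positive")
        lo, hi = self.lowpass_cutoff_range
        if not (0 < lo < hi < self.target_rate / 2):
            raise ValueError("lowpass cutoff range must lie within (0, Nyquist)")
        if not 0.0 <= self.augment_probability <= 1.0:
            raise ValueError("augment_probability must be in [0, 1]")

    @property
    def target_length(self) -> int:
        return int(round(self.target_rate * self.target_seconds))


def _resample(samples: np.ndarray, rate_in: int, rate_out: int) -> np.ndarray:
    """Polyphase resampling with a Kaiser window."""
    from math import gcd

    g = gcd(rate_in, rate_out)
    return signal.resample_poly(samples, rate_out // g, rate_in // g, window=("kaiser", 5.0))


def _frame_rms(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    if x.size < frame:
        return np.array([np.sqrt(np.mean(x ** 2))])
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.sqrt(np.mean(x[idx] ** 2, axis=1))


def trim_silence(clip: AudioClip, config: PreprocessConfig | None = None) -> AudioClip:
    """Remove leading and trailing low-energy frames.

    A frame is silent when its RMS is more than ``trim_threshold_db`` below
    the loudest frame's RMS.  Interior silence is preserved.
    """
    config = config or PreprocessConfig()
    frame = max(1, int(round(config.trim_frame_seconds * clip.sample_rate)))
    hop = max(1, int(round(config.trim_hop_seconds * clip.sample_rate)))
    rms = _frame_rms(clip.samples, frame, hop)
    peak = rms.max()
    if peak <= 0:
        raise EmptyAfterTrimError(f"clip {clip.speaker_id}/{clip.sentence_id} is all zeros")
    threshold = peak * 10.0 ** (-config.trim_threshold_db / 20.0)
    keep = np.flatnonzero(rms >= threshold)
    if keep.size == 0:
        raise EmptyAfterTrimError(f"clip {clip.speaker_id}/{clip.sentence_id} entirely below threshold")
    start = keep[0] * hop
    end = min(keep[-1] * hop + frame, clip.samples.size)
    return clip.with_samples(clip.samples[start:end])


def standardize(clip: AudioClip, config: PreprocessConfig | None = None) -> AudioClip:
    """Resample to ``target_rate`` and fix length to ``target_seconds``.

    Shorter clips are zero-padded at the end; longer clips keep their head.
    """
    config = config or PreprocessConfig()
    samples = clip.samples
    if clip.sample_rate != config.target_rate:
        samples = _resample(samples, clip.sample_rate, config.target_rate)
    target = config.target_length
    if samples.size >= target:
        samples = samples[:target]
    else:
        samples = np.concatenate([samples, np.zeros(target - samples.size)])
    return clip.with_samples(samples, sample_rate=config.target_rate)


def augment_lowpass(clip: AudioClip, config: PreprocessConfig | None = None,
                    seed: int = 0) -> AudioClip:
    """Training-only augmentation: random low-pass filtering.

    With probability ``augment_probability`` applies an 8th-order Butterworth
    low-pass with cutoff drawn uniformly from ``lowpass_cutoff_range``;
    otherwise returns the clip unchanged.  Output length always equals input
    length.
    """
    config = config or PreprocessConfig()
    rng = np.random.default_rng(seed)
    if rng.random() >= config.augment_probability:
        return clip
    lo, hi = config.lowpass_cutoff_range
    cutoff = rng.uniform(lo, hi)
    sos = signal.butter(8, cutoff, btype="low", fs=clip.sample_rate, output="sos")
    return clip.with_samples(signal.sosfilt(sos, clip.samples))


def prepare_clip(clip: AudioClip, config: PreprocessConfig | None = None) -> AudioClip:
    """Full evaluation-path preprocessing: resample → trim → fix length."""
    config = config or PreprocessConfig()
    if clip.sample_rate != config.target_rate:
        clip = clip.with_samples(_resample(clip.samples, clip.sample_rate, config.target_rate),
                                 sample_rate=config.target_rate)
    clip = trim_silence(clip, config)
    return standardize(clip, config)


def split_train_test(clips: list[AudioClip], test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[list[AudioClip], list[AudioClip]]:
    """Speaker-disjoint stratified train/test split.

    Speakers (not clips) are partitioned; per class, the closest integer
    number of speakers to ``test_fraction`` goes to the test side (at least
    one).  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for clip in clips:
        by_class.setdefault(clip.label, [])
        if clip.speaker_id not in by_class[clip.label]:
            by_class[clip.label].append(clip.speaker_id)
    rng = np.random.default_rng(seed)
    test_speakers: set[str] = set()
    for label in sorted(by_class):
        speakers = sorted(by_class[label])
        if len(speakers) < 2:
            raise ValueError(f"need at least 2 speakers in class {label} to split")
        n_test = int(round(test_fraction * len(speakers)))
        n_test = min(max(n_test, 1), len(speakers) - 1)
        order = rng.permutation(len(speakers))
        test_speakers.update(speakers[i] for i in order[:n_test])
    train = [c for c in clips if c.speaker_id not in test_speakers]
    test = [c for c in clips if c.speaker_id in test_speakers]
    return train, test


def assert_speaker_disjoint(*clip_sets: list[AudioClip]) -> None:
    """Raise if any speaker appears in more than one of the given sets."""
    seen: dict[str, int] = {}
    for i, clips in enumerate(clip_sets):
        speakers = {c.speaker_id for c in clips}
        for s in speakers:
            if s in seen and seen[s] != i:
                raise ValueError(f"speaker {s} leaks across partitions {seen[s]} and {i}")
            seen[s] = i
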