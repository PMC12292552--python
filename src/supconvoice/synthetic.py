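"""Synthetic two-class voice cohort with controllable dysphonia cues.

Emulates the structure of a sentence-repetition voice study: two speaker
groups (healthy controls, HC, and a patient group, PD), a fixed set of
sentence types repeated by every speaker, and variable utterance durations.
Speech is synthesised with a source–filter model: a glottal pulse train with
cycle-to-cycle frequency perturbation (jitter) and amplitude perturbation
(shimmer), passed through a cascade of formant resonators, with additive
aspiration noise, alternating voiced segments and pauses at the speaker's
speech rate.

The class signal is carried purely by phonatory/prosodic statistics — the
cues reported for hypokinetic dysarthric speech: elevated jitter and shimmer,
compressed F0 range (monotonicity), extra breath noise, reduced intensity and
a slightly slowed speech rate.  ``effect_size = 0`` makes the two class
distributions identical; the group differences grow monotonically with
``effect_size``.  The synthesis is not intelligible speech and makes no
attempt at phonetic realism; see the methods note for what that implies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .audio import HC, PD, AudioClip

__all__ = ["SpeakerProfile", "CohortConfig", "synth_utterance", "make_cohort",
           "sample_speaker_profile"]

# Healthy-speaker priors (means / sds of the per-speaker parameter draws).
# Jitter and shimmer levels follow the conventional dysphonia ranges
# (sub-percent jitter, few-percent shimmer for modal voice).
HC_PRIORS = {
    "log_f0_mean": np.log(130.0), "log_f0_sd": 0.20,   # Hz, log-normal
    "f0_range_mean": 4.0, "f0_range_sd": 1.0,          # semitones
    "jitter_mean": 0.008, "jitter_sd": 0.002,          # fraction of period
    "shimmer_mean": 0.04, "shimmer_sd": 0.010,         # fraction of amplitude
    "breath_mean": 0.020, "breath_sd": 0.005,          # linear amplitude
    "rate_mean": 4.0, "rate_sd": 0.4,                  # syllables / s
    "intensity_mean": 0.25, "intensity_sd": 0.03,      # linear peak amplitude
}

# Additive / multiplicative shifts applied to a PD speaker per unit
# effect_size.  All monotone; zero effect gives the HC distribution.
PD_SHIFTS = {
    "jitter_add": 0.008,
    "shimmer_add": 0.030,
    "breath_add": 0.030,
    "f0_range_log_mult": -0.35,
    "intensity_log_mult": -0.18,
    "rate_log_mult": -0.08,
}


@dataclass
class SpeakerProfile:
    """Per-speaker voice-source parameters."""

    speaker_id: str
    class_label: str
    base_f0: float            # Hz
    f0_range: float           # semitones, peak-to-peak prosodic excursion
    base_jitter: float        # cycle-to-cycle F0 perturbation fraction
    base_shimmer: float       # cycle-to-cycle amplitude perturbation fraction
    breath_noise_level: float # linear amplitude of aspiration noise
    speech_rate: float        # syllables / s
    intensity: float = 0.25   # linear peak amplitude
    sample_rate: int = 16000

    def __post_init__(self):
        if self.class_label not in (HC, PD):
            raise ValueError(f"class_label must be HC or PD, got {self.class_label!r}")
        if self.base_f0 <= 0 or self.speech_rate <= 0 or self.sample_rate <= 0:
            raise ValueError("base_f0, speech_rate and sample_rate must be positive")
        if not (0 <= self.base_jitter < 1 and 0 <= self.base_shimmer < 1):
            raise ValueError("jitter and shimmer must lie in [0, 1)")


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic cohort."""

    n_speakers_per_class: int = 10
    sentences_per_speaker: int = 16
    duration_range: tuple[float, float] = (2.0, 8.0)
    effect_size: float = 1.0
    sample_rate: int = 16000
    seed: int = 0

    def __post_init__(self):
        if self.n_speakers_per_class < 1 or self.sentences_per_speaker < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.duration_range
        if not (0 < lo < hi):
            raise ValueError("duration_range must satisfy 0 < min < max")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def sample_speaker_profile(speaker_id: str, class_label: str, effect_size: float,
                           rng: np.random.Generator, sample_rate: int = 16000) -> SpeakerProfile:
    """Draw one speaker from the class-conditional parameter priors."""
    p = HC_PRIORS
    base_f0 = float(np.exp(rng.normal(p["log_f0_mean"], p["log_f0_sd"])))
    f0_range = float(np.clip(rng.normal(p["f0_range_mean"], p["f0_range_sd"]), 0.5, 12.0))
    jitter = float(np.clip(rng.normal(p["jitter_mean"], p["jitter_sd"]), 1e-4, 0.3))
    shimmer = float(np.clip(rng.normal(p["shimmer_mean"], p["shimmer_sd"]), 1e-3, 0.6))
    breath = float(np.clip(rng.normal(p["breath_mean"], p["breath_sd"]), 0.0, 0.5))
    rate = float(np.clip(rng.normal(p["rate_mean"], p["rate_sd"]), 1.5, 8.0))
    intensity = float(np.clip(rng.normal(p["intensity_mean"], p["intensity_sd"]), 0.05, 0.95))
    if class_label == PD:
        e = effect_size
        s = PD_SHIFTS
        jitter = float(np.clip(jitter + s["jitter_add"] * e, 1e-4, 0.3))
        shimmer = float(np.clip(shimmer + s["shimmer_add"] * e, 1e-3, 0.6))
        breath = float(np.clip(breath + s["breath_add"] * e, 0.0, 0.5))
        f0_range = float(np.clip(f0_range * np.exp(s["f0_range_log_mult"] * e), 0.1, 12.0))
        intensity = float(np.clip(intensity * np.exp(s["intensity_log_mult"] * e), 0.02, 0.95))
        rate = float(np.clip(rate * np.exp(s["rate_log_mult"] * e), 1.0, 8.0))
    return SpeakerProfile(speaker_id=speaker_id, class_label=class_label, base_f0=base_f0,
                          f0_range=f0_range, base_jitter=jitter, base_shimmer=shimmer,
                          breath_noise_level=breath, speech_rate=rate, intensity=intensity,
                          sample_rate=sample_rate)


def _sentence_template(sentence_id: str, n_syllables: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-sentence prosody contour and formant track.

    The same sentence id yields the same contour shape and formant sequence
    for every speaker, giving sentences a stable identity in the cohort.
    Returns (contour coefficients, formant table of shape n_syllables x 3).
    """
    rng = np.random.default_rng(np.random.SeedSequence([_stable_hash(sentence_id), 0x5E47]))
    # prosodic contour: two slow sinusoids, amplitude-normalised to [-0.5, 0.5]
    contour_coeff = rng.uniform(-1.0, 1.0, size=4)
    f1 = rng.uniform(300.0, 800.0, size=n_syllables)
    f2 = rng.uniform(900.0, 2200.0, size=n_syllables)
    f3 = rng.uniform(2400.0, 3000.0, size=n_syllables)
    return contour_coeff, np.column_stack([f1, f2, f3])


def _contour(coeff: np.ndarray, t_frac: np.ndarray) -> np.ndarray:
    """Slow prosodic contour in [-0.5, 0.5] over normalised time."""
    raw = (coeff[0] * np.sin(2 * np.pi * (0.5 * t_frac + coeff[1]))
           + coeff[2] * np.sin(2 * np.pi * (1.0 * t_frac + coeff[3])))
    peak = max(np.max(np.abs(raw)), 1e-9)
    return 0.5 * raw / peak


def _resonator_sos(freqs_hz: np.ndarray, sr: int) -> np.ndarray:
    """Cascade of 2nd-order resonators (formants) as SOS sections."""
    bandwidths = np.array([80.0, 120.0, 160.0])[: len(freqs_hz)]
    sections = []
    for f, bw in zip(freqs_hz, bandwidths):
        r = np.exp(-np.pi * bw / sr)
        theta = 2 * np.pi * f / sr
        # unit-gain-at-peak resonator: y[n] = x[n] + 2r cosθ y[n-1] - r² y[n-2]
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        g = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
        sections.append([g, 0.0, 0.0, *a])
    return np.asarray(sections)


def synth_utterance(profile: SpeakerProfile, sentence_id: str, duration: float,
                    seed: int) -> AudioClip:
    """Synthesise one utterance; bit-deterministic in all four arguments."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    sr = profile.sample_rate
    n = int(round(duration * sr))
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed & 0x7FFFFFFF, _stable_hash(profile.speaker_id), _stable_hash(sentence_id),
         int(round(duration * 1e6))]))

    syllable_period = 1.0 / profile.speech_rate
    n_syllables = max(1, int(np.floor(duration / syllable_period)))
    contour_coeff, formants = _sentence_template(sentence_id, max(n_syllables, 1))

    out = np.zeros(n)
    voiced_mask = np.zeros(n, dtype=bool)
    voiced_frac = 0.75  # voiced portion of each syllable slot

    for k in range(n_syllables):
        seg_start = int(round(k * syllable_period * sr))
        seg_len = int(round(voiced_frac * syllable_period * sr))
        seg_end = min(seg_start + seg_len, n)
        if seg_end - seg_start < int(0.02 * sr):
            continue
        # glottal pulse train with jitter / shimmer over the segment
        excitation = np.zeros(seg_end - seg_start)
        t = 0.0
        seg_dur = (seg_end - seg_start) / sr
        while t < seg_dur:
            t_frac = (seg_start / sr + t) / duration
            semis = _contour(contour_coeff, np.array([t_frac]))[0] * profile.f0_range
            f0 = profile.base_f0 * 2.0 ** (semis / 12.0)
            f0_cycle = f0 * (1.0 + profile.base_jitter * rng.standard_normal())
            f0_cycle = max(f0_cycle, 30.0)
            amp = 1.0 + profile.base_shimmer * rng.standard_normal()
            idx = int(round(t * sr))
            if idx < excitation.size:
                excitation[idx] += amp
            t += 1.0 / f0_cycle
        sos = _resonator_sos(formants[k % len(formants)], sr)
        voiced = signal.sosfilt(sos, excitation)
        peak = max(np.max(np.abs(voiced)), 1e-9)
        out[seg_start:seg_end] += voiced / peak
        voiced_mask[seg_start:seg_end] = True

    # aspiration noise inside voiced segments, faint elsewhere
    noise = rng.standard_normal(n)
    out += profile.breath_noise_level * noise * np.where(voiced_mask, 1.0, 0.1)
    out *= profile.intensity
    out = np.clip(out, -1.0, 1.0)
    return AudioClip(samples=out, sample_rate=sr, speaker_id=profile.speaker_id,
                     label=profile.class_label, sentence_id=sentence_id)


def make_cohort(config: CohortConfig) -> tuple[list[AudioClip], pd.DataFrame]:
    """Generate the full cohort: every speaker utters every sentence once.

    Returns the clips plus a metadata table (speaker_id, label, sentence_id,
    duration_s).  Bit-reproducible from ``config`` alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xC0C0]))
    sentence_ids = [f"S{i + 1:02d}" for i in range(config.sentences_per_speaker)]
    profiles: list[SpeakerProfile] = []
    for label, tag in ((HC, "HC"), (PD, "PD")):
        for i in range(config.n_speakers_per_class):
            profiles.append(sample_speaker_profile(
                f"{tag}{i + 1:03d}", label, config.effect_size, rng, config.sample_rate))
    lo, hi = config.duration_range
    clips: list[AudioClip] = []
    rows = []
    for profile in profiles:
        for sid in sentence_ids:
            duration = float(rng.uniform(lo, hi))
            clip_seed = int(rng.integers(0, 2 ** 31 - 1))
            clip = synth_utterance(profile, sid, duration, clip_seed)
            clips.append(clip)
            rows.append({"speaker_id": profile.speaker_id, "label": profile.class_label,
                         "sentence_id": sid, "duration_s": clip.duration})
    return clips, pd.DataFrame(rows)
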