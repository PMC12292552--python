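"""Audio container and WAV / metadata I/O.

An :class:`AudioClip` is the unit every stage of the pipeline operates on: a
mono floating-point waveform in [-1, 1] plus the identifiers needed for
speaker-independent evaluation (speaker, class label, sentence type).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

HC, PD = "HC", "PD"
LABELS = (HC, PD)

#: integer coding used by classifiers; PD is the positive class
LABEL_TO_INT = {HC: 0, PD: 1}

METADATA_COLUMNS = ["speaker_id", "label", "sentence_id", "path", "duration_s"]


@dataclass
class AudioClip:
    """Mono waveform with speaker / label / sentence metadata."""

    samples: np.ndarray
    sample_rate: int
    speaker_id: str
    label: str
    sentence_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray, sample_rate: int | None = None) -> "AudioClip":
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       sample_rate=int(sample_rate or self.sample_rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, (scaled * 32767.0).astype(np.int16))


def read_wav(path: str | Path, speaker_id: str = "", label: str = HC,
             sentence_id: str = "") -> AudioClip:
    """Read a PCM WAV file; stereo is downmixed by channel averaging."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioClip(samples=data, sample_rate=int(rate), speaker_id=speaker_id,
                     label=label, sentence_id=sentence_id)


def write_cohort(clips: list[AudioClip], out_dir: str | Path) -> pd.DataFrame:
    """Write clips as WAV files plus the metadata CSV; returns the table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for clip in clips:
        name = f"{clip.speaker_id}_{clip.sentence_id}.wav"
        write_wav(out_dir / name, clip)
        rows.append({"speaker_id": clip.speaker_id, "label": clip.label,
                     "sentence_id": clip.sentence_id, "path": name,
                     "duration_s": round(clip.duration, 6)})
    table = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table


def read_cohort(metadata_csv: str | Path) -> list[AudioClip]:
    """Load a cohort from its metadata CSV (paths relative to the CSV)."""
    metadata_csv = Path(metadata_csv)
    table = pd.read_csv(metadata_csv)
    missing = set(METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    clips = []
    for row in table.itertuples(index=False):
        clips.append(read_wav(metadata_csv.parent / row.path, speaker_id=str(row.speaker_id),
                              label=str(row.label), sentence_id=str(row.sentence_id)))
    return clips
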