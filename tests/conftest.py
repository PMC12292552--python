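import numpy as np
import pytest

from supconvoice.audio import AudioClip
from supconvoice.preprocessing import PreprocessConfig
from supconvoice.synthetic import CohortConfig, make_cohort, sample_speaker_profile


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-class cohort: 4 speakers/class x 6 sentences, 1.5-2.5 s."""
    config = CohortConfig(n_speakers_per_class=4, sentences_per_speaker=6,
                          duration_range=(1.5, 2.5), effect_size=2.0, seed=11)
    clips, meta = make_cohort(config)
    return clips, meta, config


@pytest.fixture(scope="session")
def short_preprocess():
    """Preprocessing to 2 s clips at 16 kHz (keeps matrices small)."""
    return PreprocessConfig(target_seconds=2.0)


@pytest.fixture()
def hc_profile():
    rng = np.random.default_rng(0)
    return sample_speaker_profile("HC001", "HC", effect_size=1.0, rng=rng)


@pytest.fixture()
def tone_clip():
    """1 s of a 440 Hz tone bracketed by 0.5 s of exact silence."""
    sr = 16000
    tone = 0.5 * np.sin(2 * np.pi * 440 * np.arange(sr) / sr)
    samples = np.concatenate([np.zeros(sr // 2), tone, np.zeros(sr // 2)])
    return AudioClip(samples=samples, sample_rate=sr, speaker_id="T1",
                     label="HC", sentence_id="S01")


def unit_rows(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """Random points on the unit sphere in R^p."""
    z = rng.standard_normal((n, p))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
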