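"""Encoder contract, dual-head architecture and gradient-blocked forward pass.

The architecture mirrors the usual self-supervised speech fine-tuning setup:
a frame-level encoder maps a fixed-length waveform to a T×d matrix of 20 ms
frame embeddings, which are mean-pooled into an utterance embedding and fed
to two parallel heads:

* a **classification head** (d → 64 → ReLU → dropout → 2 logits), and
* a **projection head** (d → 128 → ReLU → p, L2-normalised) whose unit-norm
  output is the operand of the supervised contrastive loss.

In contrastive mode the classifier receives a gradient-*detached* copy of the
utterance embedding: its cross-entropy loss can never update the encoder, so
representation learning is driven purely by the contrastive objective while
both are trained in a single phase.  In plain cross-entropy mode there is no
detachment and no projection path — ordinary fine-tuning.

Any callable satisfying :class:`EncoderSpec` (waveform batch in, frames out,
selectable layer) can stand behind the heads; :class:`TinyEncoder` is a small
fully-trainable transformer used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm1d, Dropout, LayerNorm, Linear, Module, SelfAttentionBlock

__all__ = ["EncoderSpec", "TinyEncoder", "make_tiny_encoder", "pool_frames",
           "ClassifierHead", "ProjectionHead", "DualHeadModel",
           "SUPCON", "CE_ONLY", "MODES"]

SUPCON = "SUPCON"
CE_ONLY = "CE_ONLY"
MODES = (SUPCON, CE_ONLY)


@dataclass
class EncoderSpec:
    """Contract a frame-level encoder must satisfy."""

    frame_dim: int = 768     # embedding width d
    frame_rate: float = 50.0 # frames per second of audio
    n_layers: int = 12       # selectable output layers 1..n_layers


class TinyEncoder(Module):
    """Small trainable frame encoder: strided conv front-end + attention blocks.

    The front-end is a single strided convolution (kernel = stride = 320
    samples, i.e. a 20 ms hop at 16 kHz) projecting each frame to ``d``
    dimensions, followed by ``n_layers`` pre-norm self-attention blocks.
    ``forward(x, layer=ℓ)`` returns the activations after block ℓ, so
    intermediate layers can be probed exactly as with the large pre-trained
    encoders this stands in for.
    """

    STRIDE = 320

    def __init__(self, d: int = 64, n_layers: int = 2, seed: int = 0,
                 ffn_mult: int = 2):
        if d < 8:
            raise ValueError(f"embedding width must be >= 8, got {d}")
        if n_layers < 1:
            raise ValueError(f"need at least one block, got {n_layers}")
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xE11C]))
        self.d = d
        self.n_layers = n_layers
        # bias-free filterbank: a bias offset would dominate the squared
        # output of low-energy bands and mask quiet spectral cues
        self.frame_proj = Linear(self.STRIDE, 2 * d, rng, bias=False)
        self.frame_proj.weight.data = self._quadrature_init(d).astype(np.float32)
        self.blocks = [SelfAttentionBlock(d, rng, ffn_mult=ffn_mult) for _ in range(n_layers)]
        self.spec = EncoderSpec(frame_dim=d, frame_rate=16000 / self.STRIDE, n_layers=n_layers)

    def __call__(self, x, layer: int | None = None) -> Tensor:
        """Waveform batch (B, L) → frame embeddings (B, T, d), T = L // 320."""
        if layer is None:
            layer = self.n_layers
        if not 1 <= layer <= self.n_layers:
            raise ValueError(f"layer must be in [1, {self.n_layers}], got {layer}")
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        b, length = x.shape
        t = length // self.STRIDE
        if t < 1:
            raise ValueError("waveform shorter than one frame stride")
        frames = x[:, : t * self.STRIDE].reshape(b, t, self.STRIDE)
        # log band energies from quadrature FIR pairs: a trainable
        # spectrogram, phase-invariant at initialisation
        filt = self.frame_proj(frames)
        cos_part, sin_part = filt[:, :, : self.d], filt[:, :, self.d:]
        energy = cos_part * cos_part + sin_part * sin_part
        h = (energy + 1e-8).log() * 0.25  # log band energies, mildly scaled;
        # the floor clamps silent bins to a constant instead of log-noise
        # residual stream is left unnormalised: absolute band levels carry
        # the phonatory cues, and the damped residual branches preserve them
        for block in self.blocks[:layer]:
            h = block(h)
        return h

    def _quadrature_init(self, d: int, sr: int = 16000) -> np.ndarray:
        """Hamming-windowed cos/sin FIR pairs at mel-spaced centre frequencies."""
        mel = np.linspace(2595 * np.log10(1 + 60 / 700), 2595 * np.log10(1 + (sr / 2 - 200) / 700), d)
        freqs = 700 * (10 ** (mel / 2595) - 1)
        n = np.arange(self.STRIDE)
        window = np.hamming(self.STRIDE)
        scale = 2.0 / self.STRIDE
        cos_bank = np.stack([window * np.cos(2 * np.pi * f * n / sr) for f in freqs], axis=1)
        sin_bank = np.stack([window * np.sin(2 * np.pi * f * n / sr) for f in freqs], axis=1)
        return scale * np.concatenate([cos_bank, sin_bank], axis=1)  # (STRIDE, 2d)

    def block_parameters(self):
        """Parameters of the attention blocks only (front-end excluded),
        the set updated when the feature extractor is kept frozen."""
        params = []
        for block in self.blocks:
            params.extend(block.parameters())
        return params

    @property
    def final_block(self) -> SelfAttentionBlock:
        return self.blocks[-1]


def make_tiny_encoder(d: int = 64, n_layers: int = 2, seed: int = 0) -> TinyEncoder:
    """Build the desk-scale encoder with seed-deterministic initialisation."""
    return TinyEncoder(d=d, n_layers=n_layers, seed=seed)


def pool_frames(frames) -> Tensor:
    """Mean over the time axis: (B, T, d) → (B, d), or (T, d) → (d,)."""
    frames = frames if isinstance(frames, Tensor) else Tensor(np.asarray(frames, dtype=float))
    if frames.ndim not in (2, 3):
        raise ValueError(f"expected (T, d) or (B, T, d), got shape {frames.shape}")
    if frames.shape[-2] < 1:
        raise ValueError("cannot pool an empty frame matrix")
    return frames.mean(axis=-2)


class ClassifierHead(Module):
    """d → 64 → ReLU → dropout(0.2) → 2 logits."""

    HIDDEN = 64

    def __init__(self, in_dim: int, n_classes: int = 2, dropout: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xC1A5]))
        self.fc1 = Linear(in_dim, self.HIDDEN, rng)
        self.drop = Dropout(dropout, np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD209])))
        self.fc2 = Linear(self.HIDDEN, n_classes, rng)

    def __call__(self, embedding: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(embedding).relu()))


class ProjectionHead(Module):
    """d → h → ReLU → p, followed by L2 normalisation onto the unit sphere.

    ``p`` (the projection size varied in ablations) defaults to 32; the
    hidden width ``h`` is fixed at 128.  A vanishing pre-normalisation vector
    is epsilon-stabilised so the output is never NaN.
    """

    HIDDEN = 128
    EPS = 1e-12

    def __init__(self, in_dim: int, out_dim: int = 32, seed: int = 0):
        if out_dim < 2:
            raise ValueError(f"projection width must be >= 2, got {out_dim}")
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x9801]))
        self.fc1 = Linear(in_dim, self.HIDDEN, rng)
        self.fc2 = Linear(self.HIDDEN, out_dim, rng)
        self.out_dim = out_dim

    def __call__(self, embedding: Tensor) -> Tensor:
        raw = self.fc2(self.fc1(embedding).relu())
        norm = ((raw * raw).sum(axis=-1, keepdims=True) + self.EPS) ** 0.5
        return raw / norm


@dataclass
class DualHeadOutput:
    logits: Tensor            # (B, 2)
    projection: Tensor | None # (B, p) unit-norm rows, None in CE_ONLY mode
    embedding: Tensor         # (B, d) pooled utterance embedding (live)


class DualHeadModel(Module):
    """Encoder + classification head + projection head with mode switching."""

    def __init__(self, encoder: TinyEncoder, n_classes: int = 2, projection_dim: int = 32,
                 dropout: float = 0.2, seed: int = 0, layer: int | None = None):
        self.encoder = encoder
        self.embed_norm = BatchNorm1d(encoder.spec.frame_dim)
        self.classifier = ClassifierHead(encoder.spec.frame_dim, n_classes, dropout, seed=seed)
        self.projector = ProjectionHead(encoder.spec.frame_dim, projection_dim, seed=seed)
        self.layer = layer

    def embed(self, waveforms) -> Tensor:
        """Standardised pooled utterance embedding (shared trunk of both heads)."""
        frames = self.encoder(waveforms, layer=self.layer)
        return self.embed_norm(pool_frames(frames))

    def __call__(self, waveforms, mode: str = SUPCON) -> DualHeadOutput:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        embedding = self.embed(waveforms)
        if mode == SUPCON:
            projection = self.projector(embedding)
            logits = self.classifier(embedding.detach())  # gradient-blocked path
        else:
            projection = None
            logits = self.classifier(embedding)
        return DualHeadOutput(logits=logits, projection=projection, embedding=embedding)

    def encoder_parameters(self):
        return self.encoder.parameters()

    def head_parameters(self):
        return (self.classifier.parameters() + self.projector.parameters()
                + self.embed_norm.parameters())
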