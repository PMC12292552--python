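"""Gradient-based relevance maps over waveforms and 2-D embedding views.

The relevance map follows the classic class-activation recipe adapted to a
frame-level speech transformer: the hook point is the output projection of
the final self-attention block (a T×d activation matrix A).  Channel weights
are the time-averaged gradients of the target-class logit with respect to A;
the frame relevance is the ReLU of the weighted channel sum, normalised to a
maximum of one and linearly interpolated to sample resolution for overlay on
the waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .audio import LABEL_TO_INT, AudioClip
from .model import DualHeadModel, pool_frames

__all__ = ["RelevanceMap", "grad_cam_map", "embed_2d", "plot_relevance_overlay"]


@dataclass
class RelevanceMap:
    frame_relevance: np.ndarray   # (T,) in [0, 1], max 1 unless all-zero
    sample_relevance: np.ndarray  # (L,) interpolated to the waveform grid
    target_class: str
    is_zero: bool = False         # the raw map was identically zero


def grad_cam_map(model: DualHeadModel, clip: AudioClip | np.ndarray,
                 target_class: str = "PD") -> RelevanceMap:
    """Relevance of each 20 ms frame to the target-class logit.

    The model must expose its final attention block's output-projection
    activations (:class:`TinyEncoder` and any compliant encoder do).
    """
    if target_class not in LABEL_TO_INT:
        raise ValueError(f"target_class must be one of {tuple(LABEL_TO_INT)}")
    waveform = clip.samples if isinstance(clip, AudioClip) else np.asarray(clip, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("expected a single mono waveform")
    encoder = model.encoder
    if not hasattr(encoder, "final_block"):
        raise TypeError("encoder does not expose a final attention block hook; "
                        "relevance mapping requires it")
    model.eval()
    model.zero_grad()
    frames = encoder(waveform[None, :])
    block = encoder.final_block
    activations = block.attn_out  # (1, T, d), recorded during the forward pass
    if activations is None:
        raise TypeError("encoder forward did not record attention output activations")
    logits = model.classifier(model.embed_norm(pool_frames(frames)))
    target = logits[0, LABEL_TO_INT[target_class]]
    target.backward()

    a = activations.data[0]                                      # (T, d)
    grad = activations.grad[0] if activations.grad is not None else np.zeros_like(a)
    weights = grad.mean(axis=0)                                  # time-averaged, per channel
    # weight each frame's *deviation* from the temporal mean: the hook
    # activations are signed log-energy features, so the raw weighted sum
    # would be dominated by their common offset rather than by how much a
    # frame pushes the logit relative to the clip average
    deviations = a - a.mean(axis=0, keepdims=True)
    raw = np.maximum(deviations @ weights, 0.0)                  # (T,)
    peak = raw.max()
    is_zero = bool(peak <= 0.0)
    frame_rel = raw / peak if not is_zero else np.zeros_like(raw)

    t = frame_rel.size
    stride = waveform.size / t
    centres = (np.arange(t) + 0.5) * stride
    sample_rel = np.interp(np.arange(waveform.size), centres, frame_rel)
    return RelevanceMap(frame_relevance=frame_rel, sample_relevance=sample_rel,
                        target_class=target_class, is_zero=is_zero)


def embed_2d(embeddings: np.ndarray, labels=None, seed: int = 0,
             perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of utterance embeddings, deterministic given ``seed``.

    Perplexity is shrunk (with a warning) when the sample count is too small
    for the requested value; fewer than 5 points is an error.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 points for a 2-D embedding, got {n}")
    max_perplexity = (n - 1) / 3.0
    if perplexity > max_perplexity:
        warnings.warn(f"perplexity {perplexity} too large for n={n}; "
                      f"shrinking to {max_perplexity:.1f}")
        perplexity = max_perplexity
    from sklearn.manifold import TSNE

    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(embeddings)


def plot_relevance_overlay(waveform: np.ndarray, relevance: RelevanceMap, path,
                           sample_rate: int = 16000) -> None:
    """Render the waveform coloured by sample relevance to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(waveform.size) / sample_rate
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, waveform, color="0.6", linewidth=0.5)
    ax.scatter(t[::80], waveform[::80], c=relevance.sample_relevance[::80],
               cmap="inferno", s=4, vmin=0.0, vmax=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude")
    ax.set_title(f"relevance toward class {relevance.target_class}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
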