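"""scikit-learn estimator facade over the dual-head contrastive model.

:class:`SupConVoiceClassifier` exposes the whole fine-tuning recipe —
encoder, dual heads, joint contrastive + cross-entropy objective with
gradient blocking, cosine-annealed AdamW, early stopping — through the
standard ``fit`` / ``predict`` / ``predict_proba`` interface, so it composes
with sklearn pipelines and model selection.  ``X`` is a batch of
fixed-length waveforms (one row per standardized clip); pass ``speaker_ids``
to ``fit`` to make the internal validation split speaker-disjoint.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .losses import SupConConfig
from .model import SUPCON, DualHeadModel, make_tiny_encoder
from .training import ClipDataset, TrainConfig, train_model

__all__ = ["SupConVoiceClassifier"]


class SupConVoiceClassifier(BaseEstimator, ClassifierMixin):
    """Speech classifier fine-tuned with supervised contrastive learning.

    Parameters mirror the published recipe; ``mode`` selects contrastive
    training with a gradient-blocked classification head (``"SUPCON"``) or
    plain cross-entropy fine-tuning (``"CE_ONLY"``).
    """

    def __init__(self, mode: str = SUPCON, encoder_dim: int = 64, encoder_layers: int = 2,
                 encoder_layer: int | None = None, projection_dim: int = 32,
                 temperature: float = 0.07, hard_scale: float = 1.5, hard_k: int = 1,
                 hard_negatives: bool = True, epochs: int = 100, batch_size: int = 32,
                 lr: float = 2e-5, encoder_lr: float | None = None,
                 head_consolidation_epochs: int = 5,
                 dropout: float = 0.2, weight_decay: float = 0.01,
                 patience: int = 15, fine_tune_encoder: bool = True,
                 val_fraction: float = 0.2, seed: int = 0):
        self.mode = mode
        self.encoder_dim = encoder_dim
        self.encoder_layers = encoder_layers
        self.encoder_layer = encoder_layer
        self.projection_dim = projection_dim
        self.temperature = temperature
        self.hard_scale = hard_scale
        self.hard_k = hard_k
        self.hard_negatives = hard_negatives
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.encoder_lr = encoder_lr
        self.head_consolidation_epochs = head_consolidation_epochs
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.patience = patience
        self.fine_tune_encoder = fine_tune_encoder
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, speaker_ids=None, sentence_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_clips, n_samples) standardized waveforms")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("expected exactly two classes")
        y_idx = np.searchsorted(self.classes_, y)
        n = X.shape[0]
        speakers = (np.asarray(speaker_ids, dtype=object) if speaker_ids is not None
                    else np.array([f"sp{i}" for i in range(n)], dtype=object))
        sentences = (np.asarray(sentence_ids, dtype=object) if sentence_ids is not None
                     else np.array(["-"] * n, dtype=object))

        rng = np.random.default_rng(self.seed)
        val_speakers: set = set()
        for cls in (0, 1):
            cls_speakers = sorted({s for s, c in zip(speakers, y_idx) if c == cls})
            n_val = min(max(1, int(round(self.val_fraction * len(cls_speakers)))),
                        len(cls_speakers) - 1)
            order = rng.permutation(len(cls_speakers))
            val_speakers.update(cls_speakers[i] for i in order[:n_val])
        val_mask = np.array([s in val_speakers for s in speakers])

        data = ClipDataset(X, y_idx, speakers, sentences)
        encoder = make_tiny_encoder(self.encoder_dim, self.encoder_layers, seed=self.seed)
        model = DualHeadModel(encoder, projection_dim=self.projection_dim,
                              dropout=self.dropout, seed=self.seed, layer=self.encoder_layer)
        config = TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size, initial_lr=self.lr,
            encoder_lr=self.encoder_lr,
            head_consolidation_epochs=self.head_consolidation_epochs,
            weight_decay=self.weight_decay, dropout=self.dropout, patience=self.patience,
            seed=self.seed, mode=self.mode, fine_tune_encoder=self.fine_tune_encoder,
            supcon=SupConConfig(temperature=self.temperature, hard_scale=self.hard_scale,
                                hard_k=self.hard_k, hard_negatives=self.hard_negatives))
        model, history = train_model(model, data.subset(~val_mask), data.subset(val_mask), config)
        self.model_ = model
        self.history_ = history
        return self

    # ------------------------------------------------------------- inference
    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        from .training import _forward_scores

        pd_scores = _forward_scores(self.model_, np.asarray(X, dtype=float))
        return np.column_stack([1.0 - pd_scores, pd_scores])

    def predict(self, X):
        """Class labels at the validation-calibrated decision threshold."""
        check_is_fitted(self, "model_")
        threshold = getattr(self.model_, "decision_threshold_", 0.5)
        pd_scores = self.predict_proba(X)[:, 1]
        return self.classes_[(pd_scores >= threshold).astype(int)]

    def embed(self, X):
        """Pooled utterance embeddings (useful for 2-D visualisation)."""
        check_is_fitted(self, "model_")
        from .model import CE_ONLY

        self.model_.eval()
        X = np.asarray(X, dtype=float)
        outs = []
        for lo in range(0, X.shape[0], 64):
            outs.append(self.model_(X[lo:lo + 64], mode=CE_ONLY).embedding.data)
        return np.vstack(outs)
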