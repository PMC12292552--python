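"""Single-phase joint training and the speaker-independent evaluation protocol.

Training follows the published recipe: AdamW (β₁=0.9, β₂=0.999, weight decay
0.01), initial learning rate annealed by a cosine schedule over the epoch
budget, batch size 32, dropout 0.2, early stopping on validation F1 with the
best-epoch parameters retained.  Evaluation uses a speaker-disjoint 80/20
train/test split and stratified speaker-independent 5-fold cross-validation
inside the training portion: speakers — never clips — are assigned to folds,
each fold's best model is scored on the common held-out test set, and results
are reported as mean ± sample standard deviation across folds together with
the cumulative confusion matrix and a pooled ROC curve.

Leakage guards are unconditional: any configuration that would place a
speaker on two sides of a train/validate/test boundary raises immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import LABEL_TO_INT, AudioClip
from .losses import SupConConfig, combined_objective
from .metrics import (ConfusionCounts, MetricsReport, aggregate_reports,
                      compute_metrics, confusion_from_predictions,
                      cumulative_confusion, per_sentence_accuracy, roc_curve_auc)
from .model import CE_ONLY, MODES, SUPCON, DualHeadModel
from .nn import AdamW, cross_entropy
from .preprocessing import PreprocessConfig, augment_lowpass, prepare_clip

__all__ = ["TrainConfig", "ClipDataset", "dataset_from_clips", "make_folds",
           "train_model", "evaluate_model", "run_cv_experiment", "CVResult",
           "TrainHistory"]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    initial_lr: float = 2e-5
    #: learning rate for encoder parameters; None = same as initial_lr.
    #: fine-tuning wants a much smaller step on the encoder than on the
    #: freshly-initialised heads, mirroring standard pre-trained fine-tuning
    encoder_lr: float | None = None
    #: keep the convolutional feature extractor fixed while fine-tuning the
    #: attention blocks — the standard recipe for frame-level speech encoders
    freeze_frontend: bool = True
    #: extra classifier-only epochs after the joint schedule (contrastive
    #: mode only).  The classification pathway is gradient-blocked, so these
    #: epochs cannot alter the representation — they only let the blocked
    #: head finish converging on the final embeddings
    head_consolidation_epochs: int = 0
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    dropout: float = 0.2
    patience: int = 15
    seed: int = 0
    mode: str = SUPCON
    fine_tune_encoder: bool = True
    supcon: SupConConfig = field(default_factory=SupConConfig)

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.initial_lr <= 0:
            raise ValueError("epochs must be >= 0, batch_size >= 1, initial_lr > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class ClipDataset:
    """Standardized clips as dense arrays, metadata kept aligned."""

    waveforms: np.ndarray       # (N, L) float
    labels: np.ndarray          # (N,) int, 1 = PD
    speaker_ids: np.ndarray     # (N,) str
    sentence_ids: np.ndarray    # (N,) str

    def __len__(self) -> int:
        return self.labels.size

    @property
    def speakers(self) -> set[str]:
        return set(self.speaker_ids.tolist())

    def subset(self, mask: np.ndarray) -> "ClipDataset":
        return ClipDataset(self.waveforms[mask], self.labels[mask],
                           self.speaker_ids[mask], self.sentence_ids[mask])


def dataset_from_clips(clips: list[AudioClip], pre_config: PreprocessConfig | None = None,
                       augment_seed: int | None = None) -> ClipDataset:
    """Preprocess clips into a dataset.

    ``augment_seed`` enables the training-only augmentation: the training
    set is *expanded* with low-pass-filtered copies (each clip contributes a
    filtered duplicate with probability ``augment_probability``) while every
    original is kept.  Leave it ``None`` for validation/test data — the
    training loader is the sole caller that sets it, so evaluation data can
    never be augmented.
    """
    pre_config = pre_config or PreprocessConfig()
    rng = np.random.default_rng(augment_seed) if augment_seed is not None else None
    waves, labels, speakers, sentences = [], [], [], []

    def push(clip_std, clip):
        waves.append(clip_std.samples)
        labels.append(LABEL_TO_INT[clip.label])
        speakers.append(clip.speaker_id)
        sentences.append(clip.sentence_id)

    for clip in clips:
        std = prepare_clip(clip, pre_config)
        push(std, clip)
        if rng is not None:
            extra = augment_lowpass(std, pre_config, seed=int(rng.integers(0, 2 ** 31 - 1)))
            if extra is not std:  # the filter was actually applied
                push(extra, clip)
    return ClipDataset(np.asarray(waves, dtype=np.float32), np.asarray(labels, dtype=int),
                       np.asarray(speakers, dtype=object), np.asarray(sentences, dtype=object))


def make_folds(clips_or_dataset, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign speakers to k folds, stratified by class.

    Per class, speakers are shuffled with ``seed`` and dealt round-robin, so
    per-class speaker counts across folds differ by at most one.  Returns a
    speaker_id → fold index (1..k) map.
    """
    if isinstance(clips_or_dataset, ClipDataset):
        pairs = {(s, int(l)) for s, l in zip(clips_or_dataset.speaker_ids, clips_or_dataset.labels)}
    else:
        pairs = {(c.speaker_id, LABEL_TO_INT[c.label]) for c in clips_or_dataset}
    by_class: dict[int, list[str]] = {}
    for speaker, label in sorted(pairs):
        by_class.setdefault(label, []).append(speaker)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in sorted(by_class):
        speakers = sorted(set(by_class[label]))
        if len(speakers) < k:
            raise ValueError(f"need at least {k} speakers per class, "
                             f"class {label} has {len(speakers)}")
        order = rng.permutation(len(speakers))
        for j, idx in enumerate(order):
            assignment[speakers[idx]] = (j % k) + 1
    return assignment


@dataclass
class TrainHistory:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _check_disjoint(train: ClipDataset, val: ClipDataset) -> None:
    overlap = train.speakers & val.speakers
    if overlap:
        raise ValueError(f"speaker leakage between train and validation: {sorted(overlap)}")


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing F1 on validation scores.

    Candidates are midpoints between consecutive unique scores (plus 0.5);
    ties prefer the candidate closest to 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    candidates = [0.5] if uniq.size < 2 else \
        np.concatenate([[0.5], (uniq[1:] + uniq[:-1]) / 2.0])
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        counts = confusion_from_predictions(labels, (scores >= t).astype(int))
        f1 = compute_metrics(counts).f1
        if f1 > best_f1 + 1e-12 or (abs(f1 - best_f1) <= 1e-12
                                    and abs(t - 0.5) < abs(best_t - 0.5)):
            best_f1, best_t = f1, t
    return float(best_t)


def _forward_scores(model: DualHeadModel, waveforms: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    """PD probabilities from the classifier path (eval mode, deterministic)."""
    model.eval()
    probs = []
    for lo in range(0, waveforms.shape[0], batch_size):
        out = model(waveforms[lo:lo + batch_size], mode=CE_ONLY)
        logits = out.logits.data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs.append((e / e.sum(axis=1, keepdims=True))[:, 1])
    return np.concatenate(probs)


def evaluate_model(model: DualHeadModel, dataset: ClipDataset,
                   threshold: float | None = None
                   ) -> tuple[MetricsReport, ConfusionCounts, np.ndarray]:
    """Metrics, confusion counts and PD scores of a model on a dataset.

    The decision threshold defaults to the model's validation-calibrated
    ``decision_threshold_`` when present, else 0.5.
    """
    if threshold is None:
        threshold = getattr(model, "decision_threshold_", 0.5)
    scores = _forward_scores(model, dataset.waveforms)
    preds = (scores >= threshold).astype(int)
    counts = confusion_from_predictions(dataset.labels, preds)
    report = compute_metrics(counts)
    if len(np.unique(dataset.labels)) == 2:
        _, _, auc = roc_curve_auc(scores, dataset.labels)
        report.auc = auc
    return report, counts, scores


def train_model(model: DualHeadModel, train_data: ClipDataset, val_data: ClipDataset,
                config: TrainConfig) -> tuple[DualHeadModel, TrainHistory]:
    """Joint single-phase training with early stopping on validation F1.

    Returns the model carrying the best-epoch parameters plus the per-epoch
    history.  Deterministic given ``config.seed`` and the model's init seed.
    """
    _check_disjoint(train_data, val_data)
    head_opt = AdamW(model.head_parameters(), lr=config.initial_lr, betas=config.betas,
                     weight_decay=config.weight_decay)
    enc_lr = config.initial_lr if config.encoder_lr is None else config.encoder_lr
    enc_params = (model.encoder.block_parameters() if config.freeze_frontend
                  else model.encoder_parameters())
    enc_opt = (AdamW(enc_params, lr=enc_lr, betas=config.betas,
                     weight_decay=config.weight_decay)
               if config.fine_tune_encoder else None)
    model.classifier.drop.rate = config.dropout
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_f1, best_state, best_epoch = -1.0, model.state_dict(), -1
    stale = 0
    n = len(train_data)
    for epoch in range(config.epochs):
        # cosine-annealed learning rates over the epoch budget
        anneal = 0.5 * (1.0 + math.cos(math.pi * epoch / max(config.epochs, 1)))
        head_opt.lr = config.initial_lr * anneal
        if enc_opt is not None:
            enc_opt.lr = enc_lr * anneal
        model.train(True)
        order = rng.permutation(n)
        sup_total = ce_total = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if idx.size < 2:
                continue
            x, y = train_data.waveforms[idx], train_data.labels[idx]
            out = model(x, mode=config.mode)
            if config.mode == SUPCON:
                total, sup, ce = combined_objective(out.logits, out.projection, y, config.supcon)
                sup_total += sup.item()
            else:
                total = cross_entropy(out.logits, y)
                ce = total
            ce_total += ce.item()
            n_batches += 1
            head_opt.zero_grad()
            if enc_opt is not None:
                enc_opt.zero_grad()
            total.backward()
            head_opt.step()
            if enc_opt is not None:
                enc_opt.step()
        # monitor: validation F1 at the validation-calibrated operating point
        val_scores = _forward_scores(model, val_data.waveforms)
        val_threshold = select_threshold(val_scores, val_data.labels)
        val_counts = confusion_from_predictions(
            val_data.labels, (val_scores >= val_threshold).astype(int))
        val_report = compute_metrics(val_counts)
        history.rows.append({"epoch": epoch, "lr": head_opt.lr,
                             "supcon_loss": sup_total / max(n_batches, 1),
                             "ce_loss": ce_total / max(n_batches, 1),
                             "val_f1": val_report.f1, "val_accuracy": val_report.accuracy})
        if val_report.f1 > best_f1:
            best_f1, best_state, best_epoch = val_report.f1, model.state_dict(), epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_epoch >= 0:
        model.load_state_dict(best_state)
    if config.mode == SUPCON and config.head_consolidation_epochs > 0 and config.epochs > 0:
        _consolidate_head(model, train_data, config)
    if config.epochs > 0:
        # operating point calibrated on validation scores, never on test
        val_scores = _forward_scores(model, val_data.waveforms)
        model.decision_threshold_ = select_threshold(val_scores, val_data.labels)
    model.release_graphs()
    return model, history


def _consolidate_head(model: DualHeadModel, train_data: ClipDataset,
                      config: TrainConfig) -> None:
    """Classifier-only CE epochs on the frozen final embeddings (SUPCON mode).

    Equivalent to continuing the joint schedule with the encoder's learning
    rate at zero: the blocked pathway never updates the encoder, so only the
    head moves.  Embeddings are computed once in eval mode and reused.
    """
    model.eval()
    embeddings = []
    for lo in range(0, len(train_data), 64):
        embeddings.append(model.embed(train_data.waveforms[lo:lo + 64]).data)
    embeddings = np.vstack(embeddings)
    optimizer = AdamW(model.classifier.parameters(), lr=config.initial_lr / 2,
                      betas=config.betas, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 0x5EAD)
    model.classifier.train(True)
    from .autodiff import Tensor

    for _ in range(config.head_consolidation_epochs):
        order = rng.permutation(len(train_data))
        for lo in range(0, len(train_data), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if idx.size < 2:
                continue
            logits = model.classifier(Tensor(embeddings[idx]))
            loss = cross_entropy(logits, train_data.labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    model.classifier.eval()


@dataclass
class CVResult:
    fold_models: list[DualHeadModel]
    fold_reports: list[MetricsReport]
    fold_counts: list[ConfusionCounts]
    histories: list[TrainHistory]
    summary: dict[str, tuple[float, float]]   # metric -> (mean, sample sd)
    cumulative: ConfusionCounts
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_auc: float
    per_sentence: pd.DataFrame


def run_cv_experiment(train_clips: list[AudioClip], test_clips: list[AudioClip],
                      model_factory, config: TrainConfig, k: int = 5,
                      pre_config: PreprocessConfig | None = None) -> CVResult:
    """Stratified speaker-independent k-fold CV with held-out test evaluation.

    For each fold the model trains on the other k−1 folds with the fold as
    validation (early stopping), then the best model is scored on the common
    held-out test set.  ``model_factory(seed)`` must return a fresh
    :class:`DualHeadModel`.
    """
    pre_config = pre_config or PreprocessConfig()
    test_speakers = {c.speaker_id for c in test_clips}
    train_speakers = {c.speaker_id for c in train_clips}
    if test_speakers & train_speakers:
        raise ValueError(f"speaker leakage between train and test: "
                         f"{sorted(test_speakers & train_speakers)}")
    folds = make_folds(train_clips, k=k, seed=config.seed)
    test_data = dataset_from_clips(test_clips, pre_config)

    fold_models, fold_reports, fold_counts, histories = [], [], [], []
    all_scores, all_labels = [], []
    sentence_true, sentence_pred, sentence_ids = [], [], []
    for fold in range(1, k + 1):
        val_clips = [c for c in train_clips if folds[c.speaker_id] == fold]
        fit_clips = [c for c in train_clips if folds[c.speaker_id] != fold]
        fit_data = dataset_from_clips(fit_clips, pre_config,
                                      augment_seed=config.seed * 1000 + fold)
        val_data = dataset_from_clips(val_clips, pre_config)
        if (fit_data.speakers & test_speakers) or (val_data.speakers & test_speakers):
            raise ValueError("speaker leakage into the held-out test set")
        model = model_factory(config.seed * 100 + fold)
        model, history = train_model(model, fit_data, val_data, config)
        report, counts, scores = evaluate_model(model, test_data)
        model.release_graphs()
        fold_models.append(model)
        fold_reports.append(report)
        fold_counts.append(counts)
        histories.append(history)
        all_scores.append(scores)
        all_labels.append(test_data.labels)
        threshold = getattr(model, "decision_threshold_", 0.5)
        sentence_true.extend(test_data.labels.tolist())
        sentence_pred.extend((scores >= threshold).astype(int).tolist())
        sentence_ids.extend(test_data.sentence_ids.tolist())

    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    _, _, pooled_auc = roc_curve_auc(pooled_scores, pooled_labels)
    return CVResult(
        fold_models=fold_models, fold_reports=fold_reports, fold_counts=fold_counts,
        histories=histories, summary=aggregate_reports(fold_reports),
        cumulative=cumulative_confusion(fold_counts),
        pooled_scores=pooled_scores, pooled_labels=pooled_labels, pooled_auc=pooled_auc,
        per_sentence=per_sentence_accuracy(sentence_true, sentence_pred, sentence_ids))
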