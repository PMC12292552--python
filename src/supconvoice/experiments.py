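"""Desk-scale experiment protocols on the synthetic cohort.

These are the package's reference experiments: a complete speaker-independent
evaluation (80/20 speaker-disjoint split, stratified speaker-independent
5-fold cross-validation, held-out test scoring) run end-to-end on synthetic
cohorts with the tiny encoder.  Problem sizes are chosen so a full
mode-comparison finishes on a single CPU core in minutes: 10 speakers per
class uttering 16 sentence types of 2-4 s, standardized to 2 s clips, an
encoder of width 64 with 2 attention blocks, and 20 training epochs.

The training recipe follows the published fine-tuning setup (AdamW, cosine
annealing, batch 32, dropout 0.2, early stopping on validation F1) with the
desk-scale adaptations documented in the methods note: head learning rate
1e-3 with a gentler 2e-4 on the attention blocks, and the convolutional
filterbank kept frozen as in standard frame-encoder fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CE_ONLY, SUPCON, DualHeadModel, make_tiny_encoder
from .preprocessing import PreprocessConfig, split_train_test
from .synthetic import CohortConfig, make_cohort
from .training import CVResult, TrainConfig, run_cv_experiment

__all__ = ["ScaledProtocol", "run_scaled_cv", "compare_modes", "run_null_check",
           "run_relevance_check"]


@dataclass
class ScaledProtocol:
    """Study conditions for the desk-scale experiments."""

    n_speakers_per_class: int = 10
    sentences_per_speaker: int = 16
    duration_range: tuple[float, float] = (2.0, 4.0)
    effect_size: float = 2.0
    target_seconds: float = 2.0
    encoder_dim: int = 64
    encoder_layers: int = 2
    projection_dim: int = 32
    epochs: int = 12
    head_lr: float = 1e-3
    encoder_lr: float = 2e-4
    head_consolidation_epochs: int = 5
    batch_size: int = 32
    patience: int = 15
    k_folds: int = 5
    test_fraction: float = 0.2

    def cohort_config(self, seed: int, effect_size: float | None = None) -> CohortConfig:
        return CohortConfig(
            n_speakers_per_class=self.n_speakers_per_class,
            sentences_per_speaker=self.sentences_per_speaker,
            duration_range=self.duration_range,
            effect_size=self.effect_size if effect_size is None else effect_size,
            seed=seed)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(target_seconds=self.target_seconds)

    def train_config(self, mode: str, seed: int) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           initial_lr=self.head_lr, encoder_lr=self.encoder_lr,
                           patience=self.patience, seed=seed, mode=mode,
                           head_consolidation_epochs=self.head_consolidation_epochs)

    def model_factory(self):
        def factory(seed: int) -> DualHeadModel:
            encoder = make_tiny_encoder(self.encoder_dim, self.encoder_layers, seed=seed)
            return DualHeadModel(encoder, projection_dim=self.projection_dim, seed=seed)

        return factory


def run_scaled_cv(mode: str, seed: int, protocol: ScaledProtocol | None = None,
                  effect_size: float | None = None) -> CVResult:
    """One full protocol run: cohort → split → k-fold CV → test metrics."""
    protocol = protocol or ScaledProtocol()
    clips, _ = make_cohort(protocol.cohort_config(seed, effect_size))
    train_clips, test_clips = split_train_test(clips, protocol.test_fraction, seed=seed)
    return run_cv_experiment(train_clips, test_clips, protocol.model_factory(),
                             protocol.train_config(mode, seed), k=protocol.k_folds,
                             pre_config=protocol.preprocess_config())


def compare_modes(seeds=(1, 2, 3), protocol: ScaledProtocol | None = None,
                  effect_size: float | None = None) -> dict:
    """Contrastive vs plain cross-entropy fine-tuning over several seeds.

    Returns per-seed mean test F1 for both modes plus pooled AUCs, the raw
    CV results, and the count of seeds where the contrastive mode's mean F1
    is at least the cross-entropy mode's.
    """
    protocol = protocol or ScaledProtocol()
    out = {"seeds": list(seeds), "supcon_f1": [], "ce_f1": [],
           "supcon_auc": [], "ce_auc": [], "results": {}}
    for seed in seeds:
        res_sc = run_scaled_cv(SUPCON, seed, protocol, effect_size)
        res_ce = run_scaled_cv(CE_ONLY, seed, protocol, effect_size)
        out["supcon_f1"].append(res_sc.summary["f1"][0])
        out["ce_f1"].append(res_ce.summary["f1"][0])
        out["supcon_auc"].append(res_sc.pooled_auc)
        out["ce_auc"].append(res_ce.pooled_auc)
        out["results"][seed] = {"supcon": res_sc, "ce": res_ce}
    out["supcon_wins"] = int(sum(s >= c for s, c in zip(out["supcon_f1"], out["ce_f1"])))
    out["supcon_mean_f1"] = float(np.mean(out["supcon_f1"]))
    out["ce_mean_f1"] = float(np.mean(out["ce_f1"]))
    return out


def run_null_check(seed: int = 0, protocol: ScaledProtocol | None = None,
                   eval_speakers_per_class: int = 30, epochs: int = 3) -> dict:
    """No-effect cohort sanity check: held-out AUC must sit at chance.

    Trains both modes on an ``effect_size = 0`` cohort (class-conditional
    parameter distributions identical), then scores each fold model on a
    large, freshly generated null cohort of unseen speakers and pools the
    scores.  Any AUC away from 0.5 would indicate leakage through speaker or
    sentence structure.  A short epoch budget suffices: with no class signal
    there is nothing to converge to.
    """
    from .metrics import roc_curve_auc
    from .training import dataset_from_clips

    protocol = protocol or ScaledProtocol()
    eval_config = protocol.cohort_config(seed + 90_001, effect_size=0.0)
    eval_config.n_speakers_per_class = eval_speakers_per_class
    eval_clips, _ = make_cohort(eval_config)
    eval_data = dataset_from_clips(eval_clips, protocol.preprocess_config())

    out = {}
    for mode in (SUPCON, CE_ONLY):
        small = ScaledProtocol(**{**protocol.__dict__, "epochs": epochs})
        result = run_scaled_cv(mode, seed, small, effect_size=0.0)
        scores = np.concatenate([
            _scores_on(model, eval_data) for model in result.fold_models])
        labels = np.tile(eval_data.labels, len(result.fold_models))
        _, _, auc = roc_curve_auc(scores, labels)
        out[mode] = float(auc)
    return out


def _scores_on(model, data):
    from .training import _forward_scores

    return _forward_scores(model, data.waveforms)


def run_relevance_check(seeds=(0, 1, 2, 3, 4), target_seconds: float = 3.0) -> dict:
    """Signal-vs-padding localization of the relevance maps.

    For each seed: train a small contrastive model on short utterances that
    are zero-padded to the fixed clip length, then test whether the mean
    relevance over the signal region exceeds the mean over the padding on
    held-out clips.  Returns the per-seed outcomes and the success count.
    """
    from .explain import grad_cam_map
    from .model import DualHeadModel, make_tiny_encoder
    from .preprocessing import PreprocessConfig, split_train_test
    from .training import TrainConfig, dataset_from_clips, make_folds, train_model

    pre = PreprocessConfig(target_seconds=target_seconds)
    outcomes = []
    for seed in seeds:
        config = CohortConfig(n_speakers_per_class=4, sentences_per_speaker=8,
                              duration_range=(1.2, 1.8), effect_size=2.0, seed=seed + 500)
        clips, _ = make_cohort(config)
        train_clips, test_clips = split_train_test(clips, 0.25, seed=seed)
        folds = make_folds(train_clips, k=3, seed=seed)
        fit = [c for c in train_clips if folds[c.speaker_id] != 1]
        val = [c for c in train_clips if folds[c.speaker_id] == 1]
        fit_d = dataset_from_clips(fit, pre, augment_seed=seed)
        val_d = dataset_from_clips(val, pre)
        model = DualHeadModel(make_tiny_encoder(64, 2, seed=seed), seed=seed)
        cfg = TrainConfig(epochs=5, batch_size=32, initial_lr=1e-3, encoder_lr=2e-4,
                          patience=5, seed=seed, mode=SUPCON)
        model, _ = train_model(model, fit_d, val_d, cfg)

        ratios = []
        for clip in test_clips[:6]:
            from .preprocessing import prepare_clip

            std = prepare_clip(clip, pre)
            nonzero = np.flatnonzero(std.samples)
            if nonzero.size == 0 or nonzero[-1] >= std.samples.size - 1600:
                continue  # no padding region worth comparing
            signal_len = int(nonzero[-1]) + 1
            rel = grad_cam_map(model, std, target_class=clip.label)
            if rel.is_zero:
                continue
            sig = float(rel.sample_relevance[:signal_len].mean())
            pad = float(rel.sample_relevance[signal_len:].mean())
            ratios.append((sig, pad))
        n_ok = sum(1 for s, p in ratios if s > p)
        outcomes.append(bool(ratios) and n_ok > len(ratios) / 2)
    return {"per_seed": outcomes, "successes": int(sum(outcomes)), "n_seeds": len(seeds)}
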