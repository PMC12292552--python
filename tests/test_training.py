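"""Fold construction, training-loop contracts, and leakage guards."""

import numpy as np
import pytest

from supconvoice.audio import AudioClip
from supconvoice.model import CE_ONLY, SUPCON, DualHeadModel, make_tiny_encoder
from supconvoice.preprocessing import split_train_test
from supconvoice.training import (ClipDataset, TrainConfig, dataset_from_clips,
                                  evaluate_model, make_folds, run_cv_experiment,
                                  train_model)


def _dummy_clips(n_hc, n_pd):
    clips = []
    rng = np.random.default_rng(0)
    for tag, n in (("HC", n_hc), ("PD", n_pd)):
        for i in range(n):
            clips.append(AudioClip(rng.standard_normal(1600) * 0.1, 16000,
                                   f"{tag}{i:02d}", tag, "S01"))
    return clips


class TestMakeFolds:
    def test_balanced_cohort_divides_exactly(self):
        folds = make_folds(_dummy_clips(10, 10), k=5, seed=0)
        for fold in range(1, 6):
            speakers = [s for s, f in folds.items() if f == fold]
            assert sum(s.startswith("HC") for s in speakers) == 2
            assert sum(s.startswith("PD") for s in speakers) == 2

    def test_every_speaker_in_exactly_one_fold(self):
        clips = _dummy_clips(7, 9)
        folds = make_folds(clips, k=5, seed=1)
        assert set(folds) == {c.speaker_id for c in clips}

    def test_unbalanced_cohort_within_one_speaker_per_class(self):
        folds = make_folds(_dummy_clips(11, 12), k=5, seed=2)
        for tag, total in (("HC", 11), ("PD", 12)):
            counts = [sum(1 for s, f in folds.items() if f == fold and s.startswith(tag))
                      for fold in range(1, 6)]
            assert sum(counts) == total
            assert max(counts) - min(counts) <= 1

    def test_too_few_speakers_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_dummy_clips(3, 10), k=5, seed=0)

    def test_assignment_deterministic_given_seed(self):
        clips = _dummy_clips(8, 8)
        assert make_folds(clips, 4, seed=3) == make_folds(clips, 4, seed=3)


@pytest.fixture(scope="module")
def mini_datasets(small_cohort, short_preprocess):
    clips, _, _ = small_cohort
    train_clips, test_clips = split_train_test(clips, 0.25, seed=1)
    folds = make_folds(train_clips, k=3, seed=1)
    val = [c for c in train_clips if folds[c.speaker_id] == 1]
    fit = [c for c in train_clips if folds[c.speaker_id] != 1]
    return (dataset_from_clips(fit, short_preprocess),
            dataset_from_clips(val, short_preprocess),
            dataset_from_clips(test_clips, short_preprocess))


def _mini_config(**kw):
    defaults = dict(epochs=2, batch_size=16, initial_lr=1e-3, encoder_lr=2e-4,
                    patience=5, seed=0, mode=SUPCON)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainModel:
    def test_zero_epochs_leaves_parameters_untouched(self, mini_datasets):
        fit_d, val_d, _ = mini_datasets
        model = DualHeadModel(make_tiny_encoder(32, 1, seed=0), seed=0)
        before = model.state_dict()
        model, history = train_model(model, fit_d, val_d, _mini_config(epochs=0))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert history.to_frame().empty

    def test_frozen_encoder_is_bit_identical_after_training(self, mini_datasets):
        fit_d, val_d, _ = mini_datasets
        model = DualHeadModel(make_tiny_encoder(32, 1, seed=1), seed=1)
        before = {k: v for k, v in model.encoder.state_dict().items()}
        model, _ = train_model(model, fit_d, val_d,
                               _mini_config(fine_tune_encoder=False, mode=CE_ONLY))
        after = model.encoder.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_speaker_overlap_raises_immediately(self, mini_datasets):
        fit_d, _, _ = mini_datasets
        model = DualHeadModel(make_tiny_encoder(32, 1, seed=2), seed=2)
        with pytest.raises(ValueError, match="leakage"):
            train_model(model, fit_d, fit_d, _mini_config())

    def test_training_is_deterministic_given_seeds(self, mini_datasets):
        fit_d, val_d, _ = mini_datasets
        outs = []
        for _ in range(2):
            model = DualHeadModel(make_tiny_encoder(32, 1, seed=3), seed=3)
            model, _ = train_model(model, fit_d, val_d, _mini_config(epochs=1))
            outs.append({k: v for k, v in model.state_dict().items()})
        assert all(np.array_equal(outs[0][k], outs[1][k]) for k in outs[0])

    def test_history_records_losses_and_validation_metrics(self, mini_datasets):
        fit_d, val_d, _ = mini_datasets
        model = DualHeadModel(make_tiny_encoder(32, 1, seed=4), seed=4)
        _, history = train_model(model, fit_d, val_d, _mini_config(epochs=2))
        frame = history.to_frame()
        assert list(frame.columns) == ["epoch", "lr", "supcon_loss", "ce_loss",
                                       "val_f1", "val_accuracy"]
        assert len(frame) == 2


class TestEvaluateModel:
    def test_report_confusion_and_scores_align(self, mini_datasets):
        _, _, test_d = mini_datasets
        model = DualHeadModel(make_tiny_encoder(32, 1, seed=5), seed=5)
        report, counts, scores = evaluate_model(model, test_d)
        assert counts.total == len(test_d)
        assert scores.shape == (len(test_d),)
        assert np.all((scores >= 0) & (scores <= 1))
        assert 0.0 <= report.accuracy <= 1.0


class TestRunCvExperiment:
    def test_protocol_structure_and_guards(self, small_cohort, short_preprocess):
        clips, _, _ = small_cohort
        train_clips, test_clips = split_train_test(clips, 0.25, seed=2)

        def factory(seed):
            return DualHeadModel(make_tiny_encoder(32, 1, seed=seed), seed=seed)

        config = _mini_config(epochs=1, mode=CE_ONLY, seed=2)
        result = run_cv_experiment(train_clips, test_clips, factory, config, k=3,
                                   pre_config=short_preprocess)
        assert len(result.fold_models) == 3
        assert len(result.fold_reports) == 3
        assert result.cumulative.total == 3 * len(test_clips)
        assert result.pooled_scores.shape == (3 * len(test_clips),)
        assert set(result.summary) >= {"accuracy", "f1", "sensitivity", "specificity"}
        assert not result.per_sentence.empty

    def test_test_speaker_leak_rejected(self, small_cohort, short_preprocess):
        clips, _, _ = small_cohort
        train_clips, test_clips = split_train_test(clips, 0.25, seed=3)

        def factory(seed):
            return DualHeadModel(make_tiny_encoder(32, 1, seed=seed), seed=seed)

        leaked = train_clips + test_clips[:1]
        with pytest.raises(ValueError, match="leakage"):
            run_cv_experiment(leaked, test_clips, factory,
                              _mini_config(epochs=1, mode=CE_ONLY), k=3,
                              pre_config=short_preprocess)


def test_training_loss_decreases_on_separable_cohort(small_cohort, short_preprocess):
    """Descent check: contrastive loss after a few epochs is below epoch 0."""
    clips, _, _ = small_cohort
    train_clips, _ = split_train_test(clips, 0.25, seed=4)
    folds = make_folds(train_clips, k=3, seed=4)
    fit = [c for c in train_clips if folds[c.speaker_id] != 1]
    val = [c for c in train_clips if folds[c.speaker_id] == 1]
    fit_d = dataset_from_clips(fit, short_preprocess)
    val_d = dataset_from_clips(val, short_preprocess)
    model = DualHeadModel(make_tiny_encoder(32, 1, seed=6), seed=6)
    _, history = train_model(model, fit_d, val_d, _mini_config(epochs=6, patience=6))
    frame = history.to_frame()
    assert frame.iloc[-1]["supcon_loss"] < frame.iloc[0]["supcon_loss"]
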