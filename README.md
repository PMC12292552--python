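# supconvoice

Supervised-contrastive fine-tuning of frame-level speech encoders for
detecting Parkinson's disease (PD) from voice recordings.

Speech is one of the earliest affected motor domains in PD: patients show
elevated cycle-to-cycle perturbation of vocal fundamental frequency
("jitter") and amplitude ("shimmer"), compressed F0 range, added breath
noise, and reduced intensity. This package implements a classification
system that fine-tunes a frame-level speech encoder on short sentence
recordings with a **dual-head architecture**:

- a **classification head** (linear d→64, ReLU, dropout 0.2, linear 64→2)
  trained with softmax cross-entropy, and
- a **projection head** (d→128→p, L2-normalised, p = 32 by default) trained
  with the multi-positive **supervised contrastive (SupCon) loss**

  L = Σ_{i∈I} −1/|P(i)| Σ_{p∈P(i)} log [ exp(sim(z_i, z_p)/τ) / Σ_{a∈A(i)} exp(sim(z_i, z_a)/τ) ]

  with temperature τ = 0.07, cosine similarity on the unit sphere, and
  ×1.5 up-weighting of each anchor's most similar ("hardest") negatives in
  the denominator.

Both heads are trained in a **single phase**: the classifier receives a
gradient-detached copy of the pooled utterance embedding, so its
cross-entropy loss can never update the encoder — representation learning
is driven purely by the contrastive objective, and no separate training
stages are needed. The package also provides the classical baselines
(39-dim MFCC vectors and 88-dim eGeMAPS functionals classified by an MLP or
gradient-boosted trees), the speaker-independent evaluation protocol
(80/20 speaker-disjoint split + stratified speaker-independent 5-fold
cross-validation, cumulative confusion matrices, pooled ROC/AUC,
per-sentence accuracy), gradient-based relevance maps over the waveform,
and a synthetic dysphonia cohort generator so every experiment runs fully
offline.

## Worked example

```python
import numpy as np
from supconvoice import (CohortConfig, make_cohort, split_train_test,
                         SupConVoiceClassifier, dataset_from_clips,
                         PreprocessConfig, roc_curve_auc)

clips, meta = make_cohort(CohortConfig(n_speakers_per_class=6,
                                       sentences_per_speaker=8,
                                       duration_range=(2.0, 3.0),
                                       effect_size=2.0, seed=7))
train, test = split_train_test(clips, test_fraction=0.25, seed=7)
pre = PreprocessConfig(target_seconds=2.0)
tr, te = dataset_from_clips(train, pre), dataset_from_clips(test, pre)

clf = SupConVoiceClassifier(encoder_dim=64, encoder_layers=2, epochs=10,
                            lr=1e-3, encoder_lr=2e-4, seed=0)
clf.fit(tr.waveforms, tr.labels, speaker_ids=tr.speaker_ids)
scores = clf.predict_proba(te.waveforms)[:, 1]
_, _, auc = roc_curve_auc(scores, te.labels)
acc = (clf.predict(te.waveforms) == te.labels).mean()
print(f"held-out accuracy {acc:.3f}, AUC {auc:.3f}")
```

Output:

```
held-out accuracy 0.969, AUC 1.000
```

The cohort here has a strong synthetic PD effect (`effect_size=2.0`:
elevated jitter/shimmer/breath noise, compressed F0 range and intensity),
and the test speakers are disjoint from the training speakers, so the
numbers reflect generalization to unseen voices, not memorization.

A full protocol run — 80/20 speaker split, stratified 5-fold CV, test-set
scoring of each fold's best model, both training modes — is one call:

```python
from supconvoice.experiments import compare_modes
out = compare_modes(seeds=(1, 2, 3))
print(out["supcon_mean_f1"], out["ce_mean_f1"], out["supcon_auc"], out["ce_auc"])
```

Command-line equivalents: `synth-cohort` writes a WAV cohort + metadata
CSV; `supcon-voice crossval` runs the full protocol on any such cohort;
`supcon-voice explain` renders a relevance overlay for one clip.

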