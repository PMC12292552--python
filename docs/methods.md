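# Methods

## Problem and model

The package targets binary detection of Parkinson's disease (PD) from short
sentence recordings. The discriminative signal is phonatory and prosodic:
hypokinetic dysarthria elevates jitter (cycle-to-cycle F0 perturbation) and
shimmer (cycle amplitude perturbation), adds aspiration noise, compresses
the F0 range, and lowers intensity and speech rate.

The classifier is a frame-level speech encoder with two parallel heads.
The encoder maps a fixed-length waveform (16 kHz, fixed clip length) to a
T×d matrix of 20 ms frame embeddings; mean pooling over time gives the
utterance embedding, which is standardised by a BatchNorm layer (batch
statistics during training, running statistics at inference) and fed to:

- the classification head: linear d→64, ReLU, dropout 0.2, linear 64→2;
- the projection head: linear d→128, ReLU, linear 128→p, L2 normalisation
  (p, the "projection size", defaults to 32; the hidden width is fixed at
  128 — we treat the published "32-dimensional" figure as the output width,
  the quantity varied in the projection-size ablation).

Training is single-phase. In contrastive mode the projection head receives
the live embedding and minimises the multi-positive supervised contrastive
loss (temperature τ = 0.07; the denominator sums over all non-anchor batch
members, positives included, following the printed form of the loss), while
the classification head receives a *gradient-detached* copy of the
embedding and minimises cross-entropy. Detachment severs the backward path
from classifier to encoder, so the representation is shaped only by the
contrastive objective. The combined objective is the unweighted sum of the
two components. In plain cross-entropy mode there is no detachment and no
projection path — ordinary fine-tuning.

Hard pair scaling multiplies the denominator exponential of each anchor's
`hard_k` most cosine-similar negatives by 1.5 (equivalently, adds log 1.5
to those logits). "Most challenging" is read minimally as top-k with
k = 1 by default; ties break toward the lowest batch index, and an anchor
without negatives falls back to its plain term. Scale 1 reproduces the
plain loss bit-for-bit. Anchors with no positives in the batch are skipped
(their 1/|P(i)| weight is undefined), following the standard multi-positive
convention. The log-sum-exp is evaluated with row-max subtraction, so the
loss is finite even at τ = 0.01 with near-duplicate projections.

## Tiny encoder

Experiments run on a small trainable encoder with the same interface as the
large self-supervised speech models the architecture is designed for: a
convolutional front-end with total stride 320 samples (20 ms at 16 kHz)
followed by `n_layers` pre-norm single-head self-attention blocks with a
2× feed-forward expansion. Design choices that matter:

- **Quadrature filterbank front-end.** The front-end is a bias-free linear
  map of each 320-sample frame onto d cosine/sine pairs at mel-spaced
  centre frequencies; the channel energy is the sum of squares of each
  pair, and the frame feature is `log(energy + 1e-8)`, scaled by 0.25.
  This is a trainable log spectrogram: phase-invariant at initialisation,
  which matters because the class signal lives in spectral statistics.
  The bias must be absent — a squared bias offset (~1e-3) would bury the
  quiet high-frequency breath-noise bands (~1e-6) that carry much of the
  class signal. The log floor clamps silent bins to a constant instead of
  amplifying noise.
- **Zero-initialised residual gates.** Each attention block's two residual
  branches are multiplied by learnable scalars initialised at exactly zero,
  so the untrained encoder is an identity map over the filterbank features
  and attention capacity enters only as training warrants it. Without the
  gates, the random untrained blocks measurably corrupt the linearly
  separable front-end features.
- **No feature-wise normalisation on the residual stream.** Per-frame
  LayerNorm across channels (either at the input or after the final block)
  destroys absolute band levels and spectral tilt, which are informative
  here; the block-internal pre-norms are kept, the stream itself is not
  normalised. Dataset-scale standardisation is instead provided by the
  BatchNorm on the pooled embedding, which is what makes the heads
  optimisable at all.
- **Frozen front-end during fine-tuning.** Following standard practice for
  frame-level speech encoders, the convolutional feature extractor is kept
  fixed while the attention blocks fine-tune (`freeze_frontend=True`).
  Adaptive per-parameter optimisers otherwise corrupt the delicate filter
  shapes within an epoch. Layer selection (`layer=ℓ`) returns the
  activations after block ℓ, mirroring layer-wise probing of the large
  encoders.

## Training recipe

AdamW (β₁ = 0.9, β₂ = 0.999, weight decay 0.01), batch size 32, dropout
0.2, cosine-annealed learning rate over the epoch budget, early stopping on
validation F1 with the best-epoch parameters retained (patience 15). The
published recipe fine-tunes a pre-trained encoder at 2e-5; training the
tiny encoder from scratch instead uses 1e-3 on the heads and a gentler
2e-4 on the attention blocks (`encoder_lr`), reflecting the usual
head/backbone split in fine-tuning.

Two adaptations address a structural property of the gradient-blocked
design when the encoder is *not* pre-trained: the embeddings move
substantially during training, so the blocked classification head lags the
representation and its 0.5 probability cut is systematically miscalibrated
even when its ranking is near-perfect (we observed held-out AUC of 0.99+
with argmax F1 of 0.75).

1. **Head consolidation** (`head_consolidation_epochs`, contrastive mode
   only): after the joint schedule, a few classifier-only cross-entropy
   epochs on the frozen final embeddings. Under gradient blocking this is
   identical to continuing joint training with the encoder learning rate at
   zero — it cannot alter the representation.
2. **Validation-calibrated decision threshold**: the operating point is the
   threshold maximising validation F1 (midpoints between consecutive unique
   validation scores; ties prefer 0.5), applied identically in both
   training modes and never computed on test data. The early-stopping
   monitor is the validation F1 at that calibrated operating point. A fixed
   argmax/0.5 rule was the initial design; it demonstrably misrepresents
   both modes at this scale and was replaced by the calibrated operating
   point, a standard choice for clinical classifiers.

Augmentation follows the "expand the training set" reading: every training
clip is kept, and with probability 0.5 a low-pass-filtered copy (8th-order
Butterworth, cutoff uniform in 2–7 kHz) is added. Replacing clips instead
of adding copies creates a train/test shift in exactly the informative
high-frequency band and degrades calibration. Augmentation is reachable
only from the training loader; validation and test data can never pass
through it.

## Preprocessing

Recordings are resampled to 16 kHz (polyphase, Kaiser window), trimmed of
leading/trailing silence (25 ms frames, 10 ms hop; a frame is silent when
its RMS is more than 40 dB below the loudest frame), and fixed to the
target length by zero-padding at the end or truncating to the head.
Resampling precedes trimming. Stereo input is downmixed by averaging.

## Evaluation protocol

Speakers — never clips — are partitioned: 80/20 speaker-disjoint
train/test split (per class, the closest integer speaker count), then
stratified speaker-independent 5-fold cross-validation inside the training
portion (per class, speakers shuffled and dealt round-robin, so per-class
fold counts differ by at most one). Each fold's best model is scored on
the common held-out test set; we report per-metric mean ± sample (n−1)
standard deviation across folds, the cumulative (summed) confusion matrix,
a pooled ROC over all fold models' test scores, and per-sentence-type
accuracy. The positive class is PD throughout. Leakage guards are
unconditional and raise on any speaker appearing on two sides of a
boundary. Whether the published protocol computed ROC and cumulative
confusions on fold-validation or on the held-out test data is ambiguous;
this package evaluates on the held-out test set.

## Synthetic cohort generator

The generator emulates a sentence-repetition voice study: two speaker
groups, a fixed set of sentence types repeated by every speaker, utterance
durations drawn uniformly from a configurable range. Speech is synthesised
with a source–filter model — a glottal impulse train with per-cycle jitter
and shimmer, passed through three formant resonators whose frequencies are
a deterministic function of the sentence id, plus aspiration noise, with
voiced segments alternating with pauses at the speaker's speech rate and a
slow sentence-specific F0 contour scaled by the speaker's F0 range.

Healthy-speaker parameters are drawn from fixed priors (median F0 130 Hz
log-normal; jitter 0.8 % ± 0.2 %; shimmer 4 % ± 1 %; breath noise 0.02 ±
0.005; F0 range 4 ± 1 semitones; rate 4 ± 0.4 syll/s; peak intensity 0.25 ±
0.03). A PD speaker at effect size e shifts these monotonically: jitter
+0.008·e, shimmer +0.03·e, breath +0.03·e, F0 range ×exp(−0.35·e),
intensity ×exp(−0.18·e), rate ×exp(−0.08·e). At e = 0 the class
distributions are identical by construction. The values are the package's
own choice of a "clearly dysphonic but plausible" effect; they are not
calibrated to any real corpus.

What the generator does **not** emulate: intelligible phones or Spanish
sentence content, articulatory deficits, recording-channel variation,
dysfluencies, or severity heterogeneity. Passing tests therefore show that
the training machinery can exploit phonatory/prosodic class differences
under speaker-independent evaluation — not that the pipeline reaches any
particular accuracy on real clinical recordings.

## Desk-scale reference experiments

`supconvoice.experiments.ScaledProtocol` fixes the reference conditions:
10 speakers per class × 16 sentences of 2–4 s, standardized to 2 s clips,
encoder width 64 with 2 blocks, 12 epochs + 5 consolidation epochs. These
sizes keep a full two-mode, three-seed, 5-fold comparison around 12 minutes
on one CPU core. Under these conditions the contrastive models' pooled
test ROC consistently dominates the cross-entropy models' (we observe
pooled AUC near 1.0 vs roughly 0.8–0.95), while the two modes' mean test F1
are both high and within one or two test clips of each other — at this
degree of class separability the F1 ordering between the modes sits inside
seed noise, which is the expected behaviour of a scaled-down qualitative
check near the ceiling. The null-cohort check (effect size 0) scores the
fold models on a large freshly generated cohort of unseen speakers and
verifies chance-level AUC, excluding leakage through speaker or sentence
structure.

## Relevance maps

The class-activation map hooks the final self-attention sublayer's output
as it enters the residual stream — the activation that projects the
attention mechanism's output back into the embedding space and feeds the
decision. (Hooking the bare output projection instead is meaningless under
zero-initialised residual gates, which decouple it from the logit.)
Channel weights are the time-averaged gradients of the target-class logit
with respect to that T×d activation, as in the classic class-activation
formulation; the activation term, however, is each frame's *deviation from
the temporal mean* rather than the raw value — the hook activations are
signed log-energy features whose large common offset would otherwise
dominate the weighted sum (the classic recipe presumes nonnegative
post-ReLU feature maps). Frame relevance is the ReLU of the weighted
deviation sum, normalised to max 1 (identically zero maps are returned as
zeros with a flag) and linearly interpolated to sample resolution. 2-D embedding views use t-SNE
with a fixed random state; perplexity is shrunk with a warning when the
sample count is too small.

## Numerical and engineering notes

- All neural components run on a compact reverse-mode autodiff engine over
  numpy arrays written for this package (broadcasting arithmetic, batched
  matmul, reductions, structural ops); float32 parameters, float64 loss
  oracles. Gradient correctness is tested against central finite
  differences.
- Determinism: every stochastic component (cohort, initialisation, batch
  order, dropout, augmentation) derives from explicit integer seeds;
  repeated runs are bit-identical.
- Stored models drop their retained forward graphs (`release_graphs`) so a
  cross-validation result holds parameters only.
- Known limitations: single-head attention and small widths are not a
  substitute for pre-trained encoders; the eGeMAPS feature mathematics is
  deliberately not implemented (tables from an external extractor are
  validated and ingested); the optional loader for published pre-trained
  checkpoints is out of scope — any callable satisfying the encoder
  contract can be plugged in instead.
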