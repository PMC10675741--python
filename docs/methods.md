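# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `fallrisk`.

## Problem setting

The package targets continuous gait monitoring of people with impaired
balance (e.g. stroke survivors with hemiparesis) using one ankle-mounted
IMU: six channels — accelerometer x/y/z in m/s² and gyroscope x/y/z in
deg/s — sampled at 40 Hz, with observed signal ranges within ±40 m/s²
and ±260 deg/s. Each subject carries a Berg balance score (observed
range 33–56; higher = better balance) and a gait-quality group (1–5).
The goal is to flag the *instants* of a recording that carry the most
fall risk without ever labeling such instants for training: the encoder
is trained to predict the Berg score, and its attention map is read
back as a per-timestamp importance curve.

## Data representation

Recordings are cut into 10 s windows with a 1.25 s overlap between
consecutive windows (stride 8.75 s = 350 samples). Windows anchor at
sample 0; a trailing partial window is discarded. A 10 s window holds
roughly six steps at the default cadence, enough for repetition and
asymmetry to be visible. Each 400-sample channel is folded row-major
into a 20 × 20 matrix (`matrix[i][j] = channel[20·i + j]`), and the six
matrices are stacked into the 20 × 20 × 6 model input; the folding is
exactly invertible, which is what lets attention positions be mapped
back to timestamps (`p = 20·i + j ↔ t = p`).

Channels are z-scored with statistics computed on the *training*
partition only (raw m/s² and deg/s scales differ by roughly 6×, and the
augmentation magnitudes below are defined in z-units). A zero-variance
channel falls back to a unit divisor with a warning. An identity mode
is available.

The train/eval split is stratified per (subject, activity) and defaults
to **training on 20%** of windows and evaluating on the remaining 80% —
deliberately inverted from the usual 80/20 to demonstrate label
efficiency. Strata with fewer than two windows go to evaluation.

## Augmented views

Each training window is paired with four views, in fixed order:

| view | rule | defaults |
|---|---|---|
| noise | add Gaussian noise per channel, sd = `sd_scale`·channel sd | `sd_scale` 0.05 |
| quantize | snap each channel to `n_levels` equal levels spanning its min–max | `n_levels` 20 |
| drift | add a smooth curve through `n_knots` offsets in ±`max_drift` | `max_drift` 0.5, `n_knots` 5 |
| reverse | time-reverse every channel | — |

Magnitudes are in normalized (z-score) units and were fixed once at
values that perturb without destroying the signal. Noise is
zero-centered by default: centering it on each channel's own mean (an
alternative reading of "a Gaussian with a mean computed for each
signal") shifts the view's amplitude and is available as
`noise_center="mean"`. Drift uses a shape-preserving PCHIP interpolant
so the added curve never overshoots ±`max_drift`. Every stochastic view
is a deterministic function of (input, parameters, seed), with per-view
sub-seeds spawned from the window seed.

## Encoder and attention block

```
input (6×20×20) → 1×1 stem conv (6→D) → ReLU
                → self-attention block → global average pool → embedding (D)
```

Defaults: embedding dimension D = 64; key/query channels D/8 (floored
at 1); value channels D. The attention block computes key, query, and
value with three convolution layers (kernel size from
{1, 2, 4, 6, 8}, default 1 — the optimum found by grid search), flattens
the 20 × 20 positions to S = 400, forms logits Q^T K, and softmaxes over
key positions, giving a row-stochastic S × S map. The attended values
are gated by a learned scalar:

    y = γ · o + x,   γ initialized to 0.

With γ = 0 the block is exactly the identity and the encoder equals the
same network with the block deleted — a property the tests assert. The
gate makes γ's learned magnitude a direct measure of how much the model
relies on attention. Where the gate acts (before the residual addition)
is a design choice; only this gated-residual form is implemented. The
stem is kept minimal (one 1×1 convolution) since the three K/Q/V layers
are the architectural core; global average pooling produces the
embedding.

The regression head is one linear map from the 5·D concatenation of the
five view embeddings to a scalar. At inference on a bare window the
original embedding is replicated five times, because the head's input
layout is five views. Berg targets are z-scored inside `train()` (the
statistics travel with the model and predictions are rescaled to Berg
points); with raw 33–56 targets the scalar head would need thousands of
Adam steps just to reach the target's mean.

The network and its backpropagation are implemented directly in numpy
(convolutions via im2col with a 1×1 fast path; softmax and attention
gradients in closed form) and verified against finite differences to
~1e-9 in the test suite. Optimization uses Adam (β = 0.9/0.999,
ε = 1e-8, no weight decay).

## Losses and pairing

Total loss: `λ·L_contrastive + (1−λ)·L_MAE` with λ = 0.5 (neither the
mixing weight nor the margin is prescribed anywhere; both are config
keys, margin default 1.0). Pairs per batch of B windows: all
C(5,2) = 10 within-window view pairs are positives (y = 1);
original-vs-original pairs across windows are negative candidates
(y = 0), subsampled to at most the positive count. The method is
non-contrastive in spirit — alignment of views — but the margin loss has
a live y = 0 branch, and in-batch negatives keep it meaningful and
guard against representation collapse; `positives_only=True` gives the
strict alignment-only reading.

Grid search covers batch size {1, 4, 8, 16, 32}, learning rate
{1e-2 … 1e-5}, epochs {5 … 50}, and attention kernel {1, 2, 4, 6, 8}
(700 combinations in full), ranking by validation MAE with ties broken
toward fewer epochs, then smaller batches. The package default is the
optimized configuration: batch 4, learning rate 1e-3, 20 epochs,
kernel 1.

## Synthetic cohort generator

The generator emulates the *conditions* of a rehabilitation gait study,
not its biomechanics:

- **Profiles.** Berg score uniform on {33 … 56}; gait group mapped
  monotonically from the score onto 1–5; paretic side
  left/right/none with probabilities 0.45/0.45/0.10; step frequency
  ~N(0.6, 0.05) Hz per foot (≈6 steps per 10 s window).
- **Event-rate link.** Instability events per minute
  `r = 6·(56 − berg)/23 + 0.2`: strictly decreasing in the Berg score,
  from 6.2/min at the worst observed balance to a 0.2/min floor at the
  best. The linearity is a modeling choice (simple and monotone); slope
  and floor are configurable.
- **Signal.** Per channel, a sinusoid at the step frequency plus one
  harmonic whose amplitude is asymmetric by paretic side, plus Gaussian
  sensor noise (sd 0.3 m/s² for accelerometer channels, 10× for
  gyroscope channels); amplitudes keep event-free |acc_y| well below
  5 m/s². Channels are clipped to ±40 m/s² / ±260 deg/s.
- **Events.** Poisson-placed (count mean = rate·duration, ≥1 s apart),
  each a 150–250 ms raised-sine burst on acc_y peaking at 18–34 m/s²
  with random sign, with smaller echoes on the other axes. This shape
  rises from below 5 to above 15 m/s² within ≤300 ms — exactly the
  signature the reference labeler detects. The ground-truth instant is
  the first sample where the burst drives |acc_y| across 5 m/s²,
  aligning the simulator with the labeler convention.
- **Activities.** Default catalogue: 6-minute walk (391 ± 13 s), get up
  and go (50 ± 29 s), one-foot balance (53 ± 31 s), step (46 ± 27 s),
  leaning (71 ± 6 s); durations are drawn per recording and truncated
  at 12 s.

Everything is bit-reproducible from the config seed (per-recording
seeds are spawned from a root `SeedSequence`).

**What the generator does not emulate** — and hence what passing tests
do not show about clinical data: realistic gait biomechanics and
inter-stride variability, sensor drift and calibration error, activity
transitions, the true (uncharacterized) statistics of instability
events, demographic structure, and any within-subject correlation
beyond the event rate. The burst shape in particular is a stand-in.
Results on this cohort demonstrate that the pipeline recovers a known
balance-score/event link, not that it detects real falls.

## Risk detection and evaluation

**Timestamp weights.** Importance of position p = mean over queries of
`A[q, p]` (the column mean — attention *received*; a row-mean variant
is available), scaled by |γ| and max-normalized per window. γ = 0
therefore yields all-zero weights and no flags.

**Flagging.** Candidate instants are all samples with weight ≥
threshold (default 0.1; 0.5 is the strict alternative). Weight-ordered
non-maximum suppression with a 250 ms refractory radius keeps the
locally highest-weight sample of each excursion; the same suppression
merges flags across overlapping windows (pooling each instant's maximum
normalized weight). Flagging the excursion *peak* rather than its rim
makes flag sets provably nested across thresholds — raising the
threshold can only remove flags — which is the monotonicity the
0.1-vs-0.5 trade-off analysis relies on.

**Reference labeler.** |acc_y| is used (magnitude, not signed
exceedance, since the mounting frame's sign convention is arbitrary);
events at rising crossings of 5 m/s² plus jump-rule events at the start
of any ≤300 ms rise from ≤5 to ≥15 m/s², deduplicated within 250 ms
(first instant kept). The vertical axis and all levels are
configurable.

**Scoring.** Each reference event owns an inclusive acceptance interval
— `[r−w, r]` (before), `[r, r+w]` (after), `[r−w, r+w]` (centered) —
for w ∈ {125, 250, 500} ms. Matching is greedy earliest-first and
one-to-one. True negatives are counted at sample-instant granularity
(`n_samples − tp − fp − fn`), which makes the heavy class imbalance of
rare-event detection explicit in the confusion matrices. Recall is
non-decreasing in w by construction; the tests also verify it
empirically.

## Problem sizes and reproduction

The test suite and `scripts/acceptance.py` run the study at desk scale:
16 subjects, a 180 s walk plus a 50 s mobility exercise per subject
(~400 windows, ~80 of them for training), 10 epochs at the optimized
hyperparameters. These sizes were chosen so a full reproduction
completes in about a minute on one CPU core while leaving the
qualitative results stable across seeds: held-out subject-level
Spearman ρ between true and predicted Berg scores around 0.85–0.91, and
centered-500 ms recall of the attention flags above the 95th percentile
of a 200-draw random-placement null with matched flag counts.

## Known limitations

- The attention-to-timestamp projection (column mean) is the simplest
  faithful reading; other projections (row mean, diagonal) are
  plausible and one is exposed as an option.
- One attention block, no multi-head attention, no deeper backbone.
- Precision of the attention flags on the synthetic cohort is low at
  threshold 0.1 (many flags fall outside reference intervals); the
  pipeline's claim is ranking and above-chance localization, not
  calibrated alarm rates.
- Training determinism holds for a fixed BLAS backend; across backends
  bit-level results may differ.
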