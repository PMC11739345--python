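# Methods

This note documents the models, numerical choices, and design decisions
behind the package, and what the synthetic benchmark does and does not
establish.

## Problem setting

The classification unit is a fixed-length EEG window X̃ ∈ ℝ^{C×W}
(microvolts, C channels at sampling rate fs) with a label y ∈ {1..K}
describing a brain state (e.g. low vs high arousal). Recordings are
band-pass filtered, cleaned with ICA, segmented (sliding or event-locked
windows), and z-scored per window and channel before classification.

## Preprocessing chain

- **Band-pass.** Fourth-order Butterworth design, 0.5–50 Hz by default,
  applied forward–backward (`sosfiltfilt`), so the effective order is eight
  and the phase response is exactly zero. Zero phase preserves event timing;
  the pass-band gain at 10 Hz deviates from unity by well under 5 % and a
  0.05 Hz drift or a 60 Hz mains component (at fs = 128) is attenuated by
  more than 20 dB.
- **ICA artifact removal.** FastICA decomposes the band-passed recording
  into C sources. Components are rejected by automated criteria standing in
  for manual review: (a) *blink* — absolute correlation with a blink
  template (supplied, or estimated as the < 5 Hz low-passed mean of the
  frontal channels) above 0.7; (b) *line noise* — more than half the
  component's Welch power within ±1 Hz of the mains frequency (default
  50 Hz, configurable for 60 Hz data); (c) *muscle* — more than 60 % of
  power above 30 Hz. The signal is rebuilt from retained components.
  Near-Gaussian background sources can stall FastICA's fixed-point
  iteration without invalidating the unmixing estimate, so non-convergence
  is logged but the decomposition is kept; hard failures return the input
  unmodified with an empty rejection list.
- **Bad channels.** A channel's SNR estimate is
  10·log10(P_passband / P_out-of-band) from Welch spectra of the raw
  signal; channels below 20 dB (default) are flagged and replaced by the
  arithmetic mean of their good neighbors from a user-supplied neighbor map
  (no montage geometry is assumed).
- **Normalization.** Per window and channel, mean 0 and variance 1; a
  variance floor of 1e-8 maps constant channels to all-zero with a logged
  warning. The operation is idempotent.

## Synthetic generator

Each class is defined by relative power weights over the canonical bands
(delta 1–4, theta 4–8, alpha 8–12, beta 13–30, gamma 30–45 Hz) and a
ground-truth C×C inter-channel correlation matrix (symmetric, unit
diagonal, entries in [0, 1], positive semidefinite — non-PSD targets are
rejected with a shrinkage suggestion). A window is a weighted sum of
band-limited Gaussian processes; each band's C independent unit-variance
processes are mixed through the symmetric matrix square root of the target
correlation, so the generated windows carry both the spectral signature and
the connectivity exactly, up to sampling noise. The standard benchmark
(`two_class_spec`) is 8 channels at 128 Hz, 2 s windows, amplitude 20 µV:
class 1 alpha-dominant with strong within-community coupling (two
4-channel blocks, 0.6 within / 0.1 between), class 2 beta/gamma-raised with
flatter coupling (0.3 / 0.4) — the band-power direction mirrors the
low- vs high-arousal signatures reported for affective EEG.

Artifacts: blinks are Poisson-timed 300 ms half-cosine bumps mixed with an
exponentially decaying frontal topography; mains interference is a pure
sinusoid. Additive white noise at a requested SNR is rescaled per window so
the realized 10·log10(P_signal/P_noise) is exact, with powers defined as
per-window mean squares over all channels.

What the generator does **not** emulate: 1/f spectral background,
non-stationarity, inter-subject variability, volume conduction, or real
artifact morphology. Green tests therefore establish correctness of the
machinery and learnability under controlled conditions — not expected
accuracy on real recordings.

## Model

- **Temporal stream.** Non-overlapping patches (default 0.125 s, i.e. 16
  samples at 128 Hz) are flattened across channels and linearly embedded to
  d_model (default 64). Nodes are patch-level time steps (the channel
  dimension is handled by the spatial stream); the edge mask is full by
  default or banded ±k. Multi-head (default 4) scaled dot-product attention
  produces a row-stochastic A_t per head; masked entries are exactly zero.
  Propagation uses the head-averaged A_t in
  H^(l+1) = ReLU(A_t H^(l) W^(l)) (one layer by default), and the temporal
  feature h_t is the node mean. The "dynamic graph" is realized through
  input-dependent attention weights over a fixed mask rather than discrete
  re-wiring.
- **Spatial stream.** Channel time courses are linearly embedded to width d.
  The hierarchy's level-1 adjacency comes from one of: a learned scorer
  (default), a supplied matrix (e.g. functional connectivity), or full
  connectivity. Convolutions use D^{-1/2}(A+I)D^{-1/2}; self-loops are
  added before normalization so isolated nodes remain well-defined. Pooling
  to the next level is mean by default (max and softmax-attention
  available; uniform attention reduces to the mean). PAD mean-pools each
  level to one vector of shared width d, aggregates across levels
  (sum/mean/attention), and adds W_PAD·H_global back to every node of every
  level. The spatial feature h_s is the top level's node mean.
- **Learned adjacency.** W_ij = softplus(z_iᵀ M z_j + aᵀ[z_i‖z_j] + b),
  symmetrized, with z = θᵀx a width-16 projection of the channel
  embeddings. The bilinear term is essential: a purely node-additive
  (concatenation-only) scorer can only modulate node degrees and cannot
  express community structure, whereas z_iᵀ M z_j tracks realized
  inter-channel correlation. Initialization keeps the softplus out of its
  saturated region (small weights, bias −1, so W starts near a weak uniform
  graph ≈ 0.31): large initial scores put the alignment gradient in the
  softplus dead zone and the learned graph collapses toward zero instead of
  structure.
- **Fusion and loss.** One fusion head serves the whole model (the temporal
  and spatial streams feed the same ReLU affine layer and softmax output).
  Cross-entropy is averaged over the batch; predicted probabilities are
  floored at 1e-12 before the log, with a warning when a true class is
  floored. The optional alignment term λ·‖C − W‖²_F (λ = 0 by default)
  pulls the per-window learned adjacency toward that window's rectified
  Pearson correlation matrix.
- **Ablations.** Without the temporal attention stack, h_t is the
  mean-pooled patch embedding; without the hierarchy, h_s comes from a
  single-level fully connected convolution; without the fusion layer, the
  head is a ReLU of separately projected h_t and h_s summed. All variants
  keep the training interface.

The stack is implemented in NumPy on a small reverse-mode autodiff core
(`eegmind.autodiff`) providing batched matmul, broadcasting arithmetic,
reductions, concatenation, and a masked softmax; an end-to-end gradient
check against central differences is part of the test suite.

## Training protocol

Adam with the reference protocol's initial learning rate 1e-4, batch size
64, a cosine-annealing schedule with warm restarts (initial period 10
epochs, period doubling), early stopping after 10 epochs without
validation-loss improvement, and best-validation checkpointing. Splits are
stratified 80/10/10; stratified 5-fold cross-validation is provided as an
alternative protocol (the two are selected by configuration, not
composed). Augmentation (random crop+resize, SNR-scaled noise, circular
jitter, piecewise-linear time-warp) is label-preserving and off by default.

**Desk-scale schedule.** The benchmark experiments compress the reference
schedule (1000 epochs at lr 1e-4) into 30 epochs by raising the initial
learning rate to 1e-2; with ~5k parameters and 320 training windows this
converges in seconds and reaches ≥ 93 % validation accuracy across seeds.
The structure-recovery experiment uses 60 windows/class, 60 epochs at
lr 3e-2 with early stopping disabled, and a dominant alignment weight
λ = 10 against a λ = 0 control; with the cross-entropy objective active,
weaker weights leave the scorer short of convergence within the step
budget. Metrics in that experiment compare each class's ground-truth
connectivity with the mean learned adjacency over that class's validation
windows. These scales are the package's reference conditions and are also
what `scripts/acceptance.py` runs.

## Evaluation

Accuracy, macro-averaged recall/precision/F1, one-vs-rest macro AUC, and
sensitivity/specificity from the confusion matrix; in the binary case
sensitivity is the recall of class 2 ("positive") and specificity the
recall of class 1. Single-class evaluation sets report AUC as missing with
a warning. The noise-robustness harness evaluates the trained model on
noise-injected copies of the dataset at 20/10/5 dB and tabulates accuracy
and F1 per tier next to the clean baseline.

## Connectivity statistics

- Functional connectivity: Pearson correlation of channel time courses
  (windows are concatenated along time when a stack is given); constant
  channels get correlation 0, logged.
- Graph similarity S is the cosine between matrix entries. The [0, 1] range
  holds for nonnegative inputs, so Pearson matrices are rectified
  (absolute value) by default before comparison; this is configurable.
- Modularity uses the standard Newman form
  Q = (1/2m)·Σ_ij [W_ij − k_i k_j/(2m)]·δ(g_i,g_j) with k the weighted
  degrees and 2m the total weight.
- The group contrast is the Welch unequal-variance t with
  Welch–Satterthwaite degrees of freedom for the two-sided p-value;
  zero variance in both groups with equal means returns t = 0.
- Node importance is the normalized weighted degree (sums to 1).

## Known limitations

- FastICA separates the blink because it is the dominant non-Gaussian
  direction; on fully Gaussian data component identity is arbitrary, which
  is inherent to ICA, not to this implementation.
- The learned-adjacency scorer sees only linear projections of raw
  windows; it recovers correlation structure but not directed or lagged
  coupling.
- Subject-level grouping is exposed as an optional key but the synthetic
  fixtures carry no subject identity, so cross-validation is stratified
  over windows.
- The structure-recovery contrast is stochastic: the λ = 0 control's
  adjacency occasionally lands close to the ground-truth pattern by
  chance, so the comparison is framed as a majority of seeded runs rather
  than a per-seed guarantee.
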