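# Methods

## Problem setting and model

The package addresses sleep-to-fatigue transfer for single-channel EEG. The
unit of analysis is a 30 s epoch with one class label: five sleep stages
(W, N1, N2, N3, REM) in the source domain, three fatigue levels (Awake,
Mild Fatigue, Severe Fatigue) in the target domain. The two domains share a
marginal-distribution mismatch (different subjects, electrodes — Fpz–Cz vs
O1 — recording conditions and sampling rates), which is what the MMD penalty
addresses.

### Feature extractor

A dual-branch 1-D CNN over the raw 3000-sample epoch (30 s × 100 Hz):

| stage | small branch | large branch |
|---|---|---|
| conv 1 | kernel 50, stride 6, 64 filters | kernel 400, stride 50, 64 filters |
| maxpool | 8 / 8 | 4 / 4 |
| conv ×3 | kernel 8, 128 filters | kernel 6, 128 filters |
| maxpool | 4 / 4 | 2 / 2 |

ReLU activations; dropout 0.5 after each pooling stage. The first (wide)
convolutions and the pools are valid; the three mid convolutions use *same*
padding — valid padding is geometrically impossible there, because the large
branch is only 13 samples long after its first pool while three valid
kernel-6 convolutions need at least 16. Branch outputs are truncated to the
shorter time length and concatenated to 256 channels (per-epoch sequence
lengths 15 and 6 at the default geometry, merged at 6).

Two normalisations are part of the architecture. Each epoch is z-scored at
the extractor input: EEG arrives on a microvolt scale (tens of µV) and
unnormalised inputs saturate the downstream recurrent gates. Each pooled
epoch embedding is then layer-normalised (parameter-free, across its 256
dims) before the encoder: the ReLU/pool chain emits features with a tiny
dynamic range (per-dim spread ~0.01 at initialisation), and without
rescaling the sequence model receives nearly constant inputs and
desk-scale training stalls at chance.

### Sequence classifier

Sequences of 10 consecutive epochs feed a seq2seq model: 2-layer BiLSTM
encoder (128 units per direction), Luong multiplicative attention with a
64-dim projection, 2-layer LSTM decoder (128 units) whose input is a 10-dim
embedding of the previously decoded label (teacher forcing in training,
greedy decoding at inference; a 6-entry embedding table covers the five
source classes plus a start token, so the table survives head replacement).
Each decoding step t combines the attention context, the step-t encoder
state, and the decoder state through a dense+tanh layer before the class
head. Feeding the aligned encoder state is a deliberate design choice for
this sequence-labeling setting (inputs and labels align one-to-one): with
near-uniform initial attention every step would otherwise see the same
averaged context, and short training runs cannot break that symmetry.

Initialisation: Glorot-uniform for conv/dense kernels, per-gate orthogonal
for recurrent kernels, zero biases (so an all-zero epoch yields all-zero
extractor features at initialisation — a property the tests pin).

### MMD and the training protocol

The biased (V-statistic) multi-kernel Gaussian MMD² is used as the
adaptation loss; the kernel is a convex combination of L Gaussian widths on
a geometric ladder σₗ = σ·f^(l−(L−1)/2) with equal weights 1/L (defaults
L = 5, σ = 2, f = 2 → 0.5, 1, 2, 4, 8). The weights are never optimised. An
unbiased (U-statistic) variant is available but not the default. The MMD is
taken between the encoder's per-sequence pooled hidden states of equal-sized
source and target batches — the deepest trainable representation under the
freezing scheme.

Stages: (1) source pre-training minimises `CE + β·L2` end-to-end;
(2) adaptation replaces Dense(5)→Dense(3), freezes the extractor
(checksum-verified), and minimises `CE_target + λ·MMD² + β·L2` over the
seq2seq parameters only; (3) fine-tuning is stage 2 with λ = 0 and no
source batches — with the same seed it follows the bit-identical
trajectory, which the tests assert. Source-domain cross-entropy during
adaptation is exposed as a config toggle but off by default (it would need
a source→target label mapping). Optimiser: RMSProp, lr 0.001, ρ = 0.9,
ε = 1e-8; L2 sums the squared norms of all trainable parameters with
β = 0.001; λ defaults to 1 (the loss is written as an unweighted sum).

Since the frozen extractor runs without dropout during adaptation, epoch
embeddings are constants and are precomputed once per run.

### Grid search

`grid_search_kernels` holds out 20% of the target sequences, then evaluates
each (kernel width, kernel count) cell by k-fold cross-validation on the
remainder, re-running only the adaptation phase per cell from a clone of
the pre-trained model. With the default five folds, each fold trains on 4
parts and validates on 1 — this realises the 4:1 train/validation ratio;
the two split descriptions compose rather than conflict. Ties break toward
the smallest kernel count, then the smallest width (preferring the simpler
kernel family). The package defaults (width 2, five kernels) follow the
validation optimum reported for this protocol on real recordings.

## Preprocessing

* **Bandpass**: 0.5–45 Hz, 4th-order Butterworth applied forward-backward
  (zero phase, so epoch-aligned labels are not latency-shifted), with
  even-reflection edge padding — the default odd reflection doubles the
  slope discontinuity at epoch edges and leaks stop-band energy back into
  the filtered epoch (60 Hz rejection degrades from ~97% to ~92%).
* **ICA artifact removal**: single-channel data offers no spatial mixture,
  so consecutive fixed-length windows (default 2 s) are stacked as
  pseudo-channels and FastICA (deflation) separates temporal components.
  A component is rejected when its excess kurtosis exceeds 5 (sparse
  transients: blinks) or >60% of its power lies below 4 Hz (slow ocular
  drift). Only the rejected components' contributions are subtracted from
  the original signal, so when nothing is rejected the data pass through
  bit-exactly and the whitening truncation error never touches clean data.
* **Resampling**: polyphase (rational approximation of the rate ratio),
  used to bring 128 Hz target recordings to the 100 Hz geometry the network
  expects; output length is `round(new_rate × duration)`. The 128→100 Hz
  default is a reconciliation choice, not a property of the data.
* **EDF**: reading goes through MNE; a minimal 16-bit single-channel EDF
  writer is included so round-trip tests need no external recordings.

## Synthetic data

The generator emulates exactly what the pipeline consumes: fixed-length
single-channel epochs (default 30 s at 100 Hz) whose class identity is a
band-power signature over delta/theta/alpha/beta, realised as three
random-frequency oscillators per band over a 1/f background (30% relative
RMS), plus blink/EMG artifact injection with the clean ground truth
returned alongside. Source signatures follow stage physiology (wake
alpha/beta, N1 theta, N2 mixed at higher amplitude, N3 delta-dominant at
the largest amplitude, REM low-amplitude theta/beta). The target classes
draw uniformly from linked source signatures — W→Awake, {N1,N2}→Mild,
{N3,REM}→Severe — a synthetic-world convention only, chosen so transfer
gain is measurable; under an identity shift the target class-conditionals
are exact mixtures of source ones, which a test verifies via an FFT
band-power oracle. The covariate shift is parametric: amplitude gain,
additive white noise (µV), and a frequency drift applied to the
oscillators. Everything is deterministic given one seed.

What the generator does *not* emulate: volume conduction or any biophysical
forward model, non-stationarity within epochs, subject-level variability,
or realistic artifact morphology beyond band placement. Passing tests
therefore demonstrate that the pipeline's machinery behaves as specified
under controlled shift, not that a given accuracy will hold on real
driving EEG.

## The adaptation benchmark

The documented MMD-vs-fine-tune comparison uses 50 epochs per class
(250 source / 150 target), shift gain 1.5 and noise sd 5 µV, five seeds.
Stage 2 sees only 3 labeled target sequences (30 epochs) — the transfer
setting assumes scarce target labels, and with generous labels plain
fine-tuning saturates the synthetic task, leaving the comparison
uninformative — and both arms start from the same pre-trained model and
are scored on the remaining 120 held-out target epochs. Pre-training runs
30 epochs (batch 5 sequences) and stage 2 runs 30 epochs; these counts are
desk-scale choices that leave source training around 85% accuracy. The
claim checked is directional (adapted ≥ fine-tuned on average), not an
absolute accuracy.

## Numerical choices and limitations

* All numerics are float64 on a numpy reverse-mode autograd engine written
  for this package; convolution forward/backward go through BLAS
  (`tensordot` on im2col windows). Training is bit-reproducible given the
  config seed; there are no nondeterministic kernels.
* Epochs are half-open sample intervals, 0-based; sequence formation drops
  the trailing partial sequence; epoching drops the trailing partial epoch.
* Zero denominators in metrics yield 0 with a logged warning; display
  rounding is half-up (1 decimal for percent, 4 for fractions, snapped to 6
  decimals first so binary float noise cannot flip a boundary); internal
  values are never rounded. Confusion matrices are rows = true,
  columns = predicted — the orientation consistent with every reference
  precision/recall pair. K-fold aggregation reports the arithmetic mean and
  sample variance (population variance by option).
* The closed-form length calculator (and hence the extractor) requires
  inputs long enough for the large branch to survive both pools — about
  1000 samples; shorter inputs raise.
* Known limitations: no multichannel montages or re-referencing; no
  linear-time MMD approximations or kernel-weight learning; no significance
  testing between models; the seq2seq sequence length (10 epochs) and the
  MMD tap point are design choices the source material leaves open.
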