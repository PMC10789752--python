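# Methods

This note documents the models and procedures implemented in
`preictal`, the defaults chosen where the method leaves room, and what
the synthetic experiments do and do not demonstrate.

## Period definitions and sampling

Time is measured in seconds from recording start; all intervals are
half-open `[start, end)` and windows are 0-based.  For each seizure
onset `o` the pre-ictal candidate is `[o − 60·m, o)` with
`m ∈ {10, 15, 30}` minutes, ending exactly at onset (no forecasting
horizon gap).  Inter-ictal time is the complement of the union of
`[onset − 3 h, offset + 3 h]` buffers.  Everything else — ictal spans,
the buffers, and pre-ictal candidate time that overlaps an earlier
seizure's ictal interval — is excluded.  When an earlier seizure splits
a candidate, only the contiguous clean remainder abutting the onset is
kept; if that remainder is shorter than one 10-s window the seizure is
skipped and logged.  These clustered-seizure rules are this package's
choice; the method itself does not specify them.

Class balance is restored per seizure: one contiguous inter-ictal block
of exactly the pre-ictal duration is drawn with a seeded RNG, uniformly
over all admissible start points (the block must fit inside a single
inter-ictal interval).  Contiguity keeps the block usable for sequence
models and the per-seizure pairing defines the cross-validation unit.
Both segments are then cut into 10-s windows sliding by 1 s
(`floor(L − 10) + 1` windows for an L-second segment), which
simultaneously oversamples the scarce data and keeps the two classes
exactly balanced.

## Spectrograms

Each window is transformed per channel with a short-time Fourier
transform: 1-s Hanning window (exactly `sfreq` samples, so bins are
1 Hz at both 200 and 256 Hz), 50 % overlap, zero-padded boundary
framing.  The padding places frame centres at 0, 0.5, …, 10 s — 21
frames; without it only 19 full frames exist.  Frames are the plain
windowed DFT sums.  The magnitude is log-compressed as `log(1 + |X|)`
(configurable; the method does not state whether amplitude, power or a
log scale feeds the network, and log compression is the standard choice
for spectrogram images), and the band crop keeps bins 0–59 Hz — 60 rows
including DC, matching the tensor width the architecture expects.

## Augmentation

Two views per source spectrogram, used only in the pretext task:

* **band-stop**: a contiguous `[f0, f0 + w)` Hz band is zeroed, `f0`
  uniform over the 61 − w admissible integer offsets.  Width default
  10 Hz (the tuned value is not published; the knob is
  `augment.bandstop_width_hz`).
* **temporal cutout**: a contiguous 6-s span is zeroed; the start is
  drawn uniformly on the 0.5-s frame grid and frames whose centre falls
  in the half-open span are cleared — exactly 12 of 21 frames for every
  admissible offset (a full-window cutout clears all 21, including the
  boundary frame).

Masks are applied to the spectrogram image (not as signal-domain
filters) and span all channels jointly.  Untouched entries are
bit-identical to the source; labels and shapes never change.

## Losses

Embeddings are L2-normalised before the loss, so the logits are
temperature-scaled cosines; without normalisation 512-d dot products
overflow `exp`.  The losses sum over all 2N anchors; `A(i)` excludes
only the anchor, and `P(i)` is defined by labels (supervised) or by the
sibling view (self-supervised).  Anchors without positives are dropped
with a warning; an all-singleton batch falls back to view pairing.  The
temperature default is τ = 0.07 (unpublished in the method; exposed in
config).  No projection head is used — the encoder output feeds the
loss directly.  Log-sum-exp is computed with per-row max subtraction.
During training the loss is additionally divided by 2N so the gradient
scale is batch-size independent; the reference (sum) form is kept in
`preictal.contrastive` and the two are tested against each other and
against brute-force double-loop oracles.

## Architecture

The encoder is the five-block residual layout that reproduces the
printed feature-map chain on 21 × 60 inputs: a 3×3 stride-1 stem (no
7×7/stride-2 stem, no stem max-pool — a standard-ImageNet stem would
collapse the 21-pixel axis), then four stages of two basic blocks with
stage strides (1, 2, 2, 2), 3×3 kernels, padding 1, batch-norm after
every convolution, and 1×1 stride-2 projection shortcuts where shape
changes.  Stride-2 arithmetic gives 21 → 11 → 6 → 3 and 60 → 30 → 15 →
8; adaptive average pooling and flatten yield the 512-d embedding.

The LSTM is a single layer on the concatenated `[h, x]` vector with the
classic gate equations (the output gate multiplies `tanh(C_t)`).
Hidden size defaults to 128 (64-unit `[h,x]` blocks at desk scale).  By
default each 10-s window is one classification unit (sequence length
S = 1); a config option groups S consecutive windows of one segment
into a sequence, since the method does not state where the LSTM's time
axis comes from.  The head is ReLU → dropout (p = 0.5, train mode only)
→ affine map to two logits.

Everything runs on a small numpy reverse-mode autodiff core:
convolution as im2col + GEMM (input transposed to channel-first so the
column copies are near-contiguous), batch-norm composed from
differentiable primitives, and SGD with classical momentum 0.9.
Gradients are verified against central finite differences in the tests.

## Training protocol

Reference hyperparameters: SGD, batch 512, 300 pretraining epochs at
lr 0.05, then 100 fine-tuning epochs at lr 0.01 on the original
(un-augmented) spectrograms.  Pretraining uses a class-balanced batch
sampler (half of each batch per class) so every anchor has a positive
beyond its sibling view.  Cross-validation is leave-one-unit-out: the
N − 1 training units never share a segment with the test unit, so the
9-s window overlaps cannot leak across the split (asserted at run
time).  Per-patient metrics are micro-averaged (confusion counts summed
over folds before the ratios) — per-fold ratios on a dozen windows are
too unstable.  Metrics with zero denominators are reported as NaN, not
zero.  The paired t-test between arms is two-sided on per-patient
means, with a NaN marker when the differences have zero variance.

Two runs with equal seeds and configuration are bit-identical on fixed
hardware: every stochastic choice (initialisation, batch order,
augmentation masks, undersampling draws, dropout) flows from explicit
`numpy` generators.

### Desk-scale profile

`TrainConfig.desk_scale()` is the profile used by the tests and sized
for a single CPU with the numpy backend: batch 32, 10 + 10 epochs at
the reference learning rates, encoder width divided by 8 (widths
8, 8, 16, 32, 64; 64-d embedding), LSTM hidden 32, and one training /
evaluation window kept per 50 s of segment.  Because batch-norm's
exponential running statistics lag the weights when only a few dozen
optimiser steps are taken, both training phases end with an exact
recalibration pass that replaces the running statistics with cumulative
averages over the training data under the final weights; without it
eval-mode predictions diverge sharply from train-mode behaviour at this
scale.  The full-width profile keeps the printed hyperparameters and
the structural contracts (shape chain, embedding length) are always
tested at full width.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
exploits: per-channel `1/f`-amplitude background noise with a white
floor (unit variance, scaled to 30 µV RMS), seizure onsets placed so a
leading inter-ictal region, the 3-h buffers, and the seizure train
coexist by construction, and — during each pre-ictal span — an added
independent band-limited component calibrated per channel so the power
in `effect_band` (default 14–20 Hz) is multiplied by `effect_size` in
expectation.  `effect_size = 1` adds nothing and is the exact
no-signal null; ictal spans are rendered as 3× amplitude bursts and are
excluded from sampling anyway.  Defaults mirror the 18-channel / 256-Hz
configuration.  Datasets round-trip through a built-in 16-bit EDF
writer and the same MNE-based reader used for clinical files, with at
most one quantisation step of per-sample error.

What passing synthetic tests show: the pipeline's plumbing, losses,
optimisation and evaluation operate correctly, recover a planted
band-power contrast, and stay at chance under the null.  What they do
not show: performance on real scalp EEG, whose pre-ictal signatures are
weaker, non-stationary, artifact-laden and patient-specific; the
desk-scale accuracy on synthetic data says nothing quantitative about
clinical recordings.

## Known limitations

* The EDF writer emits the plain 16-bit EDF variant (no EDF+
  annotations block); seizure times travel in the CSV bridge.
* Pre-ictal periods of temporally clustered seizures are handled by the
  truncation rule above; alternatives (merging, discarding) are
  plausible and unspecified by the method.
* Whether inter-ictal blocks may come from a different recording of the
  same patient is unspecified; this implementation draws them from the
  same recording.
* The numpy backend is single-threaded BLAS-bound; full-width,
  full-epoch training at the reference hyperparameters is out of reach
  on one CPU and is not attempted by the tests.
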