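# Methods

This note documents the models, algorithms and design choices behind
`rhythmnet`: what each stage computes, which knobs matter, what the
synthetic data generator does and does not emulate, and where the design was
genuinely open.

## Problem setting

The package classifies single-lead ECG recordings (300 Hz, 9–61 s) into four
rhythm classes: normal sinus rhythm (`N`), atrial fibrillation (`A`), other
rhythm (`O`) and noisy/uninterpretable (`~`). The pipeline is: record-length
filtering → wavelet + median-filter denoising → fixed-length normalization →
a deep 1-D CNN + BiLSTM classifier trained with a tan-mapped squared-error
loss (TMSE) → confusion-matrix evaluation, with a five-way ablation harness
over the preprocessing stages and the loss.

## Synthetic ECG generator

Real challenge recordings are an optional input; the mandatory, fully tested
path runs on synthetic records so that every stage is exercisable offline.

**Beat model.** Each beat is a sum of five Gaussians (P, Q, R, S, T) with
amplitudes in mV, center offsets relative to the R peak in seconds, and
Gaussian widths in seconds. The default template is a textbook lead-II-like
morphology with a dominant 1 mV R wave. This sum-of-Gaussians model is the
standard way to synthesize ECG morphology when only rhythm-level statistics
matter.

**Rhythm classes.** Classes are distinguished by the statistics a
cardiologist would use at rhythm level:

| class | mean RR (s) | RR CV | P wave | extras |
|---|---|---|---|---|
| N | 0.85 | 0.03 | yes | — |
| A | 0.70 | 0.20 | no | 0.05 mV fibrillatory oscillation at 7 Hz |
| O | 0.80 | 0.06 | yes | 18 % premature ectopic beats, QRS widened 1.8× |
| ~ | 0.85 | 0.03 | yes | noise rescaled to −3 dB SNR |

RR intervals are drawn i.i.d. from a Gaussian (N, O) or a log-normal (A —
heavy right tail, matching irregularly irregular conduction), truncated at
0.2 s so beats never overlap non-physiologically. Ectopic beats arrive
0.35·RR early, lose their P wave and widen their QRS. These values are
desk-scale stand-ins chosen once for physiological plausibility (resting
heart rates of 70–85 bpm; sinus-rhythm RR variability of a few percent
versus ≥ 15 % in atrial fibrillation); the source recordings' class
statistics are not published, so nothing here is fit to data.

**Noise model.** Additive contamination with independent components:
baseline wander (0.3 Hz sinusoid, respiration scale), powerline interference
(50 Hz by default, configurable to 60 Hz), broadband Gaussian noise
(EMG-like), and Poisson impulse artifacts. When a record requests a target
SNR the noise waveform is rescaled so that
`10·log10(P_clean / P_noise)` equals the target exactly; the clean signal
and realized SNR are kept in the record metadata for later bookkeeping.

**Determinism.** Generation is a pure function of (spec, seed): record seeds
are spawned from the master seed with `numpy.random.SeedSequence`, and
regeneration is bit-identical.

**What the generator does *not* emulate.** Real P/QRS/T morphology variation
across subjects and leads, heart-rate autocorrelation (the RR draws are
i.i.d.), rhythm transitions within a record, electrode pop/motion
transients with realistic spectra, and the heavy class imbalance of the
challenge corpus (the generator is balanced by default). Passing tests on
synthetic data therefore demonstrate that the pipeline is implemented
correctly and that it can learn rhythm-level statistics — not that it
reaches any particular accuracy on clinical recordings.

## Denoising

**Wavelet stage.** `wavedec`/`waverec` (PyWavelets) with symmetric boundary
extension, default family `db4` (a common ECG choice; the family is
configurable and nothing downstream depends on it when thresholding is off),
decomposition level 9. Detail coefficients are shrunk with the universal
threshold `σ·sqrt(2·ln n)`, σ estimated from the finest detail level as
MAD/0.6745; soft and hard rules are available, plus `none` (pure
decompose/reconstruct — a perfect-reconstruction identity to ~1e-14, which
the tests assert at 1e-8). Levels beyond the library's data-length heuristic
are deliberate (boundary extension keeps the transform invertible), so the
corresponding warning is suppressed.

*Which levels to shrink* is genuinely open. The default shrinks all detail
levels (classic VisuShrink). Measured on synthetic records, soft-shrinking
every level also attenuates QRS energy (most QRS power lives around 5–40 Hz,
i.e. detail levels 3–6 at 300 Hz), and in combination with the median stage
this distortion can cost more SNR than the removed noise is worth. The
efficacy tests therefore restrict shrinkage to the three finest detail
levels (> ~19 Hz), where broadband noise dominates and QRS energy is small;
`DenoiseConfig.threshold_levels` exposes the choice.

**Median stage.** A running median with edge replication (via
`scipy.ndimage.median_filter`, mode `nearest`), window odd. Two modes:
`smooth` (replace the signal by its running median) and the default
`baseline-subtract` (subtract the running-median trend — the only reading of
"superimpose the trend with the original signal" that actually removes
drift, so the subtraction is deliberate). The printed neighborhood size 9 is
kept as the default window, but 9 samples at 300 Hz is 30 ms: a median that
short tracks the whole signal, so subtracting it removes the ECG along with
the drift. For drift removal the window must straddle entire beats while
staying shorter than the wander period; the efficacy tests and the
desk-scale experiment configuration use 241 samples (~0.8 s). The window is
independently configurable for exactly this reason.

**Stage order and ablation flags.** Wavelet first, then median;
`use_wavelet`/`use_median` switch stages off individually, and the pipeline
equals the composition of the enabled stages (identity, with a warning, when
both are off).

## Network

The full architecture: 24 same-padded 1-D convolutions of kernel width 16 in
three 8-layer blocks of 32, 64 and 128 filters; each convolution is followed
by batch normalization, ReLU and dropout (rate 0.2, configurable — the
conventional conv → BN → ReLU → dropout order); a max pool of size/stride 2
after every two convolutions (12 pools, so a 9000-sample input reaches the
recurrent stack with temporal length 2); a BiLSTM with 64 units per
direction returning sequences, then a BiLSTM with 128 units per direction
whose final forward and backward hidden states are concatenated (the
bidirectional merge is concatenation by contract, never a sum); and a dense
head 128/64/32/4 with ReLU between layers and softmax at the output. The
literal table variant that applies ReLU to the last dense layer before
softmax is available as `final_activation="relu-then-softmax"`; plain
softmax is the default. Max pooling of size 2 is the minimal choice that
keeps a 9000-sample input valid through 12 pools; same padding makes the
pools the only length-changing layers, so the sequence length entering the
BiLSTM is `input_length // stride**n_pools` by repeated floor division.

`build_architecture` emits the backend-agnostic layer list;
`output_sequence_length` and `parameter_count` give the closed-form shape
and parameter bookkeeping (2 983 524 trainable parameters for the default
configuration); `instantiate` realizes the list on the bundled numpy engine
with seeded initialization (He for conv/dense, uniform ±1/√H for LSTM
weights with forget-gate bias 1).

**Backend.** A compact numpy engine implements exactly the needed layer set
with hand-written backward passes (im2col-free convolution as a kernel-width
loop of batched matmuls, full backpropagation through time for both LSTM
directions) and Adam. Parameters default to float32 for speed; float64 is
available and is what the test suite's central-difference gradient checks
use. Correctness is guarded by end-to-end numerical gradient checks through
the entire stack and by a gradient-flow smoke test (one Adam step on a
singleton batch strictly decreases its loss).

## Loss functions

TMSE maps each squared residual through the tangent before averaging:

    TMSE = (1/N) · Σ_i tan((y_i − ŷ_i)²),   N = rows × classes.

Squared residuals are clamped to [0, 1] before the tangent. For one-hot
targets and probability predictions residuals never exceed 1, so the clamp
is inactive in classification use; it exists to keep the map inside tan's
first branch if the loss is pointed at unbounded regressions. `clamp ≥ π/2`
is rejected. The analytic gradient is
`−2(y − ŷ)·sec²((y − ŷ)²)/N` (zero where the clamp binds). Two exact
properties anchor the tests: `tan s ≥ s` on [0, π/2) makes TMSE ≥ MSE with
equality only at zero residual, and `tan s = s + s³/3 + …` makes TMSE → MSE
in the small-residual limit. Note that on [0, 1] the tangent *amplifies*
large squared residuals rather than damping them; the implementation
computes the formula as defined and documents this observed behaviour
without asserting any outlier-suppression property. N counts scalar
elements (flat sum); a per-row mean differs only by a constant factor.
MSE and clipped categorical cross-entropy are provided as ablation
counterparts. All three are applied to softmax outputs, not logits.

## Evaluation

A 4×4 confusion matrix (rows = true, columns = predicted) with one-vs-rest
TP/FN/FP/TN per class; accuracy = overall fraction correct; per-class
precision, recall and F1 = 2PR/(P+R). Zero denominators yield 0 with a
logged note. Two "overall F1" aggregates are always reported: the mean over
the N/A/O classes (the CinC 2017 scoring convention, which excludes the
noisy class) and the mean over all four — the two can differ materially, so
neither is presented as *the* overall score.

## Experiments

**Length normalization.** Networks take fixed-length input; records are
tail-zero-padded or head-cropped to `input_length` (9000 by default — the
record-length filter guarantees real records are at least that long, so
padding only ever affects synthetic/toy data). Each record is z-scored after
denoising.

**Splits.** Stratified 90/10 hold-out (largest-remainder allocation so the
global fraction is exact while per-class counts stay within one record of
their target) and stratified k-fold (k = 10 default; per-class fold counts
differ by at most 1; k = 1 and classes smaller than k are rejected). Both
are seed-reproducible; fold aggregation is the unweighted mean of fold
metrics, with confusion matrices summed.

**Ablations.** `WT-TMSE` (wavelet only), `MT-TMSE` (median only),
`WT-MT-CEEF` (both stages, cross-entropy), `WT-MT-MSE` (both, MSE), and the
headline `WT-MT-TMSE`. The ablation id pins the stage flags and loss; the
harness emits a five-row table (F1 Normal/AF/Other/Overall, Accuracy).

**Training defaults.** Adam, learning rate 1e-3, batch 32, 50 epochs for the
full configuration (the original description states no hyperparameters; all
are exposed). Training aborts with a descriptive error if the loss becomes
non-finite — which the TMSE clamp prevents by construction.

**Desk-scale configuration** (`scaled_config`). Full-scale training on the
challenge corpus needs GPUs; the package's quantitative guarantees are
instead stated on a configuration sized for one CPU: 100 records per class,
3000-sample inputs, six convolutions (two per block, filters 16/24/32,
kernel 16, 2/2 pooling — the finer pooling keeps ~27 ms per BiLSTM step so
RR-interval jitter remains resolvable), BiLSTM 24/32, dense 32/4, dropout
0.2, batch 8, learning rate 3e-3, 10 epochs, wavelet level 6 and median
window 241. Across five development seeds this reaches hold-out accuracies
of roughly 0.65–0.90 (chance 0.25); the acceptance suite requires ≥ 0.7 on
at least four of five seeds. These numbers characterize the synthetic task
only.

## Numerical and degenerate-input choices

- Wavelet boundary: symmetric extension; median boundary: edge replication.
- Median window must be odd, ≥ 1 and ≤ signal length; window 1 is the
  identity.
- Record-length filter threshold is inclusive (length ≥ 9000 retained) and
  configurable; filtering is idempotent and monotone in the threshold.
- `pad_or_crop` keeps the earliest samples when cropping (rhythm statistics
  are stationary within a record, so nothing is lost at desk scale by
  discarding the tail).
- Probabilities are clipped at 1e-12 inside cross-entropy; softmax uses the
  max-subtraction trick.
- Class imbalance is handled by stratification only; no re-weighting.

## Known limitations

- The numpy backend is single-threaded apart from BLAS matmuls and is not
  meant for full-scale (7561-record, 24-layer, 50-epoch) training; that mode
  exists but is practical only with patience or a port of the layer specs to
  a GPU framework.
- Synthetic classes are easier to separate than real CinC 2017 classes;
  reported desk-scale accuracies say nothing about clinical performance.
- The `O` class stands in for dozens of real arrhythmias with a single
  ectopy mechanism.
- Record amplitudes are converted to mV only when the header declares a
  gain; gainless headers fall back to raw units with a logged warning.
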