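# Methods

This note describes what `emgmeta` computes, the modelling choices behind
it, and what its synthetic experiments do and do not establish.

## Problem

Surface EMG (sEMG) gesture recognition degrades sharply on users it was not
trained on: electrode placement, skin impedance, muscle geometry and
contraction style all shift the signal distribution between subjects. The
package implements a fast-adaptation recipe for this setting: a compact
convolutional classifier with channel–spatial attention over multichannel
time–frequency features, whose initial weights are meta-learned (MAML) so
that a handful of labelled gestures from a new user — one gradient step or a
few — already yields a usable subject-specific classifier.

## Pipeline

1. **Preprocessing.** Each raw trial (C channels × T samples, nominally 128
   channels at 1 kHz) is band-stop filtered at 45–55 Hz with a second-order
   Butterworth to remove 50 Hz powerline interference, cut to the middle
   one-second window (1000 samples per channel), and z-scored per channel.
   Filtering is zero-phase (forward–backward), so the window feeding the
   time–frequency transform carries no phase distortion; the effective
   attenuation is the squared magnitude response, >40 dB at 50 Hz. The
   centered window start is floor((T−L)/2), breaking ties toward the earlier
   sample. Normalization is the per-channel z-score with an SD floor of
   1e-12; constant channels map to zeros.

2. **Features.** The primary input is the per-channel STFT magnitude
   spectrogram: Hann window of 64 samples, hop 29, frames starting at sample
   0 with no centering or padding. A 1000-sample channel gives
   floor((1000−64)/29)+1 = 33 frames × 33 one-sided frequency bins — a
   33×33 image per channel. Magnitude (not power, not dB) is used; a
   `log1p` option exists but is off by default. Alternative inputs: the
   one-sided FFT magnitude spectrum of the whole window (501 bins, treated
   as a single-channel image over electrodes), the raw window as a 1×L×C
   image, and the classical mean-absolute-value feature (200 ms windows,
   25 ms step → 33 values per channel). MAV is computed with |x|; the
   normalization of the time signal (not the spectrogram) is the package's
   reading of the pipeline order.

3. **Classifier.** Three attention-convolution cells, each
   conv(3×3, pad 1) → channel attention → spatial attention → batch-norm →
   ReLU → max-pool(2, stride 2), followed by flatten → fully connected →
   softmax. Channel attention is a squeeze-excite bottleneck fed by
   GAP+GMP with reduction r=4; spatial attention applies scalar gains to
   the channel-pooled mean and max maps, ReLU, then a 7×7 single-output
   convolution and a sigmoid. Both gates lie in (0,1), so attention only
   shrinks features — a soft threshold driving unimportant responses toward
   zero. The channel plan is 128→64→64→32 for the 128-channel spectrogram
   stack (33→16→8→4 spatially, 512-dim flattened feature); exact widths,
   padding and the FC size are this package's choices where the architecture
   family leaves them open. Single-channel inputs (raw/FFT/MAV images) use
   the same cells with an adaptive average pooling to a fixed 4×4 before the
   classifier. Ablation variants replace the removed attention module(s)
   with a depthwise 3×3 convolution: a conventional, shape-preserving conv
   layer whose cost keeps all four variants' parameter counts within a few
   percent, so comparisons measure the attention mechanism, not capacity.
   (A dense same-channel 3×3 conv would triple some cells' parameters and
   confound the comparison.)

4. **Episodes.** An N-way K-shot task draws N classes and 2K distinct
   samples per class — K support, K query; support and query never share a
   sample but always share the same N classes, and labels are remapped to
   0..N−1. Meta-train/val/test pools are subject-disjoint, so meta-testing
   always measures adaptation to unseen subjects. The sampler can draw a
   task entirely from one subject (`within_subject=True`); the desk-scale
   experiments use this for meta-training because a task then is exactly
   the target problem — one user's gesture discrimination — and because
   under the generator's electrode-shift model, pooled-subject tasks can
   contain cross-subject label aliasing (see below).

5. **Meta-learning.** MAML with inner (fast) rate α=0.1, one inner step in
   training, outer Adam at β=0.001, meta-batch 8 tasks, second-order
   gradients by default. First-order MAML (`second_order=False`) takes the
   outer gradient at the adapted parameters; it is roughly 3× cheaper and
   is what the desk-scale experiments use. At meta-test, adaptation runs
   for a configurable number of steps with query accuracy recorded after
   each, so both fixed-step and best-step summaries are available (the
   number of test-time steps is open in the protocol; 5 is the default).
   Batch-norm uses batch statistics for support and query during
   meta-learning (transductive BN, the common MAML convention); running
   statistics are only used for supervised evaluation. Outer SGD is
   available to mirror the plain gradient-descent formulation.

6. **Supervised baseline.** Conventional training pools samples across
   subjects, splits 6:2:2 stratified by class, and minimizes cross-entropy
   with Adam (lr 1e-3 dropping to 1e-4 after epoch 150 of 300, batch 64,
   weight decay 1e-4), returning the best-validation checkpoint. The
   pretrain-transfer probe trains on one subject group (70/30 train/val)
   and evaluates frozen on held-out subjects — quantifying the
   subject-shift failure mode that motivates meta-learning.

## Numerical core

No deep-learning framework is used; the package includes a small
reverse-mode autodiff engine over numpy arrays (`emgmeta.autodiff`). Every
backward rule is itself composed of differentiable primitives, so gradients
are graph nodes and the second-order MAML outer gradient is exact (verified
against central finite differences of the full two-loop objective).
Convolution is im2col — a constant-index gather whose adjoint is a cached
sparse scatter matrix — followed by a single GEMM. Float64 is the default
dtype and what the exactness tests use; experiments run in float32 for
speed. Max-pool ties break to the first index; softmax/cross-entropy are
computed via a max-shifted log-sum-exp; the probability-space cross-entropy
helper clamps predictions at 1e-12.

## Synthetic data: what it emulates, and what it does not

`emgmeta.synthetic` generates datasets with the structure that makes the
inter-subject problem hard, without physiological detail:

- each gesture has a smooth spatial activation map over the electrode grid
  (a Gaussian bump at a gesture-specific electrode, circular in the column
  direction, matching a sleeve wrapped around the forearm);
- each channel carries that envelope times unit-RMS band-passed white noise
  (20–150 Hz, 4th-order Butterworth) — the sEMG surrogate spectrum — plus
  additive white noise and a 50 Hz powerline tone with a per-recording
  phase shared across channels;
- subjects differ by a log-normal overall gain (SD 0.2), a circular
  electrode-column shift (up to ±2 columns), and independent noise.

A consequence worth stating explicitly: per-channel z-scoring removes
amplitude information, so after preprocessing the class signal lives in
each channel's **spectral shape** — strongly activated channels are
carrier-dominated (band-limited), quiet channels are noise-dominated
(white). This is why the generator's noise floor is not a nuisance
parameter but the carrier of identifiability; the compact test profile
(8 subjects, 8 gestures, 4×4 grid, 1 s trials) sets noise_sd=0.3 and
envelope width 1.2 electrodes so that a linear probe separates gestures
within subject essentially perfectly, while subject gain/shift still breaks
naive pooling. With few grid columns, the circular shift can map one
gesture's envelope exactly onto another's for a shifted subject —
cross-subject label aliasing. That aliasing is deliberate (it produces the
pretrain-transfer collapse the supervised probe measures) and is why
meta-training tasks are sampled within subject.

Not modelled: motor-unit action potentials, force levels, fatigue,
nonstationarity within a trial, session effects, crosstalk correlation
between electrodes. Passing tests on this generator show the pipeline's
machinery — filtering, features, attention network, episodic protocol,
meta-optimization — behaves as specified and that meta-learning recovers
subject-adaptive classification under gain/shift/noise subject structure.
They do not certify accuracy on real recordings; the CapgMyo loader and
full-size configurations exist for that, but the data is an external
download and runs are long.

## Desk-scale experiment profiles

The shipped experiments (tests and `scripts/acceptance.py`) are sized for
minutes on one CPU core, as the package's own scaled-down study conditions:

- **Adaptation-gain experiment.** Easy profile: 8-channel (2×4 grid)
  variant of the compact profile with 10 subjects split 7/1/2, STFT
  features, width-4 network (~1.1k parameters), first-order MAML, α=0.1,
  outer Adam at β=0.01 with a 30-batch linear warmup and meta-gradient
  norm clipping at 10, meta-batch 8, 300 meta-batches of within-subject
  5-way 5-shot tasks, three repetition seeds. β is raised from the
  full-size 0.001 in proportion to the much smaller model; warmup and
  clipping are the standard stabilizers for Adam-driven MAML at this
  scale, and a run whose meta-validation accuracy never exceeds 0.35 (a
  never-learned detector) is restarted once from a fresh initialization.
  The best meta-validation checkpoint is kept. Training adapts for 1 inner
  step; at test time adaptation runs 20 steps over 50 tasks drawn
  within-subject from the two held-out subjects, with accuracy recorded
  after every step. Expected behaviour: post-adaptation accuracy well
  above both chance (0.20) and the pre-adaptation accuracy, typically
  0.6–0.85 depending on the realization; individual training runs vary
  substantially (roughly 0.5–1.0), which is why the experiment reports a
  three-seed mean over two held-out subjects.
- **Pretrain-transfer experiment.** Compact 16-channel profile in which the
  training cohort (6 subjects, gain SD 0.5) shares a consistent sleeve
  placement, and the 2 held-out subjects wear the sleeve rotated by 2 grid
  columns (`rotate_electrodes` — the controlled form of the new-user
  electrode offset). Supervised training for 40 epochs; the frozen model
  then collapses on the rotated subjects while within-subjects validation
  accuracy does not, a gap of roughly 35–80 points depending on the
  realization — the qualitative analogue of the failure mode that
  motivates the method (its real-data counterpart shows ~95% validation
  against ~24% transfer). The rotation is controlled rather than drawn
  because on a 4-column circular grid a random per-subject shift takes
  only four values, so a drawn test subject usually shares its placement
  with someone in the training cohort and the premise of a strong shift
  would hold only for lucky draws. With the rotation set to zero the gap
  vanishes (the no-shift control).

## Known limitations

- The desk profiles are far below the real problem's scale (128 channels,
  20k tasks, 300 epochs); the full-scale configurations are provided but
  not exercised by the automated experiments.
- The engine is single-threaded numpy; it is adequate for the shipped
  profiles, not for full CapgMyo training.
- Top-k accuracy is the standard definition (non-decreasing in k). Reported
  top-5 numbers in parts of the source literature are lower than top-1,
  which standard top-k cannot produce; no attempt is made to reproduce
  that.
- The RL-style task tuple (transition distributions, horizon) sometimes
  attached to the meta-learning formalism degenerates for supervised
  few-shot classification and is not modelled.
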