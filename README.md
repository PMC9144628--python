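# emgmeta

Few-shot, subject-adaptive gesture recognition from high-density surface
EMG: STFT time–frequency features, a channel–spatial attention CNN, and
MAML episodic meta-learning, with a synthetic HD-sEMG generator so the
whole pipeline runs and is tested without any external download.

## Who this is for

Researchers in myoelectric control and biosignal decoding who need a
classifier that adapts to a **new user** from a handful of labelled
gestures, rather than a model that only works on the subjects it was
trained on. The package is a library first (importable modules plus
`examples/`), with a thin `emgmeta` CLI for shell use.

## The method

A raw trial (C channels × T samples at 1 kHz) is band-stop filtered at
45–55 Hz (2nd-order Butterworth, zero-phase), cut to the middle 1 s window
and z-scored per channel. Each channel then becomes a 33×33 STFT magnitude
spectrogram (Hann window 64, hop 29, no padding):

    STFT{x[n]}(m, ω) = Σ_n x[n] w[n − m] e^{−jωn}

The classifier stacks three attention-convolution cells —
conv(3×3) → channel attention → spatial attention → batch-norm → ReLU →
max-pool(2) — then a fully connected layer and softmax. The gates are

    CAM:  Y = X · σ(W₂ δ(W₁ (GAP + GMP)))          (per channel)
    SAM:  Y = X ⊙ σ(W₃ δ(W₁·GAP + W₂·GMP))         (per pixel)

with δ = ReLU, σ = sigmoid, so attention only shrinks features. Ablation
variants (`sac`, `cac`, `cnn`) replace the removed attention with a
depthwise 3×3 conv of comparable cost.

Adaptation uses MAML over N-way K-shot episodes: each task holds N·K
support and N·K disjoint query samples of the same N classes; the inner
loop takes gradient steps θ′ = θ − α∇_θ L_support(θ) (α = 0.1, one step in
training), and the outer optimizer (Adam, β = 0.001) minimizes the
post-adaptation query loss across a meta-batch of tasks — second-order by
default, first-order as a cheap option. Meta-train/val/test pools contain
disjoint subjects, so evaluation always measures adaptation to an unseen
user.

Everything runs on a small numpy reverse-mode autodiff engine included in
the package (`emgmeta.autodiff`), whose backward rules are themselves
differentiable — the second-order meta-gradient is exact, and tested
against finite differences.

## Worked example

`examples/04_meta_learning.py` meta-trains on six synthetic subjects and
adapts to a never-seen subject (8-channel easy profile, first-order MAML,
100 meta-batches; a few minutes on one core):

```
meta-training query accuracy: first 20 batches 0.198 -> last 20 0.319
held-out subject, 100 tasks:
  after 0 adaptation steps: top-1 0.208 +/- 0.110
  after 1 adaptation steps: top-1 0.322 +/- 0.132
  after 2 adaptation steps: top-1 0.384 +/- 0.129
  after 3 adaptation steps: top-1 0.431 +/- 0.136
  after 4 adaptation steps: top-1 0.468 +/- 0.114
  after 5 adaptation steps: top-1 0.495 +/- 0.139
pre-adaptation 0.208 vs post-adaptation 0.495 (chance 0.200) — the
adaptation gain on a never-seen subject.
```

Before adaptation the network is at the 5-way chance level on the new
subject; five gradient steps on 25 labelled samples more than double its
accuracy, and the full-length run (the acceptance script: 300 meta-batches,
three seeds, ten adaptation steps) reaches post-adaptation accuracy around
0.67. The counterpart, `examples/05_pretrain_transfer_gap.py`, shows why
plain pretraining is not enough: a conventionally trained model at 0.847
validation accuracy scores 0.000 on two subjects wearing the electrode
sleeve rotated by two columns. The other examples cover the generator, the
feature pipeline, and the attention network.

## CLI

```sh
emgmeta synth --out data/synth --subjects 8 --gestures 8
emgmeta train-supervised --data data/synth --input-mode stft --variant csac
emgmeta meta-train --data data/synth --ways 5 --shots 5 --meta-batches 300
emgmeta meta-test --data data/synth --model runs/meta/model.npz
emgmeta describe --variant csac
```
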