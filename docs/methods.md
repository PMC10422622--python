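# Methods

## Overview

`mudring-ecg` classifies short ECG records into the five diagnostic
superclasses used by large public ECG collections — NORM (normal), MI
(myocardial infarction), STTC (ST/T change), CD (conduction disturbance)
and HYP (hypertrophy) — with a three-stage pipeline:

1. **Preprocessing.** Records labelled NULL (no usable diagnostic
   statement) are removed, every record is resampled to a common rate
   (100 Hz by default) and each lead is z-scored.
2. **Feature extraction.** Ten features per lead: four sub-band powers,
   mean, standard deviation, zero-crossing rate, Higuchi fractal
   dimension, approximate entropy and correlation dimension.
3. **Classification.** A tied-weight stacked autoencoder (SAE) with a
   softmax head, greedily pretrained and then fine-tuned; its
   hyperparameters are chosen by the mud-ring optimization algorithm
   (MROA) minimising the percent validation classification error.

## Synthetic data generator

Real 12-lead recordings are not bundled; the generator produces records
with the same shape and label structure so the whole pipeline is
exercisable and testable offline.

A beat is a sum of five Gaussian bumps (P, Q, R, S, T waves), repeated at
70 beats/min, plus white Gaussian noise (default SD 0.05 mV, a typical
magnitude for baseline noise on a resting ECG).  The NORM wave table
(center offset from the R peak [s], amplitude [mV], width [s]) is:

| wave | offset | amplitude | width |
|------|-------:|----------:|------:|
| P    | −0.20  | 0.10      | 0.025 |
| Q    | −0.05  | −0.15     | 0.010 |
| R    | 0.00   | 1.00      | 0.012 |
| S    | 0.04   | −0.25     | 0.010 |
| T    | 0.25   | 0.30      | 0.050 |

Class-specific shifts (fixed, so tests are reproducible): MI deepens Q to
−0.45 mV and widens/advances the T wave (center 0.18 s, width 0.09 s),
elevating the ST segment; STTC inverts and delays the T wave (−0.25 mV at
0.30 s); CD multiplies the Q, R, S widths by 2.2 (widened QRS); HYP
amplifies R to 1.8 mV.  NULL records borrow the morphology of a uniformly
random diagnostic class, so the NULL filter — not the waveform — is what
the preprocessing tests exercise.

Default conditions: single lead, 10 s, half the records at 100 Hz and half
at 500 Hz (so the resampling stage always runs), class proportions uniform
over the five diagnostic classes, NULL fraction ≈ 1% (35 of 3000 at full
scale, 6 of 600 in the default scaled run).  Extra leads are attenuated
copies (gain 1/(1+0.15·lead)) with independent noise.

What the generator does **not** emulate: inter-patient morphology
variability, rhythm disturbances, baseline wander, powerline interference,
electrode artefacts, or genuinely 12-lead vectorcardiographic structure.
Class-conditional waveforms differ only by the fixed shift table, which
makes the classes far more separable than real diagnostic superclasses.
Passing tests therefore demonstrate that the pipeline is wired correctly
and that the optimizer finds good hyperparameters on a learnable problem —
not that the method reaches any particular accuracy on real ECGs.

## Preprocessing choices

* Resampling is Fourier-domain (`scipy.signal.resample`): deterministic and
  alias-free for the band-limited synthetic waveforms.  Output length is
  `round(duration × target_fs)`.
* Normalisation is per-lead z-scoring; a constant lead maps to zeros
  rather than dividing by zero.

## Feature set

* **Sub-band powers (F1–F4).**  Welch PSD (`nperseg = min(256, n)`,
  no detrending) integrated by the rectangle rule over the bands
  (0.5–4, 4–15, 15–30, 30–45) Hz — four bands below the 50 Hz Nyquist of
  the 100 Hz working rate, separating the slow T/P content, the dominant
  QRS band, and two high-frequency bands.  Half-open bin assignment makes
  powers exactly additive over disjoint bands.
* **Zero-crossing rate (F7).**  Strict sign changes / (n−1); zeros inherit
  the previous non-zero sign so grazing zero does not count.
* **Higuchi fractal dimension (F8).**  kmax = 10; slope of log curve
  length versus log(1/k).  Sanity anchors: ≈1 on a ramp, ≈2 on white
  noise.
* **Approximate entropy (F9).**  Pincus ApEn(m=2, r=0.2·SD), Chebyshev
  distance, self-matches included — the convention under which ApEn of a
  constant series is exactly 0.
* **Correlation dimension (F10).**  Grassberger–Procaccia with delay-1
  embedding, embedding dimension 2, and 10 log-spaced radii between the
  5th and 50th percentiles of the pairwise embedded distances (a robust
  scaling region for short series); least-squares slope of log C(r) vs
  log r.

All features are deterministic for fixed input.

## Stacked autoencoder

Each layer computes `h = σ(x·Wᵀ + b)` and reconstructs
`x' = σ(h·W + c)` with tied weights (the decoder uses Wᵀ).  Pretraining
minimises the summed squared reconstruction error by plain mini-batch SGD
(learning rate 0.01, batch 5, 50 epochs by default), greedily: each layer
trains on the frozen hidden activations of the one below.  Inputs to the
first layer are min–max scaled to [0, 1] per feature over the training
split (stored with the model), matching the sigmoid output range of the
decoder.

The supervised head is a softmax over the class set, fine-tuned with
cross-entropy through all layers (a head-only mode is available).
Inverted dropout (default 0.5) is applied to every hidden activation
during fine-tuning only.  Sigmoid is the default activation everywhere
because the tied decoder needs (0, 1) outputs; ReLU is available for the
encoder path as a config option.

**Architecture selection.**  For a candidate list of hidden-size layouts,
each candidate is pretrained and the input is reconstructed through the
full encode/decode chain; the structural loss

    SLF = ω₁(1 − ρ₁²) + (1 − ω₁)(1 − ρ₂²),  ω₁ = 0.5

(ρ₁ Pearson, ρ₂ Spearman with average ranks, both on the flattened
matrices) scores the reconstruction; the minimiser wins, with ties broken
by fewer total neurons, then fewer layers, then candidate order.  A
constant reconstruction has undefined correlations; both are treated as 0,
giving the worst score 1.

## Mud-ring optimizer

A population of N agents in a box, run for T iterations with exactly
N·(T+1) fitness evaluations.  Per agent and iteration, with
r ~ U(0, 1):

    a = 2(1 − t/T),  K = 2ar − a,  C = 2r

|K| ≥ 1 triggers exploration — a fresh uniform velocity in [Vmin, Vmax]
added to the position (or, optionally, a spiral around a random agent);
|K| < 1 triggers exploitation — `D' = D*·sin(2πl) − K·|C·D* − D|` around
the global best D*, with l ~ U(−1, 1).  Positions are clamped to the box
after every move; non-finite fitness values are treated as +∞ with a
logged warning.  The random-draw order is documented in the module
docstring so an independent oracle can replay a full trace.

**Hyperparameter tuning.**  The 6-dimensional search position decodes to:
log₁₀ learning rate in [−4, −1]; layer count rounded into {1, 2, 3}; three
per-layer hidden sizes rounded into [4, 128] (unused dims ignored);
dropout in [0, 0.8].  The fitness is the percent classification error on a
held-out validation split of a classifier trained with a fixed inner seed,
making the fitness a deterministic function of position (and the whole
tuning run reproducible).  Velocity bounds are ±10% of each dimension's
range.

## Evaluation

One-vs-rest per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/n, precision TP/(TP+FP), F-score 2·prec·sens/(prec+sens),
all in percent, plus an unweighted macro average row.  Ratios with a zero
denominator are reported as 0 with a logged warning rather than raising —
small runs can leave a class entirely unpredicted.

The end-to-end default uses a stratified 70/15/15 train/validation/test
split with the run seed.

## Problem sizes

The default end-to-end configuration uses 600 records (6 NULL), single
lead, 10 s at a 50/50 mix of 100 and 500 Hz, and a tuning budget of 6
agents × 5 iterations (36 classifier fits); one full run takes well under
a minute on one CPU.  The optimizer benchmark uses the 2-D sphere function
with 20 agents × 100 iterations over 10 seeds.

## Known limitations

* Synthetic classes are much cleaner than real diagnostic superclasses;
  default-config runs typically reach near-perfect test metrics, which
  says nothing about real-data accuracy.
* The correlation-dimension and Higuchi estimators use short, fixed
  parameter choices suited to 1000-sample records, not asymptotic
  convergence.
* Training is plain SGD on small dense networks; there is no GPU path and
  no convolutional/recurrent variant.
* The optional reader for external WFDB-format collections is not
  included; the flat CSV container is the supported input format.
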