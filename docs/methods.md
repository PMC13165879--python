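# Methods

`eegverb` re-implements, end to end, a six-class EEG decoding pipeline for
visually cued overt production of Mandarin action verbs (Chi, He, Chuan, Na,
Kan, Dai), together with a synthetic-EEG generator that reproduces the
acquisition design so the whole pipeline is testable without the original
recordings. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Study design and preprocessing

The emulated acquisition records 30 participants, each completing 5 blocks
in which every verb is prompted 15 times in random order: 75 trials per
verb per participant, 13,500 four-second epochs in total. Eight wet
electrodes over the left-hemisphere language areas are used (Broca: F5,
FT7, FC5, FC3; Wernicke: TP7, CP5, CP3, P5) at 250 Hz, so one epoch is an
8 x 1000 matrix of microvolts. Each trial's timeline is 2 s idle, 1 s cue,
4 s task (the decoded window), 2 s rest.

The front end is a 4–45 Hz band-pass (4th-order Butterworth, applied
forward–backward so it is zero-phase and stimulus-locked epoch boundaries
stay valid), channel selection to the eight-electrode montage, and
half-open onset-aligned epoch windows `[onset, onset + 1000)`. Artifact
handling beyond the band-pass is a configurable amplitude-threshold trial
rejection (default 100 µV); ICA-style ocular correction is deliberately out
of scope. Classifier inputs are per-trial, per-channel z-scored; CSP is
invariant to this (its covariances are trace-normalised), and it
conditions the recurrent network's optimisation. Stratified splits
allocate `round(p * n_total)` training trials exactly, by largest
remainder over (subject, class) strata with round-robin tie-breaking over
classes — at 38% of 13,500 this gives exactly 5,130 training trials,
~171 per participant.

## Baseline: one-vs-one CSP + RBF-SVM

For each of the 15 verb pairs, the class-mean trace-normalised covariance
matrices (C̄_a, C̄_b) define the generalised eigenproblem
C̄_a w = λ (C̄_a + C̄_b) w; the m eigenvectors from each end of the
spectrum (default m = 3, i.e. 6 filters for 8 channels) form the pair's
filter bank, and a trial's features are the normalised log variances of
the filtered components, f_j = log(var(Z_j) / Σ_i var(Z_i)). A small
shrinkage (ε = 1e−6 toward the scaled identity) keeps the composite matrix
positive definite. Each pair gets its own RBF-kernel SVM (defaults C = 1,
γ = 1/(2m); the max-margin solver is scikit-learn's — the bespoke content
is CSP and the voting wrapper); a test trial is classified by majority
vote over the 15 pairwise decisions, with ties broken by summed absolute
decision margins. Filter signs are fixed (largest-magnitude coefficient
positive) and eigenvalues sorted descending for reproducibility.

## Proposed decoder: dual-LSTM recurrent network

The network is seven layers: input → three fully connected tanh layers
(128, 64, 32) applied per time step → two stacked LSTM layers (64, 64)
scanned over time → a 6-way softmax readout of the final step's hidden
state. Each LSTM cell computes input, forget, output and modulation gates
from the shared affine form T(x_t, h_{t−1}) = x_t W_x + h_{t−1} W_h + b
(distinct parameters per gate), with the usual state update
c_t = f ⊙ c_{t−1} + i ⊙ m, h_t = o ⊙ tanh(c_t). The 1000-sample epoch is
consumed as 50 non-overlapping frames of 20 samples × 8 channels
(flattened to 160 features per step); per-sample mode is available.

Training minimises the per-unit binary cross-entropy summed over the six
output units against one-hot targets — equivalent up to the complement
terms to categorical cross-entropy; the complement terms are retained
deliberately — by seeded mini-batch gradient descent with global-norm
gradient clipping (default 5). The whole network, including
backpropagation through time, is plain NumPy with hand-derived gradients,
verified against central differences to ~1e−9 relative on well-scaled
coordinates. Initialisation is uniform(−r, r), r = 1/√fan-in, with the
forget-gate bias at +1.

The learning rate is either fixed (default 0.005) or chosen per step by an
exact line search along the negative gradient: α minimising
φ(α) = f(θ − α∇f), bracketed geometrically and polished by Brent's
method; at the minimiser the new gradient is orthogonal to the old one,
which the tests verify on quadratics (where α = gᵀg / gᵀAg in closed
form). In practice the line search matters: on the synthetic tasks the
network's class information is carried by signal *variance*, not signal
mean, so the loss surface at initialisation is a nearly symmetric plateau
and fixed-rate descent at 0.005 needs thousands of steps to break
symmetry, while the line-search schedule escapes in a few epochs. The
method-contrast experiments therefore train in line-search mode; the
learning-rate-curve experiment, whose purpose is to compare fixed rates,
uses fixed-rate mode by construction.

## Synthetic EEG

Each trial is `background + artifacts + a · pattern ⊗ (envelope ×
carrier)`: 1/f background noise (10 µV RMS, slope 1), ocular (<4 Hz
frontal-weighted transients, ~60 µV, 4/min), myogenic (>30 Hz bursts,
~15 µV, 2/min) and 50 Hz line (2 µV) artifacts, and a rank-one evoked
component — a unit-norm spatial topography, a nonnegative amplitude
envelope over the task window, and a fresh 8–30 Hz band-limited noise
carrier per trial, scaled to a requested evoked-to-background SNR in dB.

Three scenario factories place the class information:

* **spatial** — distinct topographies (`normalize(u0 + separation · v_k)`
  with orthonormal v_k ⊥ u0; pairwise cosine 1/(1+separation²)), flat
  envelope: separable by covariance methods; default SNR 0 dB.
* **temporal** — one shared topography; one shared multiset of envelope
  segment amplitudes, cyclically shifted per class (circular smoothing, so
  every class envelope is an exact rotation of the same sequence). The
  time-averaged envelope power is therefore order-invariant and the
  expected channel covariance identical across classes: log-variance CSP
  features carry no class information, while the envelope *ordering*
  remains fully discriminative for a sequence model. Default SNR +20 dB —
  a deliberate calibration making the amplitude-order structure an
  unambiguous learning target; the real recordings' SNR is unknown and is
  not being estimated.
* **mixed** — both structures at once (default +5 dB).

What the generator does **not** emulate: volume conduction beyond fixed
topographies, non-stationarity across blocks, inter-subject variability in
the signatures (subjects differ only in noise), and mean-coded evoked
potentials (all class information here is second-order). Passing tests
therefore demonstrate correctness of the machinery and the qualitative
method contrast, not performance on real EEG.

## Evaluation

Confusion-matrix metrics per verb in one-vs-rest form (precision, recall,
F1), trial-level accuracy, and WER defined as 1 − accuracy for this
isolated-word task (not an edit distance). Per-class ratios with 0/0 are
reported as NaN sentinels and excluded from macro averages. Across-subject
dispersion is the sample standard deviation. Three protocols mirror the
study's analyses: accuracy vs. training repetitions per verb (nested
subsets over a fixed held-out partition, with a Spearman trend statistic),
accuracy and wall-time vs. training proportion (wall-time informational
only), and WER vs. learning rate (shared split, seed and schedule per
rate; diverged runs recorded as WER 1.0 with a flag).

Problem sizes used by the shipped experiments: the method contrast runs 6
subjects × 6 classes × 20 trials (720 epochs, pooled training on a 2/3
split); the learning-rate curve runs 2 subjects × 6 × 20 with batch size 2
for 120 epochs per rate; the design-arithmetic check generates the full
13,500-epoch dataset. These scales keep every experiment in the minutes
range on one CPU while leaving the measured contrasts far from their
decision thresholds.

### A note on the learning-rate curve

With inputs standardised as above, fixed-rate descent on these synthetic
tasks improves monotonically over the grid {0.0005, 0.005, 0.05}: the
plateau-escape time scales roughly as 1/lr, and the instability threshold
that penalises large rates sits near 0.2–0.5 here — above the grid. The
canonical U-shape (slow convergence on the left, fluctuation/divergence on
the right) is real but appears at this landscape's own rate scale; a
property test demonstrates the instability arm directly at large unclipped
rates. Where the fixed-rate optimum falls within the grid consequently
depends on the training budget and data scale, and the package reports
whatever the computation yields.

## Numerical choices and degenerate inputs

Zero-power trials raise a degenerate-trial error in covariance
normalisation; zero-variance filtered components are floored at machine
epsilon with a warning; probabilities are clipped to [1e−12, 1−1e−12] in
the loss; softmax is max-subtracted; the line search falls back to the
configured fixed rate (with a warning) if no descent bracket is found;
non-finite LSTM inputs raise immediately; training aborts with diagnostics
if the loss goes non-finite. Epoch windows extending past a recording's
end drop that trial with a logged warning. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`, so every
generator, split and training run is a pure function of (parameters, seed).

## MFCC reference features

The spoken-verb audio (24 kHz mono) is reduced to 13 cepstral coefficients
per frame by the canonical pipeline: pre-emphasis (0.97), 25 ms frames at
10 ms steps, Hamming window, FFT power spectrum, 26 triangular mel filters
(2595·log10(1 + f/700) scale), log with 1e−10 floor, orthonormal DCT-II.
MFCCs are a reference acoustic representation stored alongside trials; the
decoders' loss is label cross-entropy, and MFCC regression is only an
explicitly flagged auxiliary option, never the default objective.

## Known limitations

The synthetic generator's class signatures are shared across subjects, so
cross-subject questions cannot be studied here (and are out of scope). The
CSP chance-level contract is statistical (99% binomial interval), so a
different seed can land near the interval edges. The NumPy LSTM is
CPU-bound and single-threaded beyond BLAS; it is sized for the shipped
experiment scales, not for the full 13,500-trial dataset.
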