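# eegverb

Decoding six Mandarin action verbs — *Chi* (eat), *He* (drink), *Chuan*
(wear), *Na* (take), *Kan* (look), *Dai* (put on) — from eight-channel EEG
recorded over the left-hemisphere language areas during visually cued
reading aloud. The package implements and compares two decoders on 4-s,
250 Hz epochs (8 × 1000 samples after a 4–45 Hz band-pass):

* **CSP + SVM baseline** — one-vs-one Common Spatial Patterns: for each of
  the 15 verb pairs, filters from the generalised eigenproblem
  `C̄_a w = λ (C̄_a + C̄_b) w` on trace-normalised covariances
  `C = DDᵀ/tr(DDᵀ)`, log-variance features
  `f_j = log(var(Z_j)/Σᵢ var(Zᵢ))`, an RBF-kernel support-vector classifier
  per pair, and majority voting.
* **Dual-LSTM recurrent network** — input → three fully connected tanh
  layers (128-64-32) per time step → two stacked LSTM layers (64, 64) with
  input/forget/output/modulation gates
  `T(x_t, h_{t−1}) = x_t W_x + h_{t−1} W_h + b` → 6-way softmax readout of
  the final hidden state; trained by seeded mini-batch gradient descent on
  a per-unit cross-entropy, with an optional exact line search on the step
  size (at whose minimiser successive gradients are orthogonal). The whole
  network, including backpropagation through time, is plain NumPy.

The scientific point of the comparison: CSP is a *static* spatial-variance
method, so any class structure living purely in the temporal ordering of
the signal is invisible to it, while a recurrent network can integrate it
over the whole epoch. The bundled synthetic-EEG generator reproduces the
study design (30 subjects × 6 verbs × 75 trials in 5 randomised blocks,
1/f background, ocular/myogenic/line artifacts, rank-one evoked
components) and can place class information in the spatial topographies,
in the temporal envelope order, or both — so that contrast is directly
testable. MFCC reference features (13 coefficients per frame) for the
spoken audio and the study's evaluation protocols (confusion-matrix
metrics, repetitions / training-proportion / learning-rate curves) are
included. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import eegverb as ev

# 3 subjects x 6 verbs x 20 trials, class structure purely temporal:
# every class has the same spatial covariance, classes differ only in
# the cyclic order of their amplitude envelopes.
design = ev.ExperimentDesign(n_subjects=3, trials_per_class=20,
                             blocks=2, reps_per_block=10)
sigs = ev.make_temporal_scenario(seed=1, n_task_samples=design.n_task_samples)
ts = ev.generate_dataset(design, sigs, ev.NoiseModel(), seed=1, dtype=np.float32)
train, test = ev.split_trials(ts, 2/3, seed=1)

csp = ev.CspSvmDecoder().fit(train, seed=1)
cfg = ev.TrainConfig(lr_mode="line_search", batch_size=60, max_epochs=14, seed=1)
lstm = ev.LstmDecoder(config=cfg).fit(train, seed=1)

lo, hi = ev.chance_interval(len(test))
print(f"CSP-SVM accuracy:   {(csp.predict(test) == test.labels).mean():.3f}"
      f"  (chance 99% CI [{lo:.3f}, {hi:.3f}])")
print(f"dual-LSTM accuracy: {(lstm.predict(test) == test.labels).mean():.3f}")
```

Output:

```
CSP-SVM accuracy:   0.192  (chance 99% CI [0.083, 0.258])
dual-LSTM accuracy: 1.000
```

The baseline sits inside the chance interval — its log-variance features
genuinely carry no class information on this scenario — while the
recurrent decoder separates the classes from the envelope ordering alone.
On the *spatial* scenario (distinct topographies, flat envelopes) the
ordering flips: CSP-SVM exceeds 80% while temporal structure is absent.

A thin CLI wraps the same library calls:

```
eegverb simulate --scenario mixed --subjects 2 --trials-per-class 10 \
        --blocks 2 --seed 1 --out data/
eegverb train-csp --train data/ --seed 1 --out model.csp
eegverb predict --model model.csp --in data/ --out pred.tsv
eegverb evaluate --pred pred.tsv --out report.json
eegverb mfcc --wav verb.wav --out mfcc.tsv
```

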