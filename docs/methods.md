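# Methods

This note documents the models, conventions and numerical choices behind
`edapain`, in the spirit of a methods section: what is simulated, how the
classifiers are built and evaluated, and which design decisions were open
and how they were pinned.

## The problem

Transcutaneous electrical nerve stimulation (TENS) experiments record
electrodermal activity (EDA) — skin conductance in microsiemens (µS),
sampled here at 100 Hz — while delivering calibrated painful stimuli at
two intensities. The task is three-class classification of 10 s signal
windows into *No Pain*, *Low Pain* and *High Pain*, both offline
(subject-wise cross-validation) and in a streaming, real-time setting.
The study cohort this package emulates has 65 subjects, each
contributing one 60 s baseline and 12 + 12 stimulation trials of 10 s.

## Synthetic cohort model

The real cohort is access-restricted, so the package generates a
synthetic twin with identical structure and annotated ground truth. The
signal model is standard EDA phenomenology:

```
g(t) = tonic + drift·t + Σ_k a_k · h(t − t_k − ℓ) + ε(t),  clipped > 0
```

* **Tonic level** per subject: Normal(6.0, 1.5) µS, floored at 0.5 µS —
  typical palmar skin-conductance levels.
* **Drift**: a linear trend with slope ~ Normal(0, 0.002 µS/s),
  representing slow arousal/hydration changes.
* **Phasic responses**: each stimulus elicits one skin conductance
  response (SCR) after a fixed 1 s physiological latency ℓ, shaped by a
  bi-exponential (Bateman-type) kernel
  `h(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` with τ_r = 0.75 s, τ_d = 2.0 s,
  normalised to unit peak (the peak time has the closed form
  `τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)`).
* **Intensity coding**: SCR amplitudes are Normal(0.3, 0.1) µS for Low
  and Normal(0.8, 0.1) µS for High trials, clipped non-negative. The
  gap between the two means relative to their spread and the noise floor
  is the dataset's class-separability knob.
* **Habituation**: amplitudes decay by a factor 0.97 per trial, in time
  order, mimicking response attenuation over repeated stimulation.
* **Noise**: additive white Gaussian, sd 0.02 µS (quantisation/sensor
  noise; real EDA at these electrodes is low-noise after low-pass
  filtering).
* **Schedule**: one 60 s baseline, then the 24 trials in a seeded-random
  (counterbalanced) order, each followed by a 20 s rest. Rests are
  unannotated and count as No Pain.

What the generator deliberately does **not** model: motion artifacts,
electrode drift/detachment, stimulus-location effects, spontaneous
(non-specific) SCRs, and inter-subject differences in SCR shape. The
synthetic classes are therefore separable mainly by phasic amplitude,
which makes the cohort *well-separated by construction*: passing
accuracy thresholds on it demonstrates that the pipeline is wired
correctly end to end, not that comparable accuracy would be reached on
real EDA.

Determinism: every subject draws from an independent child seed spawned
from the cohort seed, so cohorts are reproducible and individual
subjects are independent of the cohort size.

## Preprocessing and windowing

A 4th-order Butterworth low-pass at 3 Hz (EDA is band-limited below
~3 Hz) is applied as a **causal forward pass** (`scipy.signal.lfilter`),
never zero-phase: the streaming estimator can only filter causally, and
the offline training distribution should match deployment. Offline, the
full recording is filtered once before segmentation; the streaming path
filters each 1000-sample window independently.

Windowing balances the classes selectively: the single baseline segment
is cut into 50 %-overlapping 10 s windows (step 500 samples, trailing
remainder dropped), giving `floor((6000−1000)/500)+1 = 11` No-Pain
windows per subject, while each 10 s trial stays one non-overlapping
window. Per subject: 11 + 12 + 12 = 35 windows; for 65 subjects:
715/780/780, 2275 in total. Windows are 0-based, half-open
`[start, start+1000)`.

## Handcrafted features and PCA

Each window yields 36 features: six time-domain statistics — mean,
standard deviation (sample, n−1), skewness, excess kurtosis, minimum,
maximum — on the raw window, plus the same six statistics on the detail
coefficients D1…D5 of a five-level `db4` discrete wavelet transform
(symmetric padding). Computing the statistics on the five detail bands
(not the approximation) is the only reading consistent with the
36-feature total (6 + 5×6). Whether the deepest band should instead be
the approximation A5 cannot be decided from the available description;
the choice is configurable in code.

Zero-variance inputs (e.g. detail bands of a constant window, which are
round-off-level rather than exactly zero) define skewness and kurtosis
as 0; the degeneracy threshold is a relative 1e−12.

PCA reduces 36 → 12 components. The projection is fitted on
**training-fold rows only** and re-fitted per fold — fitting globally
would leak test-subject statistics. Each feature is z-scored (training
statistics) before the decomposition, and the stored scale is reapplied
at transform time. The standardisation matters twice: without it the
highest-variance wavelet bands dominate the components, and the
resulting projections span scales (std up to ~27) at which the degree-4
polynomial SVM kernel becomes numerically pathological — its solver
needs hundreds of seconds to converge where the standardised version
fits in a fraction of a second with slightly better accuracy.
`standardize=False` is available for raw-covariance analyses.

The batch feature path (`extract_matrix`) is row-vectorised — one
axis-wise multi-signal DWT plus closed-form moments — and agrees with
the per-window reference implementation to round-off (tested).

## Classical baselines

Five scikit-learn classifiers with fixed hyperparameters (configuration,
not searched): LDA (SVD solver), logistic regression (l2, C = 97.2,
Newton–Cholesky; the recorded l1-ratio 0.07 is inert under a pure l2
penalty and retained only as provenance), SVM (polynomial kernel,
degree 4, gamma = 'auto', decision-function argmax), AdaBoost (227
estimators, learning rate 0.78) and gradient boosting (438 estimators,
learning rate 0.52, squared-error criterion). Ensemble seeds come from
the run seed.

## The FCN

Architecture (declared in `FcnConfig`, default values):

| layer | spec | output (C, L) |
|---|---|---|
| conv0 + BN + ReLU | 1→71 maps, kernel 2, valid, stride 1 | (71, 999) |
| conv1 + BN + Tanh | 71→120 maps, kernel 3, valid, stride 1 | (120, 997) |
| avg pool | kernel 3 = stride, floor | (120, 332) |
| flatten | | 39 840 |
| linear | 39 840 → 3 logits | 3 |

The two kernel lengths are forced by the published shape chain
(1000→999 ⇒ 2; 999→997 ⇒ 3), as are valid-mode stride-1 convolutions
and floor-division pooling (997→332). Softmax is applied only at
prediction time; the loss consumes logits. The analytic cost is
`Σ_conv out_len·C_out·k·C_in + 39840·3 = 25 744 698` multiply–accumulates
(≈ 51.5 MFLOPs at 2 FLOPs/MAC, consistent with the tens-of-MFLOPs
figure reported for this architecture class; exact FLOP figures depend
on whether batch-norm/activation/pool operations are counted, which is
why only the MAC count is asserted).

The network, backpropagation and the Adam optimiser are implemented in
NumPy (channel-last activations so each convolution tap is one GEMM;
the two batch-norm training kernels are numba-fused). Initialisation is
seeded uniform fan-in `U(±1/√(fan_in))` for weights and biases.

### Input centering

Each window's mean is subtracted before the first convolution
(`center_input`, on by default). The between-subject tonic offset (sd
1.5 µS) is an order of magnitude larger than the phasic class signal;
fed directly, it dominates the batch-norm batch moments, so with batch
size 32 the batch statistics seen in training differ substantially from
the aggregated statistics used at inference, and the 39 840-input
classifier amplifies that mismatch into large swings of eval-mode
accuracy (observed: validation accuracy oscillating between 0.35 and
0.85 while the training loss fell smoothly). Removing the per-window
mean — an offset carrying subject identity, not pain information —
eliminates the discrepancy: train-mode and eval-mode accuracies then
track each other and cross-validation converges within a few epochs.
Amplitude information is untouched (no variance scaling); full
per-window z-scoring remains a separate flag, off by default.

### Batch-norm inference statistics

Inference-mode batch-norm uses a **cumulative average of the batch
moments, restarted at every epoch**, rather than the conventional
exponential moving average with small momentum. With short training
budgets and a drifting activation distribution, an EMA initialised at
(0, 1) lags the true moments for many epochs and makes validation
accuracy — the early-stopping criterion — noisy and misleading; a
whole-history cumulative average has the opposite failure (stale stats
late in training). The per-epoch average always reflects the current
weights. The exponential variant remains available via the layer's
`momentum` argument.

## Training and evaluation protocol

Subjects are randomly permuted (seeded) and chunked into 5 near-equal
folds (13 each at n = 65). For CV iteration i: test = fold i,
validation = fold (i mod 5)+1, training = the rest — the rotation rule
is pinned; all three sets are pairwise subject-disjoint, asserted at
runtime. Training: Adam, learning rate 1.94e−4, cross-entropy, batch 32,
seeded shuffling; reduce-on-plateau scheduling (factor 0.5, patience 50
epochs, monitored on validation accuracy); early stopping when
validation accuracy fails to improve for `patience` consecutive epochs;
the best-validation-accuracy checkpoint is retained. The full-protocol
defaults are max 3000 epochs with patience 500; the default pipeline and
the acceptance run use a reduced budget (cap 200 epochs, patience 6),
which the well-separated synthetic cohort comfortably converges within.

Metrics: accuracy, support-weighted F1 and precision, and a 3×3
confusion matrix row-normalised per true class. The cross-validation
summary reports mean ± sd over folds plus the median-performing fold by
test accuracy (ties to the lowest fold index; for an even fold count the
lower middle value is taken).

## Streaming estimator

A bounded FIFO holds the most recent 1000 samples. On the 1000th sample,
and every 100 samples thereafter, the buffer is Butterworth-filtered
(causally, per window, no filter state across windows) and classified;
the emitted event carries the argmax class (lowest index on ties) and
the maximum softmax probability as confidence. Replay of a recording is
by construction elementwise identical to batch inference at the same
window boundaries — property-tested, and the central streaming oracle.

Ground truth for an event is the condition covering the majority of its
1000-sample window, exact ties resolved toward the later-starting
condition; samples outside any annotated event are No Pain. This
alignment rule is this package's own definition. Per-event wall-clock
latency is logged descriptively and never asserted (hardware-dependent).

The deployment scenario (a GUI over unseen subjects) is emulated by
generating a second synthetic cohort (15 subjects, independent seed) and
replaying it through the median-fold model.

## Problem sizes and runtime

The default end-to-end run uses the full 65-subject cohort (2275
windows) for the FCN cross-validation; the classical baselines are
evaluated on a single representative fold split by default (train =
folds 2–5, test = fold 1; per-fold evaluation is a flag) since their
role here is a reference point, and the streaming stage replays 15
unseen subjects. These sizes keep a complete pipeline run in the
10–15 minute range on one CPU core.

## Known limitations

* Synthetic separability is by construction; accuracy thresholds on it
  validate plumbing and protocol, not clinical performance.
* The NumPy training loop is single-process and CPU-bound; it is sized
  for the reduced-budget protocol, not for 1000-trial hyperparameter
  searches.
* Filter edge transients differ between the offline path (one causal
  pass over the whole recording) and the streaming path (per-window
  filtering); the difference is confined to the filter's impulse-response
  tail and both paths are causal.
* Per-subject calibration of the displayed signal (as a real-time GUI
  might apply) is not implemented; predictions consume the filtered raw
  conductance.
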