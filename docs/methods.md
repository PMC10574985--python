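# Methods

This note documents the models and procedures implemented in `fatiguekit`,
the assumptions behind them, and the design decisions taken where the
problem left genuine freedom.

## Problem setting

Driver fatigue manifests in scalp EEG as a gradual shift of occipital power
from the alpha band (8–13 Hz) toward the theta band (4–8 Hz), together with
a falling blink rate on frontal channels, a lower heart rate, sparser
steering-related EMG bursts, and shallow, clipped respiration.  The toolkit
classifies 15-second EEG epochs into two, three, or five ordered fatigue
levels (Normal, Onset of Fatigue, Mid Fatigue, Warning of Fatigue, Complete
Fatigue) using channels P4, C3, O1 and O2 sampled at 250 Hz.

Because multi-level fatigue recordings with per-recording labels are
private clinical data, all development and testing run against a synthetic
generator that reproduces the signatures above in measurable form.

## Synthetic recordings (`fatiguekit.synth`)

Each EEG channel is a sum of band-limited stochastic oscillators (white
noise band-passed into the alpha and theta bands by a fourth-order
Butterworth filter, rescaled to a scheduled standard deviation) plus
broadband Gaussian noise (SD 6 µV).  Event channels are deterministic
templates on jittered-regular grids: a smooth biphasic blink transient
(90 µV, 0.35 s) on Fp1/Fp2, a QRS-like template at the scheduled heart
rate on ECG, Hann-windowed noise bursts on EMG, and a 0.25 Hz sinusoid with
amplitude clipping on the respiration belt.

The per-level schedules (levels 0–4) are:

| quantity                 | 0    | 1    | 2    | 3    | 4    |
|--------------------------|------|------|------|------|------|
| alpha SD (µV, occipital) | 30   | 25   | 20   | 15   | 10   |
| theta SD (µV, occipital) | 8    | 14   | 20   | 26   | 32   |
| blinks / min             | 18   | 14   | 10   | 6    | 2    |
| heart rate (bpm)         | 72   | 66   | 60   | 54   | 48   |
| EMG bursts / min         | 30   | 24   | 18   | 12   | 6    |
| respiration clipping     | 0    | 0.1  | 0.2  | 0.35 | 0.5  |

Only the *directions* of these trends are established facts; the magnitudes
are calibration choices, fixed once so that adjacent levels overlap through
the stochastic oscillator variance while the extreme levels separate
cleanly.  P4/C3 carry the alpha/theta schedule at weight 0.7, Fp1/Fp2 at
0.3 (blinks are frontal-only).  Every channel draws from its own seeded
substream, so regeneration with the same `(config, seed)` is bit-identical
and channel content does not depend on generation order.

What the generator does *not* emulate: volume conduction and channel
correlation, 1/f background spectra, subject-level variability, movement
artifacts other than blinks, and any nonstationarity within an epoch.
Passing tests therefore demonstrate that the pipeline machinery is correct
and that the architecture can learn spectral class structure — not that the
published accuracies transfer to real recordings.

## Preprocessing (`fatiguekit.preprocess`)

Five deterministic stages in fixed order: (1) a centred 15 s window
(half-open sample ranges, 0-based); (2) a second-order IIR notch at the
50 Hz mains frequency, quality factor 30; (3) a first-order Butterworth
band-pass, 0.05–60 Hz; (4) blink suppression; (5) per-channel min–max
normalization to [0, 1].  All filters run forward–backward (zero phase) so
that event morphology is not skewed; this doubles the stop-band attenuation
relative to a single pass.

Blink suppression is re-implemented from first principles: candidate
windows are slow transients on the low-passed (8 Hz) frontal mean exceeding
6 × 1.4826 × MAD; within each window the low-passed, linearly detrended
frontal waveform serves as a blink template that is regressed out of every
channel by least squares.  Channels without blink leakage receive a
near-zero regression weight, and untouched segments are exactly preserved.
Normalization is per channel per epoch (the alternative — one range per
epoch — is exposed as a flag); constant channels map to all zeros by
convention.

## GAN augmentation (`fatiguekit.gan`)

Generator: a 100-dimensional uniform latent vector through fully connected
blocks of widths 128, 256, 512, 1024 and 3750 with leaky-rectifier
activations (slope 0.2) and a logistic output, matching the [0, 1] range of
preprocessed epochs.  The published description labels these widths
"convolution layers", but scalar widths are not reconcilable with
convolutional feature-map arithmetic, so they are realized as dense
layers — the one place where the architecture description had to be
interpreted.  Discriminator: five fully connected layers (512, 256, 128,
64, 1) with dropout (0.3) after layers 1 and 3 and a logistic scalar
output.

Training alternates k discriminator steps (default 1) with one generator
step under the standard minimax objective; the generator loss defaults to
the non-saturating form −E[log D(G(z))] to avoid early-training gradient
vanishing, with the saturating form available by flag.  Probabilities are
clamped at 1e-7 before logs.  Reference hyperparameters: batch 10, SGD,
learning rate 1e-5, 200 epochs; the generator uses the same optimizer
settings as the discriminator since nothing else is specified.  Scaled-down
runs in the test suite use Adam at 5e-4 for tens of epochs — at that scale
a dense GAN reliably learns the coarse waveform of an easy signal family
but not its full diversity (mode collapse), so the training test asserts
support overlap of the generated band-power distribution (two-sample KS
statistic < 0.75 against 1.0 for an untrained generator) rather than
distributional equality.

Augmentation trains one GAN per class on the pooled single-channel traces
of that class; a synthetic multi-channel epoch stacks independent draws.
Synthetic epochs are flagged in the dataset's `synthetic` vector, class
proportions are preserved by largest-remainder apportionment, and real
epochs are never mutated.  Whether a stated corpus growth (e.g. 3750 →
6000 epochs) is per class or total is left to the caller via explicit
`target_total`.

## The classifier (`fatiguekit.network`)

Seven convolution blocks — conv → activation → max-pool(2,2) → batch-norm,
with dropout 0.3 both on the input and after the first block — followed by
a dense softmax head.  Filters 16, 32, 64, 64, 64, 64, 64; the first kernel
is 128 samples with stride 20 (a learned filter bank over the raw
waveform), the rest are kernel 3, stride 1, all same-padded.  Temporal
lengths follow ceil(L/stride) for same-padded convolution and floor(L/2)
for pooling; anchored at a first-conv output of 2375 the chain is
2375→1187→1187→593→593→296→296→148→148→74→74→37→37→18.  That anchor is not
consistent with any of the natural input lengths here (a 3750-sample epoch
gives 188; the four-channel concatenation, 15000 samples, gives 750), so
the input length is a configuration parameter and conformance checks feed a
length-47500 input; the inconsistency is documented rather than silently
repaired.  By default the four selected channels enter concatenated as one
1-D vector (multichannel input is a flag).

### The T2F activation

The published material motivates an interval type-2 fuzzy activation with
exactly three learnable parameters per channel but never states its
functional form.  The form adopted here is an interval type-2 fuzzy
rectifying unit,

    y = x · [ α σ(a(1+δ)x) + (1−α) σ(a(1−δ)x) ],   σ = logistic,

whose two logistic memberships bound a footprint of uncertainty of width
controlled by δ; α blends the upper and lower memberships, and a is the
slope.  This satisfies the 3C parameter count, is differentiable
everywhere, reduces exactly to the swish x·σ(ax) at δ = 0, and approaches
the rectifier as a → ∞ — so the unit interpolates linear, swish and
rectifier behaviour by adjusting its uncertainty, which is the stated
purpose of the construction.  Ranges are enforced by smooth
reparameterization (a = exp ã, δ = 0.99 σ(d̃), α = σ(ã₂)), initialized at
a = 1, δ ≈ 0.5, α = 0.5.  Gradients for x and all three parameters are
hand-derived and verified against central finite differences at 1e-5.

### Training

Cross-entropy loss, batch size 10, learning rate 1e-3, dropout 0.3 — the
tuned optima — with Adadelta as the default optimizer (the tuning table's
choice; RMSProp, which the architecture description names, is selectable
and is what the scaled-down runs use because it converges much faster at
this learning rate).  Splits are stratified 70/10/20 with exact
largest-boundary rounding; five-fold cross-validation uses stratified
shuffled folds.  Early stopping monitors validation accuracy; the best
checkpoint snapshot includes the batch-norm running statistics (restoring
weights without them pairs old weights with drifted statistics and destroys
inference accuracy).  An optional step decay halves the learning rate every
`lr_step` epochs, which damps the late-training oscillation of
best-validation selection at small sample sizes.  Inside the estimator the
[0, 1]-normalized epochs are mapped to [−1, 1] before the input dropout
layer; with uncentred inputs that layer injects offset (non-zero-mean)
noise and roughly doubles the epochs needed to converge.

Everything — weight initialization, batching, dropout, splits — derives
from one integer seed; identical seeds give bit-identical training
histories (the implementation is single-threaded NumPy throughout, which is
also why problem sizes in the tests are tens-to-hundreds of epochs rather
than thousands).

## Evaluation (`fatiguekit.evaluate`)

The metric panel (confusion matrix, accuracy, per-class and macro
sensitivity/specificity/precision/F-score, Cohen's kappa) is computed via
scikit-learn behind a single `MetricsReport`; multiclass rates are
macro-averaged one-vs-rest (the averaging scheme was unspecified).  ROC
curves are per-class one-vs-rest with trapezoidal AUC; a class absent from
the truth vector is flagged degenerate with NaN AUC.  "Peak coefficient"
among the engineered features is interpreted as the crest factor
max|x|/RMS; variance is the population variance and kurtosis the Fisher
excess.

The robustness protocol adds white Gaussian noise to the classifier inputs
at a grid of SNRs (dB, higher = cleaner; noise power is set against the
empirical signal power of each epoch), with seeded replicates; the
infinite-SNR grid point bypasses noise entirely and therefore reproduces
clean accuracy exactly.  The qualitative expectation — accuracy
non-increasing as SNR drops, for every activation variant — is asserted
within replicate standard deviations; the ordering of variants under heavy
noise is reported, never asserted, since at desk scale it is not stable.

## Problem sizes in the scaled runs

The end-to-end five-level check uses 100 epochs per class (70/10/20 split),
50 training epochs with RMSProp and step decay, and requires held-out
accuracy ≥ 0.80 — chosen as a pipeline-validation threshold on the
synthetic conditions, not a reproduction of any published accuracy.
Scenario runs in the acceptance script use 60/80/100 epochs per class for
the two-, three- and five-level settings.  The robustness runs use the
two-level task at SNRs −10, 0, 10 and ∞ dB with three replicates.

## Known limitations

* The synthetic data is far easier than real EEG; accuracies reported on
  it validate machinery, not clinical performance.
* The GAN at desk scale mode-collapses; augmentation with such a generator
  adds prototype-like epochs, which is sufficient to exercise the pipeline
  but would not enrich a real training set.
* The EDF writer quantizes each channel to its own 16-bit physical range
  (per-file, not per-record, calibration).
* Multichannel (non-concatenated) input is supported for training but not
  for checkpoint reload.
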