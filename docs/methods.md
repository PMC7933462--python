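# Methods

This note documents the models and procedures implemented in
`eumotion`, the choices made where the design was genuinely open, and
what the synthetic benchmark can and cannot show.

## The recognition problem

Emotion is modeled on the valence/arousal plane. Subjects rate each
trial on the SAM scale (integers 1-9 per dimension); every model emits
a continuous score S in [0, 1] per dimension, binarized into low/high
at a shared threshold (high iff S >= 0.5). Ground-truth binarization
uses rating >= 5 as high, applied identically everywhere. Two
modalities are analyzed — multichannel EEG and grayscale facial
images — first separately, then combined at the decision level.

## EEG features

Raw trials are (optionally) band-pass filtered 4-45 Hz with a
zero-phase windowed-sinc FIR filter (Hamming window,
`ceil(3.3 fs / transition)` taps, 1 Hz transition band, applied
forward-backward). Band powers are integrated PSD estimates over
theta (4-8 Hz), slow alpha (8-10), alpha (10-12), beta (12-30) and
gamma (30-45), computed on 1-s windows with 50% overlap. Band edges
are half-open [low, high): a spectral bin at exactly 8 Hz belongs to
slow alpha. Two estimators are provided:

* `fft` (default): rectangular-window periodogram per window, Welch
  averaging across windows. The rectangular window was chosen over a
  Hann taper because band powers are integrated over >= 2 Hz wide
  bands (integration already suppresses variance) and the rectangular
  window keeps a tone at an exact bin frequency entirely inside its
  band, which makes band attribution sharp.
* `multitaper`: DPSS tapers with 4 Hz bandwidth (NW from the window
  length), averaged across tapers.

Two feature representations feed the models:

* **Subject-dependent vector** — per-channel, per-band powers averaged
  over windows, channel-major order: 14 x 5 = 70 features per trial.
  Averaging (rather than concatenating) the overlapping windows was
  chosen because it makes the vector length independent of trial
  duration and is the natural per-trial sufficient statistic for a
  stationary band-power level.
* **Subject-independent sequences** — per-second band powers of the 14
  channels plus left-minus-right differentials of the three symmetric
  pairs (T7-T8, Fp1-Fp2, CP1-CP2), (14 + 3) x 5 = 85 features per
  second; 10-s samples with 50% overlap give k x 10 x 85 arrays with
  k = floor((seconds - 10) / 5) + 1. Overlapping 1-s PSD windows are
  binned by the integer second containing their start and averaged.

## Face pipeline

Videos (or frame stacks) are resampled to 4 Hz, grayscaled, cropped to
the detected face box, resized to 48 x 48 and scaled to [0, 1]. The
detector is a pluggable callable `frame -> (row, col, h, w) | None`;
built-ins are an identity detector (pre-cropped input) and a
contrast-box detector that thresholds deviation from the border
median, suited to synthetic faces on uniform backgrounds. Frames with
no detection are dropped.

The multitask CNN is: zero-padding 48 -> 50, conv 3x3x32 (valid, so
the first output is 48 x 48), conv 3x3x32, conv 3x3x64, all ReLU; a
64-unit ReLU dense layer; dropout 0.5; and two sigmoid output
branches (valence, arousal). There are no pooling layers. The
combined loss is L = a1 L1 + a2 L2 with Ln the per-branch binary
cross-entropy summed over the batch (predictions clipped at 1e-7);
defaults a = (1, 1); either weight set to 0 reduces the model to
single-task exactly. Training follows a two-stage transfer protocol:
stage 1 trains all layers (SGD, momentum 0.9, lr 0.01 — the stage-1
optimizer is not constrained by the model definition and these are
conventional values); stage 2 freezes the three convolutional layers
and fine-tunes the dense layers with SGD at lr 1e-4. Freezing is
exact: convolutional weight tensors are bit-identical across stage 2.
Per-trial scores are the per-dimension maximum over the trial's frame
scores. Gradients are mean-reduced within a minibatch so that the
learning rates are batch-size independent; the reported loss remains
the summed form.

The layers are implemented in NumPy (`eumotion.nn`) with hand-written
backprop — im2col convolutions, dense, ReLU, inverted dropout, and an
unrolled LSTM — and are verified against central finite differences
in the test suite.

## Subject-dependent EEG model (SVM with RFE)

One linear SVM per dimension on the 70-d vectors. Features are
standardized (band powers span orders of magnitude in volts^2).
Recursive feature elimination drops max(1, floor(0.10 k)) features
with the smallest absolute weights per round; elimination stops at 7
survivors (10% of 70) or after 2 rounds without inner-CV improvement,
and the surviving set of the best inner-CV round is kept (ties to the
smaller set). The regularization constant C is chosen from
{0.01, 0.1, 1, 10, 100} by stratified inner cross-validation (10
folds, reduced with a warning when a class is smaller). Scores in
[0, 1] come from Platt-style sigmoid calibration of the decision
values; the calibrator is fitted on out-of-fold decision values
(5-fold within the training set) because in-sample decisions of a
near-interpolating SVM overstate confidence.

## Subject-independent model (LSTM)

A stacked LSTM over the 10 x 85 sequences: hidden sizes 128 then 64
(the sequence is unrolled over the 10 time steps), a 54-unit ReLU
dense layer, two linear outputs, dropout 0.5 after each LSTM layer
and the dense layer (not inside recurrent connections). Targets are
SAM ratings mapped to [0, 1] via (r - 1) / 8; the loss is mean-squared
error over both outputs; predictions are clipped to [0, 1] and
per-trial scores are the mean over the trial's samples. Inputs are
z-scored per feature with training-set statistics only — test-subject
data never influence normalization, training, or model selection.
Training uses Adam (lr 1e-3), batch 32, up to 100 epochs with early
stopping (patience 10) on a 10% validation split; the experiment
protocols run 25 epochs, which the early-stopping curve shows is past
convergence on the synthetic cohort.

## Decision-level fusion

Fitted independently per dimension, giving four binary states overall.

* **Weight enumerator**: S_enum = sigma S_face + (1 - sigma) S_EEG,
  sigma swept over {0, 0.01, ..., 1.00}; the sigma with the highest
  training accuracy wins, smallest sigma on ties. Because sigma = 0
  and sigma = 1 lie on the grid, the fitted training accuracy can
  never fall below either single modality.
* **AdaBoost over fixed sub-classifiers** (order: EEG, then face):
  sample weights start uniform (1/m); for each sub-classifier j,
  eps_j is the weight of its errors, clamped to [1e-6, 1 - 1e-6] so a
  perfect sub-classifier keeps a finite weight, w_j =
  0.5 ln((1 - eps_j)/eps_j), and weights are multiplied by
  exp(+-w_j) and renormalized. The sub-classifiers are pre-trained
  and fixed — only the sample and classifier weights are learned,
  unlike standard AdaBoost which would retrain its learners. The
  fused score is logistic(sum w_j s_j) with s_j in {-1, +1}; the
  decision equals the sign of the weighted vote.

In the evaluation protocols, both fusion rules are fitted on the
*binarized out-of-fold* training decisions of the two modalities
(several out-of-fold repeats with different fold assignments,
stacked: three 3-fold repeats for the face head, six 5-fold repeats
for the cheaper SVM, with the face repeats cycled to align) and
applied to continuous scores at test time. Out-of-fold, stacking
practice — the CNN's dense head is re-fine-tuned per fold, the SVM
fold models carry no feature selection fitted on the full split —
because in-sample scores of models that interpolate their 20 training
trials are all on the correct side of 0.5, which ties the
enumerator's training accuracy across most of the grid and reduces
the fitted weight to the tie-break convention. Binarized, because the
position of the smallest tying sigma under continuous scores depends
on the calibration slope — an artifact that does not generalize to
test trials — whereas decisions put every disagreement's switch point
at sigma = 0.5 exactly. Repeated, because a single 5-fold pass over
20 trials too often shows zero errors for a modality that is merely
good, recreating the tie; one error in any repeat breaks it. The
fusion estimators themselves are input-agnostic; callers may fit them
on any score source.

A continuous (valence, arousal) score can be mapped to one of 16
discrete emotion names by nearest Euclidean anchor; the default table
places the 16 names uniformly by angle on a circle of radius 0.4
around (0.5, 0.5) and is fully configurable — the coordinates are a
display convention, not part of the model. Ties break to the
lexicographically smallest name.

## Synthetic data generator

The generator emulates the two physiological signatures the pipeline
targets, with dials for effect size, subject variability and noise:

* EEG: per channel, 1/f background noise plus band-limited noise
  oscillators in the five bands, synthesized by inverse FFT with
  random phases (overall scale ~20 uV). Alpha amplitude is
  asymmetrized across the three symmetric pairs in proportion to
  (valence - 5) (left up / right down for positive valence, gain
  multiplier 1 + eeg_effect (v - 5), floored at 0.05); beta amplitude
  scales the same way with (arousal - 5) on all channels. A
  per-subject log-normal gain (sd subject_sd) models inter-subject
  amplitude differences; per-trial log-normal gain jitter
  (sd 0.2 noise_sd) models non-stationarity.
* Faces: parametric 48 x 48 sketches — head ellipse, two eyes whose
  half-height follows (arousal - 5), and a parabolic mouth whose
  curvature follows face_effect (valence - 5) pixels — plus Gaussian
  pixel noise (sd 0.04 noise_sd), clipped to [0, 1]. These are
  signal-recovery fixtures, not renderings.

Labels are uniform integers 1-9 per dimension, resampled until each
subject has both binary classes in both dimensions. Both mappings
are linear in (rating - 5), so the planted effects vanish exactly at
the binary cut.

Defaults (the study conditions of the synthetic benchmark): 15
subjects x 40 trials, 128 Hz, 60-s trials, 4 face frames per trial,
eeg_effect 0.3, face_effect 1.0, subject_sd 0.15, noise_sd 1.0.
Effects were chosen so the planted signals are clearly recoverable:
frontal alpha asymmetry separates valence 9 from valence 1 with
Cohen's d > 1, and a linear classifier on raw pixels separates high
from low valence at >= 90% — both properties are asserted in the test
suite. What passing these tests shows is that every pipeline stage
(features, models, fusion, protocols) recovers signals it was built
to detect and stays at chance when the signal is absent. It does not
show real-data performance: real EEG has artifacts, non-stationarity
and much weaker, subject-specific effect topographies, and real faces
vary in pose, identity and illumination — none of which the generator
emulates.

## Evaluation protocols

* **Subject-dependent**: per subject, a random 20/20 train/test split
  of the 40 trials, resampled (up to 10 times) until the training
  half contains both classes in both dimensions. The face CNN is
  pretrained once on a synthetic corpus (240 images, 12 epochs) and
  its dense head is re-initialized from that state and fine-tuned per
  subject (25 epochs on cached convolutional features — the frozen
  trunk makes caching exact). SVM, enumerator and AdaBoost are fitted
  per subject and dimension; all four methods are evaluated on the
  test trials.
* **Subject-independent**: the LSTM is trained on all sequence samples
  of the training subjects (12 of 15 in the benchmark) and evaluated
  per trial on the held-out subjects.

Metrics: accuracy (%), recall of the high class (%) — reported as
missing, never 0, when a test set has no actually-high trials — and
RMSE on the 1-9 scale for regression outputs. Summary rows are plain
arithmetic means over subjects.

## Numerical choices and degenerate inputs

* Threshold boundary: S = 0.5 classifies as high, everywhere.
* Enumerator ties: smallest sigma.
* AdaBoost error clamp: [1e-6, 1 - 1e-6].
* PSD windows shorter than the trial raise; zero-length batches raise;
  NaN scores raise rather than classify.
* RFE removes at least one feature per round, guaranteeing progress on
  small feature sets; single-class labels raise.
* All training is seeded; identical seeds give identical models
  (bit-identical features, deterministic sklearn solvers, seeded NumPy
  initialization and shuffling).

## Known limitations

* The CNN and LSTM are NumPy implementations tuned for clarity and
  test-scale problems; they are single-threaded BLAS-bound and not
  suited to large corpora.
* MP4 input requires an imageio ffmpeg backend; PNG frame stacks are
  the first-class storage format.
* The Viola-Jones detector of the original real-time pipeline is out
  of scope; the detector interface accepts any replacement.
* Fusion weights are fitted on training scores (the protocols' choice)
  — a held-out fusion split would give less optimistic training
  accuracies but is not implemented.
* The synthetic benchmark's accuracies are not comparable to published
  accuracies on DEAP or MAHNOB-HCI; loaders for those access-controlled
  datasets are out of scope.
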