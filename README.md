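# eumotion

Multimodal emotion recognition from EEG and facial expressions:
band-power EEG features, a multitask face CNN, subject-dependent SVM
and subject-independent LSTM models, and decision-level fusion of the
two modalities into binary valence/arousal states.

## Who this is for

Affective-computing researchers who want a tested, self-contained
reference implementation of a classic EEG + face recognition stack:
every stage — storage, filtering, spectral features, models, fusion,
evaluation protocols — is a library function with unit tests and a
synthetic multimodal generator, so the whole pipeline runs end to end
without access-controlled datasets.

## The model

Emotion is a point on the valence/arousal plane; subjects rate each
trial 1-9 per dimension (SAM), and each dimension is binarized at
rating >= 5. Every recognizer emits a score S in [0, 1], classified
high iff S >= 0.5.

* **EEG features** — PSD integrated over theta (4-8 Hz), slow alpha
  (8-10), alpha (10-12), beta (12-30) and gamma (30-45) on 1-s
  windows with 50% overlap. The subject-dependent vector is the
  window-averaged band power of 14 channels (14 x 5 = 70 features);
  the subject-independent representation adds the three symmetric
  left-right pair differentials per second ((14 + 3) x 5 = 85) and
  stacks 10-s samples into 10 x 85 matrices.
* **Face CNN** — 48 x 48 grayscale faces (video resampled to 4 Hz,
  Viola-Jones-style detector interface) through conv 32/32/64 (3x3,
  first layer zero-padded to 50 x 50), dense 64, dropout 0.5, two
  sigmoid heads; loss `L = a1 L1 + a2 L2` (per-head binary
  cross-entropy); transfer protocol: pretrain all layers, then freeze
  the convolutions and fine-tune at lr 1e-4. Trial score = max over
  frames.
* **EEG models** — per dimension: a linear SVM with recursive feature
  elimination (drop the lowest-|w| 10% per round, inner 10-fold CV)
  and Platt-calibrated scores; and a stacked LSTM (128 -> 64, dense
  54, dropout 0.5, MSE) over the 10 x 85 sequences for cross-subject
  use.
* **Fusion** — per dimension: a weight enumerator
  `S = sigma S_face + (1 - sigma) S_EEG` with sigma swept in steps of
  0.01 (best training accuracy, smallest sigma on ties), and AdaBoost
  over the two fixed sub-classifiers
  (`w_j = 0.5 ln((1 - eps_j)/eps_j)`, fused score
  `logistic(sum w_j s_j)`). A nearest-anchor map turns continuous
  scores into one of 16 named discrete emotions.

See `docs/methods.md` for assumptions, parameter tables and
limitations.

## Worked example

Generate a small synthetic cohort and run the subject-dependent
protocol (three subjects, 12 trials each, to keep it quick):

```python
from eumotion import GeneratorConfig
from eumotion.synth import generate_trials
from eumotion.experiments import run_subject_dependent

cfg = GeneratorConfig(n_subjects=3, trials_per_subject=12,
                      trial_duration_s=30.0, seed=3)
data = generate_trials(cfg)
res = run_subject_dependent(data, n_train=6, n_test=6, seed=3,
                            pretrain_images=96, pretrain_epochs=6,
                            finetune_epochs=12, effect_config=cfg)
print(res.metrics.groupby(["dimension", "method"])["accuracy"].mean())
```

```
dimension  method
arousal    adaboost_fusion     88.888889
           eeg_svm             83.333333
           enum_fusion         88.888889
           face               100.000000
valence    adaboost_fusion     77.777778
           eeg_svm             66.666667
           enum_fusion         88.888889
           face                77.777778
Name: accuracy, dtype: float64
```

Each number is the mean test-trial accuracy (%) over the three
subjects for one method and dimension: `face` is the fine-tuned CNN,
`eeg_svm` the calibrated SVM on the 70-d band-power vectors, and the
two fusion rows combine those scores at the decision level. At this
small scale (six test trials per subject) the per-cell numbers are
coarse, but the qualitative picture is the intended one: both planted
signals are detected well above chance, and in the valence dimension
the enumerator fusion (88.9%) beats either single modality.

The same store can be built on disk and inspected from the shell:

```bash
eumotion synth --subjects 3 --trials 8 --seed 0 --out /tmp/db
eumotion store ls /tmp/db --subject s01
eumotion features extract /tmp/db --mode vector --out /tmp/feats
```

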