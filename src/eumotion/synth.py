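"""Synthetic multimodal trial generator.

Emulates the two physiological signatures the recognition pipeline is
built to detect, with controllable effect sizes so every downstream
stage is trainable and testable without any real recordings:

* **EEG** — each channel is 1/f (pink) background noise plus
  band-limited oscillators in the five canonical bands, synthesized in
  the frequency domain with random phases.  Alpha-band amplitude is
  asymmetrized between left and right paired channels in proportion to
  (valence - 5); beta-band amplitude scales with (arousal - 5).  A
  per-subject multiplicative gain models inter-subject variability.
* **Faces** — 48 x 48 parametric sketches: mouth curvature follows
  (valence - 5), eye openness follows (arousal - 5), plus Gaussian
  pixel noise.  These are signal-recovery fixtures, not renderings.

Both mappings are linear in (rating - 5), so the binary ground-truth
cut at rating >= 5 aligns with the planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import OFFLINE_MONTAGE, Montage
from .records import EEGTrial, SAMRating, TrialRecord
from .store import DatasetStore

#: Baseline oscillator amplitude per band, relative units.
_BAND_BASE = {
    "theta": 1.0,
    "slow_alpha": 1.0,
    "alpha": 1.5,
    "beta": 1.0,
    "gamma": 0.5,
}
_BAND_EDGES = {
    "theta": (4.0, 8.0),
    "slow_alpha": (8.0, 10.0),
    "alpha": (10.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}
#: Overall amplitude scale (volts); ~20 uV, a realistic scalp EEG level.
_AMPLITUDE_V = 20e-6


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    eeg_effect is the fractional band-amplitude shift per rating unit
    away from 5; face_effect the geometric displacement in pixels per
    rating unit; subject_sd the log-scale SD of the per-subject gain;
    noise_sd scales the pink background and trial-to-trial gain
    jitter.
    """

    n_subjects: int = 15
    trials_per_subject: int = 40
    fs: float = 128.0
    trial_duration_s: float = 60.0
    eeg_effect: float = 0.3
    face_effect: float = 1.0
    subject_sd: float = 0.15
    noise_sd: float = 1.0
    frames_per_trial: int = 4
    image_size: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.trials_per_subject, self.frames_per_trial) < 1:
            raise ValueError("counts must be positive")
        if min(self.eeg_effect, self.face_effect, self.subject_sd, self.noise_sd) < 0:
            raise ValueError("effects and SDs must be non-negative")

    @property
    def montage(self) -> Montage:
        return OFFLINE_MONTAGE


def generate_labels(config: GeneratorConfig, rng: np.random.Generator) -> list[SAMRating]:
    """Uniform integer SAM ratings with both binary classes guaranteed.

    Resamples until each dimension has at least one high (>= 5) and one
    low rating within the subject's trial set.
    """
    k = config.trials_per_subject
    if k < 2:
        raise ValueError("need at least 2 trials per subject to cover both classes")
    while True:
        vals = rng.integers(1, 10, size=k)
        ars = rng.integers(1, 10, size=k)
        ok = all(np.any(x >= 5) and np.any(x < 5) for x in (vals, ars))
        if ok:
            return [SAMRating(int(v), int(a)) for v, a in zip(vals, ars)]


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via inverse FFT with random phases."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(n: int, fs: float, low: float, high: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited to [low, high) Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = ((freqs >= low) & (freqs < high)).astype(float)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    x = np.fft.irfft(amp * np.exp(1j * phases), n=n)
    return x / x.std()


def _lateral_sides(montage: Montage) -> tuple[set[str], set[str]]:
    lefts = {l for l, _ in montage.pairs}
    rights = {r for _, r in montage.pairs}
    return lefts, rights


def generate_eeg(rating: SAMRating, config: GeneratorConfig,
                 subject_offset: float, rng: np.random.Generator) -> EEGTrial:
    """One 14-channel trial with planted valence/arousal effects.

    Valence modulates alpha-band amplitude asymmetrically across the
    montage's symmetric pairs (left up / right down for positive
    valence); arousal scales beta-band amplitude on every channel.
    """
    montage = config.montage
    n = int(round(config.trial_duration_s * config.fs))
    lefts, rights = _lateral_sides(montage)
    dv = rating.valence - 5  # rating units away from the binary cut
    da = rating.arousal - 5
    data = np.empty((montage.n_channels, n))
    for ci, ch in enumerate(montage.channels):
        sig = config.noise_sd * _pink_noise(n, config.fs, rng)
        for band, base in _BAND_BASE.items():
            gain = base * np.exp(rng.normal(0.0, 0.2 * config.noise_sd))
            if band == "alpha":
                if ch in lefts:
                    gain *= max(0.05, 1.0 + config.eeg_effect * dv)
                elif ch in rights:
                    gain *= max(0.05, 1.0 - config.eeg_effect * dv)
            elif band == "beta":
                gain *= max(0.05, 1.0 + config.eeg_effect * da)
            low, high = _BAND_EDGES[band]
            sig = sig + gain * _band_noise(n, config.fs, low, high, rng)
        data[ci] = sig
    data *= _AMPLITUDE_V * subject_offset
    return EEGTrial(data, config.fs, list(montage.channels))


def generate_faces(rating: SAMRating, config: GeneratorConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Parametric 48 x 48 face sketches encoding the rating.

    Mouth curvature (pixels of arc) is proportional to (valence - 5);
    eye half-height to (arousal - 5).  Returns
    (frames_per_trial, size, size) floats in [0, 1].
    """
    s = config.image_size
    imgs = np.empty((config.frames_per_trial, s, s))
    curv = config.face_effect * (rating.valence - 5)
    eye_h = np.clip(2.5 + 0.45 * config.face_effect * (rating.arousal - 5), 0.6, 8.0)
    yy, xx = np.mgrid[0:s, 0:s]
    cx = s / 2.0
    for k in range(config.frames_per_trial):
        img = np.full((s, s), 0.55)
        # head outline: filled light ellipse
        head = ((yy - s / 2.0) / (s * 0.42)) ** 2 + ((xx - cx) / (s * 0.34)) ** 2 <= 1.0
        img[head] = 0.82
        # eyes: dark ellipses, half-height encodes arousal
        for ex in (cx - 8, cx + 8):
            eye = ((yy - 18) / eye_h) ** 2 + ((xx - ex) / 3.5) ** 2 <= 1.0
            img[eye] = 0.15
        # mouth: parabolic arc, curvature encodes valence
        for dx in np.arange(-8, 8.01, 0.25):
            x = cx + dx
            y = 33 - curv * (dx / 8.0) ** 2
            r0, c0 = int(round(y)), int(round(x))
            img[max(0, r0 - 1):r0 + 1, max(0, c0):c0 + 1] = 0.1
        img = img + rng.normal(0.0, 0.04 * config.noise_sd, size=(s, s))
        imgs[k] = np.clip(img, 0.0, 1.0)
    return imgs


def subject_ids(config: GeneratorConfig) -> list[str]:
    return [f"s{k + 1:02d}" for k in range(config.n_subjects)]


def generate_subject_trials(config: GeneratorConfig, subject_index: int) -> list[TrialRecord]:
    """All trials of one subject, deterministically derived from the seed."""
    sid = subject_ids(config)[subject_index]
    rng = np.random.default_rng([config.seed % (2 ** 31), subject_index])
    offset = float(np.exp(rng.normal(0.0, config.subject_sd)))
    ratings = generate_labels(config, rng)
    records = []
    for t, rating in enumerate(ratings, start=1):
        eeg = generate_eeg(rating, config, offset, rng)
        faces = generate_faces(rating, config, rng)
        records.append(TrialRecord(
            subject_id=sid, trial_id=t, eeg=eeg, rating=rating,
            face_frames=faces, meta={"name": sid, "age": "21", "gender": "na"}))
    return records


def generate_trials(config: GeneratorConfig) -> dict[str, list[TrialRecord]]:
    """In-memory dataset: subject id -> trial records."""
    return {subject_ids(config)[i]: generate_subject_trials(config, i)
            for i in range(config.n_subjects)}


def generate_dataset(config: GeneratorConfig, root) -> DatasetStore:
    """Write a full store to disk via the folder database; returns it indexed."""
    store = DatasetStore(root)
    for i in range(config.n_subjects):
        for rec in generate_subject_trials(config, i):
            store.save_trial(rec, overwrite=True)
    store.index()
    return store
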