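"""Core record types shared across the toolbox.

Emotion is represented on the valence/arousal plane.  Subjects report
integer SAM (Self-Assessment Manikin) ratings in 1..9 per dimension;
models emit continuous scores in [0, 1] per dimension which are later
binarized at 0.5 into low/high states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

DIMENSIONS = ("valence", "arousal")

#: SAM ratings at or above this value count as the "high" state.
HIGH_RATING_CUT = 5


@dataclass(frozen=True)
class SAMRating:
    """Integer 1-9 self-report rating per emotion dimension."""

    valence: int
    arousal: int

    def __post_init__(self) -> None:
        for name in DIMENSIONS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 9):
                raise ValueError(f"{name} rating must be an integer in [1, 9], got {v!r}")

    def binary(self, dimension: str) -> bool:
        """True iff the rating for ``dimension`` is in the high state (>= 5)."""
        return getattr(self, dimension) >= HIGH_RATING_CUT

    def as_tuple(self) -> tuple[int, int]:
        return (self.valence, self.arousal)


@dataclass(frozen=True)
class EmotionScore:
    """Continuous per-dimension score in [0, 1] emitted by a model."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in DIMENSIONS:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score must be finite and in [0, 1], got {v!r}")


@dataclass
class EEGTrial:
    """One multichannel EEG recording.

    data is a channels x samples matrix (volts or device units), fs the
    sampling rate in Hz and channel_names the 10-20-system labels in row
    order.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D channels x samples matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.fs <= 2 * 45:
            raise ValueError("sampling rate must exceed 90 Hz (Nyquist for the gamma band)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def pick(self, names: list[str]) -> "EEGTrial":
        """Return a copy restricted to ``names``, in that order."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in trial: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return EEGTrial(self.data[idx].copy(), self.fs, list(names))


@dataclass
class TrialRecord:
    """One trial of a subject: EEG, optional face frames, and the SAM rating.

    face_frames, when present, is an n x H x W float array in [0, 1]
    (grayscale).  EEG-only trials are allowed.
    """

    subject_id: str
    trial_id: int
    eeg: EEGTrial
    rating: SAMRating
    face_frames: Optional[np.ndarray] = None
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not (isinstance(self.trial_id, (int, np.integer)) and self.trial_id >= 1):
            raise ValueError("trial_id must be an integer >= 1")
        if self.face_frames is not None:
            self.face_frames = np.asarray(self.face_frames, dtype=float)
            if self.face_frames.ndim != 3:
                raise ValueError("face_frames must be n x H x W")
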