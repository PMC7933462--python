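"""Folder-based trial storage.

On-disk layout::

    root/
      <subject_id>/
        labels.csv            # subject_id,trial_id,valence,arousal
        trial_<k>/
          eeg_raw.fif         # raw EEG (FIF)
          psd.npy             # optional derived band-power matrix
          meta.json           # subject metadata (name, age, gender, ...)
          frames/frame_0000.png ...   # optional 16-bit grayscale face frames

Raw EEG goes to FIF, derived PSD matrices to NPY, labels and metadata
to CSV/JSON, and face frames to a PNG stack (no video codec needed).
Re-indexing simply rescans the tree, so the index is always exactly
the set of trials on disk.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import mne
import numpy as np
import pandas as pd

from .records import EEGTrial, SAMRating, TrialRecord

_TRIAL_DIR = re.compile(r"^trial_(\d+)$")
LABEL_COLUMNS = ["subject_id", "trial_id", "valence", "arousal"]


def parse_rating_cell(cell: str) -> SAMRating:
    """Parse a combined ``"valence,arousal"`` CSV cell, e.g. ``"5,7"``."""
    parts = [p.strip() for p in str(cell).split(",")]
    if len(parts) != 2:
        raise ValueError(f"cannot parse rating cell {cell!r}")
    return SAMRating(int(parts[0]), int(parts[1]))


class DatasetStore:
    """Handle to a folder database of trials."""

    def __init__(self, root: str | Path):
        self.root = Path(root)

    # -- indexing -----------------------------------------------------
    def index(self) -> list[tuple[str, int]]:
        """Scan the tree; sorted (subject, trial) pairs. Idempotent."""
        pairs = []
        if not self.root.exists():
            return pairs
        for subject_dir in sorted(p for p in self.root.iterdir() if p.is_dir()):
            for trial_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
                m = _TRIAL_DIR.match(trial_dir.name)
                if m and (trial_dir / "eeg_raw.fif").exists():
                    pairs.append((subject_dir.name, int(m.group(1))))
        pairs.sort()
        return pairs

    def list_trials(self, subject_id: Optional[str] = None) -> list[tuple[str, int]]:
        pairs = self.index()
        if subject_id is None:
            return pairs
        return [p for p in pairs if p[0] == subject_id]

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.index()})

    def _trial_dir(self, subject_id: str, trial_id: int) -> Path:
        return self.root / subject_id / f"trial_{trial_id}"

    # -- saving -------------------------------------------------------
    def save_trial(self, rec: TrialRecord, overwrite: bool = False,
                   psd: Optional[np.ndarray] = None) -> Path:
        """Write one trial; returns its directory.

        Refuses to overwrite an existing (subject, trial) pair unless
        ``overwrite`` is set.
        """
        tdir = self._trial_dir(rec.subject_id, rec.trial_id)
        if tdir.exists() and not overwrite:
            raise FileExistsError(
                f"trial ({rec.subject_id}, {rec.trial_id}) already stored; "
                "pass overwrite=True to replace it")
        tdir.mkdir(parents=True, exist_ok=True)

        info = mne.create_info(list(rec.eeg.channel_names), rec.eeg.fs, ch_types="eeg")
        raw = mne.io.RawArray(rec.eeg.data, info, verbose="error")
        raw.save(tdir / "eeg_raw.fif", overwrite=True, verbose="error")

        if psd is not None:
            np.save(tdir / "psd.npy", np.asarray(psd))
        if rec.meta:
            (tdir / "meta.json").write_text(json.dumps(dict(rec.meta)))
        if rec.face_frames is not None:
            frames_dir = tdir / "frames"
            frames_dir.mkdir(exist_ok=True)
            for i, frame in enumerate(rec.face_frames):
                img = np.clip(frame, 0.0, 1.0)
                iio.imwrite(frames_dir / f"frame_{i:04d}.png",
                            np.round(img * 65535).astype(np.uint16))

        self._update_labels(rec)
        return tdir

    def _update_labels(self, rec: TrialRecord) -> None:
        path = self.root / rec.subject_id / "labels.csv"
        if path.exists():
            df = pd.read_csv(path)
        else:
            df = pd.DataFrame(columns=LABEL_COLUMNS)
        df = df[df["trial_id"] != rec.trial_id]
        row = pd.DataFrame([{
            "subject_id": rec.subject_id, "trial_id": rec.trial_id,
            "valence": rec.rating.valence, "arousal": rec.rating.arousal,
        }])
        df = pd.concat([df, row], ignore_index=True).sort_values("trial_id")
        df.to_csv(path, index=False)

    # -- loading ------------------------------------------------------
    def load_trial(self, subject_id: str, trial_id: int) -> TrialRecord:
        tdir = self._trial_dir(subject_id, trial_id)
        fif = tdir / "eeg_raw.fif"
        if not fif.exists():
            raise FileNotFoundError(
                f"no stored trial ({subject_id}, {trial_id}) under {self.root}")
        raw = mne.io.read_raw_fif(fif, preload=True, verbose="error")
        eeg = EEGTrial(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names))

        rating = self._read_rating(subject_id, trial_id)
        meta_path = tdir / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

        frames = None
        frames_dir = tdir / "frames"
        if frames_dir.exists():
            files = sorted(frames_dir.glob("frame_*.png"))
            if files:
                imgs = [iio.imread(f) for f in files]
                frames = np.stack([i.astype(float) / 65535.0 for i in imgs])
        return TrialRecord(subject_id, trial_id, eeg, rating, frames, meta)

    def _read_rating(self, subject_id: str, trial_id: int) -> SAMRating:
        path = self.root / subject_id / "labels.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing labels.csv for subject {subject_id}")
        df = pd.read_csv(path, dtype=str)
        match = df[df["trial_id"].astype(str) == str(trial_id)]
        if match.empty:
            raise KeyError(f"trial {trial_id} not present in {path}")
        row = match.iloc[0]
        try:
            return SAMRating(int(row["valence"]), int(row["arousal"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"corrupt label row for subject {subject_id}, trial {trial_id} "
                f"in {path}: {row.to_dict()}") from exc

    def load_psd(self, subject_id: str, trial_id: int) -> Optional[np.ndarray]:
        path = self._trial_dir(subject_id, trial_id) / "psd.npy"
        return np.load(path) if path.exists() else None


def save_trial(store: DatasetStore, rec: TrialRecord, **kwargs) -> Path:
    return store.save_trial(rec, **kwargs)


def load_trial(store: DatasetStore, subject_id: str, trial_id: int) -> TrialRecord:
    return store.load_trial(subject_id, trial_id)


def list_trials(store: DatasetStore, subject_id: Optional[str] = None) -> list[tuple[str, int]]:
    return store.list_trials(subject_id)
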