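"""EEG band-power feature extraction.

Raw multichannel EEG is turned into two representations:

* a per-trial **70-dimensional vector** (14 channels x 5 bands, windows
  averaged) used by the subject-dependent SVM, and
* per-sample **10 x 85 sequences** (per-second band powers of 14
  channels plus 3 symmetric-pair differentials, 10-s windows with 50%
  overlap) used by the subject-independent LSTM.

Band powers are integrated power-spectral-density estimates over the
theta / slow-alpha / alpha / beta / gamma bands, computed on 1-s
windows with 50% overlap.  Two PSD estimators are provided: ``fft``
(rectangular-window Welch average of per-window periodograms) and
``multitaper`` (DPSS tapers, 4 Hz bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .montage import BAND_NAMES, DEFAULT_BANDS, BandDefinition, Montage
from .records import EEGTrial


@dataclass
class BandPowerTable:
    """Per-window, per-channel, per-band integrated spectral power.

    values has shape (n_windows, n_channels, n_bands) and is
    non-negative.  Window i starts at ``i * window_s * (1 - overlap)``
    seconds.
    """

    values: np.ndarray
    window_s: float
    overlap: float
    channel_names: list[str]
    band_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (windows, channels, bands)")
        if np.any(self.values < 0):
            raise ValueError("band powers must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def window_starts(self) -> np.ndarray:
        step = self.window_s * (1.0 - self.overlap)
        return np.arange(self.n_windows) * step


def expected_window_count(duration_s: float, window_s: float, overlap: float) -> int:
    """floor((duration - window) / (window * (1 - overlap))) + 1."""
    return int(np.floor((duration_s - window_s) / (window_s * (1.0 - overlap)))) + 1


def bandpass_fir(trial: EEGTrial, low: float, high: float,
                 transition_hz: float = 1.0) -> EEGTrial:
    """Zero-phase FIR band-pass filter, applied per channel.

    Windowed-sinc (Hamming) design with ``ceil(3.3 * fs / transition)``
    taps (rounded up to odd), applied forward-backward (zero phase);
    the shape is preserved.
    """
    if not low < high:
        raise ValueError("require low < high")
    if high >= trial.fs / 2:
        raise ValueError(f"high edge {high} Hz must lie below Nyquist {trial.fs / 2} Hz")
    numtaps = int(np.ceil(3.3 * trial.fs / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(numtaps, [low, high], pass_zero=False,
                         window="hamming", fs=trial.fs)
    padlen = min(3 * numtaps, trial.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], trial.data, axis=1, padlen=padlen)
    return EEGTrial(filtered, trial.fs, list(trial.channel_names))


def _window_view(data: np.ndarray, win_n: int, step_n: int) -> np.ndarray:
    """(channels, samples) -> (channels, n_windows, win_n) view."""
    view = sliding_window_view(data, win_n, axis=1)
    return view[:, ::step_n, :]


def _psd_fft(segs: np.ndarray, fs: float) -> np.ndarray:
    """One-sided periodogram (rectangular window) per segment."""
    win_n = segs.shape[-1]
    spec = np.fft.rfft(segs, axis=-1)
    psd = (np.abs(spec) ** 2) / (fs * win_n)
    psd[..., 1:] *= 2.0
    if win_n % 2 == 0:
        psd[..., -1] /= 2.0
    return psd


def _psd_multitaper(segs: np.ndarray, fs: float, half_bandwidth_hz: float = 2.0) -> np.ndarray:
    """DPSS multitaper PSD per segment (eigenvalue-unweighted average)."""
    win_n = segs.shape[-1]
    nw = half_bandwidth_hz * win_n / fs
    k = max(1, int(2 * nw) - 1)
    tapers = signal.windows.dpss(win_n, NW=nw, Kmax=k)  # (k, win_n)
    spec = np.fft.rfft(segs[..., None, :] * tapers, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) / fs
    psd[..., 1:] *= 2.0
    if win_n % 2 == 0:
        psd[..., -1] /= 2.0
    return psd


def compute_band_psd(trial: EEGTrial,
                     bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                     window_s: float = 1.0,
                     overlap: float = 0.5,
                     method: str = "fft") -> BandPowerTable:
    """Integrate the PSD of sliding windows over each frequency band.

    Band membership is half-open [low, high): a bin at exactly 8 Hz
    belongs to slow alpha, not theta.  Powers carry units of
    (signal unit)^2 and satisfy Parseval within the 4-45 Hz span.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if trial.duration_s < window_s:
        raise ValueError(
            f"trial of {trial.duration_s:.3f} s is shorter than one {window_s} s window"
        )
    win_n = int(round(window_s * trial.fs))
    step_n = max(1, int(round(win_n * (1.0 - overlap))))
    segs = _window_view(trial.data, win_n, step_n)  # (ch, win, n)
    if method == "fft":
        psd = _psd_fft(segs, trial.fs)
    elif method == "multitaper":
        psd = _psd_multitaper(segs, trial.fs)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    freqs = np.fft.rfftfreq(win_n, d=1.0 / trial.fs)
    df = freqs[1] - freqs[0]
    out = np.empty(psd.shape[:2] + (len(bands),))
    for b, band in enumerate(bands):
        mask = (freqs >= band.low) & (freqs < band.high)
        out[..., b] = psd[..., mask].sum(axis=-1) * df
    # (ch, win, band) -> (win, ch, band)
    return BandPowerTable(np.transpose(out, (1, 0, 2)), window_s, overlap,
                          list(trial.channel_names), [b.name for b in bands])


def subject_dependent_features(bpt: BandPowerTable, montage: Montage) -> np.ndarray:
    """Per-trial feature vector: window-averaged band powers.

    Channel-major, band-minor ordering over the montage channels; with
    14 channels and 5 bands the vector has length 70.
    """
    missing = [c for c in montage.channels if c not in bpt.channel_names]
    if missing:
        raise KeyError(f"band-power table lacks montage channels: {missing}")
    idx = [bpt.channel_names.index(c) for c in montage.channels]
    mean_power = bpt.values.mean(axis=0)  # (ch, band)
    return mean_power[idx].reshape(-1)


def feature_layout(montage: Montage, band_names: Sequence[str] = BAND_NAMES) -> list[tuple[str, str]]:
    """(channel, band) name pairs in vector order."""
    return [(c, b) for c in montage.channels for b in band_names]


def per_second_powers(bpt: BandPowerTable) -> np.ndarray:
    """Aggregate overlapping windows into per-second band powers.

    Windows are binned by the integer second containing their start and
    averaged, yielding (n_seconds, n_channels, n_bands).
    """
    starts = bpt.window_starts()
    secs = np.floor(starts + 1e-9).astype(int)
    n_sec = secs.max() + 1
    out = np.zeros((n_sec,) + bpt.values.shape[1:])
    counts = np.zeros(n_sec)
    np.add.at(out, secs, bpt.values)
    np.add.at(counts, secs, 1.0)
    return out / counts[:, None, None]


def sequence_features(bpt: BandPowerTable, montage: Montage,
                      sample_window_s: int = 10,
                      sample_overlap: float = 0.5) -> np.ndarray:
    """Stack per-second features into overlapping sequence samples.

    Per second the feature row holds 5 band powers for each montage
    channel plus 5 left-minus-right band-power differentials for each
    symmetric pair — (14 + 3) x 5 = 85 under the offline montage.
    Returns an array of shape (k, sample_window_s, n_features) with
    ``k = floor((n_seconds - window) / step) + 1``.
    """
    if not montage.pairs:
        raise ValueError("sequence features require a montage with symmetric pairs")
    per_sec = per_second_powers(bpt)  # (sec, ch, band)
    missing = [c for c in montage.channels if c not in bpt.channel_names]
    if missing:
        raise KeyError(f"band-power table lacks montage channels: {missing}")
    idx = [bpt.channel_names.index(c) for c in montage.channels]
    chan_feats = per_sec[:, idx, :]  # (sec, 14, 5)
    pair_feats = np.stack(
        [per_sec[:, bpt.channel_names.index(l), :] - per_sec[:, bpt.channel_names.index(r), :]
         for l, r in montage.pairs], axis=1)  # (sec, n_pairs, 5)
    feats = np.concatenate([chan_feats, pair_feats], axis=1)
    feats = feats.reshape(feats.shape[0], -1)  # (sec, 85)
    n_sec = feats.shape[0]
    if n_sec < sample_window_s:
        raise ValueError(f"trial of {n_sec} s is shorter than one {sample_window_s} s sample")
    step = max(1, int(round(sample_window_s * (1.0 - sample_overlap))))
    k = (n_sec - sample_window_s) // step + 1
    return np.stack([feats[i * step: i * step + sample_window_s] for i in range(k)])


def trial_vector(trial: EEGTrial, montage: Montage, *,
                 bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                 window_s: float = 1.0, overlap: float = 0.5,
                 method: str = "fft") -> np.ndarray:
    """Convenience: raw trial -> 70-d subject-dependent vector."""
    picked = trial.pick(list(montage.channels))
    return subject_dependent_features(
        compute_band_psd(picked, bands, window_s, overlap, method), montage)


def trial_sequences(trial: EEGTrial, montage: Montage, *,
                    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                    method: str = "fft") -> np.ndarray:
    """Convenience: raw trial -> (k, 10, 85) subject-independent samples."""
    picked = trial.pick(list(montage.channels))
    return sequence_features(compute_band_psd(picked, bands, 1.0, 0.5, method), montage)


class SubjectDependentExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of EEGTrial -> (n_trials, n_channels*5) matrix."""

    def __init__(self, montage: Montage, window_s: float = 1.0,
                 overlap: float = 0.5, method: str = "fft"):
        self.montage = montage
        self.window_s = window_s
        self.overlap = overlap
        self.method = method

    def fit(self, X: Iterable[EEGTrial], y=None):
        self.n_features_out_ = self.montage.n_channels * len(DEFAULT_BANDS)
        return self

    def transform(self, X: Iterable[EEGTrial]) -> np.ndarray:
        return np.stack([
            trial_vector(t, self.montage, window_s=self.window_s,
                         overlap=self.overlap, method=self.method) for t in X])


class SequenceExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of EEGTrial -> list of (k, 10, 85) sample stacks."""

    def __init__(self, montage: Montage, method: str = "fft"):
        self.montage = montage
        self.method = method

    def fit(self, X: Iterable[EEGTrial], y=None):
        return self

    def transform(self, X: Iterable[EEGTrial]) -> list[np.ndarray]:
        return [trial_sequences(t, self.montage, method=self.method) for t in X]
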