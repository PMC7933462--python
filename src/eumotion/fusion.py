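"""Decision-level fusion of modality scores, and the discrete-emotion map.

Two fusion rules combine a facial-expression score S_face and an EEG
score S_EEG (each in [0, 1], one model per emotion dimension):

* **Weight enumerator** — exhaustive search of the convex mixture
  S = sigma * S_face + (1 - sigma) * S_EEG over sigma in {0, 0.01, ...,
  1.00}, keeping the sigma with the highest training accuracy
  (smallest sigma on ties).
* **AdaBoost over fixed sub-classifiers** — the modality classifiers
  are pre-trained and fixed; only the per-sample weights alpha and the
  per-classifier weights w_j = 0.5 * ln((1 - eps_j) / eps_j) are
  learned, with eps_j the alpha-weighted error of classifier j and
  multiplicative sample reweighting between rounds.  The fused score
  is S_boost = logistic(sum_j w_j s_j) with s_j in {-1, +1}.

Every score is binarized by a shared threshold: high iff S >= 0.5.
A continuous (valence, arousal) score can finally be mapped to one of
16 named discrete emotions by nearest Euclidean anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .records import EmotionScore

LOW, HIGH = "low", "high"


def threshold_classify(S):
    """Binarize a score (or array of scores): high iff S >= 0.5."""
    arr = np.asarray(S, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("score is NaN")
    labels = np.where(arr >= 0.5, HIGH, LOW)
    return labels.item() if np.isscalar(S) or arr.ndim == 0 else labels


def _accuracy(pred_high: np.ndarray, y_high: np.ndarray) -> float:
    return float((pred_high == y_high).mean())


class EnumeratorFusion(BaseEstimator, ClassifierMixin):
    """Grid-searched convex combination of two modality scores.

    fit expects X = (n, 2) columns [S_face, S_EEG] and binary y (high
    state truthy).  Fitted attributes: ``sigma_``, ``accuracy_table_``
    (one accuracy per grid point) and ``training_accuracy_``.
    """

    def __init__(self, grid_step: float = 0.01):
        self.grid_step = grid_step

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnumeratorFusion":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns [S_face, S_EEG]")
        if len(X) != len(y):
            raise ValueError("score/label length mismatch")
        if len(X) < 1:
            raise ValueError("need at least one trial")
        grid = np.round(np.arange(0.0, 1.0 + self.grid_step / 2, self.grid_step), 10)
        s_face, s_eeg = X[:, 0], X[:, 1]
        fused = grid[:, None] * s_face[None, :] + (1.0 - grid[:, None]) * s_eeg[None, :]
        acc = ((fused >= 0.5) == y[None, :]).mean(axis=1)
        best = int(np.argmax(acc))  # argmax takes the first maximum: smallest sigma
        self.grid_ = grid
        self.accuracy_table_ = acc
        self.sigma_ = float(grid[best])
        self.training_accuracy_ = float(acc[best])
        return self

    def fuse(self, s_face: float, s_eeg: float) -> tuple[float, str]:
        """Combined score and its low/high decision for one trial."""
        if not hasattr(self, "sigma_"):
            raise NotFittedError("enumerator is not fitted")
        s = self.sigma_ * s_face + (1.0 - self.sigma_) * s_eeg
        return s, threshold_classify(s)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "sigma_"):
            raise NotFittedError("enumerator is not fitted")
        X = np.asarray(X, dtype=float)
        return self.sigma_ * X[:, 0] + (1.0 - self.sigma_) * X[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean high-state decisions."""
        return self.predict_score(X) >= 0.5


def fit_enumerator(s_face: np.ndarray, s_eeg: np.ndarray, y: np.ndarray,
                   grid_step: float = 0.01) -> EnumeratorFusion:
    return EnumeratorFusion(grid_step=grid_step).fit(np.column_stack([s_face, s_eeg]), y)


def fuse_enumerator(model: EnumeratorFusion, s_face: float, s_eeg: float) -> tuple[float, str]:
    return model.fuse(s_face, s_eeg)


class AdaBoostFusion(BaseEstimator, ClassifierMixin):
    """AdaBoost weighting of fixed, pre-trained sub-classifiers.

    fit expects S = (n_samples, n_classifiers) decisions in {-1, +1}
    (column order given by ``order``, default EEG then face) and y in
    {-1, +1}.  Fitted attributes: ``w_`` (classifier weights),
    ``eps_`` (clamped weighted error rates), ``alpha_history_``
    (sample-weight vectors, one per round plus the initial uniform
    weights; each sums to 1) and ``t_history_`` (0/1 error
    indicators).
    """

    def __init__(self, order: tuple[str, ...] = ("eeg", "face"),
                 eps_clamp: float = 1e-6):
        self.order = order
        self.eps_clamp = eps_clamp

    def fit(self, S: np.ndarray, y: np.ndarray) -> "AdaBoostFusion":
        S = np.asarray(S, dtype=float)
        y = np.asarray(y, dtype=float)
        if S.ndim != 2:
            raise ValueError("S must be (n_samples, n_classifiers)")
        if not np.all(np.isin(S, (-1.0, 1.0))) or not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("decisions and labels must lie in {-1, +1}")
        m, n_clf = S.shape
        if m < 1 or n_clf < 1:
            raise ValueError("need at least one sample and one sub-classifier")
        alpha = np.full(m, 1.0 / m)
        self.alpha_history_ = [alpha.copy()]
        self.eps_ = np.empty(n_clf)
        self.w_ = np.empty(n_clf)
        self.t_history_ = []
        for j in range(n_clf):
            t = (S[:, j] != y).astype(float)
            self.t_history_.append(t)
            eps = float(np.clip((t * alpha).sum(), self.eps_clamp, 1.0 - self.eps_clamp))
            self.eps_[j] = eps
            w = 0.5 * np.log((1.0 - eps) / eps)
            self.w_[j] = w
            alpha = alpha * np.where(t == 1.0, np.exp(w), np.exp(-w))
            alpha /= alpha.sum()
            self.alpha_history_.append(alpha.copy())
        self.n_classifiers_ = n_clf
        return self

    def decision_value(self, s: np.ndarray) -> np.ndarray:
        if not hasattr(self, "w_"):
            raise NotFittedError("AdaBoost fusion is not fitted")
        s = np.asarray(s, dtype=float)
        if s.shape[-1] != self.n_classifiers_:
            raise ValueError(
                f"expected {self.n_classifiers_} sub-classifier decisions, got {s.shape[-1]}")
        return s @ self.w_

    def predict_score(self, s: np.ndarray) -> np.ndarray:
        """S_boost = logistic(sum_j w_j s_j)."""
        return 1.0 / (1.0 + np.exp(-self.decision_value(s)))

    def fuse(self, s: Sequence[float]) -> tuple[float, str]:
        """Fused score and low/high decision for one decision vector."""
        score = float(self.predict_score(np.asarray(s, dtype=float)))
        return score, threshold_classify(score)

    def predict(self, S: np.ndarray) -> np.ndarray:
        """Boolean high-state decisions (equivalent to sign of sum w_j s_j)."""
        return self.predict_score(S) >= 0.5


def fit_adaboost(S: np.ndarray, y: np.ndarray,
                 order: tuple[str, ...] = ("eeg", "face")) -> AdaBoostFusion:
    return AdaBoostFusion(order=order).fit(S, y)


def fuse_adaboost(model: AdaBoostFusion, s: Sequence[float]) -> tuple[float, str]:
    return model.fuse(s)


def to_pm1(high: np.ndarray) -> np.ndarray:
    """Boolean/0-1 high-state indicator -> {-1, +1} decisions."""
    return np.where(np.asarray(high).astype(bool), 1.0, -1.0)


# ---------------------------------------------------------------------------
# Discrete emotion mapping
# ---------------------------------------------------------------------------

EMOTION_NAMES = (
    "pride", "elation", "joy", "satisfaction", "relief", "hope", "interest",
    "surprise", "sadness", "fear", "shame", "guilt", "envy", "disgust",
    "contempt", "anger",
)


@dataclass(frozen=True)
class AnchorTable:
    """16 (valence, arousal) anchor points with emotion names."""

    names: tuple[str, ...]
    coords: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.coords):
            raise ValueError("names and coords must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("emotion names must be unique")


def default_anchor_table(radius: float = 0.4,
                         center: tuple[float, float] = (0.5, 0.5)) -> AnchorTable:
    """The 16 emotions placed uniformly by angle on a circle.

    The coordinates are a configurable convention, not a property of
    the underlying emotion model.
    """
    angles = 2 * np.pi * np.arange(16) / 16
    coords = tuple(
        (float(center[0] + radius * np.cos(a)), float(center[1] + radius * np.sin(a)))
        for a in angles)
    return AnchorTable(EMOTION_NAMES, coords)


def map_discrete(score: EmotionScore | tuple[float, float],
                 anchors: AnchorTable | None = None) -> str:
    """Nearest-anchor (Euclidean) discrete emotion name; ties break to
    the lexicographically smallest name."""
    if anchors is None:
        anchors = default_anchor_table()
    if not anchors.names:
        raise ValueError("anchor table is empty")
    if isinstance(score, EmotionScore):
        point = np.array([score.valence, score.arousal])
    else:
        point = np.asarray(score, dtype=float)
    coords = np.asarray(anchors.coords)
    d2 = ((coords - point) ** 2).sum(axis=1)
    best = d2.min()
    candidates = [anchors.names[i] for i in np.flatnonzero(np.isclose(d2, best, rtol=0, atol=1e-12))]
    return min(candidates)
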