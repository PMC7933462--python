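"""Facial-expression pipeline: preprocessing and the multitask CNN.

Video frames are resampled to 4 Hz, converted to grayscale, cropped to
the detected face region, resized to 48 x 48 and scaled to [0, 1].
The face detector is a pluggable callable ``frame -> (row, col, height,
width) or None``; two built-ins are provided (identity and a
contrast-box detector suited to synthetic faces on a uniform
background).

The multitask CNN maps a 48 x 48 x 1 image to two sigmoid scores
(valence, arousal).  Architecture: zero-padding to 50 x 50, three
valid 3x3 convolutions (32, 32, 64 filters, ReLU), a 64-unit dense
layer (ReLU), dropout 0.5, and a two-branch sigmoid output.  Training
follows a transfer protocol: stage 1 trains all layers (SGD with
momentum); stage 2 freezes the three convolutional layers and
fine-tunes the dense layers with SGD at learning rate 1e-4.  The
combined loss is a weighted sum of the two heads' binary
cross-entropies; per-trial scores are the per-dimension maximum over
the trial's frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

from . import nn
from .records import EmotionScore

Box = tuple[int, int, int, int]  # (row, col, height, width)
FaceDetector = Callable[[np.ndarray], Optional[Box]]


@dataclass
class ImageBatch:
    """n x 48 x 48 grayscale faces in [0, 1] with per-image timestamps."""

    images: np.ndarray
    source_fps: float = 4.0
    timestamps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] < 1:
            raise ValueError("images must be a non-empty n x H x W array")
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.images)) / self.source_fps

    def __len__(self) -> int:
        return len(self.images)


def identity_detector(frame: np.ndarray) -> Box:
    """Treat the whole frame as the face (for pre-cropped inputs)."""
    return (0, 0, frame.shape[0], frame.shape[1])


class ContrastBoxDetector:
    """Bounding box of pixels contrasting with the border background.

    Works for faces rendered on a near-uniform background; returns None
    when no pixel deviates from the border median by more than
    ``threshold``.
    """

    def __init__(self, threshold: float = 0.12, margin: int = 2):
        self.threshold = threshold
        self.margin = margin

    def __call__(self, frame: np.ndarray) -> Optional[Box]:
        border = np.concatenate([frame[0], frame[-1], frame[:, 0], frame[:, -1]])
        bg = np.median(border)
        mask = np.abs(frame - bg) > self.threshold
        if not mask.any():
            return None
        rows, cols = np.nonzero(mask)
        r0 = max(0, rows.min() - self.margin)
        c0 = max(0, cols.min() - self.margin)
        r1 = min(frame.shape[0], rows.max() + 1 + self.margin)
        c1 = min(frame.shape[1], cols.max() + 1 + self.margin)
        return (r0, c0, r1 - r0, c1 - c0)


def _to_gray01(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3] @ np.array([0.299, 0.587, 0.114])
    if frame.dtype == np.uint8:
        frame = frame / 255.0
    return np.clip(frame.astype(float), 0.0, 1.0)


def preprocess_video(frames: Sequence[np.ndarray] | np.ndarray, fps: float,
                     detector: FaceDetector = identity_detector,
                     target_fps: float = 4.0, size: int = 48) -> ImageBatch:
    """Resample to 4 Hz, grayscale, crop detected face, resize to 48 x 48.

    Frames in which the detector finds no face are dropped; an empty
    result raises.
    """
    if fps < target_fps:
        raise ValueError(f"source fps {fps} below the {target_fps} Hz resampling rate")
    n = len(frames)
    picks = np.floor(np.arange(0, n, fps / target_fps)).astype(int)
    out, times = [], []
    for i in picks:
        gray = _to_gray01(frames[i])
        box = detector(gray)
        if box is None:
            continue
        r, c, h, w = box
        crop = gray[r:r + h, c:c + w]
        if crop.shape != (size, size):
            crop = _sk_resize(crop, (size, size), order=1, mode="edge",
                              anti_aliasing=crop.shape[0] > size)
        out.append(np.clip(crop, 0.0, 1.0))
        times.append(i / fps)
    if not out:
        raise ValueError("no face detected in any frame")
    return ImageBatch(np.stack(out), source_fps=target_fps,
                      timestamps=np.asarray(times))


@dataclass
class FaceCNNConfig:
    """Architecture and training hyperparameters of the multitask CNN."""

    conv_filters: tuple[int, int, int] = (32, 32, 64)
    kernel: int = 3
    pad_first_layer: bool = True
    dense_units: int = 64
    dropout: float = 0.5
    loss_weights: tuple[float, float] = (1.0, 1.0)
    finetune_lr: float = 1e-4
    freeze_conv: bool = True
    pretrain_lr: float = 0.01
    pretrain_momentum: float = 0.9
    pretrain_epochs: int = 10
    finetune_epochs: int = 25
    batch_size: int = 32
    input_size: int = 48

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if sum(self.loss_weights) <= 0:
            raise ValueError("at least one loss weight must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def multitask_loss(y_true: np.ndarray, y_pred: np.ndarray,
                   alpha: tuple[float, float] = (1.0, 1.0)) -> float:
    """L = alpha_1 * BCE(valence head) + alpha_2 * BCE(arousal head).

    Each head's binary cross-entropy is summed over the batch;
    predictions are clipped to [1e-7, 1 - 1e-7].  With either weight
    zero the loss reduces exactly to the single-task loss of the other
    head, and L(1,1) = L(1,0) + L(0,1).
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if any(a < 0 for a in alpha):
        raise ValueError("loss weights must be non-negative")
    return sum(float(a) * nn.bce_sum(y_pred[:, i], y_true[:, i])
               for i, a in enumerate(alpha))


class MultitaskFaceCNN(BaseEstimator):
    """Dual-head sigmoid CNN for valence/arousal from 48 x 48 faces.

    ``fit`` performs stage-1 pretraining of all layers; ``finetune``
    performs stage-2 training with the convolutional trunk frozen.
    Fitted attributes: ``conv_net_`` (pad + convolutions + flatten),
    ``head_net_`` (dense + dropout + output), ``history_`` (run log).
    """

    def __init__(self, config: FaceCNNConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    # -- construction -------------------------------------------------
    def _build(self) -> None:
        cfg = self.config or FaceCNNConfig()
        rng = np.random.default_rng(self.random_state)
        f1, f2, f3 = cfg.conv_filters
        k = cfg.kernel
        layers: list[nn.Layer] = []
        if cfg.pad_first_layer:
            layers.append(nn.ZeroPad2D((k - 1) // 2))
        layers += [
            nn.Conv2D(1, f1, k, rng), nn.ReLU(),
            nn.Conv2D(f1, f2, k, rng), nn.ReLU(),
            nn.Conv2D(f2, f3, k, rng), nn.ReLU(),
            nn.Flatten(),
        ]
        self.conv_net_ = nn.Sequential(layers)
        s = cfg.input_size
        if cfg.pad_first_layer:
            s = s  # padding preserves size through the first convolution
        else:
            s -= k - 1
        s -= 2 * (k - 1)  # second and third valid convolutions
        flat = s * s * f3
        rng_head = np.random.default_rng(self.random_state + 1)
        self.head_net_ = nn.Sequential([
            nn.Dense(flat, cfg.dense_units, rng_head), nn.ReLU(),
            nn.Dropout(cfg.dropout, rng_head),
            nn.Dense(cfg.dense_units, 2, rng_head),
        ])
        self._cfg = cfg
        self.history_ = {"stage1": [], "stage2": [], "finetune_lr": cfg.finetune_lr}

    def shape_report(self) -> dict[str, tuple[int, int]]:
        """Spatial sizes of the padded input and first convolution output."""
        if not hasattr(self, "conv_net_"):
            self._build()
        cfg = self._cfg
        x = np.zeros((1, cfg.input_size, cfg.input_size, 1), dtype=np.float32)
        shapes = {}
        for layer in self.conv_net_.layers:
            x = layer.forward(x)
            if isinstance(layer, nn.ZeroPad2D):
                shapes["padded_input"] = x.shape[1:3]
            elif isinstance(layer, nn.Conv2D) and "conv1_output" not in shapes:
                shapes["conv1_output"] = x.shape[1:3]
        return shapes

    # -- training -----------------------------------------------------
    def _prep_images(self, X) -> np.ndarray:
        X = X.images if isinstance(X, ImageBatch) else np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[..., None]
        return X.astype(np.float32)

    def _epoch(self, X, Y, optimizer, rng, conv_frozen: bool,
               conv_cache: np.ndarray | None) -> float:
        cfg = self._cfg
        a1, a2 = cfg.loss_weights
        order = rng.permutation(len(X))
        total = 0.0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            yb = Y[idx]
            if conv_frozen and conv_cache is not None:
                feats = conv_cache[idx]
            else:
                feats = self.conv_net_.forward(X[idx], train=not conv_frozen)
            logits = self.head_net_.forward(feats, train=True)
            p = nn.sigmoid(logits)
            total += multitask_loss(yb, p, cfg.loss_weights)
            # mean-reduced gradient of the weighted BCE w.r.t. logits
            dl = (p - yb) * np.array([a1, a2], dtype=np.float32) / len(idx)
            dfeats = self.head_net_.backward(dl.astype(np.float32))
            if not conv_frozen:
                self.conv_net_.backward(dfeats)
            optimizer.step()
        return total / len(X)

    def fit(self, X, Y, epochs: int | None = None) -> "MultitaskFaceCNN":
        """Stage 1: train all layers (SGD with momentum) on binary targets."""
        X = self._prep_images(X)
        Y = np.asarray(Y, dtype=np.float32)
        if len(X) == 0:
            raise ValueError("training set must be non-empty")
        if not hasattr(self, "conv_net_"):
            self._build()
        cfg = self._cfg
        model = nn.Sequential(self.conv_net_.layers + self.head_net_.layers)
        opt = nn.SGD(model, lr=cfg.pretrain_lr, momentum=cfg.pretrain_momentum)
        rng = np.random.default_rng(self.random_state + 2)
        for _ in range(epochs if epochs is not None else cfg.pretrain_epochs):
            self.history_["stage1"].append(
                self._epoch(X, Y, opt, rng, conv_frozen=False, conv_cache=None))
        return self

    def finetune(self, X, Y, epochs: int | None = None,
                 conv_cache: np.ndarray | None = None) -> "MultitaskFaceCNN":
        """Stage 2: freeze the convolutional trunk, SGD at lr 1e-4 on the heads."""
        X = self._prep_images(X)
        Y = np.asarray(Y, dtype=np.float32)
        if len(X) == 0:
            raise ValueError("fine-tuning set must be non-empty")
        if not hasattr(self, "conv_net_"):
            self._build()
        cfg = self._cfg
        if conv_cache is None and cfg.freeze_conv:
            conv_cache = self.conv_features(X)
        opt = nn.SGD(self.head_net_, lr=cfg.finetune_lr, momentum=cfg.pretrain_momentum)
        rng = np.random.default_rng(self.random_state + 3)
        for _ in range(epochs if epochs is not None else cfg.finetune_epochs):
            self.history_["stage2"].append(
                self._epoch(X, Y, opt, rng, conv_frozen=True, conv_cache=conv_cache))
        return self

    # -- inference ----------------------------------------------------
    def conv_features(self, X, batch: int = 64) -> np.ndarray:
        """Frozen-trunk features, computed in batches."""
        X = self._prep_images(X)
        return np.concatenate([
            self.conv_net_.forward(X[i:i + batch]) for i in range(0, len(X), batch)])

    def predict_scores(self, X) -> np.ndarray:
        """Per-image (n, 2) sigmoid outputs in (0, 1)."""
        feats = self.conv_features(X)
        return nn.sigmoid(self.head_net_.forward(feats))

    def predict_scores_from_features(self, feats: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.head_net_.forward(feats))

    def predict_trial(self, batch) -> EmotionScore:
        """Per-trial score: maximum per dimension over the trial's frames."""
        scores = self.predict_scores(batch)
        if len(scores) == 0:
            raise ValueError("empty batch")
        v, a = scores.max(axis=0)
        return EmotionScore(float(v), float(a))

    def conv_parameters(self) -> list[np.ndarray]:
        return self.conv_net_.all_parameters()


def predict_face(model: MultitaskFaceCNN, batch) -> EmotionScore:
    """Functional wrapper over :meth:`MultitaskFaceCNN.predict_trial`."""
    return model.predict_trial(batch)


def pretrain_then_finetune(model: MultitaskFaceCNN,
                           pretrain_images, pretrain_targets,
                           finetune_images, finetune_targets) -> MultitaskFaceCNN:
    """Two-stage transfer protocol; conv weights are bit-identical across stage 2."""
    model.fit(pretrain_images, pretrain_targets)
    model.finetune(finetune_images, finetune_targets)
    return model
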