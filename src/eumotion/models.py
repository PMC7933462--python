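"""EEG emotion models.

Subject-dependent: a linear SVM per emotion dimension, preceded by
recursive feature elimination (drop the 10% of features with the
smallest absolute weights each round) and an inner 10-fold
cross-validation for both the elimination stopping point and the
regularization constant; decision values are mapped to [0, 1] scores
by Platt-style sigmoid calibration.

Subject-independent: a stacked LSTM (128 then 64 hidden units, 10 time
steps of 85 features, 54-unit ReLU dense layer, dropout 0.5) trained
with mean-squared error on valence/arousal targets scaled to [0, 1].
Inputs are z-scored per feature with training-set statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import nn


def rating_to_unit(r: np.ndarray | float) -> np.ndarray | float:
    """SAM rating 1..9 -> [0, 1] regression target, (r - 1) / 8."""
    return (np.asarray(r, dtype=float) - 1.0) / 8.0


def unit_to_rating(u: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`rating_to_unit`."""
    return 1.0 + 8.0 * np.asarray(u, dtype=float)


# ---------------------------------------------------------------------------
# SVM with recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class RFEResult:
    """Outcome of recursive feature elimination.

    ranking[i] is the round at which feature i was eliminated
    (survivors of the final round get the total round count);
    ``selected`` is the surviving index list of the best
    cross-validated round.
    """

    ranking: np.ndarray
    selected: list[int]
    weights_history: list[np.ndarray] = field(default_factory=list)
    cv_scores: list[float] = field(default_factory=list)
    survivors_history: list[list[int]] = field(default_factory=list)


def _make_svm(C: float, random_state: int):
    # band powers span orders of magnitude (volts^2); standardize first
    return make_pipeline(StandardScaler(),
                         LinearSVC(C=C, max_iter=20000, random_state=random_state))


def _inner_cv_folds(y: np.ndarray, requested: int) -> int:
    counts = np.bincount(y.astype(int))
    smallest = counts[counts > 0].min()
    folds = min(requested, int(smallest))
    if folds < requested:
        warnings.warn(
            f"reducing inner CV from {requested} to {folds} folds "
            f"(smallest class has {smallest} samples)")
    return max(folds, 2)


def _cv_mean(estimator, X: np.ndarray, y: np.ndarray, skf: StratifiedKFold) -> float:
    """Mean CV accuracy; folds that cannot be fitted score 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(estimator, X, y, cv=skf, error_score=0.0)
    return float(np.nan_to_num(scores, nan=0.0).mean())


def svm_rfe(X: np.ndarray, y: np.ndarray, drop_fraction: float = 0.10,
            min_features: int = 7, C: float = 1.0, cv: int = 10,
            patience: int = 2, random_state: int = 0) -> RFEResult:
    """Recursive feature elimination with a linear SVM.

    Each round fits the SVM on the surviving features, records the
    inner-CV accuracy, and removes ``max(1, floor(drop_fraction * k))``
    features with the smallest absolute weights.  Elimination stops at
    ``min_features`` survivors or when the inner-CV accuracy has not
    improved for ``patience`` rounds; the surviving set of the best
    round is selected (ties broken toward fewer features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("RFE requires at least two classes in y")
    n_features = X.shape[1]
    current = list(range(n_features))
    ranking = np.full(n_features, -1, dtype=int)
    result = RFEResult(ranking=ranking, selected=current)
    folds = _inner_cv_folds(y, cv)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    best_score, since_best = -np.inf, 0
    rounds = 0
    while True:
        svm = _make_svm(C, random_state)
        score = _cv_mean(svm, X[:, current], y, skf)
        svm.fit(X[:, current], y)
        w = np.abs(svm[-1].coef_.ravel())
        result.weights_history.append(w.copy())
        result.cv_scores.append(score)
        result.survivors_history.append(list(current))
        if score > best_score:
            best_score, since_best = score, 0
        else:
            since_best += 1
        rounds += 1
        if drop_fraction == 0 or len(current) <= min_features or since_best >= patience:
            break
        n_drop = max(1, int(np.floor(drop_fraction * len(current))))
        n_drop = min(n_drop, len(current) - min_features)
        drop_order = np.argsort(w, kind="stable")[:n_drop]
        for local in sorted(drop_order, reverse=True):
            ranking[current[local]] = rounds - 1
            del current[local]
    # pick the best-scoring round; ties go to the later (smaller) set
    scores = np.asarray(result.cv_scores)
    best_round = int(np.flatnonzero(scores == scores.max())[-1])
    result.selected = result.survivors_history[best_round]
    ranking[np.isin(np.arange(n_features), result.survivors_history[-1])] = rounds
    return result


class SVMEmotionClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM over band-power features with RFE and Platt calibration.

    One binary classifier per emotion dimension; ``predict_score``
    returns a calibrated score in [0, 1] to be thresholded at 0.5.
    """

    def __init__(self, C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
                 folds: int = 10, use_rfe: bool = True, drop_fraction: float = 0.10,
                 min_features: int = 7, oof_repeats: int = 6, random_state: int = 0):
        self.C_grid = C_grid
        self.folds = folds
        self.use_rfe = use_rfe
        self.drop_fraction = drop_fraction
        self.min_features = min_features
        self.oof_repeats = oof_repeats
        self.random_state = random_state

    def _select_and_fit(self, X: np.ndarray, y: np.ndarray, cv: int):
        """RFE selection, C grid search and final SVM fit on (X, y)."""
        if self.use_rfe:
            rfe = svm_rfe(X, y, self.drop_fraction, self.min_features,
                          cv=cv, random_state=self.random_state)
            selected = list(rfe.selected)
        else:
            rfe = None
            selected = list(range(X.shape[1]))
        Xs = X[:, selected]
        folds = _inner_cv_folds(y, cv)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        cv_results = {C: _cv_mean(_make_svm(C, self.random_state), Xs, y, skf)
                      for C in self.C_grid}
        best = max(cv_results.values())
        C = min(c for c, s in cv_results.items() if s == best)
        svm = _make_svm(C, self.random_state).fit(Xs, y)
        return selected, C, svm, cv_results, rfe

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMEmotionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes in y")
        if np.all(np.ptp(X, axis=0) == 0):
            raise ValueError("all features are constant")
        (self.selected_, self.C_, self.svm_,
         self.cv_results_, self.rfe_result_) = self._select_and_fit(X, y, self.folds)
        # Platt calibration on out-of-fold decision values: in-sample
        # decisions of a near-interpolating SVM overstate confidence,
        # which would also mislead any fusion fitted on these scores.
        oof_dec = np.stack([self._out_of_fold_decisions(X, y, r)
                            for r in range(max(1, self.oof_repeats))])
        self.calibrator_ = LogisticRegression(C=1e3).fit(
            oof_dec.reshape(-1, 1), np.tile(y, oof_dec.shape[0]))
        self.oof_train_scores_ = self.calibrator_.predict_proba(
            oof_dec.reshape(-1, 1))[:, 1].reshape(oof_dec.shape)
        self.oof_train_score_ = self.oof_train_scores_[0]
        self.n_features_in_ = X.shape[1]
        return self

    def _out_of_fold_decisions(self, X: np.ndarray, y: np.ndarray,
                               repeat: int = 0) -> np.ndarray:
        """Held-out decision values from one repeat of 5-fold CV.

        Fold models use all features (no per-fold RFE), so no feature
        selection fitted on the full set leaks into the held-out
        decisions; repeats differ only in the fold assignment.
        """
        folds = min(5, _inner_cv_folds(y, self.folds))
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=self.random_state + repeat)
        dec = np.empty(len(y))
        try:
            for tr, te in skf.split(X, y):
                fold_svm = _make_svm(self.C_, self.random_state).fit(X[tr], y[tr])
                dec[te] = fold_svm.decision_function(X[te])
        except ValueError:
            # a fold lost one class entirely; fall back to in-sample decisions
            dec = self.svm_.decision_function(X[:, self.selected_])
        return dec

    def _check(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "svm_"):
            raise NotFittedError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        return X[:, self.selected_]

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Calibrated score in [0, 1] per trial (probability of the high state)."""
        dec = self.svm_.decision_function(self._check(X)).reshape(-1, 1)
        return self.calibrator_.predict_proba(dec)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


def train_eeg_svm(X: np.ndarray, y: np.ndarray, folds: int = 10,
                  random_state: int = 0) -> SVMEmotionClassifier:
    """Functional wrapper: RFE + inner-CV C selection + calibration."""
    return SVMEmotionClassifier(folds=folds, random_state=random_state).fit(X, y)


def predict_eeg_svm(model: SVMEmotionClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_score(X)


# ---------------------------------------------------------------------------
# LSTM sequence regressor
# ---------------------------------------------------------------------------

@dataclass
class LSTMConfig:
    time_steps: int = 10
    input_dim: int = 85
    hidden1: int = 128
    hidden2: int = 64
    dense_units: int = 54
    outputs: int = 2
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if min(self.time_steps, self.input_dim, self.hidden1,
               self.hidden2, self.dense_units, self.outputs) <= 0:
            raise ValueError("all sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class LSTMEmotionRegressor(BaseEstimator, RegressorMixin):
    """Stacked LSTM regressing valence/arousal from 10 x 85 sequences.

    Trained by mean-squared error on targets in [0, 1]; inputs are
    z-scored per feature with training statistics; predictions are
    clipped to [0, 1].  Early stopping monitors a held-back validation
    fraction of the training samples.
    """

    def __init__(self, config: LSTMConfig | None = None, epochs: int = 100,
                 batch_size: int = 32, lr: float = 1e-3, patience: int = 10,
                 val_fraction: float = 0.1, random_state: int = 0):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _build(self, cfg: LSTMConfig) -> nn.Sequential:
        rng = np.random.default_rng(self.random_state)
        return nn.Sequential([
            nn.LSTM(cfg.input_dim, cfg.hidden1, rng),
            nn.Dropout(cfg.dropout, rng),
            nn.LSTM(cfg.hidden1, cfg.hidden2, rng),
            nn.Dropout(cfg.dropout, rng),
            nn.LastStep(),
            nn.Dense(cfg.hidden2, cfg.dense_units, rng), nn.ReLU(),
            nn.Dropout(cfg.dropout, rng),
            nn.Dense(cfg.dense_units, cfg.outputs, rng),
        ])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMEmotionRegressor":
        cfg = self.config or LSTMConfig()
        X = np.asarray(X, dtype=np.float32)
        y = np.atleast_2d(np.asarray(y, dtype=np.float32))
        if X.ndim != 3 or X.shape[1] != cfg.time_steps or X.shape[2] != cfg.input_dim:
            raise ValueError(
                f"X must be (n, {cfg.time_steps}, {cfg.input_dim}), got {X.shape}")
        self.mean_ = X.reshape(-1, cfg.input_dim).mean(axis=0)
        std = X.reshape(-1, cfg.input_dim).std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        Xn = (X - self.mean_) / self.std_
        self.net_ = self._build(cfg)
        opt = nn.Adam(self.net_, lr=self.lr)
        rng = np.random.default_rng(self.random_state + 1)
        n = len(Xn)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        best_val, best_params, since = np.inf, None, 0
        self.history_ = {"train_mse": [], "val_mse": []}
        for _ in range(self.epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for s in range(0, len(order), self.batch_size):
                idx = order[s:s + self.batch_size]
                pred = self.net_.forward(Xn[idx], train=True)
                err = pred - y[idx]
                losses.append(float((err ** 2).mean()))
                self.net_.backward((2.0 * err / err.size).astype(np.float32))
                opt.step()
            self.history_["train_mse"].append(float(np.mean(losses)))
            if n_val:
                val_pred = self.net_.forward(Xn[val_idx])
                val_mse = float(((val_pred - y[val_idx]) ** 2).mean())
                self.history_["val_mse"].append(val_mse)
                if val_mse < best_val - 1e-6:
                    best_val, since = val_mse, 0
                    best_params = [p.copy() for p in self.net_.all_parameters()]
                else:
                    since += 1
                    if since >= self.patience:
                        break
        if best_params is not None:
            for p, saved in zip(self.net_.all_parameters(), best_params):
                p[...] = saved
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-sample (n, 2) scores clipped to [0, 1]."""
        if not hasattr(self, "net_"):
            raise NotFittedError("regressor is not fitted (no normalization statistics)")
        cfg = self.config or LSTMConfig()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != cfg.time_steps or X.shape[2] != cfg.input_dim:
            raise ValueError(
                f"X must be (n, {cfg.time_steps}, {cfg.input_dim}), got {X.shape}")
        Xn = (X - self.mean_) / self.std_
        out = np.concatenate([
            self.net_.forward(Xn[i:i + 256]) for i in range(0, len(Xn), 256)])
        return np.clip(out, 0.0, 1.0)

    def predict_trials(self, sequences: list[np.ndarray]) -> np.ndarray:
        """Per-trial (n_trials, 2) scores: mean over each trial's samples."""
        return np.stack([self.predict(seq).mean(axis=0) for seq in sequences])


def build_train_lstm(X: np.ndarray, y: np.ndarray, config: LSTMConfig | None = None,
                     seed: int = 0, **kwargs) -> LSTMEmotionRegressor:
    return LSTMEmotionRegressor(config=config, random_state=seed, **kwargs).fit(X, y)


def predict_lstm(model: LSTMEmotionRegressor, sequences: list[np.ndarray]) -> np.ndarray:
    return model.predict_trials(sequences)
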