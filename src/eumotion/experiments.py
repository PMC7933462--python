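"""Evaluation protocols and metrics.

Two protocols mirror how subject-dependent and subject-independent
emotion models are evaluated:

* **Subject-dependent** — per subject, trials are split 20/20 into
  train/test (stratified by binary label where possible).  A shared
  face CNN is pretrained once on synthetic faces, its dense head is
  fine-tuned per subject; an SVM (with RFE) is trained per subject and
  dimension on the 70-d band-power vectors; both fusion rules are
  fitted on the training scores; all methods are evaluated on the test
  trials.
* **Subject-independent** — the LSTM is trained on every sequence
  sample from the training subjects (normalization statistics from the
  training set only) and evaluated on held-out subjects' trials.

Metrics: accuracy %, recall of the high class %, and RMSE on the 1-9
rating scale for regression outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .face import FaceCNNConfig, MultitaskFaceCNN
from .features import compute_band_psd, sequence_features, subject_dependent_features
from .fusion import AdaBoostFusion, EnumeratorFusion, to_pm1
from .models import LSTMEmotionRegressor, SVMEmotionClassifier, rating_to_unit, unit_to_rating
from .montage import OFFLINE_MONTAGE, Montage
from .records import DIMENSIONS, TrialRecord
from .store import DatasetStore
from .synth import GeneratorConfig, generate_faces, generate_labels

METHODS_DEPENDENT = ("face", "eeg_svm", "enum_fusion", "adaboost_fusion")


def compute_metrics(pred_high: np.ndarray, true_high: np.ndarray,
                    pred_ratings: Optional[np.ndarray] = None,
                    true_ratings: Optional[np.ndarray] = None) -> dict:
    """Accuracy %, recall of the high class %, optional RMSE on 1-9.

    Recall is reported as None (missing) when there are no actually
    high trials, never as 0.
    """
    pred_high = np.asarray(pred_high).astype(bool)
    true_high = np.asarray(true_high).astype(bool)
    if len(pred_high) != len(true_high):
        raise ValueError("prediction/label length mismatch")
    acc = 100.0 * float((pred_high == true_high).mean())
    n_high = int(true_high.sum())
    recall = 100.0 * float((pred_high & true_high).sum() / n_high) if n_high else None
    rmse = None
    if pred_ratings is not None and true_ratings is not None:
        rmse = float(np.sqrt(np.mean((np.asarray(pred_ratings, dtype=float)
                                      - np.asarray(true_ratings, dtype=float)) ** 2)))
    return {"accuracy": acc, "recall": recall, "rmse": rmse}


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per (dimension, method) over subjects."""
    return (table.groupby(["dimension", "method"])[["accuracy", "recall", "rmse"]]
            .agg(["mean", "std"]).reset_index())


def _as_dataset(data) -> dict[str, list[TrialRecord]]:
    if isinstance(data, DatasetStore):
        out: dict[str, list[TrialRecord]] = {}
        for sid, tid in data.index():
            out.setdefault(sid, []).append(data.load_trial(sid, tid))
        return out
    return data


def _stratified_split(ratings, n_train: int, n_test: int, rng: np.random.Generator,
                      max_resample: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test trial split with both classes present in training.

    Resamples the permutation up to ``max_resample`` times until the
    training half contains both binary classes in both dimensions.
    """
    n = len(ratings)
    if n < n_train + n_test:
        raise ValueError(f"subject has {n} trials, needs {n_train + n_test}")
    for _ in range(max_resample):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:n_train + n_test]
        ok = all(
            len({ratings[i].binary(dim) for i in tr}) == 2
            for dim in DIMENSIONS)
        if ok:
            return tr, te
    raise ValueError("could not find a class-complete training split")


def _pretrain_cnn(seed: int, n_images: int, epochs: int,
                  effect_config: GeneratorConfig) -> MultitaskFaceCNN:
    """Stage-1 pretraining on a synthetic face corpus."""
    rng = np.random.default_rng([seed % (2 ** 31), 977])
    cfg = GeneratorConfig(
        n_subjects=1, trials_per_subject=max(2, n_images),
        frames_per_trial=1, seed=seed % (2 ** 31),
        face_effect=effect_config.face_effect, noise_sd=effect_config.noise_sd)
    ratings = generate_labels(cfg, rng)[:n_images]
    images = np.concatenate([generate_faces(r, cfg, rng) for r in ratings])
    targets = np.array([[r.binary("valence"), r.binary("arousal")] for r in ratings],
                       dtype=float)
    cnn = MultitaskFaceCNN(config=FaceCNNConfig(), random_state=seed % (2 ** 31))
    cnn.fit(images, targets, epochs=epochs)
    return cnn


@dataclass
class SubjectDependentResult:
    metrics: pd.DataFrame
    scores: pd.DataFrame = field(repr=False, default=None)
    models: dict = field(repr=False, default_factory=dict)


def run_subject_dependent(data, n_train: int = 20, n_test: int = 20,
                          seed: int = 0, montage: Montage = OFFLINE_MONTAGE,
                          methods: Iterable[str] = METHODS_DEPENDENT,
                          psd_method: str = "fft",
                          pretrain_images: int = 240, pretrain_epochs: int = 12,
                          finetune_epochs: int = 25,
                          effect_config: GeneratorConfig | None = None,
                          cnn: MultitaskFaceCNN | None = None) -> SubjectDependentResult:
    """Per-subject 20/20 protocol over all four subject-dependent methods.

    One model per subject: the shared pretrained CNN's dense head is
    re-initialized from the pretrained state and fine-tuned on each
    subject's training trials; SVM, enumerator and AdaBoost fusions are
    fitted per subject and dimension.
    """
    dataset = _as_dataset(data)
    methods = tuple(methods)
    rng = np.random.default_rng(seed % (2 ** 31))
    if cnn is None:
        cnn = _pretrain_cnn(seed, pretrain_images, pretrain_epochs,
                            effect_config or GeneratorConfig())
    pretrained_head = [p.copy() for p in cnn.head_net_.all_parameters()]

    rows, score_rows = [], []
    models: dict = {}
    for sid in sorted(dataset):
        trials = dataset[sid]
        ratings = [t.rating for t in trials]
        tr_idx, te_idx = _stratified_split(ratings, n_train, n_test, rng)

        psd = {i: compute_band_psd(trials[i].eeg.pick(list(montage.channels)),
                                   method=psd_method)
               for i in np.concatenate([tr_idx, te_idx])}
        X = {i: subject_dependent_features(psd[i], montage) for i in psd}

        frames = {i: trials[i].face_frames for i in psd}
        conv_feats = {i: cnn.conv_features(frames[i]) for i in psd
                      if frames[i] is not None}

        def finetune_head(idx: np.ndarray, epochs: int) -> None:
            """Fine-tune the dense head on the trials in ``idx``, starting
            from the shared pretrained state."""
            for p, saved in zip(cnn.head_net_.all_parameters(), pretrained_head):
                p[...] = saved
            feats = np.concatenate([conv_feats[i] for i in idx])
            targets = np.concatenate([
                np.repeat([[ratings[i].binary("valence"), ratings[i].binary("arousal")]],
                          len(conv_feats[i]), axis=0)
                for i in idx]).astype(float)
            cnn.finetune(np.zeros((len(feats), 1, 1)), targets,
                         epochs=epochs, conv_cache=feats)

        # out-of-fold face scores for fusion fitting (stacking practice);
        # several repeats with different fold assignments reduce the
        # chance that a modality looks spuriously perfect on 20 trials;
        # fold models use 3 folds and a shortened fine-tune budget
        oof_repeats = 3
        fold_epochs = max(4, finetune_epochs // 4)
        oof_face: list[dict[int, np.ndarray]] = []
        for r in range(oof_repeats):
            per_trial: dict[int, np.ndarray] = {}
            kf = KFold(n_splits=min(3, len(tr_idx)), shuffle=True,
                       random_state=seed % (2 ** 31) + r)
            for fold_tr, fold_te in kf.split(tr_idx):
                finetune_head(tr_idx[fold_tr], fold_epochs)
                for i in tr_idx[fold_te]:
                    per_trial[i] = cnn.predict_scores_from_features(
                        conv_feats[i]).max(axis=0)
            oof_face.append(per_trial)

        # deployed per-subject model: head fine-tuned on all training trials
        finetune_head(tr_idx, finetune_epochs)
        s_face = {i: cnn.predict_scores_from_features(conv_feats[i]).max(axis=0)
                  for i in conv_feats}

        for d, dim in enumerate(DIMENSIONS):
            y_tr = np.array([ratings[i].binary(dim) for i in tr_idx])
            y_te = np.array([ratings[i].binary(dim) for i in te_idx])
            svm = SVMEmotionClassifier(random_state=seed % (2 ** 31)).fit(
                np.stack([X[i] for i in tr_idx]), y_tr)
            s_eeg_te = svm.predict_score(np.stack([X[i] for i in te_idx]))
            s_face_te = np.array([s_face[i][d] for i in te_idx])
            # fusion is fitted on the binarized out-of-fold training
            # decisions of both modalities, all repeats stacked:
            # in-sample scores of near-interpolating models tie the
            # enumerator's training accuracy across the grid, and
            # continuous score values carry calibration-slope artifacts
            # that do not generalize; the fitted weights are applied to
            # continuous test scores
            # EEG uses more repeats than the (costlier) face OOF; face
            # repeats are cycled so the stacked columns align
            eeg_reps = svm.oof_train_scores_.shape[0]
            r_eeg_tr = (svm.oof_train_scores_ >= 0.5).astype(float).ravel()
            r_face_tr = np.concatenate([
                np.array([oof_face[r % oof_repeats][i][d] >= 0.5
                          for i in tr_idx], dtype=float)
                for r in range(eeg_reps)])
            y_stacked = np.tile(y_tr, eeg_reps)

            enum = EnumeratorFusion().fit(
                np.column_stack([r_face_tr, r_eeg_tr]), y_stacked)
            boost = AdaBoostFusion().fit(
                np.column_stack([to_pm1(r_eeg_tr), to_pm1(r_face_tr)]),
                to_pm1(y_stacked))

            preds = {
                "face": s_face_te >= 0.5,
                "eeg_svm": s_eeg_te >= 0.5,
                "enum_fusion": enum.predict(np.column_stack([s_face_te, s_eeg_te])),
                "adaboost_fusion": boost.predict(
                    np.column_stack([to_pm1(s_eeg_te >= 0.5), to_pm1(s_face_te >= 0.5)])),
            }
            models[(sid, dim)] = {"svm": svm, "enum": enum, "adaboost": boost}
            for method in methods:
                m = compute_metrics(preds[method], y_te)
                rows.append({"subject": sid, "dimension": dim, "method": method, **m})
            for i, sf, se in zip(te_idx, s_face_te, s_eeg_te):
                score_rows.append({
                    "subject": sid, "trial_id": trials[i].trial_id, "dimension": dim,
                    "s_face": sf, "s_eeg": se, "y": bool(ratings[i].binary(dim))})

    return SubjectDependentResult(
        metrics=pd.DataFrame(rows), scores=pd.DataFrame(score_rows), models=models)


@dataclass
class SubjectIndependentResult:
    metrics: pd.DataFrame
    model: LSTMEmotionRegressor = field(repr=False, default=None)
    provenance: dict = field(repr=False, default_factory=dict)


def run_subject_independent(data, train_subjects: list[str], test_subjects: list[str],
                            seed: int = 0, montage: Montage = OFFLINE_MONTAGE,
                            psd_method: str = "fft", epochs: int = 25,
                            ) -> SubjectIndependentResult:
    """Cross-subject LSTM protocol.

    Training uses only the training subjects' sequence samples (their
    statistics drive the normalization); per-trial test scores are the
    mean over the trial's 10-s samples.
    """
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise ValueError(f"train/test subject sets overlap: {sorted(overlap)}")
    dataset = _as_dataset(data)

    def trial_seqs(rec: TrialRecord) -> np.ndarray:
        bpt = compute_band_psd(rec.eeg.pick(list(montage.channels)), method=psd_method)
        return sequence_features(bpt, montage)

    X_tr, y_tr, train_provenance = [], [], []
    for sid in train_subjects:
        for rec in dataset[sid]:
            seqs = trial_seqs(rec)
            X_tr.append(seqs)
            target = rating_to_unit(np.array(rec.rating.as_tuple(), dtype=float))
            y_tr.append(np.tile(target, (len(seqs), 1)))
            train_provenance += [sid] * len(seqs)
    X_tr = np.concatenate(X_tr)
    y_tr = np.concatenate(y_tr)

    model = LSTMEmotionRegressor(epochs=epochs, random_state=seed % (2 ** 31))
    model.fit(X_tr, y_tr)

    rows = []
    for sid in test_subjects:
        recs = dataset[sid]
        scores = model.predict_trials([trial_seqs(r) for r in recs])
        for d, dim in enumerate(DIMENSIONS):
            true_high = np.array([r.rating.binary(dim) for r in recs])
            true_ratings = np.array([getattr(r.rating, dim) for r in recs], dtype=float)
            pred_ratings = unit_to_rating(scores[:, d])
            m = compute_metrics(scores[:, d] >= 0.5, true_high,
                                pred_ratings, true_ratings)
            rows.append({"subject": sid, "dimension": dim, "method": "lstm", **m})

    provenance = {"train_subjects": sorted(set(train_provenance)),
                  "test_subjects": list(test_subjects),
                  "n_train_samples": len(X_tr)}
    return SubjectIndependentResult(pd.DataFrame(rows), model, provenance)
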