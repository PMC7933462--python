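"""Face preprocessing and multitask CNN contracts."""

import numpy as np
import pytest

from eumotion import (ContrastBoxDetector, FaceCNNConfig, ImageBatch,
                      MultitaskFaceCNN, SAMRating, identity_detector,
                      multitask_loss, preprocess_video)
from eumotion.synth import GeneratorConfig, generate_faces


class TestPreprocess:
    def test_resampling_to_4hz(self):
        rng = np.random.default_rng(0)
        frames = rng.random((400, 48, 48))  # 20 s at 20 fps
        batch = preprocess_video(frames, fps=20.0, detector=identity_detector)
        assert batch.images.shape == (80, 48, 48)

    def test_identity_passthrough_is_pixel_exact(self):
        rng = np.random.default_rng(1)
        frames = rng.random((8, 48, 48))
        batch = preprocess_video(frames, fps=4.0, detector=identity_detector)
        assert np.array_equal(batch.images, frames)

    def test_known_box_crop_matches_slicing_oracle(self):
        rng = np.random.default_rng(2)
        frame = rng.random((96, 96))
        box = (10, 20, 48, 48)

        def fixed_detector(_):
            return box

        batch = preprocess_video(frame[None], fps=4.0, detector=fixed_detector)
        r, c, h, w = box
        assert np.array_equal(batch.images[0], frame[r:r + h, c:c + w])

    def test_no_face_anywhere_raises(self):
        def blind(_):
            return None

        with pytest.raises(ValueError, match="no face"):
            preprocess_video(np.zeros((4, 48, 48)), fps=4.0, detector=blind)

    def test_contrast_detector_finds_synthetic_face(self):
        rng = np.random.default_rng(3)
        cfg = GeneratorConfig(frames_per_trial=1, noise_sd=0.5, seed=3)
        face48 = generate_faces(SAMRating(8, 8), cfg, rng)[0]
        frame = np.full((120, 160), float(np.median(face48[0])))
        frame[30:78, 50:98] = face48
        box = ContrastBoxDetector()(frame)
        assert box is not None
        r, c, h, w = box
        # detected box covers the head ellipse (rows ~34-74, cols ~58-90
        # in frame coordinates) embedded at (30, 50)
        assert r <= 35 and c <= 59 and r + h >= 73 and c + w >= 89

    def test_low_fps_rejected(self):
        with pytest.raises(ValueError, match="fps"):
            preprocess_video(np.zeros((4, 48, 48)), fps=2.0)

    def test_image_batch_validates_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ImageBatch(np.full((1, 48, 48), 2.0))


class TestMultitaskLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert multitask_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_zero_alpha_reduces_to_single_task(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=(6, 2)).astype(float)
        p = rng.uniform(0.05, 0.95, size=(6, 2))
        only_valence = multitask_loss(y, p, alpha=(1.0, 0.0))
        expected = -np.sum(y[:, 0] * np.log(p[:, 0]) + (1 - y[:, 0]) * np.log(1 - p[:, 0]))
        assert only_valence == pytest.approx(expected, rel=1e-10)

    def test_additivity_is_exact(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=(5, 2)).astype(float)
        p = rng.uniform(0.05, 0.95, size=(5, 2))
        assert multitask_loss(y, p, (1, 1)) == (
            multitask_loss(y, p, (1, 0)) + multitask_loss(y, p, (0, 1)))

    def test_half_probability_closed_form(self):
        # one sample, y=1, p=0.5, valence-only: -ln(0.5)
        loss = multitask_loss(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]), (1, 0))
        assert loss == pytest.approx(0.6931, abs=1e-4)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            multitask_loss(np.array([[1.0, 1.0]]), np.array([[0.5, 0.5]]), (-1, 1))


class TestCNNArchitecture:
    def test_shape_contract(self):
        shapes = MultitaskFaceCNN().shape_report()
        assert shapes["padded_input"] == (50, 50)
        assert shapes["conv1_output"] == (48, 48)

    def test_outputs_in_open_unit_interval(self):
        cnn = MultitaskFaceCNN(random_state=0)
        cnn._build()
        rng = np.random.default_rng(0)
        scores = cnn.predict_scores(rng.random((3, 48, 48)))
        assert scores.shape == (3, 2)
        assert np.all(scores > 0) and np.all(scores < 1)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            FaceCNNConfig(loss_weights=(-1.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            FaceCNNConfig(loss_weights=(0.0, 0.0))


@pytest.fixture(scope="module")
def trained_cnn_and_faces():
    """A CNN taken through both transfer stages on synthetic faces.

    Returns the model, the face set and its targets, plus a snapshot
    of the convolutional weights taken between stage 1 and stage 2.
    """
    rng = np.random.default_rng(9)
    cfg = GeneratorConfig(frames_per_trial=1, seed=9)
    images, targets = [], []
    for _ in range(48):
        v, a = int(rng.integers(1, 10)), int(rng.integers(1, 10))
        images.append(generate_faces(SAMRating(v, a), cfg, rng)[0])
        targets.append([v >= 5, a >= 5])
    images = np.stack(images)
    targets = np.array(targets, dtype=float)
    cnn = MultitaskFaceCNN(
        config=FaceCNNConfig(pretrain_epochs=3, finetune_epochs=8), random_state=9)
    cnn.fit(images, targets)
    conv_after_stage1 = [p.copy() for p in cnn.conv_parameters()]
    head_after_stage1 = [p.copy() for p in cnn.head_net_.all_parameters()]
    loss_before_ft = multitask_loss(targets, cnn.predict_scores(images))
    cnn.finetune(images, targets)
    loss_after_ft = multitask_loss(targets, cnn.predict_scores(images))
    return {"cnn": cnn, "images": images, "targets": targets,
            "conv_after_stage1": conv_after_stage1,
            "head_after_stage1": head_after_stage1,
            "loss_before_ft": loss_before_ft, "loss_after_ft": loss_after_ft}


class TestTransferProtocol:
    def test_conv_weights_frozen_through_finetune(self, trained_cnn_and_faces):
        cnn = trained_cnn_and_faces["cnn"]
        for b, a in zip(trained_cnn_and_faces["conv_after_stage1"],
                        cnn.conv_parameters()):
            assert np.array_equal(b, a)  # bit-identical
        assert any(not np.array_equal(b, a) for b, a in
                   zip(trained_cnn_and_faces["head_after_stage1"],
                       cnn.head_net_.all_parameters()))

    def test_both_stages_reduce_training_loss(self, trained_cnn_and_faces):
        cnn = trained_cnn_and_faces["cnn"]
        stage1 = cnn.history_["stage1"]
        assert stage1[-1] < stage1[0]
        # deterministic (dropout-free) loss over the fine-tuning set
        assert (trained_cnn_and_faces["loss_after_ft"]
                <= trained_cnn_and_faces["loss_before_ft"])

    def test_finetune_lr_recorded_in_run_log(self, trained_cnn_and_faces):
        cnn = trained_cnn_and_faces["cnn"]
        assert cnn.history_["finetune_lr"] == pytest.approx(1e-4)


class TestTrialAggregation:
    def test_single_frame_trial_score_equals_frame_score(self, trained_cnn_and_faces):
        cnn, images = trained_cnn_and_faces["cnn"], trained_cnn_and_faces["images"]
        per_frame = cnn.predict_scores(images[:1])
        trial = cnn.predict_trial(images[:1])
        assert trial.valence == pytest.approx(per_frame[0, 0])
        assert trial.arousal == pytest.approx(per_frame[0, 1])

    def test_trial_score_is_max_over_frames(self, trained_cnn_and_faces):
        cnn, images = trained_cnn_and_faces["cnn"], trained_cnn_and_faces["images"]
        per_frame = cnn.predict_scores(images[:5])
        trial = cnn.predict_trial(images[:5])
        assert trial.valence == pytest.approx(per_frame[:, 0].max())
        assert trial.arousal == pytest.approx(per_frame[:, 1].max())

    def test_duplicated_frames_leave_score_unchanged(self, trained_cnn_and_faces):
        cnn, images = trained_cnn_and_faces["cnn"], trained_cnn_and_faces["images"]
        once = cnn.predict_trial(images[:3])
        thrice = cnn.predict_trial(np.tile(images[:3], (3, 1, 1)))
        assert once.valence == pytest.approx(thrice.valence)
        assert once.arousal == pytest.approx(thrice.arousal)
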