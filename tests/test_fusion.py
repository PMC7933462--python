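"""Decision-level fusion: threshold, enumerator, AdaBoost, discrete map."""

import numpy as np
import pytest

from eumotion import (AdaBoostFusion, AnchorTable, EnumeratorFusion,
                      EmotionScore, default_anchor_table, map_discrete,
                      threshold_classify, to_pm1)
from sklearn.exceptions import NotFittedError


class TestThreshold:
    @pytest.mark.parametrize("score,expected", [
        (0.5, "high"),   # boundary is inclusive
        (0.49, "low"),
        (1.0, "high"),
        (0.0, "low"),
    ])
    def test_boundary_convention(self, score, expected):
        assert threshold_classify(score) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            threshold_classify(float("nan"))

    def test_vectorized(self):
        out = threshold_classify(np.array([0.2, 0.5, 0.8]))
        assert list(out) == ["low", "high", "high"]


def _enumerator_oracle(s_face, s_eeg, y, step=0.01):
    """Independent exhaustive grid scan with smallest-sigma tie-break."""
    best_sigma, best_acc = None, -1.0
    for k in range(101):
        sigma = k * step
        pred = (sigma * s_face + (1 - sigma) * s_eeg) >= 0.5
        acc = (pred == y).mean()
        if acc > best_acc:
            best_sigma, best_acc = sigma, acc
    return best_sigma, best_acc


class TestEnumerator:
    def test_matches_exhaustive_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            s_face = rng.random(n)
            s_eeg = rng.random(n)
            y = rng.random(n) < 0.5
            model = EnumeratorFusion().fit(np.column_stack([s_face, s_eeg]), y)
            sigma, acc = _enumerator_oracle(s_face, s_eeg, y)
            assert model.sigma_ == pytest.approx(sigma, abs=1e-12)
            assert model.training_accuracy_ == pytest.approx(acc, abs=1e-12)

    def test_dominates_single_modality_endpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            X = rng.random((n, 2))
            y = rng.random(n) < 0.5
            model = EnumeratorFusion().fit(X, y)
            face_only = ((X[:, 0] >= 0.5) == y).mean()
            eeg_only = ((X[:, 1] >= 0.5) == y).mean()
            assert model.training_accuracy_ >= max(face_only, eeg_only)

    def test_perfect_face_anti_predictive_eeg(self):
        # 10-trial toy: face is exactly right, EEG exactly wrong
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0], dtype=bool)
        s_face = np.where(y, 0.9, 0.1)
        s_eeg = np.where(y, 0.1, 0.9)
        model = EnumeratorFusion().fit(np.column_stack([s_face, s_eeg]), y)
        assert model.training_accuracy_ == 1.0
        assert model.sigma_ == pytest.approx(
            _enumerator_oracle(s_face, s_eeg, y)[0])

    def test_identical_scores_tie_break_to_zero(self):
        s = np.array([0.6, 0.3, 0.8])
        y = np.array([1, 0, 1], dtype=bool)
        model = EnumeratorFusion().fit(np.column_stack([s, s]), y)
        assert model.sigma_ == 0.0

    def test_endpoint_identities(self):
        y = np.array([1, 0], dtype=bool)
        X = np.array([[0.9, 0.2], [0.1, 0.8]])
        model = EnumeratorFusion().fit(X, y)
        model.sigma_ = 1.0
        assert model.fuse(0.77, 0.13)[0] == pytest.approx(0.77)
        model.sigma_ = 0.0
        assert model.fuse(0.77, 0.13)[0] == pytest.approx(0.13)

    def test_hand_arithmetic(self):
        model = EnumeratorFusion()
        model.sigma_ = 0.5
        s, decision = model.fuse(0.6, 0.2)
        assert s == pytest.approx(0.4)
        assert decision == "low"

    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            EnumeratorFusion().fuse(0.5, 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            EnumeratorFusion().fit(np.zeros((3, 2)), np.zeros(4))


def _adaboost_oracle(S, y, clamp=1e-6):
    """Independent step-by-step trace of the sample-reweighting recursion."""
    m, n = S.shape
    alpha = np.full(m, 1.0 / m)
    trace = {"alpha": [alpha.copy()], "eps": [], "w": [], "t": []}
    for j in range(n):
        t = (S[:, j] != y).astype(float)
        eps = min(max(float((t * alpha).sum()), clamp), 1 - clamp)
        w = 0.5 * np.log((1 - eps) / eps)
        new_alpha = np.where(t == 1, alpha * np.exp(w), alpha * np.exp(-w))
        alpha = new_alpha / new_alpha.sum()
        trace["eps"].append(eps)
        trace["w"].append(w)
        trace["t"].append(t)
        trace["alpha"].append(alpha.copy())
    return trace


class TestAdaBoost:
    def test_six_trial_toy_trace_matches_hand_computation(self):
        # EEG always correct; face wrong on trials 1 and 4 (0-indexed 0, 3)
        y = np.array([1, 1, 1, -1, -1, -1], dtype=float)
        eeg = y.copy()
        face = y.copy()
        face[[0, 3]] *= -1
        S = np.column_stack([eeg, face])
        model = AdaBoostFusion().fit(S, y)
        trace = _adaboost_oracle(S, y)
        np.testing.assert_allclose(model.eps_, trace["eps"], atol=1e-12)
        np.testing.assert_allclose(model.w_, trace["w"], atol=1e-12)
        for got, want in zip(model.alpha_history_, trace["alpha"]):
            np.testing.assert_allclose(got, want, atol=1e-12)
        for got, want in zip(model.t_history_, trace["t"]):
            np.testing.assert_allclose(got, want, atol=1e-12)
        # first classifier is perfect: eps clamps, weight is large positive
        assert model.eps_[0] == pytest.approx(1e-6)
        assert model.w_[0] > 0

    def test_sample_weights_sum_to_one_after_every_round(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(2, 40))
            S = to_pm1(rng.random((m, 3)) < 0.5)
            y = to_pm1(rng.random(m) < 0.5)
            model = AdaBoostFusion().fit(S, y)
            for alpha in model.alpha_history_:
                assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_error_gives_zero_weight(self):
        y = np.array([1.0, -1.0])
        S = np.array([[1.0], [1.0]])  # right on one, wrong on the other
        model = AdaBoostFusion().fit(S, y)
        assert model.w_[0] == pytest.approx(0.0)

    def test_weight_sign_tracks_error_rate_and_flips(self):
        rng = np.random.default_rng(1)
        y = to_pm1(rng.random(20) < 0.5)
        good = y * to_pm1(rng.random(20) < 0.9)  # mostly correct
        S = np.column_stack([good])
        model = AdaBoostFusion().fit(S, y)
        flipped = AdaBoostFusion().fit(-S, y)
        assert (model.w_[0] > 0) == (model.eps_[0] < 0.5)
        assert flipped.w_[0] == pytest.approx(-model.w_[0], rel=1e-9)

    def test_logistic_form_closed_values(self):
        model = AdaBoostFusion()
        model.w_ = np.array([1.0, 0.2])
        model.n_classifiers_ = 2
        score, decision = model.fuse([-1.0, 1.0])
        assert score == pytest.approx(1 / (1 + np.exp(0.8)), abs=1e-12)
        assert decision == "low"
        # equal weights, opposite votes -> exactly 0.5 -> boundary high
        model.w_ = np.array([0.7, 0.7])
        score, decision = model.fuse([1.0, -1.0])
        assert score == pytest.approx(0.5, abs=1e-12)
        assert decision == "high"

    def test_decision_equals_sign_of_weighted_vote(self):
        rng = np.random.default_rng(2)
        y = to_pm1(rng.random(30) < 0.5)
        S = np.column_stack([y * to_pm1(rng.random(30) < 0.8),
                             y * to_pm1(rng.random(30) < 0.7)])
        model = AdaBoostFusion().fit(S, y)
        votes = S @ model.w_
        np.testing.assert_array_equal(model.predict(S), votes >= 0)

    def test_all_positive_votes_with_positive_weights(self):
        model = AdaBoostFusion()
        model.w_ = np.array([0.5, 1.5])
        model.n_classifiers_ = 2
        assert model.fuse([1.0, 1.0])[0] > 0.5

    def test_invalid_decisions_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            AdaBoostFusion().fit(np.array([[0.5], [1.0]]), np.array([1.0, -1.0]))

    def test_vector_length_mismatch_rejected(self):
        model = AdaBoostFusion().fit(np.array([[1.0, -1.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="decisions"):
            model.fuse([1.0])


class TestDiscreteMap:
    def test_anchor_point_maps_to_its_name(self):
        table = default_anchor_table()
        for name, (v, a) in zip(table.names, table.coords):
            assert map_discrete((v, a), table) == name

    def test_dense_grid_covers_all_16_emotions(self):
        table = default_anchor_table()
        seen = {map_discrete((v, a), table)
                for v in np.linspace(0, 1, 41) for a in np.linspace(0, 1, 41)}
        assert len(seen) == 16

    def test_matches_brute_force_nearest_scan(self):
        rng = np.random.default_rng(0)
        table = default_anchor_table()
        coords = np.asarray(table.coords)
        for _ in range(100):
            p = rng.random(2)
            d = np.sqrt(((coords - p) ** 2).sum(axis=1))
            assert map_discrete(tuple(p), table) == table.names[int(np.argmin(d))]

    def test_tie_breaks_lexicographically(self):
        table = AnchorTable(("joy", "anger"), ((0.4, 0.5), (0.6, 0.5)))
        assert map_discrete((0.5, 0.5), table) == "anger"

    def test_accepts_emotion_score(self):
        assert isinstance(map_discrete(EmotionScore(0.9, 0.5)), str)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            AnchorTable(("joy", "joy"), ((0, 0), (1, 1)))
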