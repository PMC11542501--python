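"""Loss functions: closed forms, oracles, identities and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octseg.errors import ConfigError, LabelError
from octseg.losses import (
    compute_class_weights,
    cps_labeled_loss,
    cps_total_loss,
    cps_unlabeled_loss,
    cps_unlabeled_loss_grads,
    cross_entropy,
    dice_loss,
    ce_dice_loss,
    ema_update,
    mt_consistency_loss,
    weighted_cross_entropy,
)
from octseg.segmenters import softmax

BIG = 50.0  # logit margin that drives softmax to ~one-hot


def one_hot_scores(target: np.ndarray, n_classes: int, margin: float = BIG):
    scores = np.zeros(target.shape + (n_classes,))
    np.put_along_axis(scores, target[..., None], margin, axis=-1)
    return scores


class TestCrossEntropy:
    def test_one_hot_correct_is_zero(self, rng):
        y = rng.integers(0, 13, (6, 6))
        assert weighted_cross_entropy(one_hot_scores(y, 13), y) < 1e-6

    def test_uniform_scores_give_log_c(self):
        y = np.zeros((4, 4), dtype=int)
        loss = weighted_cross_entropy(np.zeros((4, 4, 13)), y)
        assert loss == pytest.approx(np.log(13), abs=1e-6)

    def test_two_pixel_weighted_hand_computation(self):
        # pixel 1: true class 0 with probability 0.7 (weight 1)
        # pixel 2: true class 1 with probability 0.4 (weight 3)
        scores = np.log(np.array([[[0.7, 0.3]], [[0.6, 0.4]]]))
        target = np.array([[0], [1]])
        expected = (1 * -np.log(0.7) + 3 * -np.log(0.4)) / (1 + 3)
        got = weighted_cross_entropy(scores, target, weights=(1.0, 3.0))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_unit_weights_equal_plain_ce(self, rng):
        scores = rng.standard_normal((5, 5, 13))
        y = rng.integers(0, 13, (5, 5))
        assert weighted_cross_entropy(scores, y, np.ones(13)) == pytest.approx(
            cross_entropy(scores, y), abs=1e-6
        )

    def test_out_of_range_target_rejected(self, rng):
        scores = rng.standard_normal((3, 3, 13))
        y = np.full((3, 3), 13)  # cyst id cannot be a CE target
        with pytest.raises(LabelError):
            weighted_cross_entropy(scores, y)

    def test_class_weights_upweight_thin_layers(self, rng):
        masks = []
        for _ in range(3):
            m = np.full((20, 10), 11)
            m[:1] = 7  # 1-px-thin layer
            m[1:17] = 0
            masks.append(m)
        w = compute_class_weights(masks, 13)
        assert w[7] > w[0]
        assert w.mean() == pytest.approx(1.0)
        assert (w > 0).all() and np.isfinite(w).all()


class TestDice:
    def test_exact_match_is_zero(self, rng):
        y = rng.integers(0, 3, (6, 6))
        assert dice_loss(one_hot_scores(y, 3, margin=200.0), y) < 1e-4

    def test_matches_brute_force_summation(self, rng):
        scores = rng.standard_normal((4, 4, 3))
        y = rng.integers(0, 3, (4, 4))
        p = softmax(scores, axis=-1)
        eps = 1e-6
        dices = []
        for c in range(3):
            num = den = 0.0
            for i in range(4):
                for j in range(4):
                    t = 1.0 if y[i, j] == c else 0.0
                    num += 2.0 * p[i, j, c] * t
                    den += p[i, j, c] + t
            dices.append((num + eps) / (den + eps))
        expected = 1.0 - float(np.mean(dices))
        assert dice_loss(scores, y) == pytest.approx(expected, abs=1e-9)

    def test_ce_dice_is_sum_of_parts(self, rng):
        scores = rng.standard_normal((4, 4, 3))
        y = rng.integers(0, 3, (4, 4))
        assert ce_dice_loss(scores, y) == pytest.approx(
            cross_entropy(scores, y) + dice_loss(scores, y), abs=1e-9
        )


class TestCpsLosses:
    def test_labeled_zero_at_agreement(self, rng):
        y = rng.integers(0, 13, (4, 4))
        s = one_hot_scores(y, 13)
        assert cps_labeled_loss(s, s, y) < 1e-6

    def test_labeled_uniform_plus_onehot_gives_log_c(self):
        y = np.zeros((4, 4), dtype=int)
        s_uniform = np.zeros((4, 4, 13))
        s_correct = one_hot_scores(y, 13)
        got = cps_labeled_loss(s_uniform, s_correct, y)
        assert got == pytest.approx(np.log(13), abs=1e-6)

    def test_labeled_symmetric(self, rng):
        a = rng.standard_normal((4, 4, 13))
        b = rng.standard_normal((4, 4, 13))
        y = rng.integers(0, 13, (4, 4))
        assert cps_labeled_loss(a, b, y) == pytest.approx(
            cps_labeled_loss(b, a, y), abs=1e-9
        )

    def test_unlabeled_zero_at_selfconsistent_onehot(self, rng):
        y = rng.integers(0, 13, (4, 4))
        s = one_hot_scores(y, 13)
        assert cps_unlabeled_loss(s, s) < 1e-6

    def test_unlabeled_disagreement_closed_form(self):
        # model 1 votes class 0, model 2 votes class 1, margin m, C=3
        m = 4.0
        s1 = np.zeros((1, 1, 3))
        s1[..., 0] = m
        s2 = np.zeros((1, 1, 3))
        s2[..., 1] = m
        # each CE term: -log softmax(score of the other's argmax)
        lse = np.log(np.exp(m) + 2.0)
        expected = 2.0 * (lse - 0.0)  # other's class has logit 0
        assert cps_unlabeled_loss(s1, s2) == pytest.approx(expected, abs=1e-9)

    def test_pseudo_labels_carry_no_gradient(self, rng):
        """Perturbing s2 without flipping its argmax leaves the gradient on
        s1 unchanged: the pseudo-label is a constant, not a function of s2."""
        s1 = rng.standard_normal((3, 3, 5))
        s2 = rng.standard_normal((3, 3, 5)) * 3.0
        _, g1, _ = cps_unlabeled_loss_grads(s1, s2)
        s2b = s2 + 1e-4 * rng.standard_normal(s2.shape)
        assert np.array_equal(
            np.argmax(s2, axis=-1), np.argmax(s2b, axis=-1)
        ), "perturbation must not flip the pseudo-label"
        _, g1b, _ = cps_unlabeled_loss_grads(s1, s2b)
        assert np.array_equal(g1, g1b)

    def test_total_breakdown_identity(self, rng):
        for lam in (0.0, 0.5, 1.0, 2.0):
            s1 = rng.standard_normal((4, 4, 13))
            s2 = rng.standard_normal((4, 4, 13))
            y = rng.integers(0, 13, (4, 4))
            br = cps_total_loss(s1, s2, y, lambda_u=lam)
            assert br.total == pytest.approx(
                br.labeled + lam * br.unlabeled, abs=1e-6
            )
            assert br.labeled == pytest.approx(cps_labeled_loss(s1, s2, y), abs=1e-9)

    def test_unlabeled_batch_has_zero_labeled_term(self, rng):
        s1 = rng.standard_normal((4, 4, 13))
        s2 = rng.standard_normal((4, 4, 13))
        br = cps_total_loss(s1, s2, y=None, lambda_u=0.7)
        assert br.labeled == 0.0
        assert br.total == pytest.approx(0.7 * cps_unlabeled_loss(s1, s2), abs=1e-9)

    def test_sharpening_decreases_self_unlabeled_loss(self, rng):
        s = rng.standard_normal((4, 4, 13))
        losses = [cps_unlabeled_loss(s * t, s * t) for t in (1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestMeanTeacher:
    def test_ema_limits_and_midpoint(self):
        assert ema_update(1.0, 3.0, decay=0.0) == pytest.approx(1.0)
        assert ema_update(1.0, 3.0, decay=1.0) == pytest.approx(3.0)
        assert ema_update(1.0, 3.0, decay=0.5) == pytest.approx(2.0)

    def test_ema_elementwise_on_weight_lists(self, rng):
        student = [rng.random((3, 3)), rng.random(4)]
        teacher = [rng.random((3, 3)), rng.random(4)]
        out = ema_update(student, teacher, decay=0.9)
        for s, t, o in zip(student, teacher, out):
            assert np.allclose(o, 0.9 * t + 0.1 * s)

    def test_ema_structure_mismatch_rejected(self, rng):
        with pytest.raises(ConfigError):
            ema_update([np.zeros(3)], [np.zeros(4)], decay=0.5)
        with pytest.raises(ConfigError):
            ema_update([np.zeros(3)], [np.zeros(3), np.zeros(3)], decay=0.5)

    def test_consistency_zero_and_symmetric(self, rng):
        s = rng.standard_normal((4, 4, 13))
        t = rng.standard_normal((4, 4, 13))
        assert mt_consistency_loss(s, s) == 0.0
        assert mt_consistency_loss(s, t) == pytest.approx(
            mt_consistency_loss(t, s), abs=1e-12
        )

    def test_single_pixel_two_class_value(self):
        s = np.log(np.array([[[0.8, 0.2]]]))
        t = np.log(np.array([[[0.6, 0.4]]]))
        assert mt_consistency_loss(s, t) == pytest.approx(0.04, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_losses_nonnegative_and_finite(seed):
    rng = np.random.default_rng(seed)
    s1 = rng.standard_normal((3, 3, 6)) * 5
    s2 = rng.standard_normal((3, 3, 6)) * 5
    y = rng.integers(0, 6, (3, 3))
    vals = [
        cross_entropy(s1, y),
        weighted_cross_entropy(s1, y, rng.random(6) + 0.5),
        dice_loss(s1, y),
        cps_labeled_loss(s1, s2, y),
        cps_unlabeled_loss(s1, s2),
        mt_consistency_loss(s1, s2),
    ]
    assert all(np.isfinite(v) and v >= 0 for v in vals)
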