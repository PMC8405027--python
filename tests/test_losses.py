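"""Oracle and property tests for every loss term.

Closed-form expected values were computed by hand (or with an independent
scalar-loop reference defined here) before being frozen into assertions.
"""

import math

import numpy as np
import pytest

from mammodistill import losses as L


# ---------------------------------------------------------------------------
# Independent scalar-loop reference implementations (oracles)


def loop_l1(y_hat, y):
    total = 0.0
    for a, b in zip(np.ravel(y_hat), np.ravel(y)):
        total += abs(b - a)
    return total / np.size(y)


def loop_kl(p, q):
    total = 0.0
    for pj, qj in zip(p, q):
        if qj > 0:
            total += qj * math.log(qj / max(pj, L.CLIP_EPS))
    return total


def loop_dice(a, b):
    num = 2.0 * sum(x * y for x, y in zip(np.ravel(a), np.ravel(b))) + L.DICE_EPS
    den = sum(np.ravel(a)) + sum(np.ravel(b)) + L.DICE_EPS
    return num / den


def loop_bce_mean(target, prob):
    total = 0.0
    for t, p in zip(np.ravel(target), np.ravel(prob)):
        p = min(max(p, L.CLIP_EPS), 1 - L.CLIP_EPS)
        total += -(t * math.log(p) + (1 - t) * math.log(1 - p))
    return total / np.size(target)


def loop_softmax(logits, T):
    exps = [math.exp(v / T) for v in logits]
    s = sum(exps)
    return [e / s for e in exps]


# ---------------------------------------------------------------------------
# soft targets (temperature softmax)


class TestSoftTargets:
    def test_symmetric_logits_give_uniform(self):
        np.testing.assert_allclose(L.soft_targets(np.array([0.0, 0.0]), T=3.7),
                                   [0.5, 0.5])

    def test_closed_form_example(self):
        # logits (2,0) at T=2: exp(1)/(exp(1)+1), 1/(exp(1)+1)
        rho = L.soft_targets(np.array([2.0, 0.0]), T=2.0)
        e = math.e
        np.testing.assert_allclose(rho, [e / (e + 1), 1 / (e + 1)], atol=1e-4)
        np.testing.assert_allclose(rho, [0.7311, 0.2689], atol=1e-4)

    def test_infinite_temperature_limit_is_uniform(self):
        rho = L.soft_targets(np.array([5.0, -5.0]), T=1e6)
        np.testing.assert_allclose(rho, [0.5, 0.5], atol=1e-5)

    def test_t_equal_one_is_plain_softmax(self):
        logits = np.array([0.3, -1.2, 2.2])
        np.testing.assert_allclose(L.soft_targets(logits, 1.0),
                                   loop_softmax(logits, 1.0), atol=1e-12)

    def test_sums_to_one_and_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            logits = rng.normal(0, 5, size=rng.integers(2, 6))
            rho = L.soft_targets(logits, T=float(rng.uniform(0.1, 10)))
            assert np.all(rho > 0)
            assert abs(rho.sum() - 1.0) < 1e-12

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            logits = rng.normal(size=4)
            c = rng.normal() * 10
            np.testing.assert_allclose(
                L.soft_targets(logits, 2.0), L.soft_targets(logits + c, 2.0),
                atol=1e-12)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            L.soft_targets(np.array([1.0, 2.0]), T=0.0)


# ---------------------------------------------------------------------------
# L1, CE and the teacher total


class TestTeacherLosses:
    def test_l1_identical_is_zero(self):
        x = np.random.default_rng(2).random((8, 8))
        assert L.l1_loss(x, x) == 0.0

    def test_l1_hand_example(self):
        assert L.l1_loss(np.array([1.0, 1.0]), np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_l1_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.random((2, 6, 6))
            assert L.l1_loss(a, b) == pytest.approx(loop_l1(a, b), abs=1e-7)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            L.l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_ce_closed_forms(self):
        assert L.ce_loss(1.0, 1) == pytest.approx(0.0, abs=1e-6)
        assert L.ce_loss(0.5, 1) == pytest.approx(math.log(2), abs=1e-4)
        assert L.ce_loss(0.9, 0) == pytest.approx(-math.log(0.1), abs=1e-4)

    def test_ce_invalid_label(self):
        with pytest.raises(ValueError):
            L.ce_loss(0.5, 2)

    def test_teacher_total_is_sum(self):
        assert L.teacher_loss(0.5, math.log(2)) == pytest.approx(1.1931, abs=1e-4)
        rng = np.random.default_rng(4)
        for _ in range(20):
            l1, ce = rng.random(2)
            assert L.teacher_loss(l1, ce) == l1 + ce


# ---------------------------------------------------------------------------
# KL divergence on normalized bottleneck vectors


class TestKL:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert L.kl_loss(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # 0.5*ln2 + 0.5*ln(2/3)
        val = L.kl_loss(np.array([0.25, 0.75]), np.array([0.5, 0.5]))
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.1438, abs=1e-4)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            assert L.kl_loss(p, q) == pytest.approx(loop_kl(p, q), abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            assert L.kl_loss(p, q) >= -1e-12

    def test_asymmetric(self):
        p = np.array([0.25, 0.75])
        q = np.array([0.5, 0.5])
        assert L.kl_loss(p, q) != pytest.approx(L.kl_loss(q, p), abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            L.kl_loss(np.ones(3) / 3, np.ones(4) / 4)


# ---------------------------------------------------------------------------
# Dice, KD and GT losses


class TestDiceLosses:
    def test_dice_identical_binary_masks(self):
        m = np.array([[1, 0], [1, 1]], dtype=float)
        assert L.soft_dice(m, m) == pytest.approx(1.0, abs=1e-6)

    def test_dice_disjoint_masks(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert L.soft_dice(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_dice_hand_count(self):
        # a covers 4 pixels, b covers 2 of them: 2*2/(4+2)
        a = np.array([1.0, 1.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 0.0, 0.0])
        assert L.soft_dice(a, b) == pytest.approx(2 / 3, abs=1e-5)

    def test_dice_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = rng.random((2, 10))
            assert L.soft_dice(a, b) == pytest.approx(loop_dice(a, b), abs=1e-9)

    def test_kd_perfect_agreement_is_zero(self):
        one_hot = np.array([1.0, 0.0])
        # one-hot probabilities are clipped inside BCE, so "zero" means
        # zero up to the clipping epsilon
        assert L.kd_loss(one_hot, one_hot, one_hot) == pytest.approx(0.0, abs=1e-5)

    def test_kd_hand_example(self):
        # Dice((.5,.5),(.5,.5)) = 0.5 -> first term 0.5; BCE((1,0),(.5,.5)) = ln2
        rho = np.array([0.5, 0.5])
        s = np.array([0.5, 0.5])
        rho_star = np.array([1.0, 0.0])
        d = loop_dice(rho, s)
        b = loop_bce_mean(rho_star, s)
        expected = (1 - d) + b
        assert expected == pytest.approx(0.5 + math.log(2), abs=1e-5)
        assert L.kd_loss(rho, rho_star, s) == pytest.approx(expected, abs=1e-9)
        assert L.kd_loss(rho, rho_star, s) == pytest.approx(1.1931, abs=1e-4)

    def test_kd_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            rho = rng.dirichlet(np.ones(2))
            rho_star = np.zeros(2)
            rho_star[rho.argmax()] = 1.0
            s = rng.uniform(0.01, 0.99, size=2)
            assert L.kd_loss(rho, rho_star, s) >= 0.0

    def test_kd_rejects_non_one_hot(self):
        with pytest.raises(ValueError):
            L.kd_loss(np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                      np.array([0.5, 0.5]))

    def test_gt_perfect_prediction_is_zero(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert L.gt_loss(m, m) == pytest.approx(0.0, abs=1e-5)

    def test_gt_hand_example_with_clipping(self):
        # all-ones prediction vs half-ones mask on 4 pixels
        mask = np.array([1.0, 1.0, 0.0, 0.0])
        pred = np.ones(4)
        expected = (1 - loop_dice(mask, pred)) + loop_bce_mean(mask, pred)
        assert L.gt_loss(mask, pred) == pytest.approx(expected, abs=1e-9)
        # dice term: 1 - 2*2/(2+4) = 1/3; bce term: 2 * -ln(eps) / 4
        assert expected == pytest.approx(1 / 3 + 2 * -math.log(L.CLIP_EPS) / 4, abs=1e-4)

    def test_gt_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            mask = (rng.random((5, 5)) > 0.5).astype(float)
            pred = rng.uniform(0.01, 0.99, size=(5, 5))
            expected = (1 - loop_dice(mask, pred)) + loop_bce_mean(mask, pred)
            assert L.gt_loss(mask, pred) == pytest.approx(expected, abs=1e-9)

    def test_gt_decreases_toward_mask(self):
        # moving every probability elementwise toward the mask lowers the loss
        rng = np.random.default_rng(10)
        for _ in range(20):
            mask = (rng.random(16) > 0.5).astype(float)
            pred = rng.uniform(0.05, 0.95, size=16)
            better = pred + 0.05 * (mask - pred)
            assert L.gt_loss(mask, better) < L.gt_loss(mask, pred)


# ---------------------------------------------------------------------------
# Student total


class TestStudentLoss:
    def test_alpha_zero_lambda_zero_is_gt(self):
        cfg = L.DistillConfig(T=2.0, alpha=0.0, lam=0.0)
        assert L.student_loss(kd=3.0, gt=1.25, kl=9.0, cfg=cfg) == 1.25

    def test_alpha_one_lambda_zero_is_kd(self):
        cfg = L.DistillConfig(T=2.0, alpha=1.0, lam=0.0)
        assert L.student_loss(kd=3.0, gt=1.25, kl=9.0, cfg=cfg) == 3.0

    def test_arithmetic_example(self):
        cfg = L.DistillConfig(T=1.0, alpha=0.25, lam=0.1)
        assert L.student_loss(2.0, 4.0, 1.0, cfg) == pytest.approx(3.6, abs=1e-12)

    def test_linear_in_each_component(self):
        cfg = L.DistillConfig(T=1.0, alpha=0.3, lam=0.2)
        rng = np.random.default_rng(11)
        for _ in range(50):
            kd, gt, kl, s = rng.random(4)
            base = L.student_loss(kd, gt, kl, cfg)
            assert L.student_loss(kd + s, gt, kl, cfg) - base == pytest.approx(
                cfg.alpha * s, abs=1e-12)
            assert L.student_loss(kd, gt + s, kl, cfg) - base == pytest.approx(
                (1 - cfg.alpha) * s, abs=1e-12)
            assert L.student_loss(kd, gt, kl + s, cfg) - base == pytest.approx(
                cfg.lam * s, abs=1e-12)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            L.DistillConfig(alpha=1.5)
        with pytest.raises(ValueError):
            L.DistillConfig(lam=-0.1)
        with pytest.raises(ValueError):
            L.DistillConfig(T=-1.0)


# ---------------------------------------------------------------------------
# Analytic gradients match finite differences of the loss functions


class TestLossGradients:
    def test_gt_gradient_finite_difference(self):
        rng = np.random.default_rng(12)
        mask = (rng.random((4, 4)) > 0.5).astype(float)
        logits = rng.normal(0, 2, size=(4, 4))
        from mammodistill.nn.layers import sigmoid

        g = L.grad_gt_wrt_seg_logits(mask, logits)
        eps = 1e-5
        for idx in [(0, 0), (1, 2), (3, 3)]:
            lp = logits.copy()
            lp[idx] += eps
            lm = logits.copy()
            lm[idx] -= eps
            num = (L.gt_loss(mask, sigmoid(lp)) - L.gt_loss(mask, sigmoid(lm))) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_kd_gradient_finite_difference(self):
        rng = np.random.default_rng(13)
        from mammodistill.nn.layers import sigmoid

        rho = rng.dirichlet(np.ones(2))
        rho_star = np.zeros(2)
        rho_star[rho.argmax()] = 1.0
        logits = rng.normal(0, 1, size=2)
        g = L.grad_kd_wrt_class_logits(rho, rho_star, logits)
        eps = 1e-6
        for i in range(2):
            lp, lm = logits.copy(), logits.copy()
            lp[i] += eps
            lm[i] -= eps
            num = (L.kd_loss(rho, rho_star, sigmoid(lp))
                   - L.kd_loss(rho, rho_star, sigmoid(lm))) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_kl_gradient_is_softmax_difference(self):
        rng = np.random.default_rng(14)
        s_flat = rng.normal(size=16)
        t_flat = rng.normal(size=16)
        g = L.grad_kl_wrt_student_bottleneck(s_flat, t_flat)
        eps = 1e-6
        q = L.soft_targets(t_flat, 1.0)
        for i in [0, 7, 15]:
            sp, sm = s_flat.copy(), s_flat.copy()
            sp[i] += eps
            sm[i] -= eps
            num = (L.kl_loss(L.soft_targets(sp, 1.0), q)
                   - L.kl_loss(L.soft_targets(sm, 1.0), q)) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8)
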