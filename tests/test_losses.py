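"""Loss functions against brute-force oracles and closed-form identities."""

import numpy as np
import pytest

from fundusseg.autograd import Tensor
from fundusseg.losses import (LossConfig, boundary_dice_loss, ce_loss,
                              classification_loss, combined_loss, dice_loss,
                              soft_dilate)


def bce_oracle(y, p, eps=1e-7):
    total, n = 0.0, 0
    for yi, pi in zip(y.ravel(), p.ravel()):
        pi = min(max(pi, eps), 1 - eps)
        total += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
        n += 1
    return total / n


def dilate_oracle(x, k):
    h, w = x.shape
    r = k // 2
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            vals = [x[a, b]
                    for a in range(max(0, i - r), min(h, i + r + 1))
                    for b in range(max(0, j - r), min(w, j + r + 1))]
            out[i, j] = max(vals)
    return out


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = np.where(y > 0, 1 - 1e-7, 1e-7)
        assert float(ce_loss(y, p)) < 1e-5

    def test_half_confidence_is_ln2(self):
        assert np.isclose(float(ce_loss(np.ones((1, 1)), np.full((1, 1), 0.5))),
                          np.log(2), atol=1e-6)

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = (rng.random((5, 5)) > 0.5).astype(float)
            p = rng.random((5, 5))
            assert np.isclose(float(ce_loss(y, p)), bce_oracle(y, p), rtol=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDice:
    def test_identical_masks_zero(self):
        y = (np.random.default_rng(1).random((6, 6)) > 0.5).astype(float)
        assert float(dice_loss(y, y)) < 1e-5

    def test_half_overlap_value(self):
        # 1 - 2*0.5 / (1 + 1) = 0.5
        y = np.array([1.0, 0.0])
        p = np.array([0.5, 0.5])
        assert np.isclose(float(dice_loss(y, p)), 0.5, atol=1e-5)

    def test_empty_masks_zero(self):
        assert np.isclose(float(dice_loss(np.zeros(4), np.zeros(4))), 0.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            y = (rng.random((4, 4)) > 0.5).astype(float)
            p = rng.random((4, 4))
            expected = 1 - (2 * (y * p).sum() + 1e-6) / (y.sum() + p.sum() + 1e-6)
            assert np.isclose(float(dice_loss(y, p)), expected, rtol=1e-5)


class TestSoftDilate:
    def test_single_pixel_grows_to_block(self):
        x = np.zeros((5, 5))
        x[2, 2] = 1.0
        out = soft_dilate(x, 3, 1)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        assert np.array_equal(out, expected)

    def test_saturated_mask_unchanged(self):
        x = np.ones((4, 4))
        assert np.array_equal(soft_dilate(x, 3, 1), x)

    def test_monotone_and_matches_window_max_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.random((6, 6))
            out = soft_dilate(x, 3, 1)
            assert np.all(out >= x)
            assert np.allclose(out, dilate_oracle(x, 3), atol=1e-6)

    def test_iterations_compose(self):
        rng = np.random.default_rng(4)
        x = rng.random((7, 7))
        assert np.allclose(soft_dilate(x, 3, 2), soft_dilate(soft_dilate(x, 3, 1), 3, 1))


class TestBoundaryDice:
    def test_identical_masks_zero(self):
        y = np.zeros((6, 6))
        y[2:4, 2:4] = 1.0
        assert float(boundary_dice_loss(y, y)) < 1e-5

    def test_missed_mask_ring_loss_is_one(self):
        """2x2 block in 6x6: its outer boundary is the 12-pixel ring; an all-
        zero prediction has an empty ring, so the boundary Dice loss -> 1."""
        y = np.zeros((6, 6))
        y[2:4, 2:4] = 1.0
        ring = soft_dilate(y, 3, 1) - y
        assert ring.sum() == 12
        loss = float(boundary_dice_loss(y, np.zeros((6, 6)), smooth_eps=1e-9))
        assert loss > 1 - 1e-6

    def test_full_grid_no_boundary(self):
        y = np.ones((5, 5))
        assert np.isclose(float(boundary_dice_loss(y, y)), 0.0)

    def test_boundary_ring_is_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random((6, 6))
            ring = soft_dilate(p, 3, 1) - p
            assert ring.min() >= -1e-7


class TestCombinedLoss:
    def _instance(self, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random((2, 8, 8)) > 0.6).astype(np.float32)
        p = rng.random((2, 8, 8)).astype(np.float32)
        cy = np.array([0, 1])
        cp = rng.dirichlet((2.0, 2.0), size=2).astype(np.float32)
        return y, p, cy, cp

    def test_total_recomposes_from_terms(self):
        y, p, cy, cp = self._instance()
        cfg = LossConfig(lambda1=0.7, lambda2=1.3, lambda_cls=0.5)
        bd = combined_loss(y, p, cy, cp, cfg)
        expected = (0.7 * float(bd.l_ce) + 1.3 * float(bd.l_dice)
                    + 1.3 * float(bd.l_boundary_dice) + 0.5 * float(bd.l_cls))
        assert np.isclose(float(bd.total), expected, atol=1e-9)

    def test_ce_only_configuration(self):
        y, p, cy, cp = self._instance(1)
        bd = combined_loss(y, p, cy, cp, LossConfig(lambda1=1.0, lambda2=0.0))
        assert np.isclose(float(bd.total), float(bd.l_ce) + float(bd.l_cls), atol=1e-9)

    def test_all_correct_leaves_only_classifier_term(self):
        y = (np.random.default_rng(2).random((8, 8)) > 0.5).astype(np.float32)
        p = np.where(y > 0, 1 - 1e-7, 1e-7)
        bd = combined_loss(y[None], p[None], [1], np.array([[0.3, 0.7]]))
        assert float(bd.total) == pytest.approx(float(bd.l_cls), abs=1e-4)

    def test_halving_lambda2_halves_dice_share(self):
        y, p, cy, cp = self._instance(3)
        full = combined_loss(y, p, cy, cp, LossConfig(lambda2=1.0))
        half = combined_loss(y, p, cy, cp, LossConfig(lambda2=0.5))
        share_full = float(full.total) - float(full.l_ce) - float(full.l_cls)
        share_half = float(half.total) - float(half.l_ce) - float(half.l_cls)
        assert np.isclose(share_half, share_full / 2, rtol=1e-9)

    def test_ablation_configs_expressible(self):
        # the loss-ablation axis: ce only / ce+dice / ce+boundary / all
        combos = [LossConfig(lambda2=0.0),
                  LossConfig(lambda2=1.0, lambda3=0.0),
                  LossConfig(lambda2=0.0, lambda3=1.0),
                  LossConfig(lambda2=1.0)]
        y, p, cy, cp = self._instance(4)
        values = [float(combined_loss(y, p, cy, cp, c).total) for c in combos]
        assert len(set(np.round(values, 12))) == 4

    def test_nan_probability_is_hard_error(self):
        y, p, cy, cp = self._instance(5)
        p = p.copy()
        p[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="l_ce"):
            combined_loss(y, p, cy, cp)


def test_dice_losses_gradients_match_finite_differences():
    rng = np.random.default_rng(6)
    y = (rng.random((5, 5)) > 0.5).astype(np.float64)
    p0 = rng.uniform(0.2, 0.8, (5, 5))
    for loss_fn in (dice_loss, boundary_dice_loss):
        t = Tensor(p0.copy(), requires_grad=True)
        loss_fn(y, t).backward()
        idx = [(int(a), int(b)) for a, b in rng.integers(0, 5, (10, 2))]
        for i, j in idx:
            eps = 1e-6
            pp = p0.copy(); pp[i, j] += eps
            pm = p0.copy(); pm[i, j] -= eps
            num = (float(loss_fn(y, pp)) - float(loss_fn(y, pm))) / (2 * eps)
            if abs(num) > 1e-8:
                assert abs(t.grad[i, j] - num) / max(abs(num), 1e-8) < 1e-3
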