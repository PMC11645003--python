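"""Closed-form values, empty-mask conventions and schedules of the losses."""

import numpy as np
import pytest

from entroseg import losses as L
from entroseg.autodiff import Tensor
from entroseg.entropy_masks import InvalidInputError

from conftest import oracle_ce_dice, oracle_masked_mse, random_prob_map


def as_tensor_and_numpy(fn):
    """Evaluate a loss both on numpy arrays and on Tensors; must agree."""

    def wrapped(*arrays):
        v_np = fn(*arrays)
        v_t = fn(*[Tensor(a) if a.dtype.kind == "f" else a for a in arrays])
        assert L.scalar(v_t) == pytest.approx(v_np, abs=1e-6)
        return v_np

    return wrapped


class TestMaskedLosses:
    def test_hard_region_loss_worked_example(self):
        # two masked voxels, C=2: rows (0.8,0.2) and (0.6,0.4), truth class 0
        pred = np.array([[0.8, 0.6], [0.2, 0.4]], np.float32).reshape(2, 2, 1, 1)
        gt = np.array([[1.0, 1.0], [0.0, 0.0]], np.float32).reshape(2, 2, 1, 1)
        mask = np.ones((2, 1, 1), np.uint8)
        got = L.hard_region_exploration_loss(pred, gt, mask)
        assert got == pytest.approx(0.20, abs=1e-6)

    def test_sharing_loss_worked_examples(self):
        learner = np.array([0.5, 0.5], np.float32).reshape(2, 1, 1, 1)
        target = np.array([1.0, 0.0], np.float32).reshape(2, 1, 1, 1)
        mask = np.ones((1, 1, 1), np.uint8)
        assert L.pseudo_label_sharing_directed(learner, target, mask) == pytest.approx(0.5)
        pv = np.array([0.9, 0.1], np.float32).reshape(2, 1, 1, 1)
        ph = np.array([0.7, 0.3], np.float32).reshape(2, 1, 1, 1)
        assert L.mutual_high_quality_loss(pv, ph, mask) == pytest.approx(0.08)

    def test_empty_mask_and_perfect_prediction_give_zero(self, rng):
        p = random_prob_map(rng, 2).astype(np.float32)
        empty = np.zeros((4, 4, 4), np.uint8)
        full = np.ones((4, 4, 4), np.uint8)
        assert L.hard_region_exploration_loss(p, p.copy(), full) == 0.0
        assert L.hard_region_exploration_loss(p, 1 - p, empty) == 0.0
        assert L.mutual_high_quality_loss(p, p.copy(), full) == 0.0
        assert L.pseudo_label_sharing_directed(Tensor(p), Tensor(p.copy()), empty).data == 0.0

    def test_masked_mse_matches_loop_oracle_both_paths(self, rng):
        for _ in range(20):
            c = int(rng.integers(2, 5))
            a = random_prob_map(rng, c).astype(np.float32)
            b = random_prob_map(rng, c).astype(np.float32)
            mask = rng.integers(0, 2, (4, 4, 4)).astype(np.uint8)
            expected = oracle_masked_mse(a, b, mask)
            assert L.masked_mse(a, b, mask) == pytest.approx(expected, abs=1e-6)
            assert L.scalar(L.masked_mse(Tensor(a), Tensor(b), mask)) == pytest.approx(
                expected, abs=1e-6)

    def test_sharing_target_must_be_detached(self, rng):
        p = Tensor(random_prob_map(rng, 2), requires_grad=True)
        mask = np.ones((4, 4, 4), np.uint8)
        with pytest.raises(InvalidInputError):
            L.pseudo_label_sharing_directed(p, p, mask)
        L.pseudo_label_sharing_directed(p, p.detach(), mask)  # detached is fine

    def test_shape_mismatch_rejected(self, rng):
        p = random_prob_map(rng, 2).astype(np.float32)
        with pytest.raises(InvalidInputError):
            L.hard_region_exploration_loss(p, p, np.ones((2, 2, 2), np.uint8))


class TestSupervisedLoss:
    def test_ce_and_dice_match_loop_oracle(self, rng):
        p = random_prob_map(rng, 3).astype(np.float32)[:, :2, :2, :1]
        p /= p.sum(axis=0, keepdims=True)
        gt = rng.integers(0, 3, (2, 2, 1))
        ce_ref, dice_ref = oracle_ce_dice(p, gt)
        assert L.cross_entropy_loss(p, gt) == pytest.approx(ce_ref, abs=1e-6)
        assert L.dice_loss(p, gt) == pytest.approx(dice_ref, abs=1e-6)

    def test_perfect_prediction_limits(self):
        gt = np.array([[[0, 1]]], np.int64)
        p = L.one_hot(gt, 2)
        sup = L.supervised_loss(p, gt, np.ones_like(gt, np.uint8), alpha=0.5)
        assert L.scalar(sup.l_ex) == 0.0
        assert L.scalar(sup.l_dice) == pytest.approx(0.0, abs=1e-4)
        assert L.scalar(sup.l_ce) == pytest.approx(0.0, abs=1e-6)

    def test_alpha_zero_reduces_to_ce_plus_dice(self, rng):
        p = random_prob_map(rng, 2).astype(np.float32)
        gt = rng.integers(0, 2, (4, 4, 4))
        sup = L.supervised_loss(p, gt, None, alpha=0.0)
        assert L.scalar(sup.l_sup) == pytest.approx(
            L.scalar(sup.l_ce) + L.scalar(sup.l_dice), abs=1e-7)

    def test_out_of_range_labels_rejected(self, rng):
        p = random_prob_map(rng, 2).astype(np.float32)
        with pytest.raises(InvalidInputError):
            L.supervised_loss(p, np.full((4, 4, 4), 2), None, 0.5)


class TestTotalLoss:
    def test_arithmetic_and_bundle_invariants(self, rng):
        p = random_prob_map(rng, 2).astype(np.float32)
        gt = rng.integers(0, 2, (4, 4, 4))
        sup = L.supervised_loss(p, gt, np.ones_like(gt, np.uint8), alpha=0.5)
        bundle, _ = L.total_loss(sup, 0.5, 0.08, lambda1=0.1)
        assert bundle.l_sub == pytest.approx(bundle.l_sup + 0.1 * 0.58, abs=1e-7)
        bundle.validate(alpha=0.5, lambda1=0.1)
        # explicit worked numbers
        assert 1.0 + 0.1 * (0.5 + 0.08) == pytest.approx(1.058)

    def test_lambda_zero_keeps_supervised_objective(self, rng):
        p = Tensor(random_prob_map(rng, 2), requires_grad=True)
        gt = np.zeros((4, 4, 4), np.int64)
        sup = L.supervised_loss(p, gt, None, alpha=0.0)
        bundle, obj = L.total_loss(sup, Tensor(123.0), Tensor(456.0), lambda1=0.0)
        assert bundle.l_sub == pytest.approx(bundle.l_sup)
        assert L.scalar(obj) == pytest.approx(bundle.l_sup, abs=1e-6)


class TestWarmup:
    def test_endpoint_and_start_values(self):
        sched = L.WarmupSchedule(t_max=6000)
        assert L.warmup_weight(6000, sched) == pytest.approx(0.1)
        assert L.warmup_weight(0, sched) == pytest.approx(0.1 * np.exp(-5), abs=1e-9)

    def test_non_decreasing_ramp(self):
        for squared in (True, False):
            sched = L.WarmupSchedule(t_max=1000, squared=squared)
            values = [L.warmup_weight(t, sched) for t in range(0, 1001, 10)]
            assert all(b >= a for a, b in zip(values, values[1:]))
            assert values[-1] == pytest.approx(0.1)

    def test_out_of_range_iteration_rejected(self):
        sched = L.WarmupSchedule(t_max=100)
        with pytest.raises(InvalidInputError):
            L.warmup_weight(101, sched)
        with pytest.raises(InvalidInputError):
            L.warmup_weight(-1, sched)
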