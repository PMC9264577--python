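"""Loss functions: hand-computed examples, invariants and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dhlppi.losses import (
    LossConfig,
    batch_losses_and_grads,
    bit_balance_loss,
    discrimination_loss,
    hash_constraint_loss,
    manhattan_dist,
    total_loss,
)

CFG = LossConfig(N=64)

codes = hnp.arrays(
    dtype=float,
    shape=st.integers(min_value=2, max_value=32).map(lambda n: 2 * n),
    elements=st.floats(min_value=0.001, max_value=0.999),
)


class TestManhattan:
    def test_identical_codes_have_zero_distance(self):
        a = np.array([0.2, 0.8, 0.5])
        assert manhattan_dist(a, a) == 0.0

    def test_binary_case_equals_hamming(self):
        a = np.array([1, 0, 1, 0], dtype=float)
        b = np.array([0, 0, 1, 1], dtype=float)
        assert manhattan_dist(a, b) == 2.0

    def test_hand_summed_example(self):
        assert manhattan_dist(np.array([0.9, 0.1]), np.array([0.2, 0.3])) == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            manhattan_dist(np.zeros(3), np.zeros(4))


class TestDiscrimination:
    @pytest.mark.parametrize(
        "dist,label,expected",
        [
            (2.0, 1, 0.0),    # at the interacting margin
            (12.0, 0, 0.0),   # at the non-interacting margin
            (5.0, 1, 3.0),
            (7.0, 0, 5.0),
            (0.0, 1, 0.0),
            (20.0, 0, 0.0),
        ],
    )
    def test_hinge_values(self, dist, label, expected):
        assert discrimination_loss(dist, label, CFG) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=64), st.floats(min_value=0, max_value=64))
    @settings(deadline=None)
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        # non-decreasing for interacting pairs, non-increasing for non-interacting
        assert discrimination_loss(lo, 1, CFG) <= discrimination_loss(hi, 1, CFG)
        assert discrimination_loss(lo, 0, CFG) >= discrimination_loss(hi, 0, CFG)


class TestHashConstraint:
    def test_zero_on_binary_codes(self):
        rng = np.random.default_rng(0)
        ont = rng.integers(0, 2, size=64).astype(float)
        que = rng.integers(0, 2, size=64).astype(float)
        assert hash_constraint_loss(ont, que, CFG) == 0.0

    def test_maximal_at_threshold(self):
        half = np.full(64, 0.5)
        assert hash_constraint_loss(half, half, CFG) == pytest.approx(32.0)

    def test_one_maximal_one_zero_term(self):
        half = np.full(64, 0.5)
        binary = np.tile([0.0, 1.0], 32)
        assert hash_constraint_loss(half, binary, CFG) == pytest.approx(16.0)

    @given(codes)
    @settings(deadline=None)
    def test_per_code_term_bounded(self, values):
        cfg = LossConfig(N=len(values), in_dist=0, unin_dist=len(values))
        loss = hash_constraint_loss(values, values, cfg)
        assert 0.0 <= loss <= 2 * 0.25 * len(values) + 1e-12

    def test_exhaustive_zero_set_at_small_n(self):
        # over all {0,1}^4 codes the loss is exactly zero; any interior
        # component makes it positive
        cfg = LossConfig(N=4, in_dist=0, unin_dist=4)
        for k in range(16):
            bits = np.array([(k >> i) & 1 for i in range(4)], dtype=float)
            assert hash_constraint_loss(bits, bits, cfg) == 0.0
            nudged = bits.copy()
            nudged[0] = abs(nudged[0] - 0.3)
            assert hash_constraint_loss(nudged, bits, cfg) > 0.0

    def test_decreases_toward_zero_as_components_saturate(self):
        cfg = LossConfig(N=8, in_dist=0, unin_dist=8)
        target = np.tile([0.0, 1.0], 4)
        losses = [
            hash_constraint_loss(0.5 + t * (target - 0.5), target, cfg)
            for t in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] == 0.0


class TestBitBalance:
    def test_zero_at_balanced_codes(self):
        balanced = np.tile([0.0, 1.0], 32)
        assert bit_balance_loss(balanced, balanced) == 0.0

    def test_extreme_codes(self):
        assert bit_balance_loss(np.ones(64), np.zeros(64)) == pytest.approx(0.5)

    def test_hand_example(self):
        ont = np.full(64, 0.6)
        que = np.full(64, 0.5)
        assert bit_balance_loss(ont, que) == pytest.approx(0.01)


class TestTotal:
    def test_default_weight_for_bit_balance(self):
        assert CFG.lambda_b == pytest.approx(2 / 64)

    def test_zero_losses_give_zero_total(self):
        assert total_loss(0.0, 0.0, 0.0, CFG) == 0.0

    def test_weighted_sum(self):
        assert total_loss(3.0, 32.0, 0.5, CFG) == pytest.approx(35.015625)

    @given(codes, st.integers(min_value=0, max_value=1))
    @settings(deadline=None)
    def test_all_losses_nonnegative(self, values, label):
        n = len(values)
        cfg = LossConfig(N=n, in_dist=1, unin_dist=n)
        other = values[::-1].copy()
        assert discrimination_loss(manhattan_dist(values, other), label, cfg) >= 0
        assert hash_constraint_loss(values, other, cfg) >= 0
        assert bit_balance_loss(values, other) >= 0


class TestBatch:
    def test_batch_means_match_scalar_losses(self):
        rng = np.random.default_rng(1)
        ont = rng.uniform(0.01, 0.99, size=(5, 64))
        que = rng.uniform(0.01, 0.99, size=(5, 64))
        labels = np.array([1, 0, 1, 0, 1])
        got, _, _ = batch_losses_and_grads(ont, que, labels, CFG)
        expected_ld = np.mean([
            discrimination_loss(manhattan_dist(o, q), l, CFG)
            for o, q, l in zip(ont, que, labels)
        ])
        expected_lh = np.mean([hash_constraint_loss(o, q, CFG) for o, q in zip(ont, que)])
        expected_lb = np.mean([bit_balance_loss(o, q) for o, q in zip(ont, que)])
        assert got["ld"] == pytest.approx(expected_ld)
        assert got["lh"] == pytest.approx(expected_lh)
        assert got["lb"] == pytest.approx(expected_lb)
        assert got["total"] == pytest.approx(total_loss(expected_ld, expected_lh, expected_lb, CFG))

    def test_batch_reduction_is_linear_in_subbatches(self):
        rng = np.random.default_rng(2)
        ont = rng.uniform(0.01, 0.99, size=(6, 64))
        que = rng.uniform(0.01, 0.99, size=(6, 64))
        labels = np.array([1, 0, 1, 0, 0, 1])
        full, _, _ = batch_losses_and_grads(ont, que, labels, CFG)
        a, _, _ = batch_losses_and_grads(ont[:2], que[:2], labels[:2], CFG)
        b, _, _ = batch_losses_and_grads(ont[2:], que[2:], labels[2:], CFG)
        for key in ("ld", "lh", "lb", "total"):
            assert full[key] == pytest.approx((2 * a[key] + 4 * b[key]) / 6)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        ont = rng.uniform(0.2, 0.8, size=(3, 8))
        que = rng.uniform(0.2, 0.8, size=(3, 8))
        labels = np.array([1, 0, 1])
        cfg = LossConfig(N=8, in_dist=1, unin_dist=6)
        _, g_ont, g_que = batch_losses_and_grads(ont, que, labels, cfg)
        eps = 1e-6
        for arr, grad in ((ont, g_ont), (que, g_que)):
            for i in (0, 1, 2):
                for j in (0, 3, 7):
                    old = arr[i, j]
                    arr[i, j] = old + eps
                    up, _, _ = batch_losses_and_grads(ont, que, labels, cfg)
                    arr[i, j] = old - eps
                    dn, _, _ = batch_losses_and_grads(ont, que, labels, cfg)
                    arr[i, j] = old
                    fd = (up["total"] - dn["total"]) / (2 * eps)
                    assert grad[i, j] == pytest.approx(fd, abs=1e-5)


class TestConfigValidation:
    def test_margins_must_be_ordered(self):
        with pytest.raises(ValueError):
            LossConfig(N=64, in_dist=12, unin_dist=2)

    def test_quantization_threshold_must_be_interior(self):
        with pytest.raises(ValueError):
            LossConfig(N=64, quan_thresh=1.0)
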