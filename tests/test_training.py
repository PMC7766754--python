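from __future__ import annotations

import math

import numpy as np
import pytest

import squigru as sq
from squigru.errors import ValidationError
from squigru.training import (
    TrainConfig,
    batch_loss_and_grads,
    make_chunks,
    mean_log_cosh,
)


class TestLogCoshLoss:
    def test_zero_at_equality(self, rng):
        x = rng.normal(size=50)
        assert sq.log_cosh_loss(x, x) == 0.0

    def test_unit_residual_closed_form(self):
        assert sq.log_cosh_loss([1.0], [0.0]) == pytest.approx(
            math.log(math.cosh(1.0)), abs=1e-12
        )
        assert sq.log_cosh_loss([1.0], [0.0]) == pytest.approx(0.433781, abs=1e-6)

    def test_large_residual_asymptote(self):
        # log cosh x -> |x| - log 2 for large |x|, without overflow
        assert sq.log_cosh_loss([100.0], [0.0]) == pytest.approx(
            100.0 - math.log(2.0), abs=1e-9
        )
        assert sq.log_cosh_loss([0.0], [1e6]) == pytest.approx(
            1e6 - math.log(2.0), rel=1e-12
        )

    def test_symmetric_and_nonnegative(self, rng):
        o = rng.normal(size=30)
        r = rng.normal(size=30)
        assert sq.log_cosh_loss(o, r) == pytest.approx(sq.log_cosh_loss(r, o))
        assert sq.log_cosh_loss(o, r) > 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            sq.log_cosh_loss([1.0, 2.0], [1.0])


class TestXavierInit:
    def test_bound_is_sqrt_six_over_fan_sum(self, rng):
        w = sq.xavier_init(2, 4, rng)  # bound = sqrt(6/6) = 1
        assert w.shape == (4, 2)
        assert np.all(np.abs(w) <= 1.0)

    def test_moments_and_support(self):
        rng = np.random.default_rng(1)
        bound = math.sqrt(6.0 / 6.0)
        n = 100_000
        sample = np.concatenate(
            [sq.xavier_init(3, 3, rng).ravel() for _ in range(n // 9)]
        )
        se = bound / math.sqrt(3.0) / math.sqrt(len(sample))
        assert abs(sample.mean()) < 3 * se
        # order statistics: extremes approach the bound
        assert sample.max() > bound * 0.99
        assert sample.min() < -bound * 0.99

    def test_bound_never_exceeded_at_scale(self):
        rng = np.random.default_rng(2)
        bound = math.sqrt(6.0 / (40 + 25))
        w = sq.xavier_init(40, 25, rng)
        for _ in range(1000):
            w = sq.xavier_init(40, 25, rng)
            assert np.all(np.abs(w) < bound)


class TestMakeChunks:
    def _pairs(self, lengths, rng):
        return [
            sq.TrainingPair(
                input=rng.normal(size=n), target=rng.normal(size=n), provenance=str(n)
            )
            for n in lengths
        ]

    def _count_windows(self, batches):
        return sum(b["I"].shape[1] for b in batches)

    def test_exact_multiple_of_window(self, rng):
        cfg = TrainConfig(window_length=512, batch_size=8, seed=0)
        batches = make_chunks(self._pairs([1024], rng), cfg, np.random.default_rng(0))
        assert self._count_windows(batches) == 2
        assert all(b["mask"].all() for b in batches)

    def test_short_remainder_discarded(self, rng):
        # 700 = 512 + 188; 188 < 256 so the remainder is dropped
        cfg = TrainConfig(window_length=512, batch_size=8, seed=0)
        batches = make_chunks(self._pairs([700], rng), cfg, np.random.default_rng(0))
        assert self._count_windows(batches) == 1

    def test_long_remainder_padded_with_mask(self, rng):
        # 800 = 512 + 288; 288 >= 256 so it becomes a padded window
        cfg = TrainConfig(window_length=512, batch_size=8, seed=0)
        batches = make_chunks(self._pairs([800], rng), cfg, np.random.default_rng(0))
        assert self._count_windows(batches) == 2
        masks = np.concatenate([b["mask"].T for b in batches])
        valid_counts = sorted(int(m.sum()) for m in masks)
        assert valid_counts == [288, 512]

    def test_same_seed_gives_identical_batches(self, rng):
        pairs = self._pairs([1024, 800, 700], rng)
        cfg = TrainConfig(window_length=512, batch_size=2, seed=0)
        a = make_chunks(pairs, cfg, np.random.default_rng(9))
        b = make_chunks(pairs, cfg, np.random.default_rng(9))
        for ba, bb in zip(a, b):
            assert np.array_equal(ba["I"], bb["I"])
            assert np.array_equal(ba["mask"], bb["mask"])

    def test_all_pairs_too_short_rejected(self, rng):
        cfg = TrainConfig(window_length=512, batch_size=8, seed=0)
        with pytest.raises(ValidationError):
            make_chunks(self._pairs([100, 200], rng), cfg, np.random.default_rng(0))


class TestTrain:
    def _tiny_dataset(self, n_pairs=20, seq_length=100, seed=1):
        pairs, _ = sq.make_dataset(n_pairs, seq_length, seed=seed)
        return pairs

    def test_zero_iterations_returns_initialized_network(self):
        pairs = self._tiny_dataset()
        cfg = TrainConfig(hidden_size=8, iterations=0, window_length=256, seed=3)
        net, losses = sq.train(None, pairs, cfg)
        reference = sq.initialize_network(
            hidden_size=8, n_layers=3, rng=np.random.default_rng(3)
        )
        assert len(losses) == 0
        for ours, ref in zip(net.parameters(), reference.parameters()):
            assert np.array_equal(ours, ref)

    def test_loss_decreases_on_synthetic_data(self):
        pairs = self._tiny_dataset(20, 100, seed=1)
        cfg = TrainConfig(
            hidden_size=8, iterations=100, window_length=256, batch_size=32,
            learning_rate=1e-3, seed=1,
        )
        _, losses = sq.train(None, pairs, cfg)
        assert losses[-10:].mean() < losses[:10].mean()

    def test_training_is_bitwise_reproducible(self):
        pairs = self._tiny_dataset(6, 80, seed=2)
        cfg = TrainConfig(
            hidden_size=4, iterations=5, window_length=64, batch_size=8, seed=4
        )
        net_a, losses_a = sq.train(None, pairs, cfg)
        net_b, losses_b = sq.train(None, pairs, cfg)
        assert np.array_equal(losses_a, losses_b)
        for pa, pb in zip(net_a.parameters(), net_b.parameters()):
            assert np.array_equal(pa, pb)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(12)
        net = sq.initialize_network(hidden_size=3, n_layers=2, rng=rng)
        batch = {
            "I": rng.normal(size=(9, 2)),
            "R": rng.normal(size=(9, 2)),
            "mask": np.ones((9, 2), dtype=bool),
        }
        batch["mask"][-2:, 1] = False  # exercise the padding mask
        _, grads, dfc_b = batch_loss_and_grads(net, batch)
        params = net.parameters()

        def loss_of():
            l, _, _ = batch_loss_and_grads(net, batch)
            return l

        eps = 1e-6
        for arr, g in zip(params, grads):
            flat_idx = rng.integers(arr.size)
            idx = np.unravel_index(flat_idx, arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss_of()
            arr[idx] = orig - eps
            lm = loss_of()
            arr[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-7, rel=1e-5)
        net.fc_bias += eps
        lp = loss_of()
        net.fc_bias -= 2 * eps
        lm = loss_of()
        net.fc_bias += eps
        assert dfc_b == pytest.approx((lp - lm) / (2 * eps), abs=1e-7, rel=1e-5)

    def test_padded_positions_do_not_affect_loss(self):
        rng = np.random.default_rng(13)
        net = sq.initialize_network(hidden_size=3, n_layers=1, rng=rng)
        I = rng.normal(size=(8, 1))
        R = rng.normal(size=(8, 1))
        mask = np.ones((8, 1), dtype=bool)
        mask[-3:] = False
        loss_a, _, _ = batch_loss_and_grads(net, {"I": I, "R": R, "mask": mask})
        R2 = R.copy()
        R2[-3:] += 100.0  # huge residuals, but masked out
        loss_b, _, _ = batch_loss_and_grads(net, {"I": I, "R": R2, "mask": mask})
        assert loss_a == pytest.approx(loss_b, abs=1e-12)
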