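from __future__ import annotations

import numpy as np
import pytest

import squigru as sq
from squigru.bigru import gru_forward, load_checkpoint, save_checkpoint
from squigru.errors import ValidationError

from .conftest import random_gru_params
from .oracles import scalar_bigru_layer, scalar_gru_step, scalar_network_forward


def zero_params(d, m):
    return sq.GRUParams(
        Wz=np.zeros((d, d + m)), bz=np.zeros(d),
        Wr=np.zeros((d, d + m)), br=np.zeros(d),
        W=np.zeros((d, d + m)),
    )


class TestGruStep:
    def test_all_zero_weights_and_state_give_zero(self):
        # z = 0.5, candidate = tanh(0) = 0, so h = 0.5*0 + 0.5*0
        h = sq.gru_step(zero_params(3, 2), np.zeros(3), np.ones(2))
        assert np.array_equal(h, np.zeros(3))

    def test_zero_weights_halve_previous_state(self):
        v = np.array([0.4, -1.2, 2.0])
        h = sq.gru_step(zero_params(3, 2), v, np.ones(2))
        assert np.allclose(h, 0.5 * v, atol=1e-15)

    @pytest.mark.parametrize("candidate_bias", [False, True])
    def test_matches_scalar_oracle(self, candidate_bias):
        rng = np.random.default_rng(11)
        params = random_gru_params(rng, d=3, m=2, candidate_bias=candidate_bias)
        h_prev = rng.normal(size=3)
        x = rng.normal(size=2)
        ours = sq.gru_step(params, h_prev, x)
        oracle = scalar_gru_step(params, h_prev, x)
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        params = zero_params(3, 2)
        with pytest.raises(ValidationError):
            sq.gru_step(params, np.zeros(4), np.zeros(2))

    def test_gates_keep_state_in_unit_box(self):
        # h is a convex combination of h_prev and a tanh value, so it stays
        # inside [-1, 1] whenever the previous state does
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = random_gru_params(rng, d=4, m=3, scale=2.0)
            h = rng.uniform(-1, 1, size=4)
            for _ in range(10):
                h = sq.gru_step(params, h, rng.normal(size=3))
                assert np.all(np.abs(h) <= 1.0)


class TestGruForward:
    def test_sequence_matches_stepwise_iteration(self):
        rng = np.random.default_rng(2)
        params = random_gru_params(rng, d=5, m=3)
        X = rng.normal(size=(9, 3))
        H = gru_forward(params, X)
        h = np.zeros(5)
        for t in range(9):
            h = sq.gru_step(params, h, X[t])
            assert np.allclose(H[t], h, atol=1e-12)

    def test_batched_equals_per_sequence(self):
        rng = np.random.default_rng(3)
        params = random_gru_params(rng, d=4, m=2)
        X = rng.normal(size=(7, 2, 5))
        H = gru_forward(params, X)
        for b in range(5):
            Hb = gru_forward(params, X[:, :, b])
            assert np.allclose(H[:, :, b], Hb, atol=1e-12)


class TestBigruLayer:
    def test_single_step_output_width(self):
        rng = np.random.default_rng(4)
        fwd = random_gru_params(rng, d=3, m=2)
        out = sq.bigru_layer(fwd, fwd, np.ones((1, 2)))
        assert out.shape == (1, 6)
        # both directions see the same single input from a zero state
        assert np.allclose(out[:, :3], out[:, 3:], atol=1e-12)

    def test_palindromic_input_with_tied_params_is_symmetric(self):
        rng = np.random.default_rng(6)
        params = random_gru_params(rng, d=3, m=1)
        x = np.array([[0.3], [-1.0], [0.7], [-1.0], [0.3]])  # palindrome
        out = sq.bigru_layer(params, params, x)
        # forward half at t equals backward half at the mirrored time
        assert np.allclose(out[:, :3], out[::-1, 3:], atol=1e-12)

    def test_matches_compositional_oracle(self):
        rng = np.random.default_rng(7)
        fwd = random_gru_params(rng, d=4, m=3)
        bwd = random_gru_params(rng, d=4, m=3)
        X = rng.normal(size=(6, 3))
        ours = sq.bigru_layer(fwd, bwd, X)
        oracle = scalar_bigru_layer(fwd, bwd, [list(row) for row in X])
        assert np.allclose(ours, np.array(oracle), atol=1e-12)

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(8)
        p = random_gru_params(rng, d=2, m=1)
        with pytest.raises(ValidationError):
            sq.bigru_layer(p, p, np.empty((0, 1)))


class TestNetworkForward:
    def test_dead_head_gives_constant_output(self, rng):
        net = sq.initialize_network(hidden_size=4, n_layers=3, rng=rng)
        net.fc_weight[:] = 0.0
        net.fc_bias = 3.25
        out = sq.network_forward(net, rng.normal(size=20))
        assert np.allclose(out, 3.25, atol=1e-15)

    @pytest.mark.parametrize("length", [1, 2, 17, 100])
    def test_output_length_equals_input_length(self, length, rng):
        net = sq.initialize_network(hidden_size=4, n_layers=3, rng=rng)
        assert len(sq.network_forward(net, rng.normal(size=length))) == length

    @pytest.mark.parametrize("candidate_bias", [False, True])
    def test_matches_straight_line_oracle(self, candidate_bias):
        rng = np.random.default_rng(9)
        net = sq.initialize_network(
            hidden_size=4, n_layers=3, candidate_bias=candidate_bias, rng=rng
        )
        signal = rng.normal(size=12)
        ours = sq.network_forward(net, signal)
        oracle = scalar_network_forward(net, signal)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_forward_is_deterministic(self, rng):
        net = sq.initialize_network(hidden_size=3, n_layers=2, rng=rng)
        x = rng.normal(size=30)
        assert np.array_equal(sq.network_forward(net, x), sq.network_forward(net, x))


class TestCheckpoint:
    @pytest.mark.parametrize("candidate_bias", [False, True])
    def test_round_trip_preserves_behavior(self, tmp_path, candidate_bias):
        rng = np.random.default_rng(10)
        net = sq.initialize_network(
            hidden_size=5, n_layers=3, candidate_bias=candidate_bias, rng=rng
        )
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(net, path)
        loaded = load_checkpoint(path)
        assert loaded.hidden_size == 5
        assert loaded.candidate_bias == candidate_bias
        x = rng.normal(size=40)
        assert np.array_equal(
            sq.network_forward(net, x), sq.network_forward(loaded, x)
        )
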