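from __future__ import annotations

import numpy as np
import pytest

import squigru as sq
from squigru.bigru import network_forward
from squigru.training import TrainConfig, train


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


@pytest.fixture(scope="session")
def pore():
    return sq.synthetic_pore_model(1)


def random_gru_params(rng, d, m, candidate_bias=False, scale=0.5):
    return sq.GRUParams(
        Wz=rng.normal(scale=scale, size=(d, d + m)),
        bz=rng.normal(scale=scale, size=d),
        Wr=rng.normal(scale=scale, size=(d, d + m)),
        br=rng.normal(scale=scale, size=d),
        W=rng.normal(scale=scale, size=(d, d + m)),
        bc=rng.normal(scale=scale, size=d) if candidate_bias else None,
    )


@pytest.fixture(scope="session")
def trained_setup():
    """The default synthetic study: 200 reads, 150 train / 50 held out,
    a d=16 network trained for 300 Adam steps from seed 1.

    Built once per session; several tests interrogate different aspects of
    the same trained model.
    """
    reads = sq.generate_reads(200, 500, seed=1)
    train_reads, held_reads = reads[:150], reads[150:]
    config = TrainConfig(hidden_size=16, iterations=300, seed=1)
    initial_net = sq.initialize_network(
        hidden_size=16, n_layers=3, rng=np.random.default_rng(config.seed)
    )
    net, losses = train(None, [r.pair() for r in train_reads], config)

    def held_out_loss(network):
        total = count = 0.0
        for r in held_reads:
            out = network_forward(network, r.input)
            total += sq.log_cosh_loss(out, r.target)
            count += len(r.input)
        return total / count

    return {
        "reads": reads,
        "held_reads": held_reads,
        "config": config,
        "initial_net": initial_net,
        "net": net,
        "losses": losses,
        "held_out_loss": held_out_loss,
    }
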