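"""Independent straight-line reference implementations used only by tests.

Everything here is written as plain scalar loops against the defining
equations, deliberately sharing no code with the package internals, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_gru_step(params, h_prev, x):
    """One GRU update computed element by element from the gate equations."""
    d = len(params.bz)
    m = len(x)
    a = list(h_prev) + list(x)  # concatenation order [hidden, input]

    def sigmoid(v):
        return 1.0 / (1.0 + math.exp(-v))

    z = [sigmoid(sum(params.Wz[i][j] * a[j] for j in range(d + m)) + params.bz[i])
         for i in range(d)]
    r = [sigmoid(sum(params.Wr[i][j] * a[j] for j in range(d + m)) + params.br[i])
         for i in range(d)]
    ac = [r[i] * h_prev[i] for i in range(d)] + list(x)
    h_cand = []
    for i in range(d):
        u = sum(params.W[i][j] * ac[j] for j in range(d + m))
        if params.bc is not None:
            u += params.bc[i]
        h_cand.append(math.tanh(u))
    return [(1.0 - z[i]) * h_prev[i] + z[i] * h_cand[i] for i in range(d)]


def scalar_gru_sequence(params, inputs):
    """Hidden states over a sequence of input vectors, from zero state."""
    d = len(params.bz)
    h = [0.0] * d
    states = []
    for x in inputs:
        h = scalar_gru_step(params, h, x)
        states.append(h)
    return states


def scalar_bigru_layer(fwd, bwd, inputs):
    """Concatenate forward states and time-reversed backward states."""
    hf = scalar_gru_sequence(fwd, inputs)
    hr = scalar_gru_sequence(bwd, inputs[::-1])[::-1]
    return [f + r for f, r in zip(hf, hr)]


def scalar_network_forward(net, signal):
    """Full network output built by composing the scalar-step oracles."""
    inputs = [[float(v)] for v in signal]
    for fwd, bwd in net.layers:
        inputs = scalar_bigru_layer(fwd, bwd, inputs)
    w = list(net.fc_weight)
    return [sum(wi * yi for wi, yi in zip(w, y)) + net.fc_bias for y in inputs]


def dtw_cost_oracle(a, b):
    """Brute-force DTW dynamic program (cost only), local cost |a_i - b_j|."""
    n, m = len(a), len(b)
    INF = float("inf")
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(a[i - 1] - b[j - 1])
            D[i][j] = cost + min(D[i - 1][j], D[i][j - 1], D[i - 1][j - 1])
    return D[n][m]


def lowpass_amplitude_ratio(spec, freq_hz, length=4000):
    """Measured amplitude of a pure sine after filtering, relative to input."""
    from squigru.lowpass import lowpass_filter

    t = np.arange(length) / spec.sample_rate_hz
    x = np.sin(2.0 * np.pi * freq_hz * t)
    y = lowpass_filter(x, spec)
    core = slice(spec.kernel_length, length - spec.kernel_length)
    return float(np.abs(y[core]).max() / np.abs(x[core]).max())
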