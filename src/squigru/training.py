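"""Training of the BiGRU signal-processing network.

Supervised pairs (normalized ground-truth input I, target signal R of the same
length) are cut into fixed-length windows, shuffled, batched, and fitted by
minimizing the Log-Cosh regression loss

    L(R, O) = sum_i log cosh(o_i - r_i)

with the Adam optimizer.  Weight matrices start from Xavier (Glorot) uniform
draws on +-sqrt(6 / (n_in + n_out)); biases start at zero.  The per-batch
objective is the *mean* Log-Cosh over valid (non-padded) positions so the
window length does not rescale the learning rate; the raw per-read sum is
exposed unchanged as :func:`log_cosh_loss`.

Gradients are computed by exact backpropagation through time written directly
against the GRU recurrence (see :mod:`squigru.bigru`); no autodiff framework
is involved, which keeps runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import ctypes
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bigru import BiGRUNetwork, GRUParams, gru_backward, gru_forward
from .errors import SquigruError, ValidationError

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class TrainingPair:
    """Aligned (input, target) signals of equal length, both already scaled."""

    input: np.ndarray
    target: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        inp = np.asarray(self.input, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "input", inp)
        object.__setattr__(self, "target", tgt)
        if inp.shape != tgt.shape or inp.ndim != 1:
            raise ValidationError(
                f"input/target must be equal-length 1-D arrays, got "
                f"{inp.shape} vs {tgt.shape}"
            )
        if not (np.all(np.isfinite(inp)) and np.all(np.isfinite(tgt))):
            raise ValidationError("training pair contains non-finite values")

    def __len__(self) -> int:
        return len(self.input)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    iterations: int = 1000
    window_length: int = 512
    seed: int = 0
    candidate_bias: bool = False
    hidden_size: int = 64
    n_layers: int = 3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.iterations < 0:
            raise ValidationError("learning_rate/batch_size/iterations must be positive")
        if self.window_length < 8:
            raise ValidationError("window_length must be >= 8")
        if self.hidden_size < 1 or self.n_layers < 1:
            raise ValidationError("hidden_size and n_layers must be >= 1")


def log_cosh_loss(O: Sequence[float] | np.ndarray, R: Sequence[float] | np.ndarray) -> float:
    """Sum of log cosh(o_i - r_i); overflow-safe via logaddexp."""
    O = np.asarray(O, dtype=float)
    R = np.asarray(R, dtype=float)
    if O.shape != R.shape or O.ndim != 1 or O.size < 1:
        raise ValidationError("O and R must be equal-length non-empty 1-D arrays")
    return float(np.sum(_log_cosh(O - R)))


def mean_log_cosh(O: np.ndarray, R: np.ndarray) -> float:
    """Per-position mean of the Log-Cosh loss (the training objective scale)."""
    return log_cosh_loss(O, R) / len(np.asarray(O))


def _log_cosh(x: np.ndarray) -> np.ndarray:
    # log cosh x = log((e^x + e^-x) / 2) = logaddexp(x, -x) - log 2
    return np.logaddexp(x, -x) - LOG2


def xavier_init(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    """Glorot-uniform matrix of shape (n_out, n_in), bound sqrt(6/(n_in+n_out))."""
    if n_in < 1 or n_out < 1:
        raise ValidationError("n_in and n_out must be >= 1")
    bound = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-bound, bound, size=(n_out, n_in))


def initialize_network(
    hidden_size: int = 64,
    n_layers: int = 3,
    candidate_bias: bool = False,
    rng: np.random.Generator | None = None,
) -> BiGRUNetwork:
    """Xavier-initialized BiGRU stack with zero biases and scalar output head."""
    if rng is None:
        rng = np.random.default_rng()
    d = hidden_size
    layers = []
    for li in range(n_layers):
        m = 1 if li == 0 else 2 * d
        pair = []
        for _direction in range(2):
            pair.append(
                GRUParams(
                    Wz=xavier_init(d + m, d, rng),
                    bz=np.zeros(d),
                    Wr=xavier_init(d + m, d, rng),
                    br=np.zeros(d),
                    W=xavier_init(d + m, d, rng),
                    bc=np.zeros(d) if candidate_bias else None,
                )
            )
        layers.append(tuple(pair))
    fc_weight = xavier_init(2 * d, 1, rng).ravel()
    return BiGRUNetwork(layers=tuple(layers), fc_weight=fc_weight, fc_bias=0.0)


# ---------------------------------------------------------------------------
# batching


def make_chunks(
    pairs: Sequence[TrainingPair],
    config: TrainConfig,
    rng: np.random.Generator,
) -> list[dict[str, np.ndarray]]:
    """Window, shuffle and batch training pairs for one pass.

    Each pair is sliced into non-overlapping windows of ``window_length``.  A
    final remainder shorter than half a window is discarded; otherwise it is
    zero-padded and flagged in the padding mask so the loss ignores it.
    Returns batches as dicts with keys ``I``, ``R`` (window_length, batch) and
    boolean ``mask`` of valid positions.
    """
    if not pairs:
        raise ValidationError("no training pairs given")
    W = config.window_length
    windows: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for pair in pairs:
        L = len(pair)
        n_full = L // W
        for k in range(n_full):
            sl = slice(k * W, (k + 1) * W)
            windows.append(
                (pair.input[sl], pair.target[sl], np.ones(W, dtype=bool))
            )
        rem = L - n_full * W
        if rem >= W / 2:
            i_pad = np.zeros(W)
            r_pad = np.zeros(W)
            mask = np.zeros(W, dtype=bool)
            i_pad[:rem] = pair.input[n_full * W:]
            r_pad[:rem] = pair.target[n_full * W:]
            mask[:rem] = True
            windows.append((i_pad, r_pad, mask))
    if not windows:
        raise ValidationError(
            f"all pairs are shorter than window_length/2 = {W / 2:g}; "
            "nothing to train on"
        )
    order = rng.permutation(len(windows))
    batches = []
    for start in range(0, len(order), config.batch_size):
        idx = order[start : start + config.batch_size]
        batches.append(
            {
                "I": np.stack([windows[i][0] for i in idx], axis=1),
                "R": np.stack([windows[i][1] for i in idx], axis=1),
                "mask": np.stack([windows[i][2] for i in idx], axis=1),
            }
        )
    return batches


# ---------------------------------------------------------------------------
# forward/backward through the full network


def _forward_with_cache(net: BiGRUNetwork, I: np.ndarray):
    """Batched forward pass keeping per-layer caches.  ``I``: (T, B)."""
    y = I[:, None, :]  # (T, 1, B)
    layer_caches = []
    d = net.hidden_size
    for fwd, bwd in net.layers:
        hf, cf = gru_forward(fwd, y, return_cache=True)
        hr_rev, cb = gru_forward(bwd, y[::-1], return_cache=True)
        y = np.concatenate([hf, hr_rev[::-1]], axis=1)
        layer_caches.append((cf, cb))
    O = np.einsum("tdb,d->tb", y, net.fc_weight) + net.fc_bias
    return O, y, layer_caches


def _backward(net: BiGRUNetwork, dO: np.ndarray, y_last: np.ndarray, layer_caches):
    """Gradients for every parameter given dLoss/dO of shape (T, B)."""
    d = net.hidden_size
    dfc_w = np.einsum("tb,tdb->d", dO, y_last)
    dfc_b = float(dO.sum())
    dY = net.fc_weight[None, :, None] * dO[:, None, :]
    layer_grads: list[tuple[dict, dict]] = [None] * len(net.layers)
    for li in range(len(net.layers) - 1, -1, -1):
        fwd, bwd = net.layers[li]
        cf, cb = layer_caches[li]
        dHf = dY[:, :d]
        dHr_rev = dY[::-1, d:]
        dXf, gf = gru_backward(fwd, cf, np.ascontiguousarray(dHf))
        dXr_rev, gb = gru_backward(bwd, cb, np.ascontiguousarray(dHr_rev))
        dY = dXf + dXr_rev[::-1]
        layer_grads[li] = (gf, gb)
    return layer_grads, dfc_w, dfc_b


def _flatten_grads(net: BiGRUNetwork, layer_grads, dfc_w) -> list[np.ndarray]:
    flat: list[np.ndarray] = []
    for (gf, gb), (pf, pb) in zip(layer_grads, net.layers):
        for g, p in ((gf, pf), (gb, pb)):
            flat.extend([g["Wz"], g["bz"], g["Wr"], g["br"], g["W"]])
            if p.bc is not None:
                flat.append(g["bc"])
    flat.append(dfc_w)
    return flat


def batch_loss_and_grads(net: BiGRUNetwork, batch: dict[str, np.ndarray]):
    """Mean-per-valid-position Log-Cosh loss of one batch and its gradients."""
    I, R, mask = batch["I"], batch["R"], batch["mask"]
    O, y_last, caches = _forward_with_cache(net, I)
    resid = O - R
    n_valid = int(mask.sum())
    loss = float(np.sum(_log_cosh(resid) * mask) / n_valid)
    dO = np.tanh(resid) * mask / n_valid
    layer_grads, dfc_w, dfc_b = _backward(net, dO, y_last, caches)
    return loss, _flatten_grads(net, layer_grads, dfc_w), dfc_b


_ALLOCATOR_TUNED = False


def _keep_heap_buffers() -> None:
    """Stop glibc from returning the BPTT cache pages to the OS every step.

    Each optimizer step allocates on the order of 100 MB of short-lived
    caches; with the default malloc thresholds these are mmap'd and unmapped
    every step, and the resulting page faults can dominate the runtime of the
    whole training loop.  Raising the trim threshold and disabling mmap for
    large blocks keeps the buffers in the heap for reuse.  Silently a no-op
    on platforms without glibc's mallopt.
    """
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, 2**31 - 1)  # M_TRIM_THRESHOLD
        libc.mallopt(-4, 0)          # M_MMAP_MAX
    except (OSError, AttributeError):
        pass
    _ALLOCATOR_TUNED = True


class _Adam:
    """Plain Adam over a list of parameter arrays updated in place."""

    def __init__(self, params: list[np.ndarray], lr, beta1, beta2, eps):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def train(
    net: BiGRUNetwork | None,
    pairs: Sequence[TrainingPair],
    config: TrainConfig,
) -> tuple[BiGRUNetwork, np.ndarray]:
    """Fit the network with Adam; returns (trained net, per-step loss history).

    If ``net`` is None a fresh Xavier-initialized network is built from the
    config.  Training is bit-reproducible for a given config seed.
    """
    _keep_heap_buffers()
    rng = np.random.default_rng(config.seed)
    if net is None:
        net = initialize_network(
            hidden_size=config.hidden_size,
            n_layers=config.n_layers,
            candidate_bias=config.candidate_bias,
            rng=rng,
        )
    params = net.parameters()
    adam = _Adam(
        params, config.learning_rate, config.adam_beta1, config.adam_beta2,
        config.adam_eps,
    )
    fc_bias = np.array(net.fc_bias)
    adam_bias = _Adam(
        [fc_bias], config.learning_rate, config.adam_beta1, config.adam_beta2,
        config.adam_eps,
    )
    losses: list[float] = []
    batches: list = []
    step = 0
    while step < config.iterations:
        if not batches:
            batches = make_chunks(pairs, config, rng)
        batch = batches.pop(0)
        loss, grads, dfc_b = batch_loss_and_grads(net, batch)
        if not math.isfinite(loss):
            raise SquigruError(
                f"non-finite loss at step {step}; check the learning rate and "
                "that the training pairs are sensibly scaled"
            )
        losses.append(loss)
        adam.step(grads)
        adam_bias.step([np.array(dfc_b)])
        net.fc_bias = float(fc_bias)
        step += 1
    return net, np.asarray(losses)
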