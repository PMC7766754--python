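"""Bidirectional GRU signal-processing network, implemented directly in numpy.

The network replaces the baseline low-pass filter: a normalized ground-truth
signal goes in, a filtered signal of the same length comes out.  Architecture:
three stacked bidirectional GRU layers followed by a per-time-step fully
connected scalar head.

A single GRU step computes, with sigma the logistic function and ``o`` the
element-wise product, on the concatenation ``[h_prev, i_t]``::

    z  = sigma(Wz [h_prev, i_t] + bz)        update gate
    r  = sigma(Wr [h_prev, i_t] + br)        reset gate
    h' = tanh(W [r o h_prev, i_t] (+ bc))    candidate state
    h  = (1 - z) o h_prev + z o h'

The candidate state carries no bias by default (``candidate_bias=False``);
an optional bias term turns it into the standard framework GRU cell.  The
bidirectional layer runs the same recurrence left-to-right and right-to-left
from zero initial states and concatenates the two hidden states per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit as _sigmoid

from .errors import ValidationError


@dataclass
class GRUParams:
    """Weights of one GRU direction.

    Each weight matrix has shape ``(d, d + m)`` and acts on the concatenation
    of the previous hidden state (d) and the current input (m), in that order.
    ``bc`` is the optional candidate-state bias (None = as-printed cell).
    """

    Wz: np.ndarray
    bz: np.ndarray
    Wr: np.ndarray
    br: np.ndarray
    W: np.ndarray
    bc: np.ndarray | None = None

    def __post_init__(self) -> None:
        d, dm = self.Wz.shape
        m = dm - d
        if m < 1:
            raise ValidationError("weight matrices must have width d + m with m >= 1")
        for name in ("Wz", "Wr", "W"):
            mat = getattr(self, name)
            if mat.shape != (d, dm):
                raise ValidationError(f"{name} has shape {mat.shape}, expected {(d, dm)}")
        for name in ("bz", "br"):
            vec = getattr(self, name)
            if vec.shape != (d,):
                raise ValidationError(f"{name} has shape {vec.shape}, expected {(d,)}")
        if self.bc is not None and self.bc.shape != (d,):
            raise ValidationError(f"bc has shape {self.bc.shape}, expected {(d,)}")
        for name in ("Wz", "bz", "Wr", "br", "W", "bc"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")

    @property
    def hidden_size(self) -> int:
        return self.Wz.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[1] - self.Wz.shape[0]


def gru_step(params: GRUParams, h_prev: np.ndarray, i_t: np.ndarray) -> np.ndarray:
    """One GRU update.  ``h_prev``: (d,) or (d, B); ``i_t``: (m,) or (m, B)."""
    squeeze = h_prev.ndim == 1
    h = h_prev[:, None] if squeeze else h_prev
    x = i_t[:, None] if squeeze else np.asarray(i_t)
    d = params.hidden_size
    if h.shape[0] != d or x.shape[0] != params.input_size:
        raise ValidationError(
            f"state/input widths {h.shape[0]}/{x.shape[0]} do not match "
            f"params (d={d}, m={params.input_size})"
        )
    a = np.concatenate([h, x], axis=0)
    z = _sigmoid(params.Wz @ a + params.bz[:, None])
    r = _sigmoid(params.Wr @ a + params.br[:, None])
    ac = np.concatenate([r * h, x], axis=0)
    u = params.W @ ac
    if params.bc is not None:
        u = u + params.bc[:, None]
    hc = np.tanh(u)
    h_new = (1.0 - z) * h + z * hc
    return h_new[:, 0] if squeeze else h_new


def gru_forward(
    params: GRUParams, inputs: np.ndarray, return_cache: bool = False
):
    """Run the recurrence over a sequence.  ``inputs``: (T, m) or (T, m, B).

    Returns hidden states of shape (T, d) or (T, d, B); with
    ``return_cache=True`` also returns the intermediates needed for
    backpropagation through time.

    The input-side contribution of each weight matrix is hoisted out of the
    time loop into one large matrix product per gate; only the (d, d)
    recurrent products remain sequential.
    """
    squeeze = inputs.ndim == 2
    X = inputs[:, :, None] if squeeze else inputs
    T, m, B = X.shape
    d = params.hidden_size
    if m != params.input_size:
        raise ValidationError(f"input width {m} != params input size {params.input_size}")
    # split combined (d, d + m) weights into recurrent and input parts
    Wzh, Wzx = params.Wz[:, :d], params.Wz[:, d:]
    Wrh, Wrx = params.Wr[:, :d], params.Wr[:, d:]
    Wch, Wcx = params.W[:, :d], params.W[:, d:]
    X_flat = np.ascontiguousarray(X.transpose(1, 0, 2).reshape(m, T * B))
    Uz = (Wzx @ X_flat).reshape(d, T, B) + params.bz[:, None, None]
    Ur = (Wrx @ X_flat).reshape(d, T, B) + params.br[:, None, None]
    Uc = (Wcx @ X_flat).reshape(d, T, B)
    if params.bc is not None:
        Uc = Uc + params.bc[:, None, None]
    H = np.empty((T, d, B))
    Z = np.empty((T, d, B)) if return_cache else None
    R = np.empty((T, d, B)) if return_cache else None
    Hc = np.empty((T, d, B)) if return_cache else None
    h = np.zeros((d, B))
    for t in range(T):
        z = _sigmoid(Wzh @ h + Uz[:, t])
        r = _sigmoid(Wrh @ h + Ur[:, t])
        hc = np.tanh(Wch @ (r * h) + Uc[:, t])
        h = (1.0 - z) * h + z * hc
        H[t] = h
        if return_cache:
            Z[t], R[t], Hc[t] = z, r, hc
    out = H[:, :, 0] if squeeze else H
    if return_cache:
        return out, {"Z": Z, "R": R, "Hc": Hc, "H": H, "X": X, "X_flat": X_flat}
    return out


def gru_backward(params: GRUParams, cache: dict, dH: np.ndarray):
    """Backpropagate through :func:`gru_forward`.

    ``dH``: gradient w.r.t. the hidden-state sequence, shape (T, d, B).
    Returns (dX, grads) where grads maps parameter names to gradients.

    The sequential scan only propagates the hidden-state carry; all
    parameter-gradient and input-gradient products are batched over time
    afterwards.
    """
    Z, R, Hc, H, X = cache["Z"], cache["R"], cache["Hc"], cache["H"], cache["X"]
    X_flat = cache["X_flat"]
    T, d, B = H.shape
    m = X.shape[1]
    Wzh = params.Wz[:, :d]
    Wrh = params.Wr[:, :d]
    Wch = params.W[:, :d]
    DVZ = np.empty((T, d, B))
    DVR = np.empty((T, d, B))
    DU = np.empty((T, d, B))
    zeros = np.zeros((d, B))
    carry = np.zeros((d, B))
    WzhT, WrhT, WchT = Wzh.T.copy(), Wrh.T.copy(), Wch.T.copy()
    for t in range(T - 1, -1, -1):
        h_prev = H[t - 1] if t > 0 else zeros
        z, r, hc = Z[t], R[t], Hc[t]
        dh = dH[t] + carry
        dz = dh * (hc - h_prev)
        dhc = dh * z
        dh_prev = dh * (1.0 - z)
        du = dhc * (1.0 - hc * hc)
        drh = WchT @ du  # gradient w.r.t. (r o h_prev)
        dr = drh * h_prev
        dh_prev += drh * r
        dvz = dz * z * (1.0 - z)
        dvr = dr * r * (1.0 - r)
        dh_prev += WzhT @ dvz + WrhT @ dvr
        DVZ[t], DVR[t], DU[t] = dvz, dvr, du
        carry = dh_prev
    # batched parameter/input gradients over all time steps
    to_flat = lambda A: np.ascontiguousarray(A.transpose(1, 0, 2).reshape(d, T * B))
    DVZf, DVRf, DUf = to_flat(DVZ), to_flat(DVR), to_flat(DU)
    Hprev = np.concatenate([zeros[None], H[:-1]], axis=0)
    Hprev_f = to_flat(Hprev)
    RHprev_f = to_flat(R * Hprev)
    dWz = np.concatenate([DVZf @ Hprev_f.T, DVZf @ X_flat.T], axis=1)
    dWr = np.concatenate([DVRf @ Hprev_f.T, DVRf @ X_flat.T], axis=1)
    dW = np.concatenate([DUf @ RHprev_f.T, DUf @ X_flat.T], axis=1)
    dX_flat = params.Wz[:, d:].T @ DVZf + params.Wr[:, d:].T @ DVRf + params.W[:, d:].T @ DUf
    dX = np.ascontiguousarray(dX_flat.reshape(m, T, B).transpose(1, 0, 2))
    grads = {
        "Wz": dWz, "bz": DVZf.sum(axis=1),
        "Wr": dWr, "br": DVRf.sum(axis=1),
        "W": dW,
    }
    if params.bc is not None:
        grads["bc"] = DUf.sum(axis=1)
    return dX, grads


def bigru_layer(fwd: GRUParams, bwd: GRUParams, inputs: np.ndarray) -> np.ndarray:
    """One bidirectional layer: concat forward and time-reversed backward states.

    ``inputs``: (T, m) or (T, m, B); output width is 2d.
    """
    if inputs.shape[0] == 0:
        raise ValidationError("input sequence must be non-empty")
    if fwd.hidden_size != bwd.hidden_size or fwd.input_size != bwd.input_size:
        raise ValidationError("forward and backward parameter shapes must agree")
    hf = gru_forward(fwd, inputs)
    hr = gru_forward(bwd, inputs[::-1])[::-1]
    return np.concatenate([hf, hr], axis=1)


@dataclass
class BiGRUNetwork:
    """Stack of bidirectional GRU layers plus a per-step scalar output head."""

    layers: tuple[tuple[GRUParams, GRUParams], ...]
    fc_weight: np.ndarray
    fc_bias: float

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("network needs at least one layer")
        d = self.layers[0][0].hidden_size
        for li, (fwd, bwd) in enumerate(self.layers):
            expect_m = 1 if li == 0 else 2 * d
            for name, p in (("forward", fwd), ("backward", bwd)):
                if p.hidden_size != d:
                    raise ValidationError("all layers must share the hidden size")
                if p.input_size != expect_m:
                    raise ValidationError(
                        f"layer {li} {name} input size {p.input_size}, expected {expect_m}"
                    )
        self.fc_weight = np.asarray(self.fc_weight, dtype=float).ravel()
        if self.fc_weight.shape != (2 * d,):
            raise ValidationError(
                f"fc_weight has shape {self.fc_weight.shape}, expected {(2 * d,)}"
            )
        self.fc_bias = float(self.fc_bias)

    @property
    def hidden_size(self) -> int:
        return self.layers[0][0].hidden_size

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def candidate_bias(self) -> bool:
        return self.layers[0][0].bc is not None

    def parameters(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (order is stable; fc_bias excluded —
        use :meth:`set_fc_bias`)."""
        out: list[np.ndarray] = []
        for fwd, bwd in self.layers:
            for p in (fwd, bwd):
                out.extend([p.Wz, p.bz, p.Wr, p.br, p.W])
                if p.bc is not None:
                    out.append(p.bc)
        out.append(self.fc_weight)
        return out


def network_forward(net: BiGRUNetwork, normalized_signal: np.ndarray) -> np.ndarray:
    """Filter a normalized signal; output has the same length as the input.

    Accepts a 1-D signal (T,) or a batch (T, B).
    """
    x = np.asarray(normalized_signal, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 1:
        raise ValidationError("signal must have length >= 1")
    y = x[:, None, :]  # (T, 1, B)
    for fwd, bwd in net.layers:
        y = bigru_layer(fwd, bwd, y)
    out = np.einsum("tdb,d->tb", y, net.fc_weight) + net.fc_bias
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# checkpoint I/O

CHECKPOINT_VERSION = 1


def save_checkpoint(net: BiGRUNetwork, path: str | Path) -> None:
    """Store all matrices plus architecture metadata in a single npz archive."""
    arrays: dict[str, np.ndarray] = {
        "version": np.array(CHECKPOINT_VERSION),
        "hidden_size": np.array(net.hidden_size),
        "n_layers": np.array(net.n_layers),
        "candidate_bias": np.array(int(net.candidate_bias)),
        "fc_weight": net.fc_weight,
        "fc_bias": np.array(net.fc_bias),
    }
    for li, (fwd, bwd) in enumerate(net.layers):
        for tag, p in (("f", fwd), ("b", bwd)):
            prefix = f"l{li}{tag}_"
            arrays[prefix + "Wz"] = p.Wz
            arrays[prefix + "bz"] = p.bz
            arrays[prefix + "Wr"] = p.Wr
            arrays[prefix + "br"] = p.br
            arrays[prefix + "W"] = p.W
            if p.bc is not None:
                arrays[prefix + "bc"] = p.bc
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> BiGRUNetwork:
    with np.load(path) as data:
        version = int(data["version"])
        if version != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version {version}")
        n_layers = int(data["n_layers"])
        layers = []
        for li in range(n_layers):
            pair = []
            for tag in ("f", "b"):
                prefix = f"l{li}{tag}_"
                pair.append(
                    GRUParams(
                        Wz=data[prefix + "Wz"],
                        bz=data[prefix + "bz"],
                        Wr=data[prefix + "Wr"],
                        br=data[prefix + "br"],
                        W=data[prefix + "W"],
                        bc=data[prefix + "bc"] if prefix + "bc" in data else None,
                    )
                )
            layers.append(tuple(pair))
        return BiGRUNetwork(
            layers=tuple(layers),
            fc_weight=data["fc_weight"],
            fc_bias=float(data["fc_bias"]),
        )
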