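"""From-scratch FIRNN, LSTM and GRU forward recall with full traces.

All three networks share the same outer structure: a single hidden
layer of NH units consuming the last ND samples of a 6-channel window,
followed by a dense softmax readout over NC classes from the final
hidden vector.

* FIRNN — each hidden unit's synapses are finite impulse response
  filters: taps j = 1..ND over each input channel i, so the hidden
  pre-activation is sum_ij w[i,j,h] x_i(n-j+1) - b_h evaluated once at
  the readout time, squashed by a logistic sigmoid.
* LSTM — standard gated recurrence: input/forget/output gates (sigmoid)
  and a tanh cell candidate, each an affine map of the current input
  and previous hidden state; cell c_t = f_t*c_{t-1} + i_t*cand_t and
  hidden h_t = o_t*tanh(c_t), zero initial states.
* GRU — update/reset gates and a tanh candidate whose recurrent term is
  reset-gated; hidden h_t = u_t*h_{t-1} + (1-u_t)*cand_t.

Hidden-layer and gate biases are subtracted (pre = z - b), matching the
recall equations; the readout uses the conventional additive bias.
Traces expose every intermediate needed by relevance propagation:
inputs, gate activations, candidate pre-activations, cell and hidden
state sequences, logits and class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .dims import ARCHS, ArchDims
from .synthetic import SensorWindow

__all__ = [
    "ARCHS",
    "ArchDims",
    "FIRNNParams",
    "LSTMParams",
    "GRUParams",
    "ForwardTrace",
    "softmax",
    "init_params",
    "firnn_forward",
    "lstm_forward",
    "gru_forward",
    "forward",
    "forward_batch",
    "predict",
    "predict_batch",
    "save_params",
    "load_params",
]

#: Variance of the initialization normal N(0, 0.001).
INIT_VARIANCE = 1e-3

LSTM_GATES = ("i", "f", "o")
GRU_GATES = ("u", "r")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class FIRNNParams:
    """FIR weight tensor (NI, ND, NH), hidden bias, dense readout."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def param_items(self):
        return [("w1", self.w1), ("b1", self.b1), ("w2", self.w2), ("b2", self.b2)]

    @property
    def n_params(self) -> int:
        return sum(a.size for _, a in self.param_items())


@dataclass
class _GatedParams:
    """Shared layout for LSTM/GRU: per-gate input/recurrent/bias blocks."""

    wx: dict[str, np.ndarray]  # gate -> (NI, NH)
    wh: dict[str, np.ndarray]  # gate -> (NH, NH)
    b: dict[str, np.ndarray]   # gate -> (NH,)
    w2: np.ndarray
    b2: np.ndarray
    gate_names: tuple[str, ...] = ()

    def param_items(self):
        items = []
        for g in self.gate_names:
            items += [(f"wx_{g}", self.wx[g]), (f"wh_{g}", self.wh[g]), (f"b_{g}", self.b[g])]
        items += [("w2", self.w2), ("b2", self.b2)]
        return items

    @property
    def n_params(self) -> int:
        return sum(a.size for _, a in self.param_items())


@dataclass
class LSTMParams(_GatedParams):
    """Gate blocks for input (i), forget (f), output (o), candidate (c)."""

    gate_names: tuple[str, ...] = ("i", "f", "o", "c")


@dataclass
class GRUParams(_GatedParams):
    """Gate blocks for update (u), reset (r), candidate (c)."""

    gate_names: tuple[str, ...] = ("u", "r", "c")


def init_params(arch: str, dims: ArchDims, seed: int):
    """Draw every weight and bias i.i.d. from N(0, 0.001).

    The scalar count of the returned container equals the closed-form
    weight count of :func:`dynhar.complexity.complexity_profile`.
    """
    dims.validate()
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(INIT_VARIANCE))
    ni, nd, nh, nc = dims.ni, dims.nd, dims.nh, dims.nc
    if arch == "firnn":
        return FIRNNParams(
            w1=rng.normal(0, sd, (ni, nd, nh)),
            b1=rng.normal(0, sd, nh),
            w2=rng.normal(0, sd, (nh, nc)),
            b2=rng.normal(0, sd, nc),
        )
    if arch in ("lstm", "gru"):
        cls = LSTMParams if arch == "lstm" else GRUParams
        gates = cls.gate_names
        wx = {g: rng.normal(0, sd, (ni, nh)) for g in gates}
        wh = {g: rng.normal(0, sd, (nh, nh)) for g in gates}
        b = {g: rng.normal(0, sd, nh) for g in gates}
        return cls(
            wx=wx, wh=wh, b=b,
            w2=rng.normal(0, sd, (nh, nc)),
            b2=rng.normal(0, sd, nc),
        )
    raise ValueError(f"unknown architecture {arch!r}; expected one of {ARCHS}")


# ---------------------------------------------------------------------------
# Forward passes (batched core + single-window trace wrappers)


@dataclass
class ForwardTrace:
    """All intermediates of one window's forward recall.

    ``hidden`` is (NH,) for FIRNN (readout time only) and (ND, NH) for
    the recurrent nets.  ``gates``/``pre_gates`` hold per-gate (ND, NH)
    sequences; ``candidate``/``pre_candidate`` the tanh candidate and
    its pre-activation; ``cell`` the LSTM cell-state sequence.  ``nt``
    records the full window length so relevance maps can be laid out on
    the original time axis.
    """

    arch: str
    dims: ArchDims
    nt: int
    inputs: np.ndarray            # (ND, NI) consumed suffix
    hidden: np.ndarray
    logits: np.ndarray            # (NC,)
    probs: np.ndarray             # (NC,)
    pre_hidden: np.ndarray | None = None
    gates: dict[str, np.ndarray] = field(default_factory=dict)
    pre_gates: dict[str, np.ndarray] = field(default_factory=dict)
    candidate: np.ndarray | None = None
    pre_candidate: np.ndarray | None = None
    cell: np.ndarray | None = None

    @property
    def final_hidden(self) -> np.ndarray:
        return self.hidden if self.hidden.ndim == 1 else self.hidden[-1]


def _check_window(X: np.ndarray, dims: ArchDims) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] < dims.nd:
        raise ValueError(
            f"window has {X.shape[1]} time steps, fewer than ND={dims.nd}"
        )
    if X.shape[2] != dims.ni:
        raise ValueError(f"window has {X.shape[2]} channels, expected NI={dims.ni}")
    return X


def firnn_forward_batch(params: FIRNNParams, X: np.ndarray, dims: ArchDims) -> dict:
    """Batched FIRNN recall on X of shape (B, T, NI); consumes last ND."""
    X = _check_window(X, dims)
    xs = X[:, -dims.nd :, :]               # (B, ND, NI), time ascending
    xtap = xs[:, ::-1, :]                  # tap j (0-based) reads x(n-j)
    # pre_h = sum_ij w1[i,j,h] * xtap[b,j,i] - b1[h]
    pre = np.einsum("ijh,bji->bh", params.w1, xtap) - params.b1
    hidden = _sigmoid(pre)
    logits = hidden @ params.w2 + params.b2
    return {
        "inputs": xs,
        "pre_hidden": pre,
        "hidden": hidden,
        "logits": logits,
        "probs": softmax(logits),
    }


def lstm_forward_batch(params: LSTMParams, X: np.ndarray, dims: ArchDims) -> dict:
    X = _check_window(X, dims)
    xs = X[:, -dims.nd :, :]
    B, nd, _ = xs.shape
    nh = dims.nh
    h = np.zeros((B, nh))
    c = np.zeros((B, nh))
    seq = {k: np.zeros((B, nd, nh)) for k in ("i", "f", "o", "cand", "c", "h")}
    pre_seq = {k: np.zeros((B, nd, nh)) for k in ("i", "f", "o", "c")}
    for t in range(nd):
        x_t = xs[:, t, :]
        pre = {
            g: x_t @ params.wx[g] + h @ params.wh[g] - params.b[g]
            for g in ("i", "f", "o", "c")
        }
        i_t = _sigmoid(pre["i"])
        f_t = _sigmoid(pre["f"])
        o_t = _sigmoid(pre["o"])
        cand = np.tanh(pre["c"])
        c = f_t * c + i_t * cand
        h = o_t * np.tanh(c)
        for k, v in (("i", i_t), ("f", f_t), ("o", o_t), ("cand", cand), ("c", c), ("h", h)):
            seq[k][:, t, :] = v
        for g in pre:
            pre_seq[g][:, t, :] = pre[g]
    logits = h @ params.w2 + params.b2
    return {
        "inputs": xs,
        "seq": seq,
        "pre_seq": pre_seq,
        "hidden": seq["h"],
        "logits": logits,
        "probs": softmax(logits),
    }


def gru_forward_batch(params: GRUParams, X: np.ndarray, dims: ArchDims) -> dict:
    X = _check_window(X, dims)
    xs = X[:, -dims.nd :, :]
    B, nd, _ = xs.shape
    nh = dims.nh
    h = np.zeros((B, nh))
    seq = {k: np.zeros((B, nd, nh)) for k in ("u", "r", "cand", "h")}
    pre_seq = {k: np.zeros((B, nd, nh)) for k in ("u", "r", "c")}
    for t in range(nd):
        x_t = xs[:, t, :]
        pre_u = x_t @ params.wx["u"] + h @ params.wh["u"] - params.b["u"]
        pre_r = x_t @ params.wx["r"] + h @ params.wh["r"] - params.b["r"]
        u_t = _sigmoid(pre_u)
        r_t = _sigmoid(pre_r)
        pre_c = x_t @ params.wx["c"] + (r_t * h) @ params.wh["c"] - params.b["c"]
        cand = np.tanh(pre_c)
        h = u_t * h + (1.0 - u_t) * cand
        for k, v in (("u", u_t), ("r", r_t), ("cand", cand), ("h", h)):
            seq[k][:, t, :] = v
        for g, v in (("u", pre_u), ("r", pre_r), ("c", pre_c)):
            pre_seq[g][:, t, :] = v
    logits = h @ params.w2 + params.b2
    return {
        "inputs": xs,
        "seq": seq,
        "pre_seq": pre_seq,
        "hidden": seq["h"],
        "logits": logits,
        "probs": softmax(logits),
    }


def _window_values(window) -> np.ndarray:
    return window.values if isinstance(window, SensorWindow) else np.asarray(window, float)


def firnn_forward(params: FIRNNParams, window, dims: ArchDims) -> ForwardTrace:
    """FIRNN recall of one window (SensorWindow or (NT, NI) array)."""
    vals = _window_values(window)
    out = firnn_forward_batch(params, vals, dims)
    return ForwardTrace(
        arch="firnn",
        dims=dims,
        nt=vals.shape[0],
        inputs=out["inputs"][0],
        hidden=out["hidden"][0],
        pre_hidden=out["pre_hidden"][0],
        logits=out["logits"][0],
        probs=out["probs"][0],
    )


def lstm_forward(params: LSTMParams, window, dims: ArchDims) -> ForwardTrace:
    vals = _window_values(window)
    out = lstm_forward_batch(params, vals, dims)
    seq, pre = out["seq"], out["pre_seq"]
    return ForwardTrace(
        arch="lstm",
        dims=dims,
        nt=vals.shape[0],
        inputs=out["inputs"][0],
        hidden=seq["h"][0],
        gates={g: seq[g][0] for g in ("i", "f", "o")},
        pre_gates={g: pre[g][0] for g in ("i", "f", "o")},
        candidate=seq["cand"][0],
        pre_candidate=pre["c"][0],
        cell=seq["c"][0],
        logits=out["logits"][0],
        probs=out["probs"][0],
    )


def gru_forward(params: GRUParams, window, dims: ArchDims) -> ForwardTrace:
    vals = _window_values(window)
    out = gru_forward_batch(params, vals, dims)
    seq, pre = out["seq"], out["pre_seq"]
    return ForwardTrace(
        arch="gru",
        dims=dims,
        nt=vals.shape[0],
        inputs=out["inputs"][0],
        hidden=seq["h"][0],
        gates={g: seq[g][0] for g in ("u", "r")},
        pre_gates={g: pre[g][0] for g in ("u", "r")},
        candidate=seq["cand"][0],
        pre_candidate=pre["c"][0],
        logits=out["logits"][0],
        probs=out["probs"][0],
    )


_FORWARD = {"firnn": firnn_forward, "lstm": lstm_forward, "gru": gru_forward}
_FORWARD_BATCH = {
    "firnn": firnn_forward_batch,
    "lstm": lstm_forward_batch,
    "gru": gru_forward_batch,
}


def forward(arch: str, params, window, dims: ArchDims) -> ForwardTrace:
    return _FORWARD[arch](params, window, dims)


def forward_batch(arch: str, params, X: np.ndarray, dims: ArchDims) -> dict:
    return _FORWARD_BATCH[arch](params, X, dims)


def predict(trace: ForwardTrace) -> int:
    """Argmax class; ties resolve to the lowest class id."""
    return int(np.argmax(trace.probs))


def predict_batch(arch: str, params, X: np.ndarray, dims: ArchDims) -> np.ndarray:
    return np.argmax(forward_batch(arch, params, X, dims)["probs"], axis=1)


# ---------------------------------------------------------------------------
# Serialization (HDF5 groups: /arch, /dims, /weights/*)


def save_params(path, arch: str, dims: ArchDims, params) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["arch"] = arch
        f.attrs["dims"] = (dims.ni, dims.nd, dims.nh, dims.nc)
        grp = f.create_group("weights", track_order=True)
        for name, arr in params.param_items():
            # track_times=False keeps files bit-identical across reruns
            grp.create_dataset(name, data=arr, track_times=False)


def load_params(path):
    import h5py

    with h5py.File(path, "r") as f:
        arch = str(f.attrs["arch"])
        ni, nd, nh, nc = (int(v) for v in f.attrs["dims"])
        dims = ArchDims(ni, nd, nh, nc)
        arrays = {name: np.asarray(ds) for name, ds in f["weights"].items()}
    params = init_params(arch, dims, seed=0)
    for name, arr in params.param_items():
        arr[...] = arrays[name]
    return arch, dims, params
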