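"""Epsilon-rule layer-wise relevance propagation for FIRNN, LSTM, GRU.

A prediction score (the target-class logit) is redistributed backward
through the network: at every linear (sub-)layer, lower neuron i
receives

    R_i = sum_j  x_i w_ij / (sum_i' x_i' w_i'j + eps * sign(.))  * R_j,

the signed-epsilon stabilized share of each upper neuron's relevance.
Nonlinear activations are treated as pass-through.  Architecture
adaptations:

* FIRNN — hidden relevance is redistributed across the NI x ND FIR tap
  contributions w_ijh * x_i(n-j+1), placing signed relevance on the
  original (time, channel) grid.
* LSTM / GRU — relevance is unrolled backward through time.  Additive
  junctions (cell update, GRU convex hidden update) split relevance in
  proportion to each addend's contribution, epsilon-stabilized.  At
  multiplicative gate x signal junctions the default policy
  ("signal-takes-all") passes all relevance to the signal operand and
  none to the gate — the established convention for LRP in gated
  recurrent nets; the alternative "proportional" policy splits each
  such product equally between gate and signal and propagates the
  gate's share through the gate's own affine layer.

Bias relevance is absorbed rather than redistributed, and the
epsilon stabilizer leaks a small share at every junction; both are
tracked explicitly (``bias_absorbed``, ``eps_leak``) so that

    sum(input_rel) + bias_absorbed + eps_leak == seeded output score

holds to machine precision, and epsilon leakage can be shown to vanish
as eps -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import FIRNNParams, ForwardTrace, GRUParams, LSTMParams

__all__ = [
    "GATE_POLICIES",
    "DegenerateRelevanceError",
    "LRPConfig",
    "RelevanceMap",
    "NormalizedRelevance",
    "lrp_dense",
    "lrp_firnn",
    "lrp_gated",
    "lrp",
    "normalize_temporal",
    "normalize_global",
    "classwise_mean_relevance",
]

GATE_POLICIES = ("signal-takes-all", "proportional")


class DegenerateRelevanceError(ValueError):
    """A relevance map is identically zero and cannot be normalized."""


@dataclass(frozen=True)
class LRPConfig:
    """epsilon: stabilizer; gate_policy: see module docstring; target:
    'predicted' (explain the argmax class) or 'given' (caller supplies
    the class)."""

    epsilon: float = 1e-6
    gate_policy: str = "signal-takes-all"
    target: str = "predicted"

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.gate_policy not in GATE_POLICIES:
            raise ValueError(
                f"unknown gate_policy {self.gate_policy!r}; expected {GATE_POLICIES}"
            )
        if self.target not in ("predicted", "given"):
            raise ValueError(f"unknown target mode {self.target!r}")


@dataclass
class RelevanceMap:
    """Signed relevance of one window at input and hidden layers.

    ``input_rel`` is (NT, NI) on the original time axis (zero outside
    the consumed suffix); ``hidden_rel`` is (NT, NH) — for the FIRNN
    only the readout row is nonzero, for recurrent nets row t holds the
    relevance arriving at the hidden state of step t.  ``output_rel``
    seeds exactly one nonzero entry (the target logit).
    """

    arch: str
    window_id: str
    target: int
    input_rel: np.ndarray
    hidden_rel: np.ndarray
    output_rel: np.ndarray
    seed_value: float
    bias_absorbed: float = 0.0
    eps_leak: float = 0.0
    epsilon: float = 1e-6

    def conservation_residual(self) -> float:
        """Seed minus (input + bias + leak); ~0 up to float rounding."""
        return float(
            self.seed_value - self.input_rel.sum() - self.bias_absorbed - self.eps_leak
        )


@dataclass
class NormalizedRelevance:
    """Eq.-style proportional normalizations of a relevance map.

    ``temporal`` (NT, n_units) entries are |R| divided by the total
    absolute relevance of the layer (all entries sum to 1);
    ``global_rel`` (n_units,) are the per-unit row sums (sum to 1).
    """

    layer: str
    temporal: np.ndarray | None = None
    global_rel: np.ndarray | None = None
    nt: int = 0
    n_units: int = 0


def _stab(denom: np.ndarray, eps: float) -> np.ndarray:
    return denom + eps * np.where(denom >= 0, 1.0, -1.0)


def _dense_detail(x, W, R_up, eps, bias_contrib=None):
    """Eps-rule through one dense (sub-)layer with full bookkeeping.

    ``bias_contrib`` (per upper unit) is added to the denominator so
    the denominator equals the true pre-activation; its share of the
    relevance is absorbed.  Returns (R_lower, bias_absorbed, leak).
    """
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    R_up = np.asarray(R_up, float)
    z = x[:, None] * W
    denom = z.sum(axis=0)
    if bias_contrib is not None:
        denom = denom + bias_contrib
    ratio = R_up / _stab(denom, eps)
    R_low = z @ ratio
    bias_abs = float(np.sum(bias_contrib * ratio)) if bias_contrib is not None else 0.0
    leak = float(np.sum(R_up - denom * ratio))
    return R_low, bias_abs, leak


def lrp_dense(lower_activations, weights, upper_relevance, config: LRPConfig, bias=None):
    """Eps-rule relevance through a dense layer (spec'd public form).

    ``bias`` (additive convention, pre = x @ W + bias), if given, joins
    the denominator and its share is absorbed.  Returns the lower-layer
    relevance vector.
    """
    config.validate()
    x = np.asarray(lower_activations, float)
    W = np.asarray(weights, float)
    R = np.asarray(upper_relevance, float)
    if x.ndim != 1 or W.ndim != 2 or W.shape[0] != x.size or W.shape[1] != R.size:
        raise ValueError(
            f"shape mismatch: x {x.shape}, W {W.shape}, R {R.shape}"
        )
    R_low, _, _ = _dense_detail(x, W, R, config.epsilon, bias_contrib=bias)
    return R_low


def _resolve_target(trace: ForwardTrace, config: LRPConfig, target):
    if target is not None:
        return int(target)
    if config.target == "predicted":
        return int(np.argmax(trace.probs))
    raise ValueError("config.target='given' requires an explicit target class")


def _seed_output_with(params, trace: ForwardTrace, config: LRPConfig, target):
    """Seed at the target logit and pull it through the readout layer."""
    tgt = _resolve_target(trace, config, target)
    output_rel = np.zeros(trace.logits.size)
    seed = float(trace.logits[tgt])
    output_rel[tgt] = seed
    R_hidden, bias_abs, leak = _dense_detail(
        trace.final_hidden, params.w2, output_rel, config.epsilon,
        bias_contrib=params.b2,
    )
    return tgt, seed, output_rel, R_hidden, bias_abs, leak


def lrp_firnn(
    params: FIRNNParams, trace: ForwardTrace, config: LRPConfig, target: int | None = None
) -> RelevanceMap:
    """Relevance propagation through the FIR taps of a FIRNN trace."""
    config.validate()
    if trace.arch != "firnn":
        raise ValueError(f"trace is for {trace.arch!r}, expected 'firnn'")
    dims = trace.dims
    tgt, seed, output_rel, R_hidden, bias_abs, leak = _seed_output_with(
        params, trace, config, target
    )
    hidden_rel = np.zeros((trace.nt, dims.nh))
    hidden_rel[-1] = R_hidden
    # Tap contributions: z[i, j, h] = w1[i, j, h] * x_i(n - j), n = NT-1 (0-based)
    xtap = trace.inputs[::-1].T            # (NI, ND); column j is lag j
    z = params.w1 * xtap[:, :, None]       # (NI, ND, NH)
    denom = z.sum(axis=(0, 1)) - params.b1
    ratio = R_hidden / _stab(denom, config.epsilon)
    rel_tap = np.einsum("ijh,h->ij", z, ratio)   # (NI, ND)
    bias_abs += float(np.sum(-params.b1 * ratio))
    leak += float(np.sum(R_hidden - denom * ratio))
    input_rel = np.zeros((trace.nt, dims.ni))
    input_rel[trace.nt - dims.nd :, :] = rel_tap[:, ::-1].T
    return RelevanceMap(
        arch="firnn",
        window_id="",
        target=tgt,
        input_rel=input_rel,
        hidden_rel=hidden_rel,
        output_rel=output_rel,
        seed_value=seed,
        bias_absorbed=bias_abs,
        eps_leak=leak,
        epsilon=config.epsilon,
    )


def _affine_backward(x_t, h_operand, wx, wh, b, R_up, eps):
    """Eps-rule through one gated affine: pre = x@wx + h_operand@wh - b.

    Returns (R_x, R_h_operand, bias_absorbed, leak).
    """
    acts = np.concatenate([x_t, h_operand])
    W = np.vstack([wx, wh])
    R_low, bias_abs, leak = _dense_detail(acts, W, R_up, eps, bias_contrib=-b)
    ni = x_t.size
    return R_low[:ni], R_low[ni:], bias_abs, leak


def _split_additive(terms: list[np.ndarray], total: np.ndarray, R: np.ndarray, eps: float):
    """Split R over addends proportionally to their contribution.

    ``total`` must be the exact sum of ``terms``.  Returns the per-term
    relevance shares and the epsilon leak.
    """
    ratio = R / _stab(total, eps)
    shares = [term * ratio for term in terms]
    leak = float(np.sum(R - total * ratio))
    return shares, leak


def lrp_gated(
    params, trace: ForwardTrace, config: LRPConfig, target: int | None = None
) -> RelevanceMap:
    """Relevance propagation through a gated recurrence (LSTM or GRU)."""
    config.validate()
    if trace.arch not in ("lstm", "gru"):
        raise ValueError(f"trace is for {trace.arch!r}, expected 'lstm' or 'gru'")
    expected = LSTMParams if trace.arch == "lstm" else GRUParams
    if not isinstance(params, expected):
        raise ValueError(f"params type {type(params).__name__} does not match trace arch")
    dims = trace.dims
    nd, ni, nh = dims.nd, dims.ni, dims.nh
    offset = trace.nt - nd
    eps = config.epsilon
    proportional = config.gate_policy == "proportional"

    tgt, seed, output_rel, Rh_carry, bias_abs, leak = _seed_output_with(
        params, trace, config, target
    )
    input_rel = np.zeros((trace.nt, ni))
    hidden_rel = np.zeros((trace.nt, nh))

    def gate_affine(t, gate, R_gate):
        nonlocal bias_abs, leak
        h_prev = trace.hidden[t - 1] if t > 0 else np.zeros(nh)
        r_x, r_h, b_abs, lk = _affine_backward(
            trace.inputs[t], h_prev,
            params.wx[gate], params.wh[gate], params.b[gate], R_gate, eps,
        )
        bias_abs += b_abs
        leak += lk
        input_rel[offset + t] += r_x
        return r_h

    if trace.arch == "lstm":
        Rc = np.zeros(nh)
        for t in range(nd - 1, -1, -1):
            Rh = Rh_carry
            hidden_rel[offset + t] = Rh
            h_prev = trace.hidden[t - 1] if t > 0 else np.zeros(nh)
            c_prev = trace.cell[t - 1] if t > 0 else np.zeros(nh)
            # h_t = o_t * tanh(c_t): gate o, signal c
            if proportional:
                Rh_to_c = 0.5 * Rh
                Rh_carry_extra = gate_affine(t, "o", 0.5 * Rh)
            else:
                Rh_to_c = Rh
                Rh_carry_extra = np.zeros(nh)
            Rc = Rc + Rh_to_c
            # c_t = f*c_prev + i*cand: additive junction
            term_prev = trace.gates["f"][t] * c_prev
            term_cand = trace.gates["i"][t] * trace.candidate[t]
            (R_prev_term, R_cand_term), lk = _split_additive(
                [term_prev, term_cand], trace.cell[t], Rc, eps
            )
            leak += lk
            if proportional:
                Rh_carry_extra = Rh_carry_extra + gate_affine(t, "f", 0.5 * R_prev_term)
                Rh_carry_extra = Rh_carry_extra + gate_affine(t, "i", 0.5 * R_cand_term)
                R_prev_c = 0.5 * R_prev_term
                R_cand = 0.5 * R_cand_term
            else:
                R_prev_c = R_prev_term
                R_cand = R_cand_term
            # candidate affine
            r_x, r_h, b_abs, lk = _affine_backward(
                trace.inputs[t], h_prev,
                params.wx["c"], params.wh["c"], params.b["c"], R_cand, eps,
            )
            bias_abs += b_abs
            leak += lk
            input_rel[offset + t] += r_x
            Rh_carry = r_h + Rh_carry_extra
            Rc = R_prev_c
        # t = 0 shares to zero initial states are zero by construction
        # (their contributions vanish), so nothing remains in Rc/Rh_carry.
        leak += float(Rc.sum() + Rh_carry.sum())
    else:  # gru
        for t in range(nd - 1, -1, -1):
            Rh = Rh_carry
            hidden_rel[offset + t] = Rh
            h_prev = trace.hidden[t - 1] if t > 0 else np.zeros(nh)
            u_t = trace.gates["u"][t]
            # h_t = u*h_prev + (1-u)*cand: additive junction
            term_prev = u_t * h_prev
            term_cand = (1.0 - u_t) * trace.candidate[t]
            (R_prev_term, R_cand_term), lk = _split_additive(
                [term_prev, term_cand], trace.hidden[t], Rh, eps
            )
            leak += lk
            extra_h = np.zeros(nh)
            if proportional:
                extra_h = extra_h + gate_affine(t, "u", 0.5 * R_prev_term)
                extra_h = extra_h + gate_affine(t, "u", 0.5 * R_cand_term)
                R_prev = 0.5 * R_prev_term
                R_cand = 0.5 * R_cand_term
            else:
                R_prev = R_prev_term
                R_cand = R_cand_term
            # candidate affine: recurrent operand is r*h_prev (r is a gate)
            rh_operand = trace.gates["r"][t] * h_prev
            r_x, r_h, b_abs, lk = _affine_backward(
                trace.inputs[t], rh_operand,
                params.wx["c"], params.wh["c"], params.b["c"], R_cand, eps,
            )
            bias_abs += b_abs
            leak += lk
            input_rel[offset + t] += r_x
            if proportional:
                extra_h = extra_h + gate_affine(t, "r", 0.5 * r_h)
                r_h = 0.5 * r_h
            Rh_carry = R_prev + r_h + extra_h
        leak += float(Rh_carry.sum())

    return RelevanceMap(
        arch=trace.arch,
        window_id="",
        target=tgt,
        input_rel=input_rel,
        hidden_rel=hidden_rel,
        output_rel=output_rel,
        seed_value=seed,
        bias_absorbed=bias_abs,
        eps_leak=leak,
        epsilon=eps,
    )


def lrp(params, trace: ForwardTrace, config: LRPConfig, target: int | None = None) -> RelevanceMap:
    """Dispatch to the architecture-specific backward pass."""
    if trace.arch == "firnn":
        return lrp_firnn(params, trace, config, target)
    return lrp_gated(params, trace, config, target)


# ---------------------------------------------------------------------------
# Proportional normalizations and class-wise averaging


def _layer_matrix(rmap: RelevanceMap, layer: str) -> np.ndarray:
    if layer == "input":
        return rmap.input_rel
    if layer == "hidden":
        return rmap.hidden_rel
    raise ValueError(f"layer must be 'input' or 'hidden', got {layer!r}")


def normalize_temporal(rmap: RelevanceMap, layer: str = "input") -> NormalizedRelevance:
    """T_h(n) = |R_h(n)| / sum_{c,t} |R_c(t)|; all entries sum to 1."""
    mat = np.abs(_layer_matrix(rmap, layer))
    total = mat.sum()
    if total == 0:
        raise DegenerateRelevanceError(f"all-zero {layer} relevance map")
    temporal = mat / total
    return NormalizedRelevance(
        layer=layer,
        temporal=temporal,
        global_rel=temporal.sum(axis=0),
        nt=mat.shape[0],
        n_units=mat.shape[1],
    )


def normalize_global(rmap: RelevanceMap, layer: str = "input") -> NormalizedRelevance:
    """V_h = sum_n |R_h(n)| / sum_{c,n} |R_c(n)|; entries sum to 1."""
    norm = normalize_temporal(rmap, layer)
    return NormalizedRelevance(
        layer=layer,
        temporal=None,
        global_rel=norm.global_rel,
        nt=norm.nt,
        n_units=norm.n_units,
    )


def classwise_mean_relevance(
    norms, labels, predictions, class_ids=None
) -> pd.DataFrame:
    """Average global relevance vectors per class over correct predictions.

    Only correctly predicted samples are included; per class the V
    vectors are averaged and re-normalized to sum 1.  Classes with no
    correct predictions are excluded with a warning.  Returns a
    (n_units x n_classes) DataFrame whose columns each sum to 1.
    """
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    if class_ids is None:
        class_ids = sorted(set(labels.tolist()))
    columns = {}
    for cid in class_ids:
        idx = np.where((labels == cid) & (predictions == cid))[0]
        if idx.size == 0:
            warnings.warn(f"class {cid}: no correct predictions; excluded")
            continue
        V = np.mean([norms[i].global_rel for i in idx], axis=0)
        total = V.sum()
        if total == 0:
            warnings.warn(f"class {cid}: zero mean relevance; excluded")
            continue
        columns[cid] = V / total
    if not columns:
        raise DegenerateRelevanceError("no class had correct predictions")
    return pd.DataFrame(columns)
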