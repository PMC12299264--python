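"""Forward-pass contracts, parameter counts and scalar-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynhar.complexity import complexity_profile
from dynhar.dims import ARCHS, ArchDims
from dynhar.networks import (
    firnn_forward,
    forward,
    gru_forward,
    init_params,
    load_params,
    lstm_forward,
    predict,
    save_params,
    softmax,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def firnn_oracle(params, window, dims):
    """Independent double-loop FIR convolution, 1-based tap indexing."""
    xs = window[-dims.nd:, :]
    nt = xs.shape[0]
    pre = np.zeros(dims.nh)
    for h in range(dims.nh):
        acc = 0.0
        for i in range(dims.ni):
            for j in range(1, dims.nd + 1):
                acc += params.w1[i, j - 1, h] * xs[nt - j, i]
        pre[h] = acc - params.b1[h]
    return pre


def lstm_oracle(params, window, dims):
    """Scalar per-step recurrence; returns state sequences."""
    xs = window[-dims.nd:, :]
    nh = dims.nh
    h = np.zeros(nh)
    c = np.zeros(nh)
    hs, cs = [], []
    for t in range(dims.nd):
        x = xs[t]
        pre = {}
        for g in ("i", "f", "o", "c"):
            pre[g] = np.array(
                [
                    sum(x[i] * params.wx[g][i, k] for i in range(dims.ni))
                    + sum(h[j] * params.wh[g][j, k] for j in range(nh))
                    - params.b[g][k]
                    for k in range(nh)
                ]
            )
        i_t, f_t, o_t = sigmoid(pre["i"]), sigmoid(pre["f"]), sigmoid(pre["o"])
        cand = np.tanh(pre["c"])
        c = f_t * c + i_t * cand
        h = o_t * np.tanh(c)
        hs.append(h.copy())
        cs.append(c.copy())
    return np.array(hs), np.array(cs)


def gru_oracle(params, window, dims):
    xs = window[-dims.nd:, :]
    nh = dims.nh
    h = np.zeros(nh)
    hs = []
    for t in range(dims.nd):
        x = xs[t]
        pre_u = x @ params.wx["u"] + h @ params.wh["u"] - params.b["u"]
        pre_r = x @ params.wx["r"] + h @ params.wh["r"] - params.b["r"]
        u, r = sigmoid(pre_u), sigmoid(pre_r)
        cand = np.tanh(x @ params.wx["c"] + (r * h) @ params.wh["c"] - params.b["c"])
        h = u * h + (1 - u) * cand
        hs.append(h.copy())
    return np.array(hs)


class TestInitParams:
    @pytest.mark.parametrize(
        "arch,expected",
        [("firnn", 6043), ("gru", 543), ("lstm", 713)],
    )
    def test_parameter_counts_at_study_dims(self, arch, expected):
        dims = ArchDims(6, 100, 10, 3)
        assert init_params(arch, dims, seed=0).n_params == expected

    def test_determinism(self):
        dims = ArchDims(3, 4, 2, 3)
        for arch in ARCHS:
            a = init_params(arch, dims, seed=42)
            b = init_params(arch, dims, seed=42)
            for (na, xa), (nb, xb) in zip(a.param_items(), b.param_items()):
                np.testing.assert_array_equal(xa, xb)

    def test_unknown_arch(self):
        with pytest.raises(ValueError, match="unknown"):
            init_params("cnn", ArchDims(1, 1, 1, 1), seed=0)

    @settings(deadline=None, max_examples=25)
    @given(
        ni=st.integers(1, 4),
        nd=st.integers(1, 5),
        nh=st.integers(1, 4),
        nc=st.integers(1, 4),
        arch=st.sampled_from(ARCHS),
    )
    def test_count_matches_closed_form(self, ni, nd, nh, nc, arch):
        dims = ArchDims(ni, nd, nh, nc)
        assert (
            init_params(arch, dims, seed=1).n_params
            == complexity_profile(arch, dims).n_weights
        )

    def test_init_scale(self):
        dims = ArchDims(6, 100, 10, 3)
        params = init_params("firnn", dims, seed=0)
        assert np.std(params.w1) == pytest.approx(np.sqrt(1e-3), rel=0.1)


class TestFIRNNForward:
    def test_zero_params_symmetry(self, rng):
        dims = ArchDims(6, 10, 4, 3)
        params = init_params("firnn", dims, seed=0)
        for _, arr in params.param_items():
            arr[...] = 0.0
        trace = firnn_forward(params, rng.normal(0, 1, (20, 6)), dims)
        np.testing.assert_allclose(trace.hidden, 0.5)
        np.testing.assert_allclose(trace.probs, 1 / 3)

    def test_single_tap_zero_input(self):
        dims = ArchDims(1, 1, 1, 3)
        params = init_params("firnn", dims, seed=0)
        params.w1[...] = 1.0
        params.b1[...] = 0.0
        trace = firnn_forward(params, np.zeros((1, 1)), dims)
        assert trace.hidden[0] == pytest.approx(0.5)

    def test_oracle_equivalence(self, rng):
        dims = ArchDims(2, 3, 2, 3)
        params = init_params("firnn", dims, seed=5)
        for _, arr in params.param_items():
            arr += rng.normal(0, 0.5, arr.shape)
        window = rng.normal(0, 1, (7, 2))
        trace = firnn_forward(params, window, dims)
        np.testing.assert_allclose(
            trace.pre_hidden, firnn_oracle(params, window, dims), atol=1e-12
        )

    def test_short_window_rejected(self, rng):
        dims = ArchDims(2, 10, 2, 3)
        params = init_params("firnn", dims, seed=0)
        with pytest.raises(ValueError, match="fewer than"):
            firnn_forward(params, rng.normal(0, 1, (5, 2)), dims)


class TestLSTMForward:
    def test_zero_params_fixed_point(self, rng):
        dims = ArchDims(3, 5, 2, 3)
        params = init_params("lstm", dims, seed=0)
        for _, arr in params.param_items():
            arr[...] = 0.0
        trace = lstm_forward(params, rng.normal(0, 1, (8, 3)), dims)
        for g in ("i", "f", "o"):
            np.testing.assert_allclose(trace.gates[g], 0.5)
        np.testing.assert_allclose(trace.candidate, 0.0)
        np.testing.assert_allclose(trace.cell, 0.0)
        np.testing.assert_allclose(trace.probs, 1 / 3)

    def test_saturated_forget_keeps_cell_constant(self, rng):
        """With forget ~ 1 and input gate ~ 0 the cell never moves."""
        dims = ArchDims(2, 6, 2, 3)
        params = init_params("lstm", dims, seed=1)
        params.b["f"][...] = -50.0   # pre = z + 50 -> f ~ 1
        params.b["i"][...] = 50.0    # pre = z - 50 -> i ~ 0
        trace = lstm_forward(params, rng.normal(0, 1, (6, 2)), dims)
        np.testing.assert_allclose(trace.cell - trace.cell[0], 0.0, atol=1e-12)

    def test_oracle_equivalence(self, rng):
        dims = ArchDims(2, 4, 2, 3)
        params = init_params("lstm", dims, seed=5)
        for _, arr in params.param_items():
            arr += rng.normal(0, 0.5, arr.shape)
        window = rng.normal(0, 1, (6, 2))
        trace = lstm_forward(params, window, dims)
        hs, cs = lstm_oracle(params, window, dims)
        np.testing.assert_allclose(trace.hidden, hs, atol=1e-12)
        np.testing.assert_allclose(trace.cell, cs, atol=1e-12)


class TestGRUForward:
    def test_update_gate_one_freezes_state(self, rng):
        dims = ArchDims(2, 5, 2, 3)
        params = init_params("gru", dims, seed=1)
        params.b["u"][...] = -50.0   # u ~ 1 -> hidden stays at its zero init
        trace = gru_forward(params, rng.normal(0, 1, (5, 2)), dims)
        np.testing.assert_allclose(trace.hidden, 0.0, atol=1e-12)

    def test_update_gate_zero_copies_candidate(self, rng):
        dims = ArchDims(2, 5, 2, 3)
        params = init_params("gru", dims, seed=1)
        params.b["u"][...] = 50.0    # u ~ 0 -> hidden = candidate
        trace = gru_forward(params, rng.normal(0, 1, (5, 2)), dims)
        np.testing.assert_allclose(trace.hidden, trace.candidate, atol=1e-12)

    def test_oracle_equivalence(self, rng):
        dims = ArchDims(2, 4, 2, 3)
        params = init_params("gru", dims, seed=5)
        for _, arr in params.param_items():
            arr += rng.normal(0, 0.5, arr.shape)
        window = rng.normal(0, 1, (6, 2))
        trace = gru_forward(params, window, dims)
        np.testing.assert_allclose(trace.hidden, gru_oracle(params, window, dims), atol=1e-12)


class TestPredictAndSoftmax:
    def test_argmax_and_tie_break(self, rng):
        dims = ArchDims(2, 2, 2, 3)
        params = init_params("gru", dims, seed=0)
        trace = gru_forward(params, rng.normal(0, 1, (3, 2)), dims)
        trace.probs = np.array([0.2, 0.5, 0.3])
        assert predict(trace) == 1
        trace.probs = np.array([1 / 3, 1 / 3, 1 / 3])
        assert predict(trace) == 0

    def test_softmax_hand_value(self):
        probs = softmax(np.array([0.0, 0.0, np.log(2.0)]))
        np.testing.assert_allclose(probs, [0.25, 0.25, 0.5], atol=1e-12)
        assert int(np.argmax(probs)) == 2

    @settings(deadline=None, max_examples=50)
    @given(
        logits=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=6
        ),
        shift=st.floats(-100, 100, allow_nan=False),
    )
    def test_softmax_normalized_and_shift_invariant(self, logits, shift):
        z = np.array(logits)
        p = softmax(z)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, softmax(z + shift), atol=1e-9)

    def test_gate_ranges(self, rng):
        dims = ArchDims(3, 6, 3, 3)
        for arch in ("lstm", "gru"):
            params = init_params(arch, dims, seed=2)
            for _, arr in params.param_items():
                arr += rng.normal(0, 1.0, arr.shape)
            trace = forward(arch, params, rng.normal(0, 1, (8, 3)), dims)
            for g, vals in trace.gates.items():
                assert np.all((vals > 0) & (vals < 1))
            assert np.all(np.abs(trace.candidate) < 1)


def test_serialization_round_trip(tmp_path, rng):
    dims = ArchDims(3, 4, 2, 3)
    for arch in ARCHS:
        params = init_params(arch, dims, seed=9)
        path = tmp_path / f"{arch}.h5"
        save_params(path, arch, dims, params)
        arch2, dims2, params2 = load_params(path)
        assert (arch2, dims2) == (arch, dims)
        for (na, xa), (nb, xb) in zip(params.param_items(), params2.param_items()):
            np.testing.assert_array_equal(xa, xb)
        w = rng.normal(0, 1, (6, 3))
        np.testing.assert_allclose(
            forward(arch, params, w, dims).probs,
            forward(arch2, params2, w, dims2).probs,
            atol=1e-15,
        )
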