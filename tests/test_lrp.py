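"""Epsilon-LRP: dense rule, architecture backward passes, conservation,
normalizations, and class-wise averaging."""

import numpy as np
import pytest

from dynhar.dims import ARCHS, ArchDims
from dynhar.lrp import (
    DegenerateRelevanceError,
    LRPConfig,
    NormalizedRelevance,
    RelevanceMap,
    classwise_mean_relevance,
    lrp,
    lrp_dense,
    lrp_firnn,
    lrp_gated,
    normalize_global,
    normalize_temporal,
)
from dynhar.networks import forward, gru_forward, init_params, lstm_forward


def random_net(arch, dims, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    params = init_params(arch, dims, seed=seed)
    for _, arr in params.param_items():
        arr += rng.normal(0, scale, arr.shape)
    return params


def make_map(input_rel, hidden_rel=None, arch="firnn"):
    input_rel = np.asarray(input_rel, float)
    if hidden_rel is None:
        hidden_rel = np.zeros((input_rel.shape[0], 2))
    return RelevanceMap(
        arch=arch,
        window_id="w",
        target=0,
        input_rel=input_rel,
        hidden_rel=np.asarray(hidden_rel, float),
        output_rel=np.array([1.0, 0.0]),
        seed_value=1.0,
    )


class TestLRPDense:
    def test_single_path(self):
        R = lrp_dense([1.0], [[1.0]], [1.0], LRPConfig())
        assert R[0] == pytest.approx(1.0 / (1.0 + 1e-6))

    def test_symmetric_split(self):
        R = lrp_dense([1.0, 1.0], [[1.0], [1.0]], [1.0], LRPConfig())
        np.testing.assert_allclose(R, [0.5, 0.5], atol=1e-6)

    def test_conservation_against_summation_oracle(self, rng):
        """Direct evaluation of the redistribution formula conserves the
        upper relevance to 1e-6 relative at eps = 1e-6."""
        x = rng.normal(1, 1, 4)
        W = rng.normal(0, 1, (4, 3))
        R_up = rng.normal(0, 1, 3)
        eps = 1e-6
        R = lrp_dense(x, W, R_up, LRPConfig(epsilon=eps))
        # independent summation oracle
        expected = np.zeros(4)
        for i in range(4):
            for j in range(3):
                denom = sum(x[k] * W[k, j] for k in range(4))
                denom_s = denom + eps * (1 if denom >= 0 else -1)
                expected[i] += x[i] * W[i, j] / denom_s * R_up[j]
        np.testing.assert_allclose(R, expected, atol=1e-12)
        assert abs(R.sum() - R_up.sum()) <= 1e-6 * max(1.0, abs(R_up.sum()))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            lrp_dense([1.0, 2.0], [[1.0]], [1.0], LRPConfig())

    def test_bad_config(self):
        with pytest.raises(ValueError, match="epsilon"):
            lrp_dense([1.0], [[1.0]], [1.0], LRPConfig(epsilon=0.0))


class TestFIRNNLRP:
    def test_single_tap_single_path(self, rng):
        """One hidden unit wired to one tap on channel 4: all input
        relevance lands on that (time, channel) cell."""
        dims = ArchDims(6, 5, 1, 2)
        params = init_params("firnn", dims, seed=0)
        for _, arr in params.param_items():
            arr[...] = 0.0
        params.w1[4, 2, 0] = 1.0      # tap j=3 on channel 4
        params.w2[0, 0] = 1.0
        window = rng.normal(1, 0.5, (10, 6))
        trace = forward("firnn", params, window, dims)
        rmap = lrp_firnn(params, trace, LRPConfig(), target=0)
        nz = np.argwhere(np.abs(rmap.input_rel) > 1e-15)
        assert nz.tolist() == [[10 - 3, 4]]  # x(n - j + 1), j = 3

    def test_conservation_ledger(self, rng):
        dims = ArchDims(3, 4, 2, 3)
        params = random_net("firnn", dims, 7)
        trace = forward("firnn", params, rng.normal(0, 1, (6, 3)), dims)
        rmap = lrp_firnn(params, trace, LRPConfig())
        assert abs(rmap.conservation_residual()) <= 1e-12 * max(1, abs(rmap.seed_value))

    def test_hidden_relevance_at_readout_only(self, rng):
        dims = ArchDims(3, 4, 2, 3)
        params = random_net("firnn", dims, 8)
        trace = forward("firnn", params, rng.normal(0, 1, (6, 3)), dims)
        rmap = lrp_firnn(params, trace, LRPConfig())
        assert np.all(rmap.hidden_rel[:-1] == 0)
        assert np.any(rmap.hidden_rel[-1] != 0)


class TestGatedLRP:
    @pytest.mark.parametrize("arch", ["lstm", "gru"])
    @pytest.mark.parametrize("policy", ["signal-takes-all", "proportional"])
    def test_conservation_ledger(self, arch, policy, rng):
        dims = ArchDims(2, 3, 2, 3)
        params = random_net(arch, dims, 11)
        trace = forward(arch, params, rng.normal(0, 1, (5, 2)), dims)
        rmap = lrp_gated(params, trace, LRPConfig(gate_policy=policy))
        assert abs(rmap.conservation_residual()) <= 1e-12 * max(1, abs(rmap.seed_value))

    def test_gru_update_zero_reduces_to_dense(self, rng):
        """With u ~ 0 and one step, hidden = candidate and relevance on
        the inputs matches the plain dense rule on the candidate
        affine sub-layer."""
        dims = ArchDims(3, 1, 2, 3)
        params = random_net("gru", dims, 13)
        params.b["u"][...] = 60.0   # pre = z - 60 -> u ~ 0
        window = rng.normal(0, 1, (1, 3))
        trace = gru_forward(params, window, dims)
        cfg = LRPConfig()
        rmap = lrp_gated(params, trace, cfg)
        # independent dense chain: logit -> hidden, then candidate affine
        R_h = lrp_dense(trace.final_hidden, params.w2,
                        rmap.output_rel, cfg, bias=params.b2)
        R_in = lrp_dense(window[0], params.wx["c"], R_h, cfg, bias=-params.b["c"])
        np.testing.assert_allclose(rmap.input_rel[0], R_in, rtol=1e-4, atol=1e-9)

    def test_lstm_forget_zero_severs_cell_history(self, rng):
        """With f ~ 0 (and no recurrent candidate path) relevance cannot
        reach time steps before the final cell write."""
        dims = ArchDims(2, 4, 2, 3)
        params = random_net("lstm", dims, 15)
        params.b["f"][...] = 60.0    # f ~ 0
        params.wh["c"][...] = 0.0    # isolate the cell path
        params.wh["i"][...] = 0.0
        params.wh["o"][...] = 0.0
        trace = lstm_forward(params, rng.normal(0, 1, (4, 2)), dims)
        rmap = lrp_gated(params, trace, LRPConfig())
        np.testing.assert_allclose(rmap.input_rel[:-1], 0.0, atol=1e-12)
        assert np.any(np.abs(rmap.input_rel[-1]) > 0)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_epsilon_leak_monotone(self, arch, rng):
        """Epsilon leakage shrinks monotonically as eps -> 0 and total
        input+bias relevance approaches the seed exactly."""
        dims = ArchDims(2, 3, 2, 3)
        params = random_net(arch, dims, 19)
        trace = forward(arch, params, rng.normal(0, 1, (5, 2)), dims)
        leaks = []
        for eps in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10, 1e-12):
            rmap = lrp(params, trace, LRPConfig(epsilon=eps))
            leaks.append(abs(rmap.eps_leak))
        assert all(a >= b for a, b in zip(leaks, leaks[1:]))
        rmap = lrp(params, trace, LRPConfig(epsilon=1e-12))
        total = rmap.input_rel.sum() + rmap.bias_absorbed
        assert abs(total - rmap.seed_value) <= 1e-6 * max(1.0, abs(rmap.seed_value))

    @pytest.mark.parametrize("arch", ARCHS)
    def test_permutation_equivariance(self, arch, rng):
        """Permuting input channels permutes the global relevance V."""
        dims = ArchDims(4, 3, 2, 3)
        params = random_net(arch, dims, 23)
        window = rng.normal(0, 1, (5, 4))
        perm = np.array([2, 0, 3, 1])
        V = normalize_global(
            lrp(params, forward(arch, params, window, dims), LRPConfig()), "input"
        ).global_rel
        # permute the input axis of every input-weight block
        import copy

        p2 = copy.deepcopy(params)
        if arch == "firnn":
            p2.w1[...] = p2.w1[perm]
        else:
            for g in p2.wx:
                p2.wx[g][...] = p2.wx[g][perm]
        # channel i of the permuted net plays the role of original
        # channel perm[i], so V2 = V[perm]
        w2 = window[:, perm]
        V2 = normalize_global(
            lrp(p2, forward(arch, p2, w2, dims), LRPConfig()), "input"
        ).global_rel
        np.testing.assert_allclose(V2, V[perm], atol=1e-9)


class TestNormalization:
    def test_temporal_hand_values(self):
        norm = normalize_temporal(make_map([[1.0, 1.0], [2.0, 0.0]]), "input")
        np.testing.assert_allclose(norm.temporal, [[0.25, 0.25], [0.5, 0.0]])
        assert norm.temporal.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_nonzero_cell(self):
        m = np.zeros((4, 2))
        m[2, 1] = -3.0
        norm = normalize_temporal(make_map(m), "input")
        assert norm.temporal[2, 1] == pytest.approx(1.0)

    def test_global_hand_values(self):
        # channel sums (2, 2) over total 4 -> (0.5, 0.5)
        norm = normalize_global(make_map([[1.0, 2.0], [1.0, 0.0]]), "input")
        np.testing.assert_allclose(norm.global_rel, [0.5, 0.5])
        assert norm.global_rel.sum() == pytest.approx(1.0, abs=1e-9)

    def test_global_equals_temporal_row_sums(self, rng):
        m = make_map(rng.normal(0, 1, (6, 3)))
        t = normalize_temporal(m, "input")
        g = normalize_global(m, "input")
        np.testing.assert_allclose(g.global_rel, t.temporal.sum(axis=0), atol=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateRelevanceError):
            normalize_temporal(make_map(np.zeros((3, 2))), "input")


class TestClasswiseMean:
    def _norm(self, v):
        v = np.asarray(v, float)
        return NormalizedRelevance(layer="input", global_rel=v, n_units=v.size)

    def test_hand_average(self):
        norms = [self._norm([0.6, 0.4]), self._norm([0.2, 0.8])]
        df = classwise_mean_relevance(norms, [0, 0], [0, 0])
        np.testing.assert_allclose(df[0].to_numpy(), [0.4, 0.6])

    def test_single_sample_per_class(self):
        norms = [self._norm([0.7, 0.3]), self._norm([0.1, 0.9])]
        df = classwise_mean_relevance(norms, [0, 1], [0, 1])
        np.testing.assert_allclose(df[0].to_numpy(), [0.7, 0.3])
        np.testing.assert_allclose(df[1].to_numpy(), [0.1, 0.9])

    def test_columns_sum_to_one(self, rng):
        norms = [self._norm(np.abs(rng.normal(1, 1, 4))) for _ in range(12)]
        labels = rng.integers(0, 3, 12)
        df = classwise_mean_relevance(norms, labels, labels)
        np.testing.assert_allclose(df.sum(axis=0), 1.0, atol=1e-9)

    def test_misclassified_excluded(self):
        norms = [self._norm([0.6, 0.4]), self._norm([0.0, 1.0])]
        df = classwise_mean_relevance(norms, [0, 0], [0, 1])
        np.testing.assert_allclose(df[0].to_numpy(), [0.6, 0.4])

    def test_class_without_correct_predictions_warned(self):
        norms = [self._norm([0.6, 0.4]), self._norm([0.2, 0.8])]
        with pytest.warns(UserWarning, match="class 1"):
            df = classwise_mean_relevance(norms, [0, 1], [0, 0])
        assert list(df.columns) == [0]
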