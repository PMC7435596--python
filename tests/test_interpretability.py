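"""Neuron-importance propagation and Jacobian saliency against oracles."""

import numpy as np
import pytest

from modtransfer.errors import AnalysisError
from modtransfer.interpretability import (ImportanceVector, compare_models,
                                          inffs_scores, input_jacobian,
                                          jacobian_channel_saliency,
                                          layer_difference,
                                          nisp_backpropagate,
                                          penultimate_activations,
                                          seed_scores_penultimate,
                                          variance_scores)
from modtransfer.interpretability import _propagate_through
from modtransfer.evaluation import TargetSegmentSet
from modtransfer.models import build_mdnn, build_sdnn, forward
from modtransfer.nn import Conv1D, Dense, MaxPool1D, Softmax


class TestSeedScores:
    def test_variance_scorer_matches_hand_computation(self):
        acts = np.array([[1.0, 0.0], [3.0, 0.0], [5.0, 6.0]])
        iv = seed_scores_penultimate(acts, scorer=variance_scores)
        np.testing.assert_allclose(iv.scores, acts.var(axis=0))

    def test_duplicated_neurons_get_equal_scores(self, rng):
        col = rng.standard_normal((20, 1))
        acts = np.hstack([col, rng.standard_normal((20, 2)), col])
        for scorer in (variance_scores, inffs_scores):
            s = scorer(acts)
            assert s[0] == pytest.approx(s[3], rel=1e-9)

    def test_constant_activations_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            iv = seed_scores_penultimate(np.zeros((5, 3)),
                                         scorer=variance_scores)
        np.testing.assert_array_equal(iv.scores, 0.0)

    def test_inffs_scores_nonnegative(self, rng):
        s = inffs_scores(rng.standard_normal((50, 8)))
        assert (s >= 0).all() and s.shape == (8,)

    def test_negative_scorer_output_rejected(self, rng):
        with pytest.raises(AnalysisError, match="nonnegative"):
            seed_scores_penultimate(rng.standard_normal((5, 3)),
                                    scorer=lambda a, l: np.array([-1., 0, 1]))


class TestNISPPropagation:
    def test_fully_connected_toy_case(self):
        # connection weights from 2 input neurons to 2 output neurons:
        # w[i][j] = [[1, -2], [3, 0]]; seeds (1, 1) -> scores (3, 3)
        layer = Dense(2, 2, name="fc")
        layer.params["W"][...] = np.array([[1.0, -2.0], [3.0, 0.0]]).T
        out = _propagate_through(layer, np.array([1.0, 1.0]), False)
        np.testing.assert_allclose(out, [3.0, 3.0])

    def test_zero_seeds_give_zero_everywhere(self, tiny_sdnn_spec, rng):
        net = build_sdnn(tiny_sdnn_spec, seed=0)
        net.forward(rng.standard_normal((4, 32)))
        width = net["softmax_dense"].in_features
        out = nisp_backpropagate(net, ImportanceVector("p", np.zeros(width)))
        for iv in out:
            np.testing.assert_array_equal(iv.scores, 0.0)

    def test_conv_matches_dense_unrolling(self, rng):
        """Score propagation through a conv layer equals |M|^T s for the
        explicit sparse-matrix unrolling M of the convolution."""
        c_in, c_out, K, L_in = 3, 4, 5, 17
        L_out = L_in - K + 1
        conv = Conv1D(c_in, c_out, K, rng=rng, name="c")
        W = conv.params["W"]
        M = np.zeros((c_out * L_out, c_in * L_in))
        for o in range(c_out):
            for l in range(L_out):
                for c in range(c_in):
                    for k in range(K):
                        M[o * L_out + l, c * L_in + l + k] = W[o, c, k]
        s = rng.uniform(0, 1, c_out * L_out)
        oracle = np.abs(M).T @ s
        out = _propagate_through(conv, s, False)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_pool_propagates_uniformly_to_receptive_fields(self, rng):
        pool = MaxPool1D(2, name="p")
        pool.forward(rng.standard_normal((1, 2, 7)))  # remainder sample
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])  # (2 ch, 3 out)
        out = _propagate_through(pool, s, False).reshape(2, 7)
        np.testing.assert_allclose(out[0], [1, 1, 2, 2, 3, 3, 0])
        np.testing.assert_allclose(out[1], [4, 4, 5, 5, 6, 6, 0])

    def test_linearity_in_seed_scores(self, tiny_sdnn_spec, rng):
        net = build_sdnn(tiny_sdnn_spec, seed=1)
        net.forward(rng.standard_normal((4, 32)))
        width = net["softmax_dense"].in_features
        seed = rng.uniform(0, 1, width)
        once = nisp_backpropagate(net, ImportanceVector("p", seed))
        twice = nisp_backpropagate(net, ImportanceVector("p", 2 * seed))
        for a, b in zip(once, twice):
            np.testing.assert_allclose(2 * a.scores, b.scores, atol=1e-12)

    def test_score_mass_grows_toward_input_for_heavy_weights(self, rng):
        """With |W| column sums above 1, layer score sums increase from the
        penultimate layer toward the input."""
        net = build_sdnn(
            __import__("modtransfer.models", fromlist=["SDNNSpec"]).SDNNSpec(
                32, 3, conv_filters=(4, 4), kernel_size=3), seed=0)
        for name in ("conv1", "conv2"):
            net[name].params["W"][...] = 1.0   # column sums = K * C_out > 1
        net.forward(rng.standard_normal((4, 32)))
        width = net["softmax_dense"].in_features
        out = nisp_backpropagate(net, ImportanceVector("p", np.ones(width)))
        sums = [iv.scores.sum() for iv in out]
        assert all(b >= a for a, b in zip(sums, sums[1:]))
        assert sums[-1] > sums[0]

    def test_unsupported_layer_rejected(self):
        with pytest.raises(AnalysisError, match="unsupported"):
            _propagate_through(Softmax(), np.ones(3), False)

    def test_mdnn_walk_covers_branches_and_head(self, tiny_mdnn_spec, rng):
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        x = rng.standard_normal((6, 32, 3))
        acts = penultimate_activations(net, x)
        assert acts.shape == (6, 16)
        seed = seed_scores_penultimate(acts, scorer=variance_scores)
        out = nisp_backpropagate(net, seed)
        groups = {iv.device_group for iv in out}
        assert groups == {"other", "all"}
        # every branch contributes its own layer entries
        branch_entries = [iv for iv in out if iv.device_group == "all"]
        assert len(branch_entries) == 3 * len(net.groups[0].branches[0].layers)


class TestLayerDifference:
    def test_identical_vectors_give_zero(self, rng):
        v = rng.uniform(0, 5, 7)
        assert layer_difference(v, v.copy()) == 0.0

    def test_opposed_unit_vectors(self):
        assert layer_difference(np.array([0.0, 1.0]),
                                np.array([1.0, 0.0])) == pytest.approx(np.sqrt(2))

    def test_matches_hand_computation_on_random_vectors(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 3, 5), rng.uniform(0, 3, 5)
            na = (a - a.min()) / (a.max() - a.min())
            nb = (b - b.min()) / (b.max() - b.min())
            assert layer_difference(a, b) == pytest.approx(
                np.sqrt(((na - nb) ** 2).sum()))

    def test_constant_vector_normalises_to_zeros(self):
        d = layer_difference(np.full(3, 7.0), np.array([0.0, 0.5, 1.0]))
        assert d == pytest.approx(np.sqrt(0 + 0.25 + 1.0))

    def test_length_mismatch(self):
        with pytest.raises(AnalysisError):
            layer_difference(np.ones(2), np.ones(3))


class TestJacobian:
    def _fd_saliency(self, net, X, h=1e-4):
        """Central finite-difference oracle for the global channel scores."""
        n, L, S = X.shape
        probs = forward(net, X)
        C = probs.shape[1]
        acc = np.zeros((n, S))
        for l in range(L):
            for s in range(S):
                Xp, Xm = X.copy(), X.copy()
                Xp[:, l, s] += h
                Xm[:, l, s] -= h
                J = (forward(net, Xp) - forward(net, Xm)) / (2 * h)  # (n, C)
                acc[:, s] += np.abs(J).sum(axis=1)
        omega = acc / (C * L)
        return omega.mean(axis=0)

    def test_matches_finite_differences(self, rng):
        from modtransfer.models import MDNNSpec
        spec = MDNNSpec.single_group(2, 12, 3, conv_filters=(3,),
                                     kernel_size=3, head_units=(6,))
        net = build_mdnn(spec, seed=0)
        X = rng.standard_normal((3, 12, 2))
        sal = jacobian_channel_saliency(net, TargetSegmentSet(X, np.zeros(3, int)))
        oracle = self._fd_saliency(net, X)
        np.testing.assert_allclose(sal.Omega, oracle, atol=1e-4)

    def test_ignored_channel_has_zero_score(self, tiny_mdnn_spec, rng):
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        dead = net.groups[0].branches[1]
        dead["conv1"].params["W"][...] = 0.0
        dead["conv1"].params["b"][...] = 0.0
        X = rng.standard_normal((5, 32, 3))
        sal = jacobian_channel_saliency(net, TargetSegmentSet(X, np.zeros(5, int)))
        assert sal.Omega[1] == 0.0
        assert sal.Omega[0] > 0 and sal.Omega[2] > 0

    def test_symmetric_channels_get_equal_scores(self, tiny_mdnn_spec, rng):
        from modtransfer.transfer import transfer_weights
        from modtransfer.models import build_sdnn
        sdnn = build_sdnn(tiny_mdnn_spec.sdnn_spec("all", 4), seed=1)
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        transfer_weights(sdnn, net)          # identical branches
        # identical data in channels 0 and 1; symmetrise the head weights
        W = net.head["fc1"].params["W"]
        width = W.shape[1] // 3              # per-branch output width
        W[:, width:2 * width] = W[:, :width]
        X = rng.standard_normal((6, 32, 3))
        X[:, :, 1] = X[:, :, 0]
        sal = jacobian_channel_saliency(net, TargetSegmentSet(X, np.zeros(6, int)))
        assert sal.Omega[0] == pytest.approx(sal.Omega[1], rel=1e-9)

    def test_omega_is_mean_of_per_example_omega(self, tiny_mdnn_spec, rng):
        net = build_mdnn(tiny_mdnn_spec, seed=2)
        X = rng.standard_normal((7, 32, 3))
        sal = jacobian_channel_saliency(net, TargetSegmentSet(X, np.zeros(7, int)))
        np.testing.assert_allclose(sal.Omega, sal.omega.mean(axis=0))
        perm = rng.permutation(7)
        sal2 = jacobian_channel_saliency(net,
                                         TargetSegmentSet(X[perm],
                                                          np.zeros(7, int)))
        np.testing.assert_allclose(sal.Omega, sal2.Omega, atol=1e-12)

    def test_jagged_groups_concatenate_in_channel_order(self,
                                                        two_group_mdnn_spec,
                                                        rng):
        net = build_mdnn(two_group_mdnn_spec, seed=0)
        X = [rng.standard_normal((4, 40, 2)), rng.standard_normal((4, 24, 2))]
        sal = jacobian_channel_saliency(
            net, TargetSegmentSet(X, np.zeros(4, int),
                                  group_names=["watch", "glasses"]))
        assert sal.Omega.shape == (4,)
        assert sal.channel_groups == ["watch", "watch", "glasses", "glasses"]

    def test_input_jacobian_shape(self, tiny_mdnn_spec, rng):
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        (J,) = input_jacobian(net, rng.standard_normal((2, 32, 3)))
        assert J.shape == (2, 4, 32, 3)


class TestCompareModels:
    def test_identical_models_have_zero_differences(self, tiny_mdnn_spec, rng):
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        x = rng.standard_normal((8, 32, 3))
        results = compare_models(net, net.copy(), x)
        assert all(r["difference"] == 0.0 for r in results)

    def test_output_is_sorted_and_covers_all_layers(self, tiny_mdnn_spec, rng):
        a = build_mdnn(tiny_mdnn_spec, seed=0)
        b = build_mdnn(tiny_mdnn_spec, seed=5)
        x = rng.standard_normal((8, 32, 3))
        results = compare_models(a, b, x)
        diffs = [r["difference"] for r in results]
        assert diffs == sorted(diffs, reverse=True)
        walk = nisp_backpropagate(
            a, seed_scores_penultimate(penultimate_activations(a, x)))
        assert len(results) == len(walk)
        assert {r["device_group"] for r in results} == {"other", "all"}

    def test_architecture_mismatch_rejected(self, tiny_mdnn_spec,
                                            two_group_mdnn_spec, rng):
        a = build_mdnn(tiny_mdnn_spec, seed=0)
        b = build_mdnn(two_group_mdnn_spec, seed=0)
        with pytest.raises(AnalysisError, match="architecture"):
            compare_models(a, b, rng.standard_normal((4, 32, 3)))
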