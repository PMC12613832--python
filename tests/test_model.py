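"""Model core: layer operations, fusion, head, full forward pass."""

import numpy as np
import pytest

from omicsgcn.graphs import ContractError
from omicsgcn.model import (
    GraphSet,
    extract_embeddings,
    forward,
    forward_multiomics,
    fuse_weighted,
    init_params,
    inter_layer,
    intra_layer,
    predict_head,
)

from conftest import random_normalized_graphs


class TestIntraLayer:
    def test_identity_propagation(self):
        H = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        out = intra_layer(H, np.eye(3), np.eye(3), slope=0.01)
        np.testing.assert_allclose(out, H)

    def test_hand_computed_example(self):
        A = np.full((2, 2), 0.5)
        H = np.array([[1.0], [3.0]])
        out = intra_layer(H, A, 2 * np.eye(2), slope=0.01)
        np.testing.assert_allclose(out, [[4.0], [4.0]])

    def test_leaky_relu_on_negative_preactivation(self):
        out = intra_layer(np.array([[1.0]]), np.array([[1.0]]), np.array([[-1.0]]), slope=0.01)
        np.testing.assert_allclose(out, [[-0.01]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            intra_layer(np.ones((3, 2)), np.eye(2), np.eye(2), 0.01)


class TestInterLayer:
    def test_zero_incidence_gives_zero_output(self):
        out = inter_layer(np.ones((3, 5)), np.zeros((2, 3)), np.eye(2), 0.01)
        assert not out.any()

    def test_scalar_example(self):
        out = inter_layer(np.array([[2.0]]), np.array([[0.5]]), np.array([[1.0]]), 0.01)
        np.testing.assert_allclose(out, [[1.0]])


def test_layer_outputs_match_per_node_aggregation_oracle():
    """Dense layer ops equal explicit neighbor sums on random instances."""
    rng = np.random.default_rng(7)
    slope = 0.01
    for _ in range(25):
        d, d2, n = rng.integers(1, 16), rng.integers(1, 16), rng.integers(1, 9)
        A = rng.random((d, d))
        A = (A + A.T) / 2
        W = rng.normal(size=(d, d))
        H = rng.normal(size=(d, n))
        out = intra_layer(H, A, W, slope)
        # brute force: pre[i, s] = sum_k W[i, k] * sum_j A[k, j] H[j, s]
        for i in range(d):
            for s in range(n):
                pre = sum(
                    W[i, k] * sum(A[k, j] * H[j, s] for j in range(d))
                    for k in range(d)
                )
                expected = pre if pre >= 0 else slope * pre
                assert abs(out[i, s] - expected) < 1e-8
        B = rng.random((d, d2))
        H2 = rng.normal(size=(d2, n))
        out2 = inter_layer(H2, B, W, slope)
        for i in range(d):
            for s in range(n):
                pre = sum(
                    W[i, k] * sum(B[k, j] * H2[j, s] for j in range(d2))
                    for k in range(d)
                )
                expected = pre if pre >= 0 else slope * pre
                assert abs(out2[i, s] - expected) < 1e-8


class TestFuseWeighted:
    def test_endpoints_exact(self, rng):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        assert (fuse_weighted(a, b, 1.0) == a).all()
        assert (fuse_weighted(a, b, 0.0) == b).all()

    def test_midpoint(self):
        np.testing.assert_allclose(
            fuse_weighted(np.array([[2.0]]), np.array([[0.0]]), 0.5), [[1.0]]
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            fuse_weighted(np.zeros((1, 1)), np.zeros((1, 1)), 1.5)


class TestPredictHead:
    def test_binary_scalar_example(self):
        pred = predict_head(
            [np.array([[1.0]]), np.array([[1.0]])], np.array([[1.0], [1.0]]), "binary"
        )
        assert pred.logits[0, 0] == pytest.approx(2.0)
        assert pred.scores[0, 0] == pytest.approx(1 / (1 + np.exp(-2.0)))

    def test_zero_weights_give_half_scores(self, rng):
        pred = predict_head([rng.normal(size=(3, 5))], np.zeros((3, 1)), "binary")
        np.testing.assert_allclose(pred.scores, 0.5)

    def test_softmax_rows_sum_to_one(self, rng):
        pred = predict_head([rng.normal(size=(4, 6))], rng.normal(size=(4, 3)), "multiclass")
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0, atol=1e-6)


class TestForward:
    def test_k_one_matches_intra_only_bitwise(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        params_k1 = params.copy()
        params_k1.k = 1.0
        pred_both, _ = forward(params_k1, graphs, X)
        params_intra = params.copy()
        params_intra.mode = "intra_only"
        pred_intra, _ = forward(params_intra, graphs, X)
        assert (pred_both.scores == pred_intra.scores).all()

    def test_k_zero_matches_inter_only_bitwise(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        params_k0 = params.copy()
        params_k0.k = 0.0
        pred_both, _ = forward(params_k0, graphs, X)
        params_inter = params.copy()
        params_inter.mode = "inter_only"
        pred_inter, _ = forward(params_inter, graphs, X)
        assert (pred_both.scores == pred_inter.scores).all()

    def test_single_layer_linear_closed_form(self, rng):
        """With identity weights, slope 1 and k=1, layer 1 is A_hat @ X^T."""
        graphs = random_normalized_graphs(rng, 4, 3)
        params = init_params({"u": 4, "v": 3}, L=1, k=1.0, leaky_slope=1.0, seed=0)
        for layer in params.intra_weights:
            for m in layer:
                layer[m] = np.eye(layer[m].shape[0])
        X = {"u": rng.normal(size=(5, 4)), "v": rng.normal(size=(5, 3))}
        _, state = forward(params, graphs, X)
        np.testing.assert_allclose(
            state.layers[0].h_out["u"], graphs.intra["u"] @ X["u"].T, atol=1e-12
        )

    def test_sample_permutation_equivariance(self, tiny_problem, rng):
        params, graphs, X, _ = tiny_problem
        perm = rng.permutation(X["u"].shape[0])
        pred, _ = forward(params, graphs, X)
        pred_p, _ = forward(params, graphs, {m: X[m][perm] for m in X})
        np.testing.assert_allclose(pred_p.scores, pred.scores[perm], atol=1e-12)

    def test_feature_permutation_equivariance(self, tiny_problem, rng):
        """Consistently permuting features of one block permutes its
        hidden rows and leaves predictions unchanged."""
        params, graphs, X, _ = tiny_problem
        p = params.dims["u"]
        perm = rng.permutation(p)
        params2 = params.copy()
        for l in range(params.L):
            params2.intra_weights[l]["u"] = params.intra_weights[l]["u"][np.ix_(perm, perm)]
            params2.inter_weights[l][("u", "v")] = params.inter_weights[l][("u", "v")][np.ix_(perm, perm)]
        graphs2 = GraphSet(
            intra={"u": graphs.intra["u"][np.ix_(perm, perm)], "v": graphs.intra["v"]},
            inter={
                ("u", "v"): graphs.inter[("u", "v")][perm, :],
                ("v", "u"): graphs.inter[("v", "u")][:, perm],
            },
        )
        head2 = params.head_weight.copy()
        head2[:p] = params.head_weight[:p][perm]
        params2.head_weight = head2
        X2 = {"u": X["u"][:, perm], "v": X["v"]}
        pred, state = forward(params, graphs, X)
        pred2, state2 = forward(params2, graphs2, X2)
        np.testing.assert_allclose(pred2.scores, pred.scores, atol=1e-10)
        np.testing.assert_allclose(
            state2.layers[-1].h_out["u"], state.layers[-1].h_out["u"][perm], atol=1e-10
        )

    def test_hidden_shapes_constant_across_layers(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        _, state = forward(params, graphs, X)
        n = X["u"].shape[0]
        for st in state.layers:
            assert st.h_out["u"].shape == (params.dims["u"], n)
            assert st.h_out["v"].shape == (params.dims["v"], n)

    def test_missing_bipartite_pair_rejected(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        broken = GraphSet(intra=graphs.intra, inter={})
        with pytest.raises(ContractError, match=r"pair"):
            forward(params, broken, X)


class TestMultiOmics:
    def _three_omics(self, rng, zero_into_u=False):
        from omicsgcn.graphs import (
            BipartiteGraph,
            FeatureGraph,
            assemble_and_normalize_bipartite,
            normalize_sym,
        )

        dims = {"a": 4, "b": 3, "c": 3}
        intra, bip = {}, {}
        for m, d in dims.items():
            adj = np.triu((rng.random((d, d)) < 0.5).astype(np.int8), k=1)
            adj = adj + adj.T
            intra[m] = normalize_sym(FeatureGraph(m, [f"{m}{i}" for i in range(d)], adj, 0.0))
        names = list(dims)
        for i, u in enumerate(names):
            for v in names[i + 1 :]:
                if zero_into_u and "a" in (u, v):
                    inc = np.zeros((dims[u], dims[v]), dtype=np.int8)
                else:
                    inc = (rng.random((dims[u], dims[v])) < 0.5).astype(np.int8)
                bip[(u, v)] = assemble_and_normalize_bipartite(
                    BipartiteGraph(
                        [f"{u}{i}" for i in range(dims[u])],
                        [f"{v}{i}" for i in range(dims[v])],
                        inc,
                    )
                )
        graphs = GraphSet.from_normalized(intra, bip)
        X = {m: rng.normal(size=(5, d)) for m, d in dims.items()}
        return dims, graphs, X

    def test_two_omics_paths_identical(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        pred_a, _ = forward(params, graphs, X)
        pred_b, _ = forward_multiomics(params, graphs, X)
        assert (pred_a.scores == pred_b.scores).all()

    def test_zero_bipartite_into_one_block_scales_intra_by_k(self, rng):
        dims, graphs, X = self._three_omics(rng, zero_into_u=True)
        params = init_params(dims, L=1, k=0.7, seed=1)
        _, state = forward(params, graphs, X)
        st = state.layers[0]
        # inter terms into 'a' are LeakyReLU(0) = 0, so H_a = k * Z_a
        np.testing.assert_allclose(st.h_out["a"], 0.7 * st.z_intra["a"], atol=1e-12)

    def test_permuting_other_omics_leaves_block_unchanged(self, rng):
        """The mean aggregation over incoming blocks is order-symmetric."""
        dims, graphs, X = self._three_omics(rng)
        params = init_params(dims, L=2, k=0.5, seed=2)
        _, state = forward(params, graphs, X)
        # swap omics b and c everywhere (names relabelled consistently)
        swap = {"a": "a", "b": "c", "c": "b"}
        dims2 = {swap[m]: d for m, d in dims.items()}
        params2 = init_params(dims2, L=2, k=0.5, seed=3)
        for l in range(2):
            for m in dims:
                params2.intra_weights[l][swap[m]] = params.intra_weights[l][m]
            for (dst, src), w in params.inter_weights[l].items():
                params2.inter_weights[l][(swap[dst], swap[src])] = w
        graphs2 = GraphSet(
            intra={swap[m]: g for m, g in graphs.intra.items()},
            inter={(swap[d], swap[s]): b for (d, s), b in graphs.inter.items()},
        )
        X2 = {swap[m]: x for m, x in X.items()}
        _, state2 = forward(params2, graphs2, X2)
        np.testing.assert_allclose(
            state2.layers[-1].h_out["a"], state.layers[-1].h_out["a"], atol=1e-12
        )


class TestEmbeddings:
    def test_shape_and_column_order(self, rng):
        graphs = random_normalized_graphs(rng, 2, 1)
        params = init_params({"u": 2, "v": 1}, L=1, seed=0)
        X = {"u": rng.normal(size=(3, 2)), "v": rng.normal(size=(3, 1))}
        _, state = forward(params, graphs, X)
        emb = extract_embeddings(
            state, feature_ids={"u": ["g1", "g2"], "v": ["m1"]}, sample_ids=["s1", "s2", "s3"]
        )
        assert emb.shape == (3, 3)
        assert list(emb.columns) == ["g1", "g2", "m1"]

    def test_values_match_head_input(self, tiny_problem):
        params, graphs, X, _ = tiny_problem
        _, state = forward(params, graphs, X)
        emb = extract_embeddings(state)
        np.testing.assert_array_equal(emb.to_numpy(), np.vstack(state.final_blocks()).T)
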