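"""The attention mechanism, graph views, layers and forward pass.

Numerical checks compare the vectorized implementation against the dense
per-node brute-force oracle in oracles.py.
"""

import numpy as np
import pytest

from trigat import (
    GATViewParams,
    ModelConfig,
    TriGATParams,
    attention_coefficients,
    cross_entropy_loss,
    derive_graph_views,
    gat_layer,
    model_forward,
    trigat_layer,
)
from trigat.autodiff import Tensor, gather

from conftest import make_graph
from oracles import (
    dense_attention,
    dense_forward,
    dense_gat_layer,
    params_to_numpy,
    random_graph,
    view_edges,
)


def init_view(rng, in_dim=4, out_dim=3, edge_dim=2, heads=2):
    return GATViewParams.init(rng, in_dim, out_dim, edge_dim, out_dim, heads)


class TestAttentionCoefficients:
    def test_isolated_node_attends_only_to_itself(self, rng):
        params = init_view(rng)
        X = rng.standard_normal((3, 4))
        # node 2 has no in-edges
        src, dst = np.array([0]), np.array([1])
        E = np.ones((1, 2))
        _, aself = attention_coefficients(X, E, src, dst, params)
        assert aself[2] == pytest.approx(1.0)

    def test_identical_features_and_zero_edge_features_give_uniform_weights(self, rng):
        params = init_view(rng)
        X = np.tile(rng.standard_normal(4), (3, 1))  # all nodes identical
        src, dst = np.array([0, 1]), np.array([2, 2])
        E = np.zeros((2, 2))  # matches the zero self-loop convention
        ae, aself = attention_coefficients(X, E, src, dst, params)
        assert ae == pytest.approx([1 / 3, 1 / 3]) and aself[2] == pytest.approx(1 / 3)

    def test_three_node_chain_matches_dense_oracle(self, rng):
        params = init_view(rng, heads=1)
        X = np.array([[1.0, 0, 0, 2], [0, 1, 1, 0], [2, 1, 0, 1]])
        edges = [(0, 1), (1, 2)]
        E = np.array([[1.0, 0], [0, 1.0]])
        ae, aself = attention_coefficients(X, E, np.array([0, 1]), np.array([1, 2]),
                                           params, head=0)
        p = params_to_numpy(params)[0]
        oe, oself = dense_attention(X, E, edges, p["W"], p["a_dst"], p["a_src"],
                                    p["a_e"], p["W_e"], slope=0.2)
        assert np.abs(ae - oe).max() < 1e-6
        assert np.abs(aself - oself).max() < 1e-6

    def test_normalization_over_random_graphs(self, rng):
        for trial in range(10):
            X, E, edges = random_graph(rng, 7, 12, 4, 2)
            params = init_view(rng)
            src = np.array([e[0] for e in edges])
            dst = np.array([e[1] for e in edges])
            for head in range(2):
                ae, aself = attention_coefficients(X, E, src, dst, params, head=head)
                sums = aself.copy()
                np.add.at(sums, dst, ae)
                assert np.abs(sums - 1.0).max() < 1e-6

    def test_wrong_feature_dimension_rejected(self, rng):
        params = init_view(rng)
        with pytest.raises(ValueError, match="dimension"):
            attention_coefficients(rng.standard_normal((3, 5)), np.ones((1, 2)),
                                   np.array([0]), np.array([1]), params)


class TestGatLayer:
    def test_isolated_node_output_is_activated_self_transform(self, rng):
        params = init_view(rng, heads=1)
        X = rng.standard_normal((2, 4))
        out = gat_layer(Tensor(X), Tensor(np.zeros((0, 2))),
                        np.array([], dtype=int), np.array([], dtype=int),
                        params, combine="concat")
        expected = X @ params.W[0].data + params.bias[0].data
        expected = np.where(expected > 0, expected, np.exp(expected) - 1)
        assert np.abs(out.data - expected).max() < 1e-9

    def test_concat_output_width_is_heads_times_hidden(self, rng):
        params = init_view(rng, out_dim=8, heads=3)
        X, E, edges = random_graph(rng, 5, 6, 4, 2)
        out = gat_layer(Tensor(X), Tensor(E),
                        np.array([e[0] for e in edges]),
                        np.array([e[1] for e in edges]), params, combine="concat")
        assert out.shape == (5, 24)

    def test_matches_dense_oracle_both_combines(self, rng):
        X, E, edges = random_graph(rng, 4, 5, 4, 2)
        src = np.array([e[0] for e in edges])
        dst = np.array([e[1] for e in edges])
        params = init_view(rng, heads=2)
        for combine in ("concat", "average"):
            out = gat_layer(Tensor(X), Tensor(E), src, dst, params, combine=combine)
            oracle = dense_gat_layer(X, E, edges, params_to_numpy(params),
                                     slope=0.2, combine=combine)
            assert np.abs(out.data - oracle).max() < 1e-6


class TestGraphViews:
    def test_reverse_and_bidirectional_definitions(self):
        views = derive_graph_views(np.array([0]), np.array([1]), np.array([[1.0, 0]]))
        src2, dst2, e2 = views["G2"]
        assert (src2.tolist(), dst2.tolist()) == ([1], [0])
        assert np.array_equal(e2, [[1.0, 0]])
        src3, dst3, e3 = views["G3"]
        assert sorted(zip(src3, dst3)) == [(0, 1), (1, 0)]
        assert np.array_equal(e3, [[1.0, 0], [1.0, 0]])  # reverse inherits

    def test_symmetric_graph_is_a_fixed_point(self):
        src = np.array([0, 1, 1, 2])
        dst = np.array([1, 0, 2, 1])
        E = np.arange(8, dtype=float).reshape(4, 2)
        views = derive_graph_views(src, dst, E)
        for name in ("G1", "G2", "G3"):
            s, d, _ = views[name]
            assert sorted(zip(s, d)) == sorted(zip(src, dst))
        # reciprocated edges keep their own features in G3
        s3, d3, e3 = views["G3"]
        feats = {(int(u), int(v)): tuple(f) for u, v, f in zip(s3, d3, e3)}
        assert feats[(0, 1)] == (0.0, 1.0) and feats[(1, 0)] == (2.0, 3.0)

    def test_g3_edge_set_equals_union_with_reverse_on_random_digraphs(self, rng):
        for _ in range(20):
            _, E, edges = random_graph(rng, 6, 10, 3, 2)
            views = derive_graph_views(np.array([e[0] for e in edges]),
                                       np.array([e[1] for e in edges]), E)
            s3, d3, _ = views["G3"]
            got = set(zip(s3.tolist(), d3.tolist()))
            expected = set(edges) | {(v, u) for u, v in edges}
            assert got == expected
            assert len(s3) == len(got)  # no duplicate edges in G3


class TestTriGATLayer:
    def test_output_width_is_three_per_view_blocks(self, rng):
        X, E, edges = random_graph(rng, 5, 7, 4, 2)
        views = derive_graph_views(np.array([e[0] for e in edges]),
                                   np.array([e[1] for e in edges]), E)
        params = {v: init_view(rng, out_dim=8, heads=2) for v in ("G1", "G2", "G3")}
        out = trigat_layer(Tensor(X), views, params, combine="concat")
        assert out.shape == (5, 3 * 16)

    def test_tied_parameters_on_symmetric_graph_give_identical_blocks(self, rng):
        src = np.array([0, 1, 1, 2])
        dst = np.array([1, 0, 2, 1])
        E = np.ones((4, 2))
        views = derive_graph_views(src, dst, E)
        shared = init_view(rng, out_dim=3, heads=1)
        out = trigat_layer(Tensor(rng.standard_normal((3, 4))), views,
                           {v: shared for v in ("G1", "G2", "G3")}, combine="concat")
        b1, b2, b3 = out.data[:, :3], out.data[:, 3:6], out.data[:, 6:]
        assert np.allclose(b1, b2) and np.allclose(b1, b3)

    def test_matches_dense_oracle(self, rng):
        X, E, edges = random_graph(rng, 5, 8, 4, 2)
        views = derive_graph_views(np.array([e[0] for e in edges]),
                                   np.array([e[1] for e in edges]), E)
        params = {v: init_view(rng, heads=2) for v in ("G1", "G2", "G3")}
        out = trigat_layer(Tensor(X), views, params, combine="concat")
        from oracles import dense_trigat_layer
        oracle = dense_trigat_layer(
            X, E, edges, {v: params_to_numpy(params[v]) for v in params},
            slope=0.2, combine="concat", views=("G1", "G2", "G3"))
        assert np.abs(out.data - oracle).max() < 1e-6


class TestModelForward:
    def test_output_in_unit_interval_with_one_entry_per_node(self):
        graph = make_graph(n_nodes=9)
        cfg = ModelConfig(num_trigat_layers=2, heads=2, hidden_dim=4, seed=3)
        params = TriGATParams.init(cfg, in_dim=graph.X.shape[1],
                                   edge_dim=graph.edge_features.shape[1])
        h = model_forward(graph, params, cfg)
        assert h.shape == (9,)
        assert ((h.data > 0) & (h.data < 1)).all()

    def test_matches_end_to_end_dense_oracle(self, rng):
        graph = make_graph(n_nodes=5, edges=((0, 1), (1, 2), (2, 3), (3, 4), (4, 0)),
                           feat_dim=3, edge_dim=2, positives=(0, 4), seed=5)
        cfg = ModelConfig(num_trigat_layers=2, heads=2, hidden_dim=3, seed=11)
        params = TriGATParams.init(cfg, in_dim=3, edge_dim=2)
        h = model_forward(graph, params, cfg)
        edges = list(zip(graph.edge_src.tolist(), graph.edge_dst.tolist()))
        layers_np = [{v: params_to_numpy(layer[v]) for v in layer}
                     for layer in params.layers]
        oracle = dense_forward(graph.X, graph.edge_features, edges, layers_np,
                               params.W_out.data, params.b_out.data,
                               slope=cfg.leaky_relu_slope,
                               combines=["concat", "average"],
                               views=("G1", "G2", "G3"))
        assert np.abs(h.data - oracle).max() < 1e-5

    def test_single_view_blind_to_downstream_but_trigat_is_not(self):
        """On a chain A→B→C, a G1-only model cannot see C from A (information
        moves only along edge direction), while the three-view model can."""
        graph = make_graph(n_nodes=3, edges=((0, 1), (1, 2)), feat_dim=4,
                           edge_dim=2, positives=(0,), seed=2)
        perturbed = make_graph(n_nodes=3, edges=((0, 1), (1, 2)), feat_dim=4,
                               edge_dim=2, positives=(0,), seed=2)
        perturbed.X[2] += 10.0
        for views, expect_change in ((("G1",), False), (("G1", "G2", "G3"), True)):
            cfg = ModelConfig(num_trigat_layers=2, heads=2, hidden_dim=4,
                              views=views, seed=9)
            params = TriGATParams.init(cfg, in_dim=4, edge_dim=2)
            base = model_forward(graph, params, cfg).data[0]
            moved = model_forward(perturbed, params, cfg).data[0]
            assert (abs(base - moved) > 1e-9) == expect_change


class TestCrossEntropyLoss:
    def test_perfect_prediction_loss_vanishes(self):
        h = Tensor(np.array([1.0 - 1e-9]))
        assert cross_entropy_loss(np.array([1.0]), h).data < 1e-6

    def test_half_probability_gives_ln2(self):
        loss = cross_entropy_loss(np.array([1.0]), Tensor(np.array([0.5])))
        assert loss.data == pytest.approx(np.log(2), abs=1e-9)

    def test_batch_mean_matches_hand_computation(self):
        loss = cross_entropy_loss(np.array([1.0, 0.0]),
                                  Tensor(np.array([0.8, 0.3])))
        assert loss.data == pytest.approx((-np.log(0.8) - np.log(0.7)) / 2, abs=1e-12)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([1.0]), Tensor(np.array([0.5, 0.5])))
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([]), Tensor(np.array([])))

    def test_gradient_flows_through_indexed_subset(self):
        h = Tensor(np.array([0.8, 0.3, 0.6]))
        loss = cross_entropy_loss(np.array([1.0, 0.0]), gather(h, np.array([0, 1])))
        loss.backward()
        assert h.grad is not None and h.grad[2] == 0.0


def test_zero_edge_weights_reduce_to_edge_free_attention(rng):
    """With W_e = 0 the edge-feature attention equals the plain (edge-free)
    formula on the same graph: bitwise, because the edge term vanishes."""
    X, E, edges = random_graph(rng, 6, 10, 4, 3)
    src = np.array([e[0] for e in edges])
    dst = np.array([e[1] for e in edges])
    params = init_view(rng, edge_dim=3)
    for k in range(params.heads):
        params.W_e[k].data[:] = 0.0
    ae, aself = attention_coefficients(X, E, src, dst, params, head=0)
    # edge-free formula == same computation with all edge features removed
    ae0, aself0 = attention_coefficients(X, np.zeros_like(E), src, dst, params, head=0)
    assert np.array_equal(ae, ae0) and np.array_equal(aself, aself0)
    # and it agrees with the independent dense edge-free oracle
    p = params_to_numpy(params)[0]
    oe, oself = dense_attention(X, np.zeros_like(E), edges, p["W"], p["a_dst"],
                                p["a_src"], np.zeros_like(p["a_e"]),
                                np.zeros_like(p["W_e"]), slope=0.2)
    assert np.abs(ae - oe).max() < 1e-12
    assert np.abs(aself - oself).max() < 1e-12
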