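import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from cginet.autodiff import Tensor
from cginet.encoder import (ConfigurationError, EncoderConfig,
                            encode_binary_stage, encode_interaction_stage,
                            encode_total, init_encoder_params, rgcn_layer)
from cginet.graph_core import build_adjacencies, split_cg_edges
from cginet.latent_links import LatentLinkSet, mine_latent_links
from conftest import make_toy_graph, random_multirelational


def dense_layer_oracle(adjacency, rels, weights, h, activation="identity"):
    """Brute-force evaluation of one relational graph convolution:
    explicit loops over relations and node pairs, straight from the edge
    sets and the documented normalization."""
    n = adjacency.n_nodes
    d_out = weights[rels[0]].shape[1]
    out = np.zeros((n, d_out))
    for rel in rels:
        A = adjacency.adj[rel].toarray()
        d_in = A.sum(axis=1)
        d_out_deg = A.sum(axis=0)
        W = weights[rel]
        for i in range(n):
            if d_in[i] == 0:
                continue
            for j in range(n):
                if A[i, j]:
                    out[i] += (h[j] @ W) / np.sqrt(d_in[i] * d_out_deg[j])
            out[i] += (h[i] @ W) / d_in[i]
    if activation == "relu":
        out = np.maximum(out, 0)
    return out


def chain_adjacency(graph):
    split = split_cg_edges(graph, (1.0, 0.0, 0.0), seed=0) \
        if graph.cg_edges else None
    if split is None:
        from cginet.graph_core import EdgeSplit
        split = EdgeSplit(folds={}, ratios=(1, 0, 0), split_seed=0)
    return build_adjacencies(graph, split)


class TestLayerOracle:
    @pytest.mark.parametrize("gseed", range(10))
    def test_sparse_equals_dense_brute_force(self, gseed):
        rng = np.random.default_rng(gseed)
        graph = random_multirelational(rng, n_chem=6, n_gene=9, n_path=3,
                                       n_types=1)
        adjacency = chain_adjacency(graph)
        rels = ["cc", "gg"] + [k for k in adjacency.adj if k.startswith("cg|")]
        assert len(rels) == 3
        d_in, d_out = 5, 4
        h = rng.normal(size=(adjacency.n_nodes, d_in))
        weights = {r: rng.normal(size=(d_in, d_out)) for r in rels}
        mats = {r: adjacency.message_matrix(r) for r in rels}
        got = rgcn_layer(Tensor(h), mats,
                         {r: Tensor(w) for r, w in weights.items()},
                         activation="identity")
        want = dense_layer_oracle(adjacency, rels, weights, h)
        assert np.allclose(got.data, want, atol=1e-6)

    def test_mutual_pair_identity_weights(self):
        graph = make_toy_graph(["c1", "c2"], [], [], cc=[("c1", "c2")])
        adjacency = chain_adjacency(graph)
        h = np.array([[1.0, 2.0], [10.0, 20.0]])
        out = rgcn_layer(Tensor(h), {"cc": adjacency.message_matrix("cc")},
                         {"cc": Tensor(np.eye(2))}, activation="identity")
        # both normalizers are 1: h1' = h2 + h1
        assert np.allclose(out.data[0], h[0] + h[1])
        assert np.allclose(out.data[1], h[0] + h[1])

    def test_isolated_node_maps_to_zero(self):
        graph = make_toy_graph(["c1", "c2", "c3"], [], [], cc=[("c1", "c2")])
        adjacency = chain_adjacency(graph)
        h = np.ones((3, 2))
        out = rgcn_layer(Tensor(h), {"cc": adjacency.message_matrix("cc")},
                         {"cc": Tensor(np.eye(2))}, activation="identity")
        assert np.allclose(out.data[2], 0.0)

    def test_path_graph_middle_node(self):
        graph = make_toy_graph(["c1", "c2", "c3"], [], [],
                               cc=[("c1", "c2"), ("c2", "c3")])
        adjacency = chain_adjacency(graph)
        h = np.array([[1.0], [4.0], [9.0]])
        out = rgcn_layer(Tensor(h), {"cc": adjacency.message_matrix("cc")},
                         {"cc": Tensor(np.eye(1))}, activation="identity")
        # degrees 1, 2, 1: middle gets (h1 + h3)/sqrt(2) + h2/2
        want_mid = (h[0, 0] + h[2, 0]) / np.sqrt(2) + h[1, 0] / 2
        assert out.data[1, 0] == pytest.approx(want_mid)


class TestEncoders:
    def _setup(self, fixture_graph_split, **cfg):
        graph, split, _ = fixture_graph_split
        adjacency = build_adjacencies(graph, split)
        config = EncoderConfig(**cfg)
        rng = np.random.default_rng(0)
        params = init_encoder_params(adjacency, config, rng)
        return adjacency, config, params

    def test_total_output_dimensionality(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split,
                                                perspective="total")
        z = encode_total(adjacency, config, params)
        assert z.values.shape == (adjacency.n_nodes, config.total_dims[-1])

    def test_all_zero_weights_give_zero_embeddings(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split,
                                                perspective="total")
        for p in params.values():
            p.data[:] = 0.0
        z = encode_total(adjacency, config, params)
        assert np.allclose(z.values.data, 0.0)

    def test_deterministic_given_seed(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split)
        z1 = encode_binary_stage(adjacency, config, params)
        z2 = encode_binary_stage(adjacency, config, params)
        assert np.array_equal(z1.values.data, z2.values.data)

    def test_binary_stage_dimensionality_and_pathways(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split)
        z = encode_binary_stage(adjacency, config, params)
        assert z.values.shape[1] == config.binary_dims[-1] == 64
        assert z.stage == "initial"
        # pathway rows are produced (they serve as message sources)
        n_cg = adjacency.n_chemicals + adjacency.n_genes
        assert z.values.data[n_cg:].shape[0] == adjacency.n_pathways

    def test_subgraph_final_dimensionality(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split)
        initial = encode_binary_stage(adjacency, config, params)
        z = encode_interaction_stage(adjacency, initial, config, params)
        assert z.values.shape[1] == config.interaction_dims[-1] == 16
        assert z.stage == "final"

    def test_latent_without_mode_is_config_error(self, fixture_graph_split):
        graph, split, _ = fixture_graph_split
        adjacency, config, params = self._setup(fixture_graph_split)
        initial = encode_binary_stage(adjacency, config, params)
        latent = mine_latent_links(graph, split, lam=0.5)
        with pytest.raises(ConfigurationError):
            encode_interaction_stage(adjacency, initial, config, params,
                                     latent=latent)

    def test_empty_latent_set_equals_no_latent(self, fixture_graph_split):
        adjacency, config, params = self._setup(fixture_graph_split)
        initial = encode_binary_stage(adjacency, config, params)
        z_none = encode_interaction_stage(adjacency, initial, config, params)
        cfg_fixed = dataclasses.replace(config, latent_mode="fixed")
        empty = LatentLinkSet(lam=0.5, candidates={}, definite={})
        z_fixed = encode_interaction_stage(adjacency, initial, cfg_fixed,
                                           params, latent=empty)
        assert np.array_equal(z_none.values.data, z_fixed.values.data)

    def test_latent_neighbor_messages_add_by_hand(self):
        # one labeled neighbor plus one latent neighbor, identity weights,
        # all degree normalizers 1, mu = 1: pre-act = h_labeled + h_latent
        from cginet.graph_core import EdgeSplit
        graph = make_toy_graph(
            ["c1"], ["g1", "g2"], [],
            cg=[("c1", "affects^x", "g1")])
        t = "affects^x"
        split = EdgeSplit(folds={t: {"train": set(graph.cg_edges),
                                     "valid": set(), "test": set()}},
                          ratios=(1, 0, 0), split_seed=0)
        adjacency = build_adjacencies(graph, split)
        latent = LatentLinkSet(lam=0.5, candidates={t: {("c1", "g2"): 3}},
                               definite={t: {("c1", "g2")}})
        config = EncoderConfig(latent_mode="fixed", latent_norm="separate",
                               interaction_dims=(2,), binary_dims=(2, 2),
                               activation="identity",
                               final_activation="identity", dropout=0.0)
        rng = np.random.default_rng(0)
        params = init_encoder_params(adjacency, config, rng)
        h0 = np.array([[1.0, 0.0],    # c1
                       [0.0, 2.0],    # g1
                       [5.0, 5.0]])   # g2
        for d in ("cg", "gc"):
            params[f"inter/{d}|{t}/W0"] = Tensor(np.eye(2))
        initial = type("E", (), {"values": Tensor(h0)})()
        z = encode_interaction_stage(adjacency, initial, config, params,
                                     latent=latent)
        # c1: labeled neighbor g1 + self + latent neighbor g2, all weights 1
        assert np.allclose(z.values.data[0], h0[1] + h0[0] + h0[2])
        # g2 has no labeled edges of the type: under the separate normalizer
        # its latent message is dropped (isolated-node convention)
        assert np.allclose(z.values.data[2], 0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        graph_a = random_multirelational(rng, n_chem=5, n_gene=6, n_path=2,
                                         n_types=1)
        # rename chemicals so the sorted order changes
        mapping = {c: f"z{i}" for i, c in enumerate(graph_a.chemicals)}
        graph_b = make_toy_graph(
            [mapping[c] for c in graph_a.chemicals],
            list(graph_a.genes), list(graph_a.pathways),
            cc={(mapping[a], mapping[b]) for a, b in graph_a.cc_edges},
            gg=graph_a.gg_edges,
            cp={(mapping[c], p) for c, p in graph_a.cp_edges},
            gp=graph_a.gp_edges,
            cg={(mapping[c], t, g) for c, t, g in graph_a.cg_edges})
        adj_a = chain_adjacency(graph_a)
        adj_b = chain_adjacency(graph_b)
        config = EncoderConfig(perspective="total", dropout=0.0)
        params_a = init_encoder_params(adj_a, config, np.random.default_rng(1))
        # permute the one-hot lookup rows to follow the relabeled index
        perm = [adj_a.node_index[{v: k for k, v in mapping.items()}.get(n, n)]
                for n in sorted(adj_b.node_index, key=adj_b.node_index.get)]
        params_b = {k: Tensor(v.data[perm] if k.endswith("W0") else v.data.copy())
                    for k, v in params_a.items()}
        z_a = encode_total(adj_a, config, params_a).values.data
        z_b = encode_total(adj_b, config, params_b).values.data
        assert np.allclose(z_b, z_a[perm], atol=1e-10)
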