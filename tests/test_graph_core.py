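import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cginet.graph_core import (EdgeSplit, GraphError, GraphParseError,
                               InteractionType, VocabularyError,
                               build_adjacencies, filter_rare_types,
                               load_graph, load_graph_dir, split_cg_edges,
                               trim_association_graphs, write_graph,
                               write_split, load_split)
from conftest import full_train_split, make_toy_graph


class TestInteractionType:
    def test_parse_canonical_roundtrip(self):
        it = InteractionType.parse("increases^activity")
        assert (it.degree, it.action) == ("increases", "activity")
        assert it.canonical == "increases^activity"

    @pytest.mark.parametrize("bad", ["enhances^activity", "increases",
                                     "increases^", "a^b^c"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(VocabularyError):
            InteractionType.parse(bad)


class TestLoadWrite:
    def _write_inputs(self, tmp_path, cg_lines, cc_lines=("c1\tc2",)):
        (tmp_path / "nodes.tsv").write_text(
            "c1\tchemical\nc2\tchemical\nc3\tchemical\n"
            "g1\tgene\ng2\tgene\np1\tpathway\n")
        (tmp_path / "cc.tsv").write_text("\n".join(cc_lines) + "\n")
        (tmp_path / "cg.tsv").write_text("\n".join(cg_lines) + "\n")
        return tmp_path / "nodes.tsv", {"cc": tmp_path / "cc.tsv",
                                        "cg": tmp_path / "cg.tsv"}

    def test_counts_echo_input(self, tmp_path):
        nodes, edges = self._write_inputs(
            tmp_path, ["c1\tincreases^activity\tg1"])
        graph = load_graph(nodes, edges)
        assert (len(graph.chemicals), len(graph.genes),
                len(graph.pathways)) == (3, 2, 1)
        assert len(graph.cg_edges) == 1

    def test_duplicate_edges_collapsed(self, tmp_path):
        nodes, edges = self._write_inputs(
            tmp_path, ["c1\tincreases^activity\tg1"],
            cc_lines=["c1\tc2", "c2\tc1"])
        graph = load_graph(nodes, edges)
        assert graph.cc_edges == {("c1", "c2")}

    def test_type_string_parses_into_components(self, tmp_path):
        nodes, edges = self._write_inputs(
            tmp_path, ["c1\tincreases^activity\tg1"])
        graph = load_graph(nodes, edges)
        it = graph.type_vocab["increases^activity"]
        assert (it.degree, it.action) == ("increases", "activity")

    def test_unknown_node_raises(self, tmp_path):
        nodes, edges = self._write_inputs(
            tmp_path, ["cX\tincreases^activity\tg1"])
        with pytest.raises(GraphError):
            load_graph(nodes, edges)

    def test_malformed_line_names_file_and_lineno(self, tmp_path):
        nodes, edges = self._write_inputs(tmp_path, ["c1\tonly-two-fields"])
        with pytest.raises(GraphParseError, match=r"cg\.tsv:1"):
            load_graph(nodes, edges)

    def test_comments_and_blanks_skipped(self, tmp_path):
        nodes, edges = self._write_inputs(
            tmp_path, ["# comment", "", "c1\tincreases^activity\tg1"])
        assert len(load_graph(nodes, edges).cg_edges) == 1

    def test_roundtrip_preserves_canonical_edges(self, tmp_path, toy_graph):
        write_graph(toy_graph, tmp_path / "out")
        again = load_graph_dir(tmp_path / "out")
        for attr in ("chemicals", "genes", "pathways", "cc_edges", "gg_edges",
                     "cp_edges", "gp_edges", "cg_edges"):
            assert getattr(again, attr) == getattr(toy_graph, attr)


class TestFilterRareTypes:
    def _graph_with_counts(self, counts):
        cg = []
        genes = set()
        for t, (name, n) in enumerate(counts.items()):
            for i in range(n):
                genes.add(f"g{i}")
                cg.append((f"c0", name, f"g{i}"))
        return make_toy_graph(["c0"], sorted(genes), [], cg=cg)

    def test_threshold_is_inclusive(self):
        graph = self._graph_with_counts(
            {"affects^a": 200, "affects^b": 179, "affects^c": 180})
        out = filter_rare_types(graph, 180)
        assert set(out.interaction_types) == {"affects^a", "affects^c"}

    def test_min_edges_one_is_identity(self, toy_graph):
        out = filter_rare_types(toy_graph, 1)
        assert out.cg_edges == toy_graph.cg_edges

    def test_empty_vocabulary_raises(self, toy_graph):
        with pytest.raises(GraphError, match="no relations survive"):
            filter_rare_types(toy_graph, 10_000)


class TestTrim:
    def test_cc_only_chemicals_removed(self):
        # 5 chemicals, 2 of which appear only in the cc layer
        graph = make_toy_graph(
            chemicals=[f"c{i}" for i in range(5)],
            genes=["g1"], pathways=["p1"],
            cc=[("c0", "c1"), ("c1", "c2"), ("c3", "c4")],
            cp=[("c0", "p1"), ("c1", "p1"), ("c2", "p1")],
            cg=[("c0", "affects^x", "g1")],
            gp=[("g1", "p1")],
        )
        out = trim_association_graphs(graph)
        assert len(out.chemicals) == len(graph.chemicals) - 2
        assert all("c3" not in e and "c4" not in e for e in out.cc_edges)

    def test_fully_anchored_graph_unchanged(self, toy_graph):
        out = trim_association_graphs(toy_graph)
        assert out.cc_edges == toy_graph.cc_edges
        assert out.chemicals == toy_graph.chemicals

    def test_idempotent(self):
        graph = make_toy_graph(
            chemicals=["c0", "c1", "c2"], genes=["g1"], pathways=[],
            cc=[("c0", "c1"), ("c1", "c2")],
            cg=[("c0", "affects^x", "g1")])
        once = trim_association_graphs(graph)
        twice = trim_association_graphs(once)
        assert once.cc_edges == twice.cc_edges
        assert once.chemicals == twice.chemicals


class TestSplit:
    def _graph_n_edges(self, n, type_id="affects^x"):
        genes = [f"g{i}" for i in range(n)]
        return make_toy_graph(["c0"], genes, [],
                              cg=[("c0", type_id, g) for g in genes])

    def test_ten_edges_split_8_1_1(self):
        split = split_cg_edges(self._graph_n_edges(10), (0.8, 0.1, 0.1), seed=0)
        sizes = tuple(len(split.folds["affects^x"][f]) for f in EdgeSplit.FOLDS)
        assert sizes == (8, 1, 1)

    def test_degenerate_ratio_all_train(self):
        split = split_cg_edges(self._graph_n_edges(7), (1.0, 0.0, 0.0), seed=0)
        sizes = tuple(len(split.folds["affects^x"][f]) for f in EdgeSplit.FOLDS)
        assert sizes == (7, 0, 0)

    def test_too_few_edges_mentions_min_edges(self):
        with pytest.raises(GraphError, match="min_edges"):
            split_cg_edges(self._graph_n_edges(2), (0.8, 0.1, 0.1), seed=0)

    def test_seeds_change_partition_not_sizes(self):
        graph = self._graph_n_edges(100)
        s1 = split_cg_edges(graph, seed=1)
        s2 = split_cg_edges(graph, seed=2)
        assert s1.folds["affects^x"]["train"] != s2.folds["affects^x"]["train"]
        for f in EdgeSplit.FOLDS:
            assert len(s1.folds["affects^x"][f]) == len(s2.folds["affects^x"][f])

    def test_same_seed_reproduces_exactly(self, fixture_graph_split):
        graph, _, _ = fixture_graph_split
        assert (split_cg_edges(graph, seed=5).folds
                == split_cg_edges(graph, seed=5).folds)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_folds_partition_each_type(self, seed):
        graph = self._graph_n_edges(23)
        split = split_cg_edges(graph, seed=seed)
        folds = split.folds["affects^x"]
        union = folds["train"] | folds["valid"] | folds["test"]
        assert union == {e for e in graph.cg_edges}
        assert not folds["train"] & folds["valid"]
        assert not folds["train"] & folds["test"]
        assert not folds["valid"] & folds["test"]

    def test_split_tsv_roundtrip(self, tmp_path, fixture_graph_split):
        graph, split, _ = fixture_graph_split
        write_split(split, tmp_path / "split.tsv")
        again = load_split(tmp_path / "split.tsv")
        assert again.folds == split.folds


class TestAdjacencies:
    def test_cc_symmetrized(self, toy_graph):
        split = full_train_split(toy_graph)
        adj = build_adjacencies(toy_graph, split)
        idx = adj.node_index
        assert adj.adj["cc"][idx["c1"], idx["c2"]] == 1
        assert adj.adj["cc"][idx["c2"], idx["c1"]] == 1

    def test_heldout_edges_absent_everywhere(self, fixture_graph_split):
        graph, split, _ = fixture_graph_split
        adj = build_adjacencies(graph, split)
        idx = adj.node_index
        for fold in ("valid", "test"):
            for c, t, g in list(split.folds[graph.interaction_types[0]][fold])[:20]:
                train_pairs = split.train_pairs(t)
                if (c, g) in train_pairs:
                    continue  # pair may also be a train edge of another type
                assert adj.adj[f"cg|{t}"][idx[c], idx[g]] == 0
                assert adj.adj[f"gc|{t}"][idx[g], idx[c]] == 0

    def test_degrees_equal_row_sums(self, toy_graph):
        split = full_train_split(toy_graph)
        adj = build_adjacencies(toy_graph, split)
        for rel, A in adj.adj.items():
            assert np.array_equal(adj.degrees(rel),
                                  np.asarray(A.sum(axis=1)).ravel())

    def test_node_without_train_edges_has_zero_degree(self, toy_graph):
        split = full_train_split(toy_graph)
        adj = build_adjacencies(toy_graph, split)
        # g4 only interacts under increases^activity; no decreases edges
        assert adj.degrees("gc|decreases^expression")[
            adj.node_index["g4"]] == 0
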