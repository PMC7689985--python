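import numpy as np
import pytest

from cginet.graph_core import (InteractionType, MultiRelationalGraph,
                               split_cg_edges)
from cginet.synthetic_data import default_fixture


@pytest.fixture(scope="session")
def fixture_graph_split():
    """The repository's canonical synthetic fixture (fixed seed)."""
    graph, split, spec = default_fixture()
    return graph, split, spec


def make_toy_graph(chemicals, genes, pathways, cc=(), gg=(), cp=(), gp=(),
                   cg=()):
    """Hand-built graph from explicit edge tuples; cg entries are
    (chemical, canonical type string, gene)."""
    vocab = {}
    cg_edges = set()
    for c, t, g in cg:
        it = InteractionType.parse(t)
        vocab[it.canonical] = it
        cg_edges.add((c, it.canonical, g))
    graph = MultiRelationalGraph(
        chemicals=tuple(sorted(chemicals)),
        genes=tuple(sorted(genes)),
        pathways=tuple(sorted(pathways)),
        cc_edges={tuple(sorted(e)) for e in cc},
        gg_edges={tuple(sorted(e)) for e in gg},
        cp_edges=set(cp),
        gp_edges=set(gp),
        cg_edges=cg_edges,
        type_vocab=vocab,
    )
    return graph.validate()


@pytest.fixture
def toy_graph():
    """Small graph with all five layers and two interaction types."""
    return make_toy_graph(
        chemicals=["c1", "c2", "c3"],
        genes=["g1", "g2", "g3", "g4"],
        pathways=["p1", "p2"],
        cc=[("c1", "c2")],
        gg=[("g1", "g2"), ("g2", "g3")],
        cp=[("c1", "p1"), ("c2", "p2")],
        gp=[("g1", "p1"), ("g2", "p1"), ("g3", "p2")],
        cg=[("c1", "increases^activity", "g1"),
            ("c1", "increases^activity", "g2"),
            ("c2", "decreases^expression", "g3"),
            ("c3", "increases^activity", "g4")],
    )


def random_multirelational(rng, n_chem=6, n_gene=8, n_path=3, n_types=2,
                           p=0.3):
    """Random small graph for oracle comparisons."""
    chemicals = [f"c{i}" for i in range(n_chem)]
    genes = [f"g{i}" for i in range(n_gene)]
    pathways = [f"p{i}" for i in range(n_path)]
    cc = [(a, b) for i, a in enumerate(chemicals) for b in chemicals[i + 1:]
          if rng.random() < p]
    gg = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
          if rng.random() < p]
    cp = [(c, q) for c in chemicals for q in pathways if rng.random() < p]
    gp = [(g, q) for g in genes for q in pathways if rng.random() < p]
    degrees = ["increases", "decreases", "affects"]
    types = [f"{degrees[i % 3]}^t{i}" for i in range(n_types)]
    cg = [(c, t, g) for c in chemicals for g in genes for t in types
          if rng.random() < p / 2]
    return make_toy_graph(chemicals, genes, pathways, cc, gg, cp, gp, cg)


def full_train_split(graph):
    """EdgeSplit with every cg edge in the train fold (for toy graphs too
    small to pass the per-type minimum of split_cg_edges)."""
    from cginet.graph_core import EdgeSplit
    folds = {t: {"train": {e for e in graph.cg_edges if e[1] == t},
                 "valid": set(), "test": set()}
             for t in graph.interaction_types}
    return EdgeSplit(folds=folds, ratios=(1.0, 0.0, 0.0), split_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
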