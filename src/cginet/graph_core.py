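"""Integrated multi-relational chemical/gene/pathway graph: data model, TSV
I/O, relation-vocabulary filtering, trimming, splitting, and sparse
adjacency construction.

The graph has three node classes (chemicals, genes, pathways) connected by
four untyped binary-association layers — chemical-chemical (cc), gene-gene
(gg), chemical-pathway (cp), gene-pathway (gp) — and one typed
chemical-gene (cg) interaction layer whose edges are triples
``(chemical, interaction_type, gene)``.  An interaction type combines a
degree (increases / decreases / affects) with an action label, written
canonically as ``"degree^action"`` (e.g. ``"decreases^activity"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEGREES = ("increases", "decreases", "affects")

ASSOCIATION_RELATIONS = ("cc", "gg", "cp", "pc", "gp", "pg")


class GraphError(Exception):
    """Base class for graph construction/validation failures."""


class GraphParseError(GraphError):
    """A malformed line in an input file."""


class VocabularyError(GraphError):
    """An interaction-type string that does not parse."""


@dataclass(frozen=True, order=True)
class InteractionType:
    """A typed chemical-gene interaction: degree + action, e.g. increases^activity."""

    degree: str
    action: str
    parent_type: str | None = None

    def __post_init__(self):
        if self.degree not in DEGREES:
            raise VocabularyError(
                f"unknown interaction degree {self.degree!r}; expected one of {DEGREES}"
            )

    @property
    def canonical(self) -> str:
        return f"{self.degree}^{self.action}"

    @classmethod
    def parse(cls, text: str, parent_type: str | None = None) -> "InteractionType":
        if text.count("^") != 1:
            raise VocabularyError(
                f"interaction type {text!r} is not of the form 'degree^action'"
            )
        degree, action = text.split("^")
        if not action:
            raise VocabularyError(f"interaction type {text!r} has an empty action")
        return cls(degree=degree, action=action, parent_type=parent_type)


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class MultiRelationalGraph:
    """Node sets plus the five relation-keyed edge stores.

    cc/gg edges are undirected and stored as canonically ordered pairs;
    cp/gp are bipartite pairs (chemical, pathway) / (gene, pathway); cg
    edges are triples (chemical, canonical type id, gene).
    """

    chemicals: tuple[str, ...]
    genes: tuple[str, ...]
    pathways: tuple[str, ...]
    cc_edges: set[tuple[str, str]] = field(default_factory=set)
    gg_edges: set[tuple[str, str]] = field(default_factory=set)
    cp_edges: set[tuple[str, str]] = field(default_factory=set)
    gp_edges: set[tuple[str, str]] = field(default_factory=set)
    cg_edges: set[tuple[str, str, str]] = field(default_factory=set)
    type_vocab: dict[str, InteractionType] = field(default_factory=dict)

    # -- introspection -------------------------------------------------------

    @property
    def interaction_types(self) -> list[str]:
        """Sorted canonical ids of types with at least one cg edge."""
        return sorted({t for _, t, _ in self.cg_edges})

    def cg_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, t, _ in self.cg_edges:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def cg_pairs(self, type_id: str) -> set[tuple[str, str]]:
        return {(c, g) for c, t, g in self.cg_edges if t == type_id}

    def with_cg_edges(self, edges: Iterable[tuple[str, str, str]]) -> "MultiRelationalGraph":
        """A shallow view of the graph with the cg layer replaced (e.g. train-only)."""
        return replace(self, cg_edges=set(edges))

    # -- validation ----------------------------------------------------------

    def validate(self) -> "MultiRelationalGraph":
        cset, gset, pset = set(self.chemicals), set(self.genes), set(self.pathways)
        for a, b in self.cc_edges:
            if a == b:
                raise GraphError(f"cc self-loop on {a!r}")
            if a not in cset or b not in cset:
                raise GraphError(f"cc edge ({a!r},{b!r}) references unknown chemical")
            if (b, a) in self.cc_edges and a != b:
                raise GraphError(f"cc edge ({a!r},{b!r}) stored non-canonically")
        for a, b in self.gg_edges:
            if a == b:
                raise GraphError(f"gg self-loop on {a!r}")
            if a not in gset or b not in gset:
                raise GraphError(f"gg edge ({a!r},{b!r}) references unknown gene")
        for c, p in self.cp_edges:
            if c not in cset or p not in pset:
                raise GraphError(f"cp edge ({c!r},{p!r}) references unknown node")
        for g, p in self.gp_edges:
            if g not in gset or p not in pset:
                raise GraphError(f"gp edge ({g!r},{p!r}) references unknown node")
        for c, t, g in self.cg_edges:
            if c not in cset or g not in gset:
                raise GraphError(f"cg edge ({c!r},{t!r},{g!r}) references unknown node")
            if t not in self.type_vocab:
                raise VocabularyError(f"cg edge uses undeclared type {t!r}")
        return self


# ---------------------------------------------------------------------------
# I/O


def _read_tsv_rows(path: Path, n_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise GraphParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def load_graph(node_manifest: str | Path,
               edge_files: Mapping[str, str | Path]) -> MultiRelationalGraph:
    """Load a validated graph from a node manifest plus per-relation TSVs.

    ``edge_files`` maps relation names (any of cc, gg, cp, gp, cg) to paths.
    Duplicate edges are deduplicated with a logged count; unknown node ids
    or malformed lines raise.
    """
    node_manifest = Path(node_manifest)
    by_class: dict[str, list[str]] = {"chemical": [], "gene": [], "pathway": []}
    seen: set[str] = set()
    for lineno, (node_id, node_class) in _read_tsv_rows(node_manifest, 2):
        if node_class not in by_class:
            raise GraphParseError(
                f"{node_manifest}:{lineno}: unknown node class {node_class!r}"
            )
        if node_id in seen:
            raise GraphParseError(
                f"{node_manifest}:{lineno}: duplicate node id {node_id!r}"
            )
        seen.add(node_id)
        by_class[node_class].append(node_id)

    graph = MultiRelationalGraph(
        chemicals=tuple(sorted(by_class["chemical"])),
        genes=tuple(sorted(by_class["gene"])),
        pathways=tuple(sorted(by_class["pathway"])),
    )
    cset, gset, pset = set(graph.chemicals), set(graph.genes), set(graph.pathways)

    def check(node_id: str, universe: set[str], path: Path, lineno: int, cls: str):
        if node_id not in universe:
            raise GraphError(f"{path}:{lineno}: unknown {cls} id {node_id!r}")

    n_dup = 0
    for rel in ("cc", "gg", "cp", "gp"):
        if rel not in edge_files:
            continue
        path = Path(edge_files[rel])
        store: set[tuple[str, str]] = getattr(graph, f"{rel}_edges")
        for lineno, (a, b) in _read_tsv_rows(path, 2):
            if rel in ("cc", "gg"):
                uni = cset if rel == "cc" else gset
                check(a, uni, path, lineno, rel[0])
                check(b, uni, path, lineno, rel[0])
                if a == b:
                    raise GraphParseError(f"{path}:{lineno}: self-loop on {a!r}")
                edge = _canon_pair(a, b)
            else:
                left = cset if rel == "cp" else gset
                check(a, left, path, lineno, rel[0])
                check(b, pset, path, lineno, "pathway")
                edge = (a, b)
            if edge in store:
                n_dup += 1
            store.add(edge)

    if "cg" in edge_files:
        path = Path(edge_files["cg"])
        for lineno, (c, type_str, g) in _read_tsv_rows(path, 3):
            check(c, cset, path, lineno, "chemical")
            check(g, gset, path, lineno, "gene")
            itype = InteractionType.parse(type_str)
            graph.type_vocab.setdefault(itype.canonical, itype)
            edge = (c, itype.canonical, g)
            if edge in graph.cg_edges:
                n_dup += 1
            graph.cg_edges.add(edge)

    if n_dup:
        logger.info("deduplicated %d duplicate edges while loading", n_dup)
    return graph.validate()


def write_graph(graph: MultiRelationalGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write the graph as the TSV dialect ``load_graph`` reads; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nodes_path = out_dir / "nodes.tsv"
    with open(nodes_path, "w") as fh:
        for cls, ids in (("chemical", graph.chemicals), ("gene", graph.genes),
                         ("pathway", graph.pathways)):
            for node_id in ids:
                fh.write(f"{node_id}\t{cls}\n")
    paths["nodes"] = nodes_path

    for rel in ("cc", "gg", "cp", "gp"):
        path = out_dir / f"{rel}.tsv"
        with open(path, "w") as fh:
            for a, b in sorted(getattr(graph, f"{rel}_edges")):
                fh.write(f"{a}\t{b}\n")
        paths[rel] = path

    cg_path = out_dir / "cg.tsv"
    with open(cg_path, "w") as fh:
        for c, t, g in sorted(graph.cg_edges):
            fh.write(f"{c}\t{t}\t{g}\n")
    paths["cg"] = cg_path
    return paths


def load_graph_dir(graph_dir: str | Path) -> MultiRelationalGraph:
    """Load a graph from a directory laid out as ``write_graph`` produces."""
    graph_dir = Path(graph_dir)
    edge_files = {rel: graph_dir / f"{rel}.tsv" for rel in ("cc", "gg", "cp", "gp", "cg")
                  if (graph_dir / f"{rel}.tsv").exists()}
    return load_graph(graph_dir / "nodes.tsv", edge_files)


# ---------------------------------------------------------------------------
# Filtering / trimming


def filter_rare_types(graph: MultiRelationalGraph,
                      min_edges: int) -> MultiRelationalGraph:
    """Keep only interaction types with at least ``min_edges`` cg triples."""
    if min_edges < 1:
        raise ValueError("min_edges must be >= 1")
    counts = graph.cg_type_counts()
    keep = {t for t, n in counts.items() if n >= min_edges}
    if not keep:
        raise GraphError(
            f"no interaction types have >= {min_edges} edges; no relations survive"
        )
    return replace(
        graph,
        cg_edges={e for e in graph.cg_edges if e[1] in keep},
        type_vocab={t: it for t, it in graph.type_vocab.items() if t in keep},
    )


def trim_association_graphs(graph: MultiRelationalGraph) -> MultiRelationalGraph:
    """Drop cc/gg nodes (and their cc/gg edges) with no cp/gp/cg membership.

    Chemical and gene node lists are then restricted to nodes that appear in
    some surviving edge.  Idempotent.
    """
    anchored_c = ({c for c, _ in graph.cp_edges}
                  | {c for c, _, _ in graph.cg_edges})
    anchored_g = ({g for g, _ in graph.gp_edges}
                  | {g for _, _, g in graph.cg_edges})
    cc = {e for e in graph.cc_edges if e[0] in anchored_c and e[1] in anchored_c}
    gg = {e for e in graph.gg_edges if e[0] in anchored_g and e[1] in anchored_g}

    used_c = anchored_c | {n for e in cc for n in e}
    used_g = anchored_g | {n for e in gg for n in e}
    return replace(
        graph,
        chemicals=tuple(n for n in graph.chemicals if n in used_c),
        genes=tuple(n for n in graph.genes if n in used_g),
        cc_edges=cc,
        gg_edges=gg,
    )


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class EdgeSplit:
    """Per-interaction-type disjoint train/validation/test cg edge subsets."""

    folds: dict[str, dict[str, set[tuple[str, str, str]]]]
    ratios: tuple[float, float, float]
    split_seed: int

    FOLDS = ("train", "valid", "test")

    def fold_edges(self, fold: str) -> set[tuple[str, str, str]]:
        return {e for per_type in self.folds.values() for e in per_type[fold]}

    def train_pairs(self, type_id: str) -> set[tuple[str, str]]:
        return {(c, g) for c, _, g in self.folds[type_id]["train"]}

    def all_pairs(self, type_id: str) -> set[tuple[str, str]]:
        return {(c, g) for fold in self.FOLDS for c, _, g in self.folds[type_id][fold]}


def _largest_remainder_sizes(n: int, ratios: tuple[float, float, float]) -> list[int]:
    raw = [n * r for r in ratios]
    base = [int(np.floor(x)) for x in raw]
    remainder = n - sum(base)
    order = sorted(range(3), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:remainder]:
        base[i] += 1
    return base


def split_cg_edges(graph: MultiRelationalGraph,
                   ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> EdgeSplit:
    """Randomly partition each type's cg edges into train/valid/test.

    Deterministic given ``seed``; per-type sizes follow ``ratios`` by the
    largest-remainder rule (within +/-1 edge of exact proportions).
    """
    if any(r < 0 for r in ratios) or not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    folds: dict[str, dict[str, set]] = {}
    for type_id in graph.interaction_types:
        edges = sorted(e for e in graph.cg_edges if e[1] == type_id)
        if len(edges) < 3:
            raise GraphError(
                f"type {type_id!r} has only {len(edges)} edges (< 3); "
                "raise min_edges in filter_rare_types before splitting"
            )
        perm = rng.permutation(len(edges))
        n_train, n_valid, n_test = _largest_remainder_sizes(len(edges), tuple(ratios))
        shuffled = [edges[i] for i in perm]
        folds[type_id] = {
            "train": set(shuffled[:n_train]),
            "valid": set(shuffled[n_train:n_train + n_valid]),
            "test": set(shuffled[n_train + n_valid:]),
        }
    return EdgeSplit(folds=folds, ratios=tuple(ratios), split_seed=seed)


def write_split(split: EdgeSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        for type_id in sorted(split.folds):
            for fold in EdgeSplit.FOLDS:
                for c, t, g in sorted(split.folds[type_id][fold]):
                    fh.write(f"{c}\t{t}\t{g}\t{fold}\n")


def load_split(path: str | Path, ratios=(0.8, 0.1, 0.1), seed: int = -1) -> EdgeSplit:
    folds: dict[str, dict[str, set]] = {}
    for lineno, (c, t, g, fold) in _read_tsv_rows(Path(path), 4):
        if fold not in EdgeSplit.FOLDS:
            raise GraphParseError(f"{path}:{lineno}: unknown fold {fold!r}")
        folds.setdefault(t, {f: set() for f in EdgeSplit.FOLDS})[fold].add((c, t, g))
    return EdgeSplit(folds=folds, ratios=tuple(ratios), split_seed=seed)


# ---------------------------------------------------------------------------
# Sparse adjacencies


@dataclass
class RelationAdjacency:
    """Sparse 0/1 adjacencies over a single global node index.

    The index stacks chemicals, genes, then pathways (each sorted).  Relation
    keys are directional from the receiver's perspective: ``cc``, ``gg``,
    ``cp``/``pc``, ``gp``/``pg``, and per interaction type ``cg|<t>``
    (chemical receives from gene) and ``gc|<t>`` (gene receives from
    chemical).  Typed layers are built from TRAIN edges only, so held-out
    edges never participate in message passing.
    """

    node_index: dict[str, int]
    n_chemicals: int
    n_genes: int
    n_pathways: int
    adj: dict[str, sp.csr_matrix]
    interaction_types: list[str]

    @property
    def n_nodes(self) -> int:
        return self.n_chemicals + self.n_genes + self.n_pathways

    def degrees(self, rel: str) -> np.ndarray:
        """Per-node neighbor counts |N_i^r| (row degrees of the adjacency)."""
        return np.asarray(self.adj[rel].sum(axis=1)).ravel()

    def sender_degrees(self, rel: str) -> np.ndarray:
        """Neighbor counts of sender nodes under rel (column degrees)."""
        return np.asarray(self.adj[rel].sum(axis=0)).ravel()

    def normalized(self, rel: str) -> sp.csr_matrix:
        """Symmetric normalization 1/sqrt(|N_i^r| |N_j^r|); zero degrees give 0."""
        A = self.adj[rel].tocoo()
        drow = self.degrees(rel)
        dcol = self.sender_degrees(rel)
        with np.errstate(divide="ignore"):
            ri = np.where(drow > 0, 1.0 / np.sqrt(drow), 0.0)
            rj = np.where(dcol > 0, 1.0 / np.sqrt(dcol), 0.0)
        data = A.data * ri[A.row] * rj[A.col]
        return sp.csr_matrix((data, (A.row, A.col)), shape=A.shape)

    def message_matrix(self, rel: str, self_loop: bool = True) -> sp.csr_matrix:
        """Normalized adjacency plus, optionally, the per-relation self term
        diag(1/|N_i^r|) applied only to nodes with >= 1 neighbor under rel."""
        M = self.normalized(rel)
        if self_loop:
            d = self.degrees(rel)
            with np.errstate(divide="ignore"):
                s = np.where(d > 0, 1.0 / d, 0.0)
            M = M + sp.diags(s)
        return sp.csr_matrix(M)


def build_adjacencies(graph: MultiRelationalGraph,
                      split: EdgeSplit) -> RelationAdjacency:
    """Build directional sparse adjacencies; cg layers from TRAIN edges only."""
    nodes = list(graph.chemicals) + list(graph.genes) + list(graph.pathways)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    def mat(pairs: Iterable[tuple[int, int]]) -> sp.csr_matrix:
        pairs = list(pairs)
        if not pairs:
            return sp.csr_matrix((n, n))
        rows, cols = zip(*pairs)
        data = np.ones(len(rows))
        m = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        m.data[:] = 1.0  # collapse accidental duplicates
        return m

    adj: dict[str, sp.csr_matrix] = {}
    cc = [(index[a], index[b]) for a, b in graph.cc_edges]
    adj["cc"] = mat(cc + [(j, i) for i, j in cc])
    gg = [(index[a], index[b]) for a, b in graph.gg_edges]
    adj["gg"] = mat(gg + [(j, i) for i, j in gg])
    cp = [(index[c], index[p]) for c, p in graph.cp_edges]
    adj["cp"] = mat(cp)
    adj["pc"] = mat([(j, i) for i, j in cp])
    gp = [(index[g], index[p]) for g, p in graph.gp_edges]
    adj["gp"] = mat(gp)
    adj["pg"] = mat([(j, i) for i, j in gp])

    types = sorted(split.folds)
    for t in types:
        pairs = [(index[c], index[g]) for c, _, g in split.folds[t]["train"]]
        adj[f"cg|{t}"] = mat(pairs)
        adj[f"gc|{t}"] = mat([(j, i) for i, j in pairs])

    return RelationAdjacency(
        node_index=index,
        n_chemicals=len(graph.chemicals),
        n_genes=len(graph.genes),
        n_pathways=len(graph.pathways),
        adj=adj,
        interaction_types=types,
    )
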