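"""Motif mining over the multi-relational graph.

Two substructures carry signal about unobserved chemical-gene interactions:

* **S-G**: chemical ``c`` interacts (typed) with gene ``g1`` and ``g1``
  associates with gene ``g2`` — suggesting a candidate link ``c — g2`` of
  the same type.
* **S-G-P**: an S-G whose chemical and genes additionally share a pathway,
  grounding the candidate in a common mechanism.

Candidate links supported by enough S-G-P instances (a threshold that is
relative to the best-supported candidate of the same type, coefficient
``lambda``, with an absolute floor of 2) are promoted to *definite latent
links* and later injected into message passing.  Mining runs on TRAIN
edges only so held-out interactions never leak into the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import EdgeSplit, MultiRelationalGraph

__all__ = [
    "enumerate_sg", "enumerate_sgp", "count_support", "select_definite",
    "mine_latent_links", "coverage_stats", "LatentLinkSet", "CoverageStats",
]


def _gg_neighbors(graph: MultiRelationalGraph) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {}
    for a, b in graph.gg_edges:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    return nbrs


def _pathway_sets(pairs) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for x, p in pairs:
        out.setdefault(x, set()).add(p)
    return out


def enumerate_sg(graph: MultiRelationalGraph,
                 type_id: str) -> set[tuple[str, str, str]]:
    """All (c, g_known, g_target) with (c, type, g_known) a cg edge and
    (g_known, g_target) a gene-gene association; g_known != g_target."""
    gg = _gg_neighbors(graph)
    out: set[tuple[str, str, str]] = set()
    for c, t, g1 in graph.cg_edges:
        if t != type_id:
            continue
        for g2 in gg.get(g1, ()):
            out.add((c, g1, g2))
    return out


def enumerate_sgp(graph: MultiRelationalGraph, type_id: str,
                  require_both_genes: bool = True) -> set[tuple[str, str, str, str]]:
    """All (c, g_known, g_target, p) extending an S-G with a shared pathway.

    With ``require_both_genes`` (default) the pathway must be shared by the
    chemical and BOTH genes; the looser reading (chemical plus at least one
    of the genes) is available for sensitivity analysis.
    """
    cp = _pathway_sets(graph.cp_edges)
    gp = _pathway_sets(graph.gp_edges)
    out: set[tuple[str, str, str, str]] = set()
    for c, g1, g2 in enumerate_sg(graph, type_id):
        pc = cp.get(c, set())
        if not pc:
            continue
        p1, p2 = gp.get(g1, set()), gp.get(g2, set())
        shared = pc & p1 & p2 if require_both_genes else pc & (p1 | p2)
        for p in shared:
            out.add((c, g1, g2, p))
    return out


def count_support(sgp_instances: set[tuple[str, str, str, str]],
                  train_pairs: set[tuple[str, str]]) -> dict[tuple[str, str], int]:
    """Per-candidate S-G-P support counts.

    The candidate implied by instance (c, g1, g2, p) is the pair (c, g2)
    when it is NOT already a train edge of the type; instances whose target
    gene is already directly linked yield no candidate.
    """
    support: dict[tuple[str, str], int] = {}
    for c, _g1, g2, _p in sgp_instances:
        pair = (c, g2)
        if pair in train_pairs:
            continue
        support[pair] = support.get(pair, 0) + 1
    return support


@dataclass
class LatentLinkSet:
    """Per-type candidate chemical-gene links, their S-G-P support, and the
    lambda-selected definite subset."""

    lam: float
    candidates: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    definite: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def latent_neighbors(self, type_id: str) -> dict[str, set[str]]:
        """Node -> latent-neighbor set under the type (both endpoints updated)."""
        nbrs: dict[str, set[str]] = {}
        for c, g in self.definite.get(type_id, ()):
            nbrs.setdefault(c, set()).add(g)
            nbrs.setdefault(g, set()).add(c)
        return nbrs

    def n_definite(self) -> int:
        return sum(len(s) for s in self.definite.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.candidates):
            definite = self.definite.get(t, set())
            for (c, g), n in sorted(self.candidates[t].items()):
                rows.append((c, t, g, n, int((c, g) in definite)))
        return pd.DataFrame(
            rows, columns=["chemical_id", "interaction_type", "gene_id",
                           "support_count", "definite"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def select_definite(candidates: dict[str, dict[tuple[str, str], int]],
                    lam: float) -> LatentLinkSet:
    """Per type, keep candidates with support >= max(2, lambda * max support)."""
    if not (0 < lam <= 1):
        raise ValueError("lambda threshold must lie in (0, 1]")
    definite: dict[str, set[tuple[str, str]]] = {}
    for t, support in candidates.items():
        if not support:
            definite[t] = set()
            continue
        cutoff = max(2.0, max(support.values()) * lam)
        definite[t] = {pair for pair, n in support.items() if n >= cutoff}
    return LatentLinkSet(lam=lam, candidates=dict(candidates), definite=definite)


def mine_latent_links(graph: MultiRelationalGraph, split: EdgeSplit,
                      lam: float = 0.5,
                      require_both_genes: bool = True) -> LatentLinkSet:
    """End-to-end mining: enumerate S-G-P on train edges, count support per
    candidate, threshold by lambda."""
    train_view = graph.with_cg_edges(split.fold_edges("train"))
    candidates: dict[str, dict[tuple[str, str], int]] = {}
    for t in sorted(split.folds):
        instances = enumerate_sgp(train_view, t, require_both_genes)
        candidates[t] = count_support(instances, split.train_pairs(t))
    return select_definite(candidates, lam)


@dataclass
class CoverageStats:
    """Per-type S-G / S-G-P participation of cg edges, plus frequency groups."""

    per_type: pd.DataFrame  # type, n_edges, n_sg, prop_sg, n_sgp, prop_sgp, group
    n_groups: int

    def mean_proportion(self, kind: str) -> float:
        return float(self.per_type[f"prop_{kind}"].mean())


def coverage_stats(graph: MultiRelationalGraph, n_groups: int = 5,
                   require_both_genes: bool = True) -> CoverageStats:
    """For each type, the fraction of its cg edges (c, t, g) whose gene g
    occurs (as known or target gene) in an S-G / S-G-P instance containing c.

    Types are sorted by descending edge count and stratified into
    ``n_groups`` near-equal groups, most-frequent group first.
    """
    counts = graph.cg_type_counts()
    rows = []
    for t in sorted(counts, key=lambda x: (-counts[x], x)):
        pairs = graph.cg_pairs(t)
        sg_cover: set[tuple[str, str]] = set()
        for c, g1, g2 in enumerate_sg(graph, t):
            if (c, g1) in pairs:
                sg_cover.add((c, g1))
            if (c, g2) in pairs:
                sg_cover.add((c, g2))
        sgp_cover: set[tuple[str, str]] = set()
        for c, g1, g2, _p in enumerate_sgp(graph, t, require_both_genes):
            if (c, g1) in pairs:
                sgp_cover.add((c, g1))
            if (c, g2) in pairs:
                sgp_cover.add((c, g2))
        n = len(pairs)
        rows.append((t, n, len(sg_cover), len(sg_cover) / n,
                     len(sgp_cover), len(sgp_cover) / n))
    frame = pd.DataFrame(
        rows, columns=["interaction_type", "n_edges", "n_sg", "prop_sg",
                       "n_sgp", "prop_sgp"])
    groups = np.concatenate(
        [np.full(len(chunk), i)
         for i, chunk in enumerate(np.array_split(np.arange(len(frame)), n_groups))]
    ) if len(frame) else np.array([], dtype=int)
    frame["group"] = groups
    return CoverageStats(per_type=frame, n_groups=n_groups)
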