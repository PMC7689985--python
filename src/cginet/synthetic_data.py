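"""Synthetic multi-relational chemical/gene/pathway graphs with planted
motif structure.

The generator emulates the shape of the real integrated graph at desk
scale.  The default ``pathway`` family is modular: genes belong to one or
a few pathways, gene-gene and chemical-chemical associations concentrate
within pathway communities, chemicals join the pathways of genes they act
on, and each chemical's interactions target genes of its pathways.  This
mirrors the modularity of curated interactomes and gives the graph
convolutional encoder a representable signal.  A structureless ``er``
family (Erdos-Renyi association layers, uniform bipartite pathway layers)
is available for contrast; its motif signal is present but much harder
for low-capacity encoders.

The typed chemical-gene layer is built per interaction type with a
geometric frequency decay calibrated so the most frequent ~20% of types
hold ~90% of the interactions, and rarer types preferentially reuse pairs
already active under more frequent types (a chemical-gene pair may
interact under several types, as in curated interaction databases).
Within each type a configurable fraction of edges is *planted* by S-G-P
closure — an edge (c, r, g2) is added only where an existing edge
(c, r, g1), a gene-gene association (g1, g2), and a pathway shared by c,
g1, g2 already exist — so motif mining and latent-link message passing
have recoverable signal; the rest is split between freely seeded edges
and uniform noise.  Every chemical-gene edge is labeled
{seeded, planted, noise} in a manifest, and generation is fully
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .graph_core import (InteractionType, MultiRelationalGraph, EdgeSplit,
                         split_cg_edges)

__all__ = ["SyntheticSpec", "generate_graph", "default_fixture",
           "type_frequency_weights", "GenerationError"]


class GenerationError(Exception):
    pass


_ACTIONS = (
    "expression", "activity", "phosphorylation", "localization", "secretion",
    "transport", "cleavage", "metabolic processing", "uptake", "degradation",
    "ubiquitination", "acetylation", "sumoylation", "chemical synthesis",
    "response to substance", "reaction", "cotreatment", "glucuronidation",
)
_PARENTS = {"cleavage": "metabolic processing",
            "phosphorylation": "metabolic processing",
            "glucuronidation": "metabolic processing",
            "uptake": "transport"}
_DEGREE_CYCLE = ("increases", "decreases", "affects")


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define the repository's study fixture."""

    n_chemicals: int = 100
    n_genes: int = 150
    n_pathways: int = 20
    n_types: int = 6
    family: str = "pathway"            # {pathway, er}

    # pathway family: community structure around pathway membership
    gene_extra_pathways: float = 0.5   # gene joins 1 + Poisson(this) pathways
    chem_extra_pathways: float = 0.5   # chemical targets 1 + Poisson(this)
    gg_within: float = 0.25            # gene-gene edge prob, shared pathway
    gg_background: float = 0.004       # ... no shared pathway
    cc_within: float = 0.20
    cc_background: float = 0.005
    cp_member: float = 0.8             # chemical joins each target pathway
    cp_background: float = 0.01
    gp_background: float = 0.01
    target_bias: float = 0.8           # seeded genes drawn from target pathways

    # er family: independent layers
    cc_density: float = 0.05
    gg_density: float = 0.03
    cp_density: float = 0.08
    gp_density: float = 0.08

    # typed chemical-gene layer
    n_cg_edges: int = 2000
    planted_fraction: float = 0.5
    noise_fraction: float = 0.1
    cross_type_coherence: float = 0.5
    min_type_edges: int = 50
    rare_type_edges: int | None = 24   # force one deliberately rare type
    top_type_fraction: float = 0.2     # share of types that should hold ...
    top_type_share: float = 0.9        # ... this share of the cg edges
    seed: int = 7

    def validate(self) -> "SyntheticSpec":
        if min(self.n_chemicals, self.n_genes, self.n_pathways,
               self.n_types, self.n_cg_edges) <= 0:
            raise ValueError("all counts must be positive")
        if self.family not in ("pathway", "er"):
            raise ValueError(f"unknown graph family {self.family!r}")
        for f in (self.planted_fraction, self.noise_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.planted_fraction + self.noise_fraction > 1.0:
            raise ValueError("planted_fraction + noise_fraction must be <= 1")
        if self.n_types > len(_ACTIONS) * len(_DEGREE_CYCLE):
            raise ValueError("n_types exceeds the built-in type vocabulary")
        return self


def type_frequency_weights(n_types: int, top_fraction: float = 0.2,
                           top_share: float = 0.9) -> np.ndarray:
    """Geometric decay weights w_i = q^i, with q calibrated so the top
    ceil(top_fraction * n_types) types hold top_share of the total mass."""
    if n_types == 1:
        return np.array([1.0])
    k = int(np.ceil(top_fraction * n_types))
    if k >= n_types:
        return np.full(n_types, 1.0 / n_types)

    def gap(q):
        w = q ** np.arange(n_types)
        return w[:k].sum() / w.sum() - top_share

    if gap(1e-9) < 0:  # even a near-degenerate decay can't reach the share
        q = 1e-9
    else:
        q = brentq(gap, 1e-9, 1 - 1e-9)
    w = q ** np.arange(n_types)
    return w / w.sum()


def _type_vocabulary(n_types: int) -> list[InteractionType]:
    types = []
    for i in range(n_types):
        action = _ACTIONS[i % len(_ACTIONS)]
        degree = _DEGREE_CYCLE[(i // len(_ACTIONS) + i) % len(_DEGREE_CYCLE)]
        it = InteractionType(degree=degree, action=action,
                             parent_type=_PARENTS.get(action))
        types.append(it)
    if len({t.canonical for t in types}) != n_types:
        # cycle alignment guarantees uniqueness for supported n_types
        raise GenerationError("type vocabulary collision")
    return types


def _per_type_counts(spec: SyntheticSpec, weights: np.ndarray) -> list[int]:
    raw = weights * spec.n_cg_edges
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: spec.n_cg_edges - counts.sum()]:
        counts[i] += 1
    # enforce the per-type floor, taking the excess from the largest types
    floor = min(spec.min_type_edges, spec.n_cg_edges // spec.n_types)
    deficit = int(np.sum(np.maximum(floor - counts, 0)))
    counts = np.maximum(counts, floor)
    order = np.argsort(counts)[::-1]
    i = 0
    while deficit > 0:
        j = order[i % len(order)]
        if counts[j] > floor:
            counts[j] -= 1
            deficit -= 1
        i += 1
    # one deliberately rare type (the least frequent) keeps the rare-type
    # code paths exercised; metric-bearing types keep the higher floor
    if spec.rare_type_edges is not None and spec.n_types >= 2:
        rare = min(spec.rare_type_edges, int(counts[-1]))
        counts[int(np.argmax(counts))] += int(counts[-1]) - rare
        counts[-1] = rare
    return counts.tolist()


def _er_pairs(ids, density: float, rng: np.random.Generator):
    n = len(ids)
    mask = rng.random((n, n)) < density
    return {(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)
            if mask[i, j]}


def _bipartite_pairs(left, right, density: float, rng: np.random.Generator):
    mask = rng.random((len(left), len(right))) < density
    return {(left[i], right[j]) for i in range(len(left))
            for j in range(len(right)) if mask[i, j]}


def _memberships(ids, n_pathways: int, extra_rate: float,
                 rng: np.random.Generator) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for x in ids:
        k = min(n_pathways, 1 + rng.poisson(extra_rate))
        out[x] = set(rng.choice(n_pathways, size=k, replace=False).tolist())
    return out


def _block_pairs(ids, groups: dict[str, set[int]], p_within: float,
                 p_background: float, rng: np.random.Generator):
    pairs = set()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_within if groups[ids[i]] & groups[ids[j]] else p_background
            if rng.random() < p:
                pairs.add((ids[i], ids[j]))
    return pairs


def _association_layers(spec: SyntheticSpec, chemicals, genes, pathways,
                        rng: np.random.Generator):
    """cc/gg/cp/gp edge sets plus per-chemical target-pathway assignments."""
    if spec.family == "er":
        cc = _er_pairs(chemicals, spec.cc_density, rng)
        gg = _er_pairs(genes, spec.gg_density, rng)
        cp = _bipartite_pairs(chemicals, pathways, spec.cp_density, rng)
        gp = _bipartite_pairs(genes, pathways, spec.gp_density, rng)
        return cc, gg, cp, gp, None

    gene_member = _memberships(genes, spec.n_pathways,
                               spec.gene_extra_pathways, rng)
    chem_target = _memberships(chemicals, spec.n_pathways,
                               spec.chem_extra_pathways, rng)
    gg = _block_pairs(genes, gene_member, spec.gg_within,
                      spec.gg_background, rng)
    cc = _block_pairs(chemicals, chem_target, spec.cc_within,
                      spec.cc_background, rng)
    gp = {(g, pathways[p]) for g, ps in gene_member.items() for p in ps}
    gp |= _bipartite_pairs(genes, pathways, spec.gp_background, rng)
    cp = {(c, pathways[p]) for c, ps in chem_target.items() for p in ps
          if rng.random() < spec.cp_member}
    cp |= _bipartite_pairs(chemicals, pathways, spec.cp_background, rng)
    return cc, gg, cp, gp, chem_target


def generate_graph(spec: SyntheticSpec) -> tuple[MultiRelationalGraph, pd.DataFrame]:
    """Generate a graph plus a manifest labeling each cg edge's provenance.

    Returns ``(graph, manifest)`` where the manifest has columns
    chemical_id, interaction_type, gene_id, label in {seeded, planted, noise}.
    """
    spec.validate()
    ss = np.random.SeedSequence([spec.seed, 101])
    rng_assoc, rng_cg = (np.random.default_rng(s) for s in ss.spawn(2))

    chemicals = [f"c{i:04d}" for i in range(spec.n_chemicals)]
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    pathways = [f"p{i:03d}" for i in range(spec.n_pathways)]

    cc, gg, cp, gp, chem_target = _association_layers(
        spec, chemicals, genes, pathways, rng_assoc)

    gg_nbrs: dict[str, set[str]] = {}
    for a, b in gg:
        gg_nbrs.setdefault(a, set()).add(b)
        gg_nbrs.setdefault(b, set()).add(a)
    cp_sets: dict[str, set[str]] = {}
    for c, p in cp:
        cp_sets.setdefault(c, set()).add(p)
    gp_sets: dict[str, set[str]] = {}
    for g, p in gp:
        gp_sets.setdefault(g, set()).add(p)
    genes_by_pathway: dict[int, list[str]] = {}
    for g, p in sorted(gp):
        genes_by_pathway.setdefault(pathways.index(p), []).append(g)

    vocab = _type_vocabulary(spec.n_types)
    weights = type_frequency_weights(spec.n_types, spec.top_type_fraction,
                                     spec.top_type_share)
    counts = _per_type_counts(spec, weights)

    def draw_seed_pair() -> tuple[str, str]:
        i = rng_cg.integers(0, spec.n_chemicals)
        c = chemicals[i]
        if chem_target is not None and rng_cg.random() < spec.target_bias:
            candidates = sorted({g for p in chem_target[c]
                                 for g in genes_by_pathway.get(p, ())})
            if candidates:
                return c, candidates[rng_cg.integers(0, len(candidates))]
        return c, genes[rng_cg.integers(0, spec.n_genes)]

    # a chemical-gene pair may interact under several types, so rarer types
    # preferentially reuse pairs already active under more frequent ones
    manifest_rows: list[tuple[str, str, str, str]] = []
    pairs_by_type: dict[str, set[tuple[str, str]]] = {}
    active_pairs: list[tuple[str, str]] = []
    for itype, total in zip(vocab, counts):
        t = itype.canonical
        n_planted = int(round(total * spec.planted_fraction))
        n_noise = int(round(total * spec.noise_fraction))
        n_seeded = total - n_planted - n_noise
        pairs: set[tuple[str, str]] = set()
        while len(pairs) < n_seeded:
            if active_pairs and rng_cg.random() < spec.cross_type_coherence:
                pair = active_pairs[rng_cg.integers(0, len(active_pairs))]
            else:
                pair = draw_seed_pair()
            if pair not in pairs:
                pairs.add(pair)
                manifest_rows.append((pair[0], t, pair[1], "seeded"))
        pairs_by_type[t] = pairs
        active_pairs.extend(sorted(pairs))

    cg_edges: set[tuple[str, str, str]] = set()
    for itype, total in zip(vocab, counts):
        t = itype.canonical
        n_planted = int(round(total * spec.planted_fraction))
        n_noise = int(round(total * spec.noise_fraction))
        pairs = pairs_by_type[t]

        # S-G-P closure: repeatedly derive candidate targets from the edges
        # placed so far until the quota is met
        remaining = n_planted
        while remaining > 0:
            candidates = []
            for c, g1 in sorted(pairs):
                pc = cp_sets.get(c, set())
                if not pc:
                    continue
                p1 = gp_sets.get(g1, set())
                for g2 in gg_nbrs.get(g1, ()):
                    if (c, g2) in pairs:
                        continue
                    if pc & p1 & gp_sets.get(g2, set()):
                        candidates.append((c, g2))
            candidates = sorted(set(candidates))
            if not candidates:
                raise GenerationError(
                    f"type {t!r}: S-G-P closure exhausted with {remaining} "
                    "planted edges still to place; increase association "
                    "densities or lower planted_fraction")
            rng_cg.shuffle(candidates)
            take = candidates[:remaining]
            for pair in take:
                pairs.add(pair)
                manifest_rows.append((pair[0], t, pair[1], "planted"))
            remaining -= len(take)

        n = n_noise
        while n > 0:
            i = rng_cg.integers(0, spec.n_chemicals)
            j = rng_cg.integers(0, spec.n_genes)
            pair = (chemicals[i], genes[j])
            if pair not in pairs:
                pairs.add(pair)
                manifest_rows.append((pair[0], t, pair[1], "noise"))
                n -= 1
        cg_edges.update((c, t, g) for c, g in pairs)

    graph = MultiRelationalGraph(
        chemicals=tuple(sorted(chemicals)),
        genes=tuple(sorted(genes)),
        pathways=tuple(sorted(pathways)),
        cc_edges=cc, gg_edges=gg, cp_edges=cp, gp_edges=gp,
        cg_edges=cg_edges,
        type_vocab={it.canonical: it for it in vocab},
    ).validate()
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["chemical_id", "interaction_type", "gene_id", "label"])
    return graph, manifest


def default_fixture(split_seed: int | None = None
                    ) -> tuple[MultiRelationalGraph, EdgeSplit, SyntheticSpec]:
    """The repository's canonical small fixture: default spec, fixed seed,
    and an 8:1:1 per-type split."""
    spec = SyntheticSpec()
    graph, _ = generate_graph(spec)
    split = split_cg_edges(graph, (0.8, 0.1, 0.1),
                           seed=spec.seed if split_seed is None else split_seed)
    return graph, split, spec
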