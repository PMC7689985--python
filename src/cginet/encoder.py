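"""Relational graph convolutional encoders.

Two perspectives produce node embeddings for the decoder:

* **total**: a single 2-layer relational GCN over every relation layer at
  once (optionally restricted to the typed chemical-gene layer only, which
  recovers the plain CG-graph GCN baseline);
* **subgraph**: a 2-layer GCN over the four binary-association layers
  produces initial embeddings ``z_bar`` (chemicals aggregate from chemicals
  and pathways, genes from genes and pathways), which seed a second 2-layer
  GCN over the typed chemical-gene layer.  In that second stage, definite
  latent links mined from S-G-P motifs may join message passing, scaled by
  a per-type latent rate ``mu_r`` in [0, 1] (trainable, or fixed to 1).

Each layer computes, per relation r with neighbor sets N_i^r,

    h_i' = act( sum_r [ sum_{j in N_i^r} W_r h_j / sqrt(|N_i^r||N_j^r|)
                        + W_r h_i / |N_i^r| ] )

with 1/|N| factors defined as 0 for isolated nodes, so an isolated node
maps to the zero vector.  The self term passes through the relation weight
and is contributed once per relation in which the node has a neighbor
(``self_loop="per_relation"``); a single unnormalized global self weight is
available as the alternative (``self_loop="global"``).  One-hot input
features are never materialized: the first layer is an embedding lookup
(row i of W_r acts on the one-hot vector of node i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, glorot_uniform, relu, sigmoid, spmm
from .graph_core import ASSOCIATION_RELATIONS, RelationAdjacency
from .latent_links import LatentLinkSet

__all__ = ["EncoderConfig", "init_encoder_params", "rgcn_layer",
           "encode_total", "encode_binary_stage", "encode_interaction_stage",
           "latent_message_matrices", "ConfigurationError", "NumericError"]

_ACTIVATIONS = {"relu": relu, "identity": lambda x: x}


class ConfigurationError(Exception):
    pass


class NumericError(Exception):
    pass


@dataclass
class EncoderConfig:
    """Encoder hyperparameters; layer-size defaults follow the reference
    configuration (total 32/16; subgraph 128/64 then 32/16; dropout 0.1)."""

    perspective: str = "subgraph"          # {total, subgraph}
    total_dims: tuple[int, int] = (32, 16)
    binary_dims: tuple[int, int] = (128, 64)
    interaction_dims: tuple[int, int] = (32, 16)
    dropout: float = 0.1
    activation: str = "relu"
    final_activation: str = "relu"         # activation of each chain's last layer
    latent_mode: str = "none"              # {none, trainable, fixed}
    latent_norm: str = "updated"           # {updated, separate}
    self_loop: str = "per_relation"        # {per_relation, global}
    total_relations: str = "all"           # {all, cg_only}
    seed: int = 0

    def __post_init__(self):
        if self.perspective not in ("total", "subgraph"):
            raise ConfigurationError(f"unknown perspective {self.perspective!r}")
        if self.latent_mode not in ("none", "trainable", "fixed"):
            raise ConfigurationError(f"unknown latent_mode {self.latent_mode!r}")
        if self.latent_norm not in ("updated", "separate"):
            raise ConfigurationError(f"unknown latent_norm {self.latent_norm!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must lie in [0, 1)")
        for act in (self.activation, self.final_activation):
            if act not in _ACTIVATIONS:
                raise ConfigurationError(f"unknown activation {act!r}")
        for dims in (self.total_dims, self.binary_dims, self.interaction_dims):
            if any(d <= 0 for d in dims):
                raise ConfigurationError("layer sizes must be positive")


@dataclass
class NodeEmbeddings:
    """Per-node embedding matrix over the global node index, with class slices."""

    values: Tensor
    adjacency: RelationAdjacency
    stage: str  # {initial, final}

    def chemical_rows(self) -> np.ndarray:
        return np.arange(self.adjacency.n_chemicals)

    def gene_rows(self) -> np.ndarray:
        nc = self.adjacency.n_chemicals
        return np.arange(nc, nc + self.adjacency.n_genes)

    def array(self) -> np.ndarray:
        return self.values.data


def _total_relation_keys(adjacency: RelationAdjacency, which: str) -> list[str]:
    typed = [f"{d}|{t}" for t in adjacency.interaction_types for d in ("cg", "gc")]
    if which == "cg_only":
        return typed
    return list(ASSOCIATION_RELATIONS) + typed


def init_encoder_params(adjacency: RelationAdjacency, config: EncoderConfig,
                        rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-initialized weights for every relation and layer of the
    configured perspective (plus latent-rate logits when trainable).

    Layer-1 weights have shape (n_nodes, d1): they double as the one-hot
    embedding table.  Parameter names are stable and sorted at optimization
    time, so initialization is reproducible for a given seed.
    """
    n = adjacency.n_nodes
    params: dict[str, Tensor] = {}

    def add_chain(prefix: str, rels: list[str], dims: tuple[int, ...],
                  input_dim: int | None):
        sizes = ([input_dim] if input_dim is not None else [n]) + list(dims)
        for k in range(len(dims)):
            for rel in rels:
                params[f"{prefix}/{rel}/W{k}"] = Tensor(
                    glorot_uniform(rng, sizes[k], sizes[k + 1]), requires_grad=True)
            if config.self_loop == "global":
                params[f"{prefix}/__self__/W{k}"] = Tensor(
                    glorot_uniform(rng, sizes[k], sizes[k + 1]), requires_grad=True)

    if config.perspective == "total":
        add_chain("total", _total_relation_keys(adjacency, config.total_relations),
                  config.total_dims, input_dim=None)
    else:
        add_chain("binary", list(ASSOCIATION_RELATIONS), config.binary_dims,
                  input_dim=None)
        typed = [f"{d}|{t}" for t in adjacency.interaction_types
                 for d in ("cg", "gc")]
        add_chain("inter", typed, config.interaction_dims,
                  input_dim=config.binary_dims[-1])
        if config.latent_mode == "trainable":
            for t in adjacency.interaction_types:
                # mu_r = sigmoid(logit) keeps the latent rate inside (0, 1)
                params[f"mu/{t}"] = Tensor(0.0, requires_grad=True)
    return params


def _apply_dropout(h: Tensor, rate: float, training: bool,
                   rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return h
    if rng is None:
        raise ConfigurationError("training-mode dropout requires an rng")
    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
    return h * Tensor(mask)


def rgcn_layer(h: Tensor | None,
               matrices: dict[str, sp.spmatrix],
               weights: dict[str, Tensor],
               activation: str = "relu",
               extra_terms: list[Tensor] | None = None,
               layer_name: str = "rgcn") -> Tensor:
    """One relational graph convolution.

    ``matrices[rel]`` is the precomputed message matrix (normalized
    adjacency plus optional self-loop diagonal); ``h=None`` denotes one-hot
    inputs, turning the layer into a sum of embedding lookups.
    ``extra_terms`` (already-built Tensors, e.g. latent-link messages) are
    added to the pre-activation.
    """
    out: Tensor | None = None
    for rel in sorted(matrices):
        W = weights[rel]
        term = spmm(matrices[rel], W if h is None else h @ W)
        out = term if out is None else out + term
    if out is None:
        raise ConfigurationError(f"{layer_name}: no relations to aggregate")
    for extra in extra_terms or ():
        out = out + extra
    act = _ACTIVATIONS[activation](out)
    if not np.all(np.isfinite(act.data)):
        raise NumericError(f"non-finite output in layer {layer_name!r}")
    return act


def _run_chain(adjacency: RelationAdjacency, rels: list[str], prefix: str,
               n_layers: int, params: dict[str, Tensor], config: EncoderConfig,
               h0: Tensor | None, training: bool,
               rng: np.random.Generator | None,
               extra_per_layer=None) -> Tensor:
    per_rel_self = config.self_loop == "per_relation"
    mats = {rel: adjacency.message_matrix(rel, self_loop=per_rel_self)
            for rel in rels}
    h = h0
    for k in range(n_layers):
        if h is not None:
            h = _apply_dropout(h, config.dropout, training, rng)
        act = (config.final_activation if k == n_layers - 1
               else config.activation)
        weights = {rel: params[f"{prefix}/{rel}/W{k}"] for rel in rels}
        extras = []
        if config.self_loop == "global":
            Wself = params[f"{prefix}/__self__/W{k}"]
            extras.append(Wself if h is None else h @ Wself)
        if extra_per_layer is not None:
            extras.extend(extra_per_layer(k, h, weights))
        h = rgcn_layer(h, mats, weights, act,
                       extra_terms=extras, layer_name=f"{prefix}/layer{k}")
    return h


def encode_total(adjacency: RelationAdjacency, config: EncoderConfig,
                 params: dict[str, Tensor], training: bool = False,
                 rng: np.random.Generator | None = None) -> NodeEmbeddings:
    """2-layer relational GCN over the whole graph (or the cg layer only)."""
    if config.perspective != "total":
        raise ConfigurationError("encode_total requires perspective='total'")
    rels = _total_relation_keys(adjacency, config.total_relations)
    z = _run_chain(adjacency, rels, "total", len(config.total_dims), params,
                   config, h0=None, training=training, rng=rng)
    return NodeEmbeddings(values=z, adjacency=adjacency, stage="final")


def encode_binary_stage(adjacency: RelationAdjacency, config: EncoderConfig,
                        params: dict[str, Tensor], training: bool = False,
                        rng: np.random.Generator | None = None) -> NodeEmbeddings:
    """First subgraph stage: 2-layer GCN over cc/cp/pc/gg/gp/pg only.

    Pathway nodes act as message sources (and are embedded) but only
    chemical/gene rows are consumed by the interaction stage.
    """
    if config.perspective != "subgraph":
        raise ConfigurationError("encode_binary_stage requires perspective='subgraph'")
    z = _run_chain(adjacency, list(ASSOCIATION_RELATIONS), "binary",
                   len(config.binary_dims), params, config, h0=None,
                   training=training, rng=rng)
    return NodeEmbeddings(values=z, adjacency=adjacency, stage="initial")


def latent_message_matrices(adjacency: RelationAdjacency,
                            latent: LatentLinkSet,
                            norm: str = "updated") -> dict[str, sp.csr_matrix]:
    """Sparse message matrices for definite latent links, both directions.

    ``norm="updated"`` (default) treats the definite latent links as a
    topology update of the typed layer: latent entries are normalized by
    1/sqrt(d_i * d_l) where d are row/column degrees of the labeled+latent
    union, making latent and labeled messages commensurate, and nodes whose
    only edges under the type are latent still receive messages.

    ``norm="separate"`` keeps the two sums fully separate: entry (i, l)
    carries 1 / sqrt(|N_i^r| * max(1, |L_l^r|)) with |N_i^r| the receiver's
    labeled train degree (0 degree zeroes the message, per the
    isolated-node convention) and |L_l^r| the sender's latent degree.
    """
    index = adjacency.node_index
    n = adjacency.n_nodes
    out: dict[str, sp.csr_matrix] = {}
    for t in adjacency.interaction_types:
        nbrs = latent.latent_neighbors(t)
        lat_deg = np.ones(n)
        for node, s in nbrs.items():
            lat_deg[index[node]] = max(1, len(s))
        for direction, labeled in (("cg", f"cg|{t}"), ("gc", f"gc|{t}")):
            pairs = sorted(latent.definite.get(t, ()))
            ij = [(index[c], index[g]) if direction == "cg" else (index[g], index[c])
                  for c, g in pairs]
            L = sp.csr_matrix(
                (np.ones(len(ij)), tuple(zip(*ij)) if ij else ([], [])),
                shape=(n, n))
            if norm == "updated":
                union = ((adjacency.adj[labeled] + L) > 0).astype(float)
                drow = np.asarray(union.sum(axis=1)).ravel()
                dcol = np.asarray(union.sum(axis=0)).ravel()
                with np.errstate(divide="ignore"):
                    ri = np.where(drow > 0, 1.0 / np.sqrt(drow), 0.0)
                    rj = np.where(dcol > 0, 1.0 / np.sqrt(dcol), 0.0)
                Lc = L.tocoo()
                out[f"lat_{direction}|{t}"] = sp.csr_matrix(
                    (ri[Lc.row] * rj[Lc.col], (Lc.row, Lc.col)), shape=(n, n))
            else:
                deg = adjacency.degrees(labeled)
                rows, cols, data = [], [], []
                for i, l in ij:
                    if deg[i] == 0:
                        continue
                    rows.append(i)
                    cols.append(l)
                    data.append(1.0 / np.sqrt(deg[i] * lat_deg[l]))
                out[f"lat_{direction}|{t}"] = sp.csr_matrix(
                    (data, (rows, cols)), shape=(n, n))
    return out


def encode_interaction_stage(adjacency: RelationAdjacency,
                             initial: NodeEmbeddings,
                             config: EncoderConfig,
                             params: dict[str, Tensor],
                             latent: LatentLinkSet | None = None,
                             training: bool = False,
                             rng: np.random.Generator | None = None) -> NodeEmbeddings:
    """Second subgraph stage: 2-layer GCN over the typed cg layer, seeded by
    the binary-stage embeddings, with optional latent-link message passing."""
    if config.perspective != "subgraph":
        raise ConfigurationError("encode_interaction_stage requires perspective='subgraph'")
    if config.latent_mode == "none" and latent is not None:
        raise ConfigurationError("latent links provided but latent_mode='none'")
    if config.latent_mode != "none" and latent is None:
        raise ConfigurationError(f"latent_mode={config.latent_mode!r} requires a LatentLinkSet")

    typed = [f"{d}|{t}" for t in adjacency.interaction_types for d in ("cg", "gc")]
    lat_mats = (latent_message_matrices(adjacency, latent, config.latent_norm)
                if config.latent_mode != "none" else {})

    def latent_terms(k: int, h: Tensor, weights: dict[str, Tensor]) -> list[Tensor]:
        terms = []
        for rel in typed:
            direction, t = rel.split("|", 1)
            L = lat_mats.get(f"lat_{direction}|{t}")
            if L is None or L.nnz == 0:
                continue
            msg = spmm(L, h @ weights[rel])
            if config.latent_mode == "trainable":
                msg = msg * sigmoid(params[f"mu/{t}"])
            terms.append(msg)  # fixed mode: mu = 1 exactly
        return terms

    z = _run_chain(adjacency, typed, "inter", len(config.interaction_dims),
                   params, config, h0=initial.values, training=training, rng=rng,
                   extra_per_layer=latent_terms if lat_mats else None)
    return NodeEmbeddings(values=z, adjacency=adjacency, stage="final")


def latent_rates(adjacency: RelationAdjacency, config: EncoderConfig,
                 params: dict[str, Tensor]) -> dict[str, float]:
    """Current per-type latent rate mu_r (empty unless a latent mode is on)."""
    if config.latent_mode == "fixed":
        return {t: 1.0 for t in adjacency.interaction_types}
    if config.latent_mode == "trainable":
        return {t: float(1.0 / (1.0 + np.exp(-params[f"mu/{t}"].data)))
                for t in adjacency.interaction_types}
    return {}
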