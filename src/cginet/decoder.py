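"""DEDICOM tensor-decomposition decoder.

A (chemical, type, gene) triple is scored bilinearly as

    score(z_i, r, z_j) = z_i^T D_r R D_r z_j

where D_r is a per-type diagonal matrix (stored as a vector) reweighting
embedding dimensions and R is a single dense matrix shared by all types,
letting the model pool evidence across interaction types.  A sigmoid maps
the score to an interaction probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, glorot_uniform, sigmoid

__all__ = ["init_decoder_params", "score", "score_batch", "probability",
           "rank_genes"]


def init_decoder_params(interaction_types: list[str], dim: int,
                        rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-initialized D_r vectors (one per type) and the global R.

    The diagonal D_r is sampled with the same fan-in/fan-out (d, d) limits
    as a dense d-by-d matrix, restricted to its diagonal, and folded to be
    non-negative: D_r enters the score bilinearly (once per side), so a
    sign-mixed init can start a rarely-updated type in a score-inverted
    basin that hinge-on-sigmoid gradients cannot escape once saturated.
    Non-negative per-dimension importances at init remove that trap without
    changing the init scale; signs remain free during training.
    """
    params = {"dec/R": Tensor(glorot_uniform(rng, dim, dim), requires_grad=True)}
    for t in interaction_types:
        params[f"dec/D/{t}"] = Tensor(
            np.abs(glorot_uniform(rng, dim, dim, shape=(dim,))),
            requires_grad=True)
    return params


def score(z_i: np.ndarray, type_id: str, z_j: np.ndarray,
          params: dict[str, Tensor]) -> float:
    """Scalar DEDICOM score z_i^T D_r R D_r z_j for one pair."""
    d = params[f"dec/D/{type_id}"].data
    R = params["dec/R"].data
    z_i, z_j = np.asarray(z_i, float), np.asarray(z_j, float)
    if z_i.shape != d.shape or z_j.shape != d.shape:
        raise ValueError(
            f"embedding dims {z_i.shape}/{z_j.shape} do not match decoder dim {d.shape}")
    return float((z_i * d) @ R @ (d * z_j))


def score_batch(z: Tensor, rows_i: np.ndarray, rows_j: np.ndarray,
                type_id: str, params: dict[str, Tensor]) -> Tensor:
    """Differentiable scores for a batch of (i, j) index pairs of one type."""
    d = params[f"dec/D/{type_id}"]
    R = params["dec/R"]
    zi = z.gather_rows(rows_i) * d
    zj = z.gather_rows(rows_j) * d
    return ((zi @ R) * zj).sum(axis=1)


def probability(s) -> np.ndarray | float:
    """Numerically stable sigmoid of a score (array or scalar)."""
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    e = np.exp(s[~pos])
    out[~pos] = e / (1.0 + e)
    return float(out) if out.ndim == 0 else out


def probability_tensor(s: Tensor) -> Tensor:
    return sigmoid(s)


@dataclass
class RankedGene:
    gene_id: str
    score: float
    probability: float
    known: bool


def rank_genes(chemical: str, type_id: str, candidate_genes: list[str],
               embeddings: np.ndarray, node_index: dict[str, int],
               params: dict[str, Tensor],
               known_pairs: set[tuple[str, str]] | None = None) -> list[RankedGene]:
    """Candidate genes sorted by interaction probability (descending), ties
    broken by gene id.  Candidates that are already known edges are flagged
    rather than dropped."""
    known_pairs = known_pairs or set()
    z_c = embeddings[node_index[chemical]]
    ranked = []
    for g in candidate_genes:
        s = score(z_c, type_id, embeddings[node_index[g]], params)
        ranked.append(RankedGene(gene_id=g, score=s, probability=probability(s),
                                 known=(chemical, g) in known_pairs))
    ranked.sort(key=lambda r: (-r.probability, r.gene_id))
    return ranked
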