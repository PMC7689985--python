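"""Per-interaction-type evaluation: AUROC, AUPRC, and AP@k.

Held-out positives of each type are scored against sampled non-edges of
the same type (1:1 by default; the ratio is configurable and documented in
reports, since absolute metric values depend on it).  AUROC and AUPRC are
delegated to scikit-learn; AP@k is the average of precision-at-rank over
relevant ranks within the top k, normalized by min(k, number of positives).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph_core import EdgeSplit, MultiRelationalGraph

__all__ = ["sample_eval_negatives", "auroc", "auprc", "ap_at_k", "evaluate",
           "EvalReport"]


def sample_eval_negatives(graph: MultiRelationalGraph, split: EdgeSplit,
                          type_id: str, n: int,
                          seed: int = 0) -> list[tuple[str, str]]:
    """n chemical-gene pairs of the type absent from ALL folds, uniformly.

    Deterministic per (seed, type).  Raises if fewer than n non-edges exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positives = split.all_pairs(type_id)
    n_total = len(graph.chemicals) * len(graph.genes)
    n_non = n_total - len(positives)
    if n_non < n:
        raise ValueError(
            f"only {n_non} non-edges exist for type {type_id!r}; cannot sample {n}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(type_id.encode())]))
    nc, ng = len(graph.chemicals), len(graph.genes)
    out: list[tuple[str, str]] = []
    chosen: set[tuple[str, str]] = set()
    # rejection sampling; positives are sparse in the chemical x gene grid
    while len(out) < n:
        ci = rng.integers(0, nc, size=4 * (n - len(out)) + 8)
        gi = rng.integers(0, ng, size=ci.size)
        for i, j in zip(ci, gi):
            pair = (graph.chemicals[i], graph.genes[j])
            if pair in positives or pair in chosen:
                continue
            chosen.add(pair)
            out.append(pair)
            if len(out) == n:
                break
    return out


def _scores_labels(scores_pos: Sequence[float], scores_neg: Sequence[float]):
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        raise ValueError("both positive and negative score sets must be non-empty")
    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([np.asarray(scores_pos, float),
                        np.asarray(scores_neg, float)])
    return y, s


def auroc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    y, s = _scores_labels(scores_pos, scores_neg)
    return float(roc_auc_score(y, s))


def auprc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Area under the precision-recall curve (step-wise, no interpolation)."""
    y, s = _scores_labels(scores_pos, scores_neg)
    return float(average_precision_score(y, s))


def ap_at_k(ranked_labels: Sequence[int], k: int) -> float:
    """Average precision truncated at rank k.

    Mean of precision@i over the relevant (positive) ranks i <= k, divided
    by min(k, total number of positives in the ranked list).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = [int(bool(x)) for x in ranked_labels]
    n_pos = sum(labels)
    if n_pos == 0:
        return 0.0
    hits = 0
    acc = 0.0
    for i, label in enumerate(labels[:k], start=1):
        if label:
            hits += 1
            acc += hits / i
    return acc / min(k, n_pos)


@dataclass
class EvalReport:
    """Per-type and macro-averaged metrics plus run metadata."""

    per_type: pd.DataFrame  # interaction_type, n_pos, n_neg, auroc, auprc, ap_at_k
    macro: dict[str, float]
    metadata: dict = field(default_factory=dict)
    skipped_types: list[str] = field(default_factory=list)

    def write_tsv(self, per_type_path: str | Path,
                  macro_path: str | Path | None = None) -> None:
        self.per_type.to_csv(per_type_path, sep="\t", index=False)
        if macro_path is not None:
            row = {"variant": self.metadata.get("variant"),
                   "seed": self.metadata.get("seed"), **self.macro}
            pd.DataFrame([row]).to_csv(macro_path, sep="\t", index=False)


def evaluate(model, fold: str = "test", seed: int = 0, neg_ratio: float = 1.0,
             k: int = 20) -> EvalReport:
    """Score fold positives vs. sampled non-edges, per type, and macro-average.

    Types with zero positives in the fold are skipped (with a record in the
    report) and excluded from the macro average.
    """
    if fold not in ("valid", "test"):
        raise ValueError("fold must be 'valid' or 'test'")
    graph, split = model.graph, model.split
    z = model.embeddings(training=False).array()
    index = model.adjacency.node_index

    rows = []
    skipped = []
    for t in sorted(split.folds):
        positives = sorted((c, g) for c, _, g in split.folds[t][fold])
        if not positives:
            skipped.append(t)
            continue
        n_neg = max(1, round(neg_ratio * len(positives)))
        negatives = sample_eval_negatives(graph, split, t, n_neg, seed=seed)

        def pair_scores(pairs):
            ci = np.array([index[c] for c, _ in pairs])
            gi = np.array([index[g] for _, g in pairs])
            d = model.params[f"dec/D/{t}"].data
            R = model.params["dec/R"].data
            return np.einsum("ij,ij->i", (z[ci] * d) @ R, d * z[gi])

        s_pos = pair_scores(positives)
        s_neg = pair_scores(negatives)
        # deterministic ranking: score descending, then pair id
        items = ([(s, 1, p) for s, p in zip(s_pos, positives)]
                 + [(s, 0, p) for s, p in zip(s_neg, negatives)])
        items.sort(key=lambda x: (-x[0], x[2]))
        labels = [lab for _, lab, _ in items]
        rows.append((t, len(positives), len(negatives),
                     auroc(s_pos, s_neg), auprc(s_pos, s_neg),
                     ap_at_k(labels, k)))

    per_type = pd.DataFrame(
        rows, columns=["interaction_type", "n_pos", "n_neg",
                       "auroc", "auprc", "ap_at_k"])
    if per_type.empty:
        raise ValueError(f"no interaction type has positives in fold {fold!r}")
    macro = {m: float(per_type[m].mean()) for m in ("auroc", "auprc", "ap_at_k")}
    metadata = {
        "variant": model.variant,
        "seed": seed,
        "model_seed": model.seed,
        "fold": fold,
        "k": k,
        "neg_ratio": neg_ratio,
        "latent_mode": model.encoder_config.latent_mode,
        "lambda": model.latent.lam if model.latent else None,
        "latent_rates": model.latent_rates(),
    }
    return EvalReport(per_type=per_type, macro=macro, metadata=metadata,
                      skipped_types=skipped)
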