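# cginet

Typed chemical–gene interaction (CGI) prediction in an integrated
multi-relational graph of chemicals, genes, and pathways.

Knowing which genes a chemical acts on — and *how* (does it increase or
decrease the gene's activity, expression, phosphorylation, ...?) — is
central to drug discovery and repositioning, but experimentally confirmed
interactions cover a tiny fraction of chemical space. This package frames
CGI identification as multi-relational link prediction: given four untyped
*binary association* layers (chemical–chemical, gene–gene,
chemical–pathway, gene–pathway) and one typed *multi-interaction* layer of
chemical–gene triples `(c, degree^action, g)`, predict the probability
that an unobserved pair interacts under each type.

## Model

**Encoder** — a 2-layer relational graph convolution. Each layer updates
node *i* by summing normalized messages over every relation *r*:

    h_i' = σ( Σ_r [ Σ_{j∈N_i^r} W_r h_j / √(|N_i^r||N_j^r|)  +  W_r h_i / |N_i^r| ] )

with one-hot input features realized as an embedding lookup. Two
perspectives are provided: *total* (one GCN over all relation layers at
once) and *subgraph* (a first GCN over the binary-association layers
produces initial embeddings `z̄`, which seed a second GCN over the typed
chemical–gene layer).

**Latent links** — two network motifs carry signal about unobserved
interactions: **S-G** (chemical *c* interacts with gene *g₁*, which
associates with gene *g₂*, suggesting a candidate link *c–g₂* of the same
type) and **S-G-P** (an S-G whose chemical and genes additionally share a
pathway, grounding the candidate in a mechanism). Candidates whose S-G-P
support count `N̂` satisfies

    N̂_i^r ≥ max(2, λ · max_j N̂_j^r)

are promoted to *definite latent links* and join message passing in the
second encoder stage, scaled by a per-type latent rate `μ^r ∈ [0,1]`
(trainable, or fixed to 1).

**Decoder** — DEDICOM tensor factorization: a triple `(c, r, g)` is scored
as `z_c^T D_r R D_r z_g` with a per-type diagonal `D_r` and one global
`R` shared across interaction types, then squashed through a sigmoid.

**Training** — joint encoder+decoder optimization with Adam under a margin
ranking loss `Σ max(0, P_neg − P_pos + m)`, pairing each known edge with a
negative built by replacing the gene with one drawn ∝ degree^(3/4).

Five variants: `gcn-cg` (GCN on the chemical–gene layer only), `gcn-total`
(GCN on the whole graph), `cginet1` (two-stage subgraph encoder),
`cginet2` (+ latent links, trainable μ), `cginet3` (+ latent links, μ=1).

## Worked example

Real curated CGI collections are large and access-controlled, so the
package ships a synthetic-graph generator whose default fixture plants
half of all chemical–gene edges via S-G-P closure (so motif mining has
recoverable signal), mirrors the heavy type-frequency imbalance of curated
vocabularies, and organizes associations around pathway communities:

```python
from cginet import default_fixture, evaluate
from cginet.training import fixture_train_config, train_variant

graph, split, spec = default_fixture()
result = train_variant(graph, split, "cginet3",
                       fixture_train_config(seed=0, variant="cginet3"))
report = evaluate(result.model, fold="test", seed=0)
print(report.per_type.round(3).to_string(index=False))
print({k: round(v, 3) for k, v in report.macro.items()})
```

prints

```
       interaction_type  n_pos  n_neg  auroc  auprc  ap_at_k
affects^phosphorylation     11     11  0.860  0.892    0.892
      affects^transport      2      2  0.500  0.583    0.583
     decreases^activity     40     40  0.756  0.768    0.758
    decreases^secretion      5      5  1.000  1.000    1.000
   increases^expression    136    136  0.717  0.741    0.864
 increases^localization      5      5  0.680  0.723    0.723
{'auroc': 0.752, 'auprc': 0.785, 'ap_at_k': 0.803}
```

Each row scores that type's held-out test edges against an equal number of
sampled non-edges: `auroc` is the probability that a true interaction
outranks a non-edge, `auprc` the area under the precision–recall curve,
and `ap_at_k` the average precision over the top 20 ranked predictions.
The macro line averages types without weighting, so rare types (here
`affects^transport`, 24 edges in the whole graph) count as much as the
dominant `increases^expression`.

The same pipeline is scriptable from the shell:

```sh
cginet generate --out graph/                       # synthetic graph (TSV)
cginet mine-latent --graph graph/ --lambda 0.5 --seed 0 --out latent.tsv
cginet train --graph graph/ --variant cginet3 --seed 0 --out run/
cginet evaluate --model run/ --graph graph/ --fold test --out run/eval/
```

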