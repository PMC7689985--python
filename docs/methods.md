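# Methods

This note documents the model implemented by `cginet`, the synthetic data
it is exercised on, and the numerical and design choices made where the
mathematics alone does not pin down an implementation.

## Problem setting

The input is an integrated heterogeneous graph over three node classes —
chemicals, genes, pathways — with four untyped binary-association layers
(chemical–chemical, gene–gene, chemical–pathway, gene–pathway) and one
typed chemical–gene layer whose edges are triples
`(chemical, degree^action, gene)`, where the degree is one of
increases / decreases / affects and the action is a free label such as
activity or expression. The task is transductive typed link prediction:
for a fixed node universe, estimate for each interaction type `r` the
probability that an unobserved chemical–gene pair interacts under `r`.
Typed edges are split 8:1:1 into train/validation/test per type; only
train edges ever participate in message passing or motif mining.

## Encoder

Both encoder perspectives use 2-layer relational graph convolutions. One
layer updates node `i` as

    h_i' = σ( Σ_r [ Σ_{j∈N_i^r} W_r h_j / √(|N_i^r| |N_j^r|) + W_r h_i / |N_i^r| ] )

* The sum runs over directional relation channels: the undirected cc/gg
  layers plus both directions of each bipartite layer (cp/pc, gp/pg, and
  per type cg/gc), each with its own weight matrix per layer.
* 1/|N| factors are defined as 0 when a count is 0, so isolated nodes map
  to the zero vector. The self term is contributed once per relation in
  which the node has at least one neighbor (a single unnormalized global
  self weight is available via `self_loop="global"`).
* The self term passes through the relation weight `W_r`. Written with a
  bare `h_i` the update is dimensionally inconsistent whenever a layer
  changes width; routing the self message through `W_r` is the unique
  reading compatible with the one-hot input convention below, and it
  reproduces all identity-weight hand calculations.
* One-hot input features are never materialized: the first layer is an
  embedding lookup (row `i` of the layer-1 weight acts on node `i`'s
  one-hot vector), so layer-1 weights have shape (n_nodes, d₁).
* σ = ReLU on every layer; dropout (rate 0.1) is applied to dense layer
  inputs during training only.

**Total perspective** runs one GCN over every relation channel at once
with embedding sizes (32, 16); restricting the channels to the typed
chemical–gene layer recovers the plain CG-graph GCN baseline.

**Subgraph perspective** first encodes the binary-association layers with
sizes (128, 64) — chemicals aggregate from chemicals and pathways, genes
from genes and pathways; pathway nodes are embedded as message sources but
not forwarded — and then feeds the resulting initial embeddings `z̄` into
a second 2-layer GCN over the typed layer with sizes (32, 16).

## Latent links

Two motifs ground candidate interactions: **S-G** — `c` interacts with
`g₁` (typed) and `g₁` associates with `g₂`, implying a candidate `c–g₂`
of the same type — and **S-G-P**, an S-G whose chemical and *both* genes
share a pathway (the shared-by-all reading; a looser chemical-plus-one-gene
reading is available as a flag). Mining runs on train edges only. A
candidate is the pair `(c, g₂)` when it is not already a train edge of the
type; its support `N̂` counts distinct S-G-P instances implying it. A
candidate is promoted to a *definite latent link* when

    N̂_i^r ≥ max(2, λ · max_j N̂_j^r),   λ ∈ (0, 1]

(inclusive cutoff; the absolute floor of 2 means support-1 candidates are
never definite; the definite set shrinks monotonically as λ grows).
Definite links update the latent neighbor sets of *both* endpoints.

In the interaction stage, latent neighbors contribute messages through the
same per-type weight `W̃_r` as labeled neighbors, scaled by a per-type
latent rate `μ^r`: fixed to 1, or trainable as `μ^r = sigmoid(a_r)` so the
rate stays inside (0, 1) by construction.

**Latent normalization.** The normalizer printed for the latent term mixes
the receiver's labeled degree with an otherwise-undefined latent-degree
quantity. Two readings are implemented:

* `latent_norm="updated"` (default): definite links are treated as a
  topology update of the typed layer — latent entries are normalized by
  1/√(d_i·d_l) where the degrees come from the labeled+latent union. This
  makes latent and labeled messages commensurate and lets nodes whose only
  edges under a type are latent still receive messages. Empirically this
  reading reproduces the expected behavior that latent links *help* (on
  the fixture, macro AUPRC of the μ=1 variant rises above the no-latent
  variant), which is the entire point of the mechanism.
* `latent_norm="separate"`: the literal two-sum reading —
  1/√(|N_i^r|·max(1, |L_l^r|)) with |N_i^r| the receiver's labeled degree
  (zero degree zeroes the message) and |L_l^r| the sender's latent degree.
  On the fixture this starves cold nodes of latent messages and lets
  high-magnitude latent terms distort training; it measurably degrades the
  μ=1 variant below the no-latent variant, so it is not the default.

## Decoder and training

A triple `(c, r, g)` is scored with the DEDICOM bilinear form
`z_c^T D_r R D_r z_g` — a per-type diagonal `D_r` reweighting embedding
dimensions and one dense `R` shared across all types, which is what lets
rare types borrow statistical strength from frequent ones — followed by a
numerically stable sigmoid.

Training minimizes the summed margin ranking loss
`Σ max(0, P_neg − P_pos + m)` with m = 0.1, pairing every train edge with
one fresh negative per epoch built by replacing the gene with a gene drawn
with probability ∝ degree^(3/4) (degrees from train cg edges, summed over
types by default; per-type degrees and symmetric corruption are flags).
Zero-degree genes have probability 0 unless all degrees are zero (then
uniform); draws that hit a known train edge of the same type are rejected
with a bounded retry budget. All parameters are optimized jointly with
Adam.

### Initialization

All weights use Glorot-uniform limits. For the decoder diagonal `D_r` the
fan-in/fan-out is taken as (d, d) and the sampled values are folded
non-negative. The fold matters: `D_r` enters the score once on each side,
so a sign-mixed diagonal can start a rarely-updated type in a basin where
its scores are systematically inverted, and because the loss acts through
a sigmoid the gradient vanishes once those wrong scores saturate — the
type can then never recover (observed as per-type AUROC far below chance
with otherwise healthy training). Non-negative per-dimension importances
at init remove the trap without changing the init scale; signs remain
free during training.

### Reference defaults vs. fixture-scale runs

`TrainConfig` defaults to the reference regimen — 10 epochs, batch size
128, learning rate 0.001, margin 0.1, dropout 0.1 — which is calibrated
for graphs with ~10⁶ train edges, where one epoch is ~10⁴ optimizer
steps. On a desk-scale fixture with ~1.6·10³ train edges the same epoch
count yields ~10² steps and the model barely moves. Fixture-scale runs
therefore use `training.fixture_train_config`: full-batch training, 400
epochs, learning rate 0.01 — roughly matching the reference optimization
effort per edge. This regimen was chosen on validation-fold macro AUROC
only; test folds were never consulted.

## Synthetic data

Real curated interaction collections are too large for unit-scale testing
and not redistributable, so every pipeline stage is exercised on generated
graphs. The generator's default (`family="pathway"`) is modular:

* each gene joins 1 + Poisson(0.5) of 20 pathways, each chemical targets
  1 + Poisson(0.5) pathways; gene–gene and chemical–chemical associations
  are dense within shared-pathway communities (0.25 / 0.20) and sparse
  outside (0.004 / 0.005); chemicals join their target pathways with
  probability 0.8; small uniform background rates add noise memberships.
* typed edges follow a geometric type-frequency decay calibrated so the
  top 20% of types hold ~90% of edges, matching the extreme imbalance of
  curated interaction vocabularies; metric-bearing types are floored at
  50 edges (the desk-scale analog of the ≥180-edge vocabulary filter,
  without which tail types contribute 1-test-positive coin flips that
  dominate macro metrics) while exactly one deliberately rare type
  (24 edges) keeps rare-type code paths exercised.
* rarer types preferentially reuse chemical–gene pairs already active
  under more frequent types (probability 0.5), reflecting that a pair may
  interact under several types.
* per type, 40% of edges are seeded (biased toward the chemical's target
  pathways), 50% are *planted* by S-G-P closure — an edge `(c, r, g₂)` is
  added only where an edge `(c, r, g₁)`, an association `(g₁, g₂)`, and a
  pathway shared by all three already exist — and 10% are uniform noise.
  Every edge's provenance is recorded in a manifest.

A structureless `family="er"` alternative (Erdős–Rényi association layers,
independent bipartite pathway layers) is kept for contrast. It was the
first implementation, and it demonstrates a real limitation: its planted
motif signal is recoverable by direct S-G-P support counting (~0.8 AUROC)
but *not* representable by a 2-layer GCN at this scale — embeddings carry
no pair signal and all model variants sit at chance. Community structure
is not a convenience here; it is the statistical feature of real
interactomes that makes graph-convolutional encoders appropriate at all.

**What passing tests do and do not show.** The fixture demonstrates
end-to-end correctness, training progress, and the qualitative value of
the subgraph staging and latent links under planted, community-aligned
signal. It does not emulate curated-data pathologies — literature bias,
hub chemicals with 10⁴ interactions, identifier noise, contradictory
annotations — so absolute metric values on the fixture say nothing about
absolute performance on real collections. Variant gaps on the fixture are
a few points of macro AUPRC and are seed-sensitive; the ordering checks
therefore average three fixed seeds under a paired protocol (same splits,
same evaluation negatives for every variant).

## Evaluation protocol

Per type, held-out positives are scored against non-edges of the same
type sampled uniformly at 1:1 (configurable); the sampled set excludes
edges of *all* folds. AUROC is the Mann–Whitney probability that a
positive outranks a negative (ties ½), AUPRC the step-wise area under the
precision–recall curve, and AP@k (k = 20) the average of precision at the
relevant ranks within the top k, normalized by min(k, #positives). Macro
metrics average types without weighting; types with no fold positives are
skipped and recorded. Rankings break score ties by pair id, so reports are
bit-reproducible for a given seed. The choice of evaluation negative
protocol is the largest caveat when comparing absolute numbers across
implementations, and reports record it in their metadata.

## Determinism

Every stochastic component (generation, splitting, initialization, batch
order, dropout, negative draws, evaluation negatives) draws from
`numpy` generators derived from explicit seeds via `SeedSequence`;
repeated runs with the same seed reproduce loss logs, checkpoints, and
reports byte-for-byte.

## Checkpoint format

`Model.save` writes a single `.npz` archive: one array per parameter
(keys `param::<name>`) plus a JSON metadata entry (`__meta__`) holding the
format version (currently 1), the variant name, the seed, the full encoder
configuration, the latent λ, and the current latent rates. `Model.load`
refuses unknown versions and rebuilds the model against a caller-supplied
graph and split (the model is transductive: parameters are meaningless
against any other node universe).

## Known limitations

* Transductive only — adding nodes requires retraining.
* Two encoder layers, as specified; no deeper stacks, attention, or
  gating.
* The validation fold is reported per epoch but never used for early
  stopping (fixed-epoch training).
* Latent-link mining enumerates motifs exactly; on graphs with very dense
  gene–gene layers the S-G-P enumeration can grow large (it is cubic in
  local neighborhood sizes), which is acceptable at fixture scale but
  would need sampling or pruning for million-edge layers.
* Baseline embedding methods (random walks, matrix factorization) are out
  of scope; the CG-only and total-graph GCN variants are the in-package
  baselines.
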