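# Methods

## Model

A molecule m is represented from two views.

**Atom view (h^A).** The molecular graph has implicit-hydrogen heavy
atoms as nodes and covalent bonds as featureless undirected edges; bond
types are recoverable from the atom features, which are four
concatenated one-hot blocks — element (corpus vocabulary plus an
unknown slot), formal charge (−2..+2 plus overflow), aromaticity, and
attached-hydrogen count (0..4 plus overflow) — so every atom row
contains exactly four ones. A learned linear map projects this F₀-wide
input to the model width d; K message-passing layers (GCN with
symmetric normalization and self loops, single-head GAT, mean-neighbor
GraphSAGE, or a TAG polynomial filter of 2 hops) follow, with a ReLU
between layers and a linear final layer, and the molecule embedding is
the **sum** of the final atom states. Sum pooling is deliberate: it
makes the embedding additive over disconnected components and, because
reactions approximately conserve atoms, gives the translation score a
meaningful geometry.

**Reaction view (h^X).** From a reaction corpus we build a
molecule-level graph whose nodes are unique molecules (by canonical
SMILES) and whose edges join every (reactant, product) pair of every
reaction, each edge tagged with its originating reaction. Node features
start as the molecule's functional-group count vector (39 substructure
patterns, shipped as an editable TSV mirroring the standard RDKit
fragment catalog) contracted with a learned 39×d embedding table. Each
of L layers updates

m_i^l = m_i^{l−1} + Σ_j π_ij m_j^{l−1},
π_ij = softmax_j( w_a · (m_i ⊙ m_j ⊙ c) ),

where c is the reaction context — the summed layer-(l−1) states of all
molecules participating in the reaction tagged on edge (i, j). Because
a node's neighbors span multiple reactions while the attention formula
is written per reaction, each edge uses the context of its own tagged
reaction; parallel edges from different reactions are kept distinct.
Updates are synchronous (contexts computed from layer-(l−1) states
before any update). Edges are traversed undirected — products inform
reactants and vice versa — with the orientation retained as metadata.
Each node aggregates a fixed-size sample of Q neighbors: uniform
without replacement when the degree allows, padded with replacement
otherwise, so the attention always normalizes over Q draws without
masking; isolated nodes keep their initial state.

The graph is built from the **training split only**; molecules outside
it (validation/test esters, unseen molecules) fall back to the
projected functional-group vector, and the embedding metadata reports
how many fallbacks occurred. This prevents evaluation reactions from
leaking structure into training through graph edges.

**Fusion and relation memory.** The fused embedding is
h = W_c(h^A ‖ h^X); a reaction side is the sum of its members' fused
embeddings. The relation network holds a key matrix K and memory matrix
M (both N×d, seeded standard normal scaled by 1/√d to keep initial
logits O(1)). Keys attend over slots via softmax((x_R ⊙ x_P)ᵀ k_n); the
relation vector is the attention-weighted combination of memory rows,
hence always inside their convex hull, and with N=1 the model collapses
exactly to a single global translation (plain TransE). The score is the
squared Euclidean norm ‖x_R + e − x_P‖²; a plain-norm variant sits
behind `memory.score_norm` since rankings coincide within either
convention, and the squared form has smoother gradients.

**Objectives.** The margin loss averages matched-pair scores and, over
the |XB|²−|XB| ordered in-batch mismatches (both directions, no
deduplication of colliding product sides), averages max(γ − S, 0); a
batch of one has no negative term. The cross-view loss is InfoNCE over
cosine similarities between the atom-view and reaction-view sums of the
same side, summed over reactant-side and product-side tasks; a
zero-norm side embedding is a hard error, which is why the synthetic
grammar guarantees every molecule a non-empty functional-group profile.
The total objective adds α·L_C and an optional λ‖Θ‖²_F (λ defaults to
0 — no published value exists for it — and is exposed in config).
Negative sampling is purely minibatch-based: epoch-level shuffling with
a seeded generator refreshes the negatives each epoch; no negative
store is kept.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `dim` (d) | 256 (64 desk-scale) | shared embedding width |
| `encoder.aggregator` | gcn | atom-view aggregator family |
| `encoder.num_layers` (K) | 2 | atom-view depth |
| `rxgraph.num_layers` (L) | 1 | reaction-view depth |
| `rxgraph.Q` | 10 | neighbor sample size |
| `memory.n_slots` (N) | 10 | relation memory slots |
| `loss.gamma` (γ) | 4 | score margin for mismatched pairs |
| `loss.tau` (τ) | 0.1 | InfoNCE temperature |
| `loss.alpha` (α) | 10⁻³ | cross-view weight |
| `loss.l2` (λ) | 0 | parameter regularization |
| `train.epochs` | 50 | optimization epochs (Adam) |
| `train.batch_size` | 1024 | reactions per step |
| `train.learning_rate` | 10⁻⁴ | Adam step size |

The K/L/Q/N/γ/τ/α defaults are the published operating point of the
method; d, learning rate and batch size defaults target corpora of
10⁴–10⁵ reactions. For the desk-scale experiments in this repository
(200 synthetic reactions) we fix d=64, learning rate 10⁻³ and batch 64
— at 160 training reactions the published batch size would give a
single optimizer step per epoch and the larger width is unnecessary.
These desk-scale values were chosen once from a small sweep on the
200-reaction corpus and are used consistently in the tests, the
acceptance script and the README example.

Model selection keeps the parameter snapshot with the best validation
MRR, evaluated after every epoch. Ranking uses a per-candidate relation
vector — the memory network conditions on both sides, so each (R_i,
P_j) candidate pair gets its own e — and breaks ties pessimistically
(the true candidate is placed after every equal-scored competitor), so
reported metrics are never flattered by degenerate constant scores.

## Synthetic corpora

The generator emulates the structural features the model consumes,
not reaction thermodynamics. Two template families give
family-constant bond/ring-change signatures: esterification-like
(alcohol + acid → ester; ΔNB = 0, ΔNR = 0 with implicit hydrogens) and
nitrile-anchored ring-opening (ΔNB = −1, ΔNR = −1). Product sides are
unique across reactions; `overlap_degree` then assigns a shared
single-atom by-product (water, ammonia, …) to that many reaction pairs,
creating the second-order neighborhoods that shared products induce
while leaving the family signatures untouched (single atoms carry no
bonds or rings). With `overlap_degree=0` the generator additionally
uses each alcohol and acid at most once, so the reaction-aware graph is
a disjoint union of per-reaction stars. Three frozen corpora (8, 200
and 2000 reactions; seeds 7, 11, 13; SHA-256 checksums in
`synthetic_fixtures.GOLDEN_CHECKSUMS`) anchor the tests; the two
smaller ones ship as files and the 2000-reaction one is regenerated
deterministically on demand.

What passing these corpora does **not** show: robustness to the
stoichiometric ambiguity, atom-mapping noise, reagent contamination and
class imbalance of curated reaction datasets, or to molecules far
outside the template grammar (charged species, stereochemistry —
unsupported throughout — or large ring systems). The corpora exercise
the learning machinery under controlled, chemically valid conditions;
absolute metric values do not transfer to USPTO-scale data.

## Numerical choices

- All computation is float64 on a package-internal reverse-mode
  autodiff core; gradients of the complete objective are verified
  against central finite differences (tolerance 10⁻⁴).
- Softmaxes subtract a detached per-row maximum before exponentiation.
- Cosine similarity on a zero-norm vector raises rather than silently
  regularizing; the l2 score variant adds a ~10⁻³⁰⁰ epsilon under the
  square root only to avoid an undefined gradient exactly at zero.
- Glorot-uniform initialization with a recorded seed everywhere; the
  training loop is bit-deterministic given its seeds (identical loss
  traces across reruns), up to BLAS reduction order.
- Isolated atoms and molecules aggregate over the self term only; empty
  attention neighborhoods return empty distributions, never NaN.
- Reactions whose sides canonicalize to the same molecule set are
  dropped at parse time with a warning: they would make the positive
  score term degenerate.

## Known limitations

- An untrained model already ranks far above chance on the synthetic
  corpora: sum-pooled random-weight embeddings preserve atom
  composition, which reactions largely conserve. Gains from training
  should therefore be read against the untrained baseline the
  acceptance script reports, not against uniform random ranking.
- The reaction-view attention weight w_a is a per-layer 1×d row vector
  — the minimal shape making the logit scalar; richer parameterizations
  were not explored.
- Whether the reaction context should include only the side opposite
  the anchor molecule is an open modeling question; the implemented
  context sums over both sides.
- The CPU implementation targets corpora up to ~10⁴ reactions; no
  GPU path, sparse-attention batching, or minibatch graph sampling for
  larger corpora is provided.
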