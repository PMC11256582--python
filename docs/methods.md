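# Methods

## Model overview

The package treats drug-target interaction (DTI) prediction as node
classification on a pair graph. The assumptions, in order of use:

1. **Similarity carries signal.** Drugs with overlapping association
   profiles (interactions, indications, side effects) or fingerprints,
   and targets with overlapping interaction/disease profiles or
   homologous sequences, tend to share binding behavior.
2. **Evidence is substitutable.** Binary similarity networks from
   different sources are fused by element-wise OR: a single source
   calling two entities similar suffices for an edge ("see one, get
   one"). This is deliberately permissive; precision is recovered later
   by the supervised stages.
3. **Pairs inform neighboring pairs.** Two drug-target pairs sharing a
   drug or a target are correlated; a graph network that aggregates
   over such neighbors can propagate label evidence between them.

## Similarity stage

* Jaccard for binary association profiles, Tanimoto for fingerprints
  (both are `|A∩B| / |A∪B|`; they are kept as separate operations
  because their inputs and failure modes differ), local alignment for
  sequences via `Bio.Align.PairwiseAligner` (BLOSUM62, gap open 10,
  extend 0.5, affine; a gap of length L costs `open + (L−1)·extend`).
* Alignment scores are normalized by `SW(i,j) / √(SW(i,i)·SW(j,j))` so
  the diagonal is 1 and all seven similarity matrices share the [0, 1]
  scale; a raw-score mode exists (`normalize=False`).
* A pair of all-zero profiles (0/0) is defined as similarity 0: no
  shared evidence implies no similarity. Such profiles are counted in
  the log.
* Binarization is strict (`S_ij > α`) with the diagonal forced to 0, so
  homogeneous networks are simple graphs — self-loops add nothing to
  random walks. α is a config parameter (default 0.5) with per-network
  overrides, and the pipeline logs every network's edge density so α
  can be calibrated from the similarity histogram.
* **Sequence-network α.** Normalized local-alignment scores are
  scale-compressed: in the synthetic data a motif covering 1/4 of the
  sequence gives within-cluster similarity ≈ 0.25 against ≈ 0.04
  background. The distribution is sharply bimodal and empty around
  0.15, so the reference studies use
  `alpha = {default: 0.5, protein_sequence: 0.15}`. With a global 0.5
  the sequence network would be empty and the ablation study
  meaningless.

## DeepWalk stage

Uniform truncated random walks (10 walks per node, 40 nodes per walk)
feed a skip-gram model with negative sampling — a vectorized numpy
trainer written for this package. Window 5, dimension 64, 5 epochs,
5 negatives from the unigram^0.75 distribution, initial learning rate
0.05 decaying linearly to ~0. Minibatches of 512 window pairs are
applied as *per-node mean* gradients: on vocabularies of tens of nodes
every node recurs many times per batch, and raw per-pair accumulation
overshoots and diverges; averaging per node bounds each step while
keeping the update direction. Nodes that never co-occur on a walk
(isolated nodes) receive zero vectors plus a warning rather than an
error, so downstream pair-feature concatenation always works.

The walk length, walks per node, window and dimension are conventional
DeepWalk settings; they were fixed once and all are config-exposed
(`deepwalk:` block).

## Pair graph

For N_D drugs and N_T targets the pair graph has `N_D · N_T` nodes and
an edge between pairs sharing the drug or the target, so every degree
is `N_D + N_T − 2`. Node id `u = i · N_T + j` gives an O(1) bijection
(row-major, inverse by divmod). The adjacency rule applied to a node
and itself is trivially 1; neighbor enumeration nevertheless excludes
self, because the layer update already concatenates the node's own
representation — including self among aggregated neighbors would count
it twice. Everything (adjacency, neighbors, features, labels, balanced
sampling) is computed on demand from O(N_D + N_T) state; nothing of
size N_DTP² is ever allocated.

Balanced sampling takes all known-interaction pairs plus an equal-count
uniform without-replacement sample of unlabeled pairs (the standard
positive-unlabeled protocol for this problem).

## GraphSAGE stage

From-scratch numpy implementation (sampling, forward, manual backprop,
Adam). Defaults: K = 2 layers with fanouts S₁ = 50, S₂ = 10 (the
standard budget `S₁·S₂ ≤ 500`; a warning fires beyond it), hidden width
128, ReLU, sigmoid scoring head, binary cross-entropy (predictions
clipped at 1e-12), Adam at learning rate 0.001, batch 256, 15 epochs.
Choices the formulation leaves open, resolved as:

* **Sampling.** Uniform without replacement when degree ≥ fanout (the
  sample tree below one parent has distinct nodes), with replacement to
  the fixed fanout otherwise; an isolated node's slots are filled with
  the node itself. Fixed-size samples keep minibatches rectangular.
  On the full implicit pair graph, neighbor ranks map to node ids by
  closed-form index arithmetic, so sampling never builds adjacency
  lists; a `RestrictedSampler` limits neighbors to a given node subset
  (desk-scale "subgraph-only" mode).
* **Aggregators.** Mean (default), max-pooling (`max relu(W_p x + b_p)`),
  and LSTM over the (randomly ordered) neighbor sequence. The LSTM
  aggregator is not permutation invariant — inherent to that design —
  and is the slowest; mean is the default.
* **No per-layer L2 normalization** — the update is exactly
  `σ(W_k · concat)`.
* **Refined features** are `h^K` (last layer before the head); they are
  what the final classifier consumes.
* **dtype.** Training runs in float32 by default (the minibatch trees
  at S₁ = 50, S₂ = 10 are memory-bandwidth-bound); float64 is available
  and is what the numerics equivalence tests use.

## Classification and evaluation

Random forest (500 trees, Gini impurity, √features per split) on the
refined features; logistic regression and an RBF SVM with probability
output behind the same interface for sensitivity comparisons. Metrics:
AUROC (rank statistic), AUPR (step integration of the
precision-recall curve / average precision), and accuracy, precision,
recall, F1 at threshold 0.5.

Fivefold cross-validation splits positives and negatives separately
into near-equal parts (fold sizes differ by at most one per class), so
every fold keeps the global balance; assignment is keyed by node id and
independent of input order. **The graph network is retrained inside
every fold by default**: refining test-node features with a model that
saw test labels would be transductive leakage. A faster
shared-embedding mode (train once on the full sample) exists and is
labeled as such in the report. A repeated-split protocol (default
50 × 75/25) is also provided. Ranked prediction lists order candidates
by descending score with deterministic (drug_id, target_id)
tie-breaking.

## Synthetic data: what it emulates and what it does not

The generator plants precisely the structure the method assumes:
entities fall into clusters; every association source gives an entity
its cluster's attribute block, flipped element-wise with probability
`assoc_noise` (default 0.05, per-source overrides available);
fingerprints share cluster bit-blocks; sequences are random backbones
with a cluster motif (length = seq_length/4) implanted at a random
position; interactions are Bernoulli within matched (drug-cluster,
target-cluster) blocks at `interaction_density` over a uniform
background (0.002). One root seed is split per artifact, so a fixed
seed yields byte-identical files.

**Interaction density and identifiability.** All features are
cluster-level, so pairs inside a matched block are statistically
interchangeable: any classifier's balanced-sample AUROC is capped at
`1 − f/2` and its top-of-ranking precision at `p/(p + f·n)` where f is
the fraction of sampled negatives falling inside matched blocks. The
default density of 0.8 makes the planted rule the majority behavior
within matched blocks (cap ≈ 0.97 AUROC / ≈ 0.94 AUPR), leaving the
planted signal genuinely recoverable; at low densities the task is
structurally unidentifiable regardless of method quality.

What passing the synthetic studies does **not** show: robustness to the
scale-free degree distributions, block-free similarity structure,
covariate shift and annotation biases of real pharmacological data, or
to the severe class imbalance of a real pair universe (the synthetic
grids are ~200× smaller than the published datasets). The synthetic
studies validate the machinery — similarity fusion, embedding, pair
graph, training, leak-free evaluation — not real-data performance.

## Reference studies (what `scripts/acceptance.py` runs)

* **Combinatorics.** Pair-node counts and degrees at the published
  dataset scales (708×1512 and 151×285) — exact integers.
* **Signal recovery.** Default 60-drug × 90-target dataset (4 + 4
  clusters, noise 0.05), full pipeline, fivefold CV. With the defaults
  above this lands around AUROC 0.97 / AUPR 0.94.
* **Permutation null.** Same data with sample labels shuffled before
  the graph network or classifier sees them; AUROC stays at chance —
  the leakage control for the whole pipeline.
* **Ablation.** Sequence-dominant conditions (40×60 grid, 3 + 3
  clusters, non-sequence target-side sources noised to
  near-uninformativeness) run with and without the sequence network,
  on five seeds, with a reduced budget chosen for the smaller graphs
  (walk length 30, embedding dim 32, GraphSAGE width 64, 10 epochs,
  twofold CV). Removing the sequence network consistently costs
  ~0.1-0.15 mean AUROC.

## Known limitations

* The skip-gram and GraphSAGE trainers are CPU/numpy implementations
  tuned for desk-scale graphs (≤ a few thousand entities); they are
  faithful but not competitive with GPU implementations at the scale of
  a million-node pair graph.
* Hierarchical-softmax skip-gram is not implemented; negative sampling
  is the sole objective.
* The LSTM aggregator trains by full backpropagation through the
  neighbor sequence and is markedly slower than mean/pooling; use it
  for sensitivity comparisons, not routine runs.
* Fingerprints are consumed as precomputed bit matrices; computing them
  from chemical structure files is out of scope.
* Smith-Waterman is all-pairs quadratic in the number of sequences;
  similarity matrices are cached per input set to amortize it.
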