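# Methods

## Model

`atacspace` learns one latent space ℝ^d containing both cells and canonical
DNA k-mers. The only supervision is the binary cell-by-event accessibility
matrix together with the events' DNA sequences; no motif database, no peak
embedding and no per-event parameters are involved. Events enter training
only through sampled subsequences, which is what lets independently
processed atlases (different peak sets over the same genome) share one
space, and what lets any DNA sequence — a motif consensus, a 10-mer, an
enhancer — be placed into the space after training.

### Featurization

* Canonical k-mers: a k-mer and its reverse complement share one embedding
  row. Rows are the dense ranks of `min(code, rc_code)` over all 4^k base-4
  codes; for even k there are (4^k + 4^(k/2))/2 classes (palindromes are
  their own class), for odd k exactly 4^k/2. The dense lookup table limits
  k to ≤ 12 in this implementation (the default is k = 8).
* Context pairs ("n-grams"): within every window of N consecutive retained
  k-mers, each of the N(N−1)/2 k-mer pairs contributes one extra feature,
  hashed into a fixed `bucket` of rows (default 2,000,000). The hashed key
  is the lexicographic minimum of the pair's concatenation and the
  concatenation of the reverse complements in swapped order, so feature
  bags — and therefore induced embeddings — are exactly strand-invariant.
  Only full windows of N retained k-mers generate pairs; repeated pairs
  from overlapping windows are kept as multiset occurrences.
* Windows containing any non-ACGT base are skipped (hard-masked genome
  practice; soft-masked lowercase bases are uppercased and used).
* Entity embedding: an entity with M feature vectors w₁…w_M is embedded as
  `Σ wᵢ / M^P` with P = 0.5. The implementation accumulates rows in sorted
  index order so that equal feature multisets give bit-identical vectors.

### Training objective

Per epoch every usable event contributes `examples_per_event` examples
(default 20), consumed in random order. An example samples an L-bp window
(L = 150; shorter events are used whole), one positive cell uniformly among
the cells with the event open, and K = 10 negative cells uniformly without
replacement among cells with the event closed — restricted to the
positive's dataset, and to its batch when `batch_aware=True`. The loss is
the cosine margin ranking loss printed in the README with margin 0.05.
Zero-hinge negatives are not updated; a zero-loss example updates nothing.
Cosine with a zero-norm vector is defined as 0 and counted in a diagnostic.

Optimizer: exact cosine gradients, applied per row with an Adagrad-style
per-row accumulator and a base rate (lr0 = 0.01) decaying linearly to zero
over the total planned examples. Because cosine similarity is
scale-invariant, the gradient w.r.t. each feature row equals the gradient
w.r.t. the un-normalized feature sum; the 1/M^P normalization affects
induced embeddings, not training. K, margin and lr0 are not dictated by the
method itself; the defaults follow the general-purpose entity-embedding
framework this builds on and are exposed in `TrainingConfig`.

Initialization is deliberately asymmetric. Cell rows start uniform in
[−10⁻³, 10⁻³]: cells receive orders of magnitude more updates than any one
feature row, and a larger random start would dominate their trained
displacement and blur within-cluster geometry. Feature rows start uniform
in [−1/d, 1/d]: the residual random component acts as a noise floor that
keeps rarely-updated k-mers away from every cell's neighborhood, while
recurrent (motif) k-mers earn displacements well above it.

Event sequences are canonically strand-oriented (lexicographic min of the
two strands) when the model is built, which makes the entire training
trajectory — including window sampling — bit-identical under reverse
complementation of the input. Training is single-threaded and
bit-reproducible for a fixed seed; `threads` is accepted for interface
compatibility but parallel (non-deterministic) updates are not implemented.
Memory is constant in the number of examples: examples are generated,
consumed and discarded inside one compiled loop.

### Downstream

* TF activity: cosine(cell, motif-consensus embedding), z-scored per motif
  across cells with population SD; constant columns become all-zero and are
  flagged. The consensus is embedded from its width−k+1 k-mers only — the
  natural reading of the entity-count convention — with an
  `include_ngrams` flag for the alternative reading.
* Graphs: exact brute-force cosine KNN (K = 20) up to 20,000 cells,
  pynndescent above; SNN weights are Jaccard overlaps of the
  K+1-neighborhoods (self included), pruned below 1/15 (the Seurat
  convention). Louvain clustering is delegated to igraph's multilevel
  algorithm, deterministic for a fixed graph.
* Small-cluster merging reassigns the smallest offending cluster wholesale
  to the cluster with maximal mean inter-cluster SNN weight (ties: larger
  cluster, then lower label) until `min_size` or `target_k` is met.
* De novo motifs: all canonical 10-mers are embedded as the plain average
  of their three 8-mer rows; a 10-mer joins a cell group when it is among
  the 50 cosine-nearest 10-mers of at least 20% of the group's cells;
  associated 10-mers are clustered with average linkage on
  `1 − max_matches/10` (best ungapped overlap over all offsets and both
  strands — a deterministic, strand-aware stand-in for external k-mer
  clustering and multiple-alignment tools), cut at 0.5; clusters of more
  than three members are star-aligned (anchor = member with minimal total
  dissimilarity; ties at placement prefer the first offset/strand scanned)
  and give a PWM over the columns covered by at least half the members,
  with a 0.01 pseudocount per base.

### Benchmarking

Biological conservation = mean of cell-type ASW rescaled to [0,1]
((s+1)/2), NMI, ARI clipped to [0,1], and homogeneity, comparing a
clustering (resolution searched so the cluster count matches the number of
cell types, with small-cluster merging as fallback) against the cell-type
labels. Batch correction = mean of batch ASW (per cell type,
mean(1 − |silhouette(batch)|)), graph connectivity (per cell type, largest
connected component fraction of the type's KNN subgraph), kBET acceptance
(per cell type: chi-squared goodness of fit of each neighborhood's batch
composition against the type's batch proportions at α = 0.05, neighborhood
size min(50, ⌊mean batch size/2⌋), up to 1,000 tested cells), and batch NMI
(per cell type, 1 − NMI(cluster, batch)). Cell types present in a single
batch are excluded from the per-type batch metrics with a warning. Overall
score = 0.6·bio + 0.4·batch.

Bootstrap comparison resamples cells with replacement (B = 1,000 by
default); the same indices are applied to every method per replicate,
clustering is re-run at the resolution found once on the full data
(re-searching inside every replicate would be 1,000× costlier and is not
what the fixed-resolution convention implies), percentile CIs are reported,
p-values come from CI inversion (floored at 1/B) and are
Benjamini–Hochberg-adjusted across all method pairs. Note that BH
adjustment is monotone and dominates the raw p-values but is not
idempotent in the strict sense — re-adjusting adjusted values can increase
them; tests pin monotonicity, dominance and determinism.

## Synthetic data

The generator produces the study conditions for every test: `n_types` cell
types with balanced membership; per type one randomly drawn 10-bp consensus
(pairwise Hamming ≥ 4 on both strands) planted into its type-specific
events at `motif_insert_rate` (0.9) with 5% per-position mutation at a
uniform position; accessibility with per-type dropout (type-specific events
open in-type with probability 1 − dropout and elsewhere at 0.02, shared
events at 0.3, background at 0.05); optional batches with batch-biased
artifact events (odds shifted by `batch_strength`) and a per-batch coverage
shift on the odds scale (±0.075·`batch_strength`); and a 10% fraction of
events shorter than L to exercise the short-event rule.

Event sequences are slices of one shared uniform-random mini-genome
(100 kb) rather than independent random strings, and the genomic positions
of the roles are interleaved so overlapping events carry different roles.
Both choices exist for one reason: in real data no k-mer is private to a
single event — any 10-mer recurs across many events of mixed cell types —
so the planted motif must be the *only* type-coherent sequence feature. A
private-per-event background would act as a perfect accessibility barcode
and dominate the latent space in a way no real sequence can. Base
composition stays uniform; GC structure, fragment-level sampling and
read-level noise are not modelled, so passing tests demonstrate the
machinery recovers planted signal under idealized composition, not
performance on real genomes.

The frozen benchmark used by the end-to-end tests is 300 cells, 3 types,
1,000 events of 500 bp, insert rate 0.9, dropout 0.5, 2 batches, generator
seed 7 — small enough for minutes-scale CPU runs, large enough that
clustering, TF scoring and de novo discovery are non-trivial.

## Numerical and design notes

* Strand invariance of induced embeddings is exact (bit-level), enforced by
  canonical hashing plus sorted accumulation.
* The N-gram pair hash is `canonical_pair_code mod bucket`; collisions are
  rare at the default bucket and harmless (they share a row, as intended by
  the hashing-trick design).
* Determinism contracts: training (fixed seed, single thread), de novo
  discovery (no randomness), clustering (igraph multilevel on a fixed
  graph).
* Degenerate inputs: events accessible in no or all cells, or with
  sequences shorter than k, are dropped before training and counted;
  an event left with no eligible negatives at sampling time is skipped and
  counted, never fatal.

## Known limitations

* De novo recovery on the frozen small benchmark is the most
  variance-sensitive stage: which motif-variant 10-mers surface in the
  bipartite top-50 lists depends on the training seed, and individual runs
  can fall short of full recovery for one cell type. The TF-scoring readout
  (z-scored, relative) is much more stable than the absolute-ranking de
  novo route.
* Batch-aware negative sampling removes all cross-batch contrast from the
  objective. At benchmark scale nothing then anchors the batches' maps to a
  common frame, and the batch-aware embedding can score *worse* on batch
  mixing than plain training — whose sequence-level representation is
  already largely immune to accessibility-level batch artifacts. The
  batch-aware mode remains most meaningful for multi-dataset co-embedding,
  where per-dataset sampling is structurally unavoidable.
* Composite/dimeric motifs receive no special handling; the consensus
  embedding flattens a PWM to its argmax string.
* kBET is implemented in one fixed variant (documented above); external
  implementations differ in neighborhood-size heuristics and will not agree
  to the digit.
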