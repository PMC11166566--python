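# atacspace

Sequence-informed co-embedding of cells and DNA k-mers for single-cell
ATAC-seq.

## The problem

scATAC-seq produces an extremely sparse binary matrix of cells × accessible
events (peaks or genomic tiles). Most embedding methods work from that matrix
alone and therefore inherit its batch artifacts and cannot say anything about
*sequence*. `atacspace` instead learns a joint latent space for cells and DNA
k-mers directly from the sequences of accessible events: cells end up near
the k-mers — and hence the transcription-factor motifs — that drive their
accessibility. The trained space supports

- cell clustering and visualization,
- per-cell TF motif activity scores,
- de novo motif discovery for any group of cells,
- co-embedding of several datasets with different peak atlases, with
  batch-aware negative sampling,
- quantitative benchmarking of embeddings (biological conservation, batch
  correction, bootstrap comparison of methods).

## The model

Training examples are sampled on the fly from the binary cell-by-event
matrix. For an event with DNA sequence *S*, an *L*-bp subsequence (default
L = 150) is drawn and represented as the bag of its L − k + 1 overlapping
k-mers (k = 8); each k-mer and its reverse complement share one embedding
row. Within every window of N = 3 consecutive k-mers, each k-mer pair adds a
hashed context ("n-gram") feature. An entity with feature vectors
w₁…w_M is embedded as

    e = (1 / M^P) Σᵢ wᵢ ,  P = 0.5.

One cell with the event open is the positive; K cells lacking the event
(drawn from the same dataset and, in batch-aware mode, the same batch) are
negatives. Parameters minimize the cosine margin ranking loss

    Loss = (1/K) Σₖ max(0, margin − sim(LHS, RHS) + sim(LHS, c_nₖ))

by streaming SGD (per-row Adagrad, learning rate decaying linearly to zero),
updating only the sampled rows — memory is constant in the number of
examples. Defaults: d = 30 dimensions, 50 epochs, 20 examples per event per
epoch, K = 10, margin = 0.05.

TF activities are the z-scored cosine similarities between each cell and a
motif's consensus-sequence embedding. De novo motifs come from embedding all
canonical 10-mers (mean of their three constituent 8-mer rows), collecting
the 10-mers recurrently among the 50 nearest neighbors of ≥ 20% of a cell
group, clustering them by ungapped sequence overlap (tree cut 0.5) and
turning every cluster of more than three members into a PWM.

## Worked example

Everything below is self-contained: the built-in generator plants one
distinct 10-bp motif per cell type into the type-specific accessible events
of a small synthetic dataset.

```python
import numpy as np
from atacspace import (simulate_dataset, SimConfig, CellEmbeddingModel,
                       TrainingConfig, FeatureSpec)
from atacspace.benchmark import resolution_search
from sklearn.metrics import adjusted_rand_score

ds, truth = simulate_dataset(SimConfig(
    n_cells=120, n_types=3, n_events=300, event_len=300,
    genome_size=30000, n_batches=1, seed=1))

cfg = TrainingConfig(epochs=10, spec=FeatureSpec(bucket=200_000))
results = CellEmbeddingModel(ds, cfg).fit(seed=0)
print(results.summary())

graph = results.build_graphs(K=20)
resolution, labels = resolution_search(graph, target_k=3)
print("clusters:", len(np.unique(labels)),
      "ARI vs truth:", round(adjusted_rand_score(truth.cell_types, labels), 3))

motifs = [truth.planted_motifs[t] for t in sorted(truth.planted_motifs)]
tf = results.tf_activity_scores(motifs)
print(tf.scores.groupby(truth.cell_types).mean().round(2))
```

Output (fit time will vary):

```
Sequence-informed cell embedding
============================================
cells                 120
datasets              1 (synthetic)
events trained on     300
latent dimension d    30
k-mer length k        8
context window N      3
hash bucket           200000
sampled length L      150
epochs                10
examples per event    20
negatives per example 10
margin                0.05
batch-aware negatives False
seed                  0
first-epoch mean loss 0.087663
final-epoch mean loss 0.022491
skipped examples      0
fit time              10.4 s
clusters: 3 ARI vs truth: 1.0
       planted_type0  planted_type1  planted_type2
type0           1.30          -0.72          -0.38
type1          -0.63           1.34          -0.94
type2          -0.67          -0.62           1.32
```

The loss trace falls as the hinge constraints are satisfied; Louvain
clustering on the shared-nearest-neighbor graph recovers the three planted
types exactly (ARI 1.0); and each planted motif's mean TF activity z-score
is strongly positive precisely in its own cell type — the matrix above is
the method's core readout.

De novo discovery runs from the same object:

```python
found = results.discover_motifs(truth.cell_types)   # {group: [DeNovoMotif]}
```

A thin CLI wraps the same functions
(`atacspace simulate / train / score / cluster / denovo / bench`); run any
subcommand with `--help`.

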