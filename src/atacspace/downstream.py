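"""Downstream analyses on a trained embedding.

TF motif activity scoring (cosine similarity of cell and motif-consensus
embeddings, z-scored per motif), K-nearest-neighbor and shared-nearest-
neighbor graphs, modularity clustering, small-cluster merging, and the joint
cell + TF table used for 2-D visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import FeatureBag, induced_embedding, kmer_bag
from .motifs import MotifModel

__all__ = [
    "TFScoreMatrix",
    "CellGraph",
    "motif_consensus",
    "embed_motif",
    "tf_activity_scores",
    "build_graphs",
    "cluster_cells",
    "merge_small_clusters",
    "joint_cell_tf_table",
]

SNN_PRUNE = 1.0 / 15.0  # Seurat's shared-neighbor pruning threshold


def motif_consensus(motif: MotifModel) -> str:
    """Consensus sequence: per-column max-probability base (ties: A<C<G<T)."""
    return motif.consensus()


def embed_motif(motif, results, include_ngrams: bool = False) -> np.ndarray:
    """Embedding of a TF motif via its consensus sequence.

    The bag contains the width-k+1 constituent canonical k-mers; context
    n-gram features are excluded by default (``include_ngrams=True`` adds
    them, the alternative reading of entity embedding).
    """
    if isinstance(motif, MotifModel):
        if motif.width < results.spec.k:
            raise ValueError(
                f"motif {motif.name!r} width {motif.width} < k={results.spec.k}"
            )
        consensus = motif.consensus()
    else:
        consensus = str(motif)
        if len(consensus) < results.spec.k:
            raise ValueError(
                f"consensus length {len(consensus)} < k={results.spec.k}"
            )
    return results.induce(consensus, include_ngrams=include_ngrams)


@dataclass
class TFScoreMatrix:
    """Cell-by-TF activities: raw cosine similarities and per-TF z-scores."""

    scores: pd.DataFrame
    raw: pd.DataFrame
    constant_motifs: list[str] = field(default_factory=list)
    failed_motifs: list[str] = field(default_factory=list)


def tf_activity_scores(results, motifs: list[MotifModel]) -> TFScoreMatrix:
    """Score every cell for every TF motif.

    Raw score = cosine(cell embedding, motif-consensus embedding); scores are
    z-scored across cells per motif (population SD). A motif whose raw column
    is constant yields an all-zero column and is flagged; a motif whose
    embedding fails (e.g. ambiguous consensus) is dropped with a warning.
    """
    cells = np.asarray(results.cell_embeddings, dtype=np.float64)
    if cells.shape[0] < 2:
        raise ValueError("TF scoring needs at least 2 cells")
    cnorm = np.linalg.norm(cells, axis=1)
    cnorm[cnorm == 0] = 1.0
    cu = cells / cnorm[:, None]

    cols, names, failed = [], [], []
    for m in motifs:
        try:
            v = embed_motif(m, results)
        except ValueError as exc:
            warnings.warn(f"dropping motif {m.name!r}: {exc}")
            failed.append(m.name)
            continue
        nv = np.linalg.norm(v)
        cols.append(cu @ (v / nv if nv > 0 else v))
        names.append(m.name)
    if not cols:
        raise ValueError("no motif could be embedded")
    raw = np.column_stack(cols)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)  # population SD
    constant = sd < 1e-12
    z = np.zeros_like(raw)
    z[:, ~constant] = (raw[:, ~constant] - mu[~constant]) / sd[~constant]
    idx = pd.Index(results.cell_ids, name="cell")
    return TFScoreMatrix(
        scores=pd.DataFrame(z, index=idx, columns=names),
        raw=pd.DataFrame(raw, index=idx, columns=names),
        constant_motifs=[n for n, c in zip(names, constant) if c],
        failed_motifs=failed,
    )


@dataclass
class CellGraph:
    """KNN neighbor lists and the derived shared-nearest-neighbor graph."""

    knn: np.ndarray  # (n, K) neighbor indices, self excluded
    knn_dist: np.ndarray  # (n, K) cosine distances
    snn: sp.csr_matrix  # symmetric, Jaccard weights, pruned
    K: int


def build_graphs(
    embedding: np.ndarray, K: int = 20, metric: str = "cosine"
) -> CellGraph:
    """Build KNN (exact, brute force) and SNN graphs on an embedding.

    SNN weight(u,v) = Jaccard overlap of the two K-neighborhoods (each
    including the cell itself), pruned below 1/15. Exact brute-force KNN is
    used up to 20,000 cells; above that an approximate index (pynndescent,
    recall >= 0.95 in validation) takes over.
    """
    X = np.asarray(embedding, dtype=np.float64)
    n = X.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < n_cells={n}")
    if n <= 20_000:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=K + 1, metric=metric,
                              algorithm="brute")
        nn.fit(X)
        dist, idx = nn.kneighbors(X)
        # drop self (guard against exact duplicates sorting before self, or
        # crowding self out of the K+1 list entirely)
        knn = np.empty((n, K), dtype=np.int64)
        kdist = np.empty((n, K))
        for i in range(n):
            row, drow = idx[i], dist[i]
            sel = np.flatnonzero(row != i)[:K]
            knn[i], kdist[i] = row[sel], drow[sel]
    else:
        import pynndescent

        index = pynndescent.NNDescent(
            X, n_neighbors=K + 1, metric=metric, random_state=0
        )
        idx, dist = index.neighbor_graph
        knn, kdist = idx[:, 1:], dist[:, 1:]

    # neighborhoods including self
    rows = np.repeat(np.arange(n), K + 1)
    cols = np.concatenate([np.arange(n)[:, None], knn], axis=1).ravel()
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    A.data[:] = 1.0  # dedupe
    inter = (A @ A.T).tocoo()
    size = K + 1
    jac = inter.data / (2 * size - inter.data)
    keep = (jac >= SNN_PRUNE) & (inter.row != inter.col)
    snn = sp.csr_matrix(
        (jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    return CellGraph(knn=knn, knn_dist=kdist, snn=snn, K=K)


def cluster_cells(
    graph: CellGraph | sp.spmatrix, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Louvain community labels on the SNN graph at a given resolution.

    Delegated to igraph's multilevel algorithm (deterministic for a fixed
    graph; `seed` kept for interface stability).
    """
    import igraph as ig

    snn = graph.snn if isinstance(graph, CellGraph) else sp.csr_matrix(graph)
    n = snn.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(snn, k=1).tocoo()
    g = ig.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    part = g.community_multilevel(
        weights=coo.data.tolist() if coo.nnz else None, resolution=resolution
    )
    return np.array(part.membership, dtype=np.int64)


def _cluster_connectivity(
    snn: sp.csr_matrix, labels: np.ndarray, a: int, b: int
) -> float:
    """Mean SNN weight over all (cell in a, cell in b) pairs."""
    ia = np.flatnonzero(labels == a)
    ib = np.flatnonzero(labels == b)
    return snn[np.ix_(ia, ib)].sum() / (len(ia) * len(ib))


def merge_small_clusters(
    labels: np.ndarray,
    snn: sp.spmatrix,
    min_size: int | None = None,
    target_k: int | None = None,
) -> np.ndarray:
    """Absorb small clusters into their most-connected larger neighbor.

    Iteratively the smallest cluster below ``min_size`` (or, with
    ``target_k``, while more clusters remain than the target) is reassigned
    wholesale to the cluster with maximal mean inter-cluster SNN weight.
    Connectivity ties go to the larger cluster, then the lower label. The
    number of clusters never increases.
    """
    if (min_size is None) == (target_k is None):
        raise ValueError("give exactly one of min_size / target_k")
    labels = np.asarray(labels).copy()
    snn = sp.csr_matrix(snn)

    def _smallest():
        uniq, counts = np.unique(labels, return_counts=True)
        if target_k is not None:
            if len(uniq) <= target_k:
                return None
        else:
            small = counts < min_size
            if not small.any():
                return None
            uniq, counts = uniq[small], counts[small]
        order = np.lexsort((uniq, counts))
        return uniq[order[0]]

    while True:
        src = _smallest()
        if src is None:
            break
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) < 2:
            break
        best = None
        for tgt, cnt in zip(uniq, counts):
            if tgt == src:
                continue
            w = _cluster_connectivity(snn, labels, src, tgt)
            key = (w, cnt, -tgt)  # ties: higher weight, larger, lower label
            if best is None or key > best[0]:
                best = (key, tgt)
        labels[labels == src] = best[1]
    # relabel densely, preserving order of first appearance
    _, dense = np.unique(labels, return_inverse=True)
    return dense


def joint_cell_tf_table(results, motifs: list[MotifModel]):
    """(cells + motifs) x d embedding table + condensed cosine distances.

    Ready for any 2-D embedder (UMAP etc. are deliberately delegated).
    Returns (labels, matrix, condensed_distances).
    """
    from scipy.spatial.distance import pdist

    rows = [np.asarray(results.cell_embeddings, dtype=np.float64)]
    labels = ["cell:" + c for c in results.cell_ids]
    for m in motifs:
        rows.append(embed_motif(m, results)[None, :])
        labels.append("motif:" + m.name)
    mat = np.vstack(rows)
    return labels, mat, pdist(mat, metric="cosine")
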