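"""Embedding benchmarking: biological conservation, batch correction, bootstrap.

Biological conservation = mean of cell-type ASW (silhouette rescaled to
[0,1]), NMI, ARI (clipped to [0,1]) and homogeneity between a clustering and
the ground-truth cell types. Batch correction = mean of batch ASW
(1 - |silhouette| per cell type), graph connectivity, kBET acceptance and
batch NMI (1 - NMI(cluster, batch) per cell type). The overall score weights
them 0.6 / 0.4. Methods are compared by bootstrap: resampled cells (the same
indices for every method per replicate), percentile confidence intervals,
CI-inversion p-values and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2
from sklearn.metrics import (
    adjusted_rand_score,
    homogeneity_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)

from .downstream import CellGraph, build_graphs, cluster_cells, merge_small_clusters

__all__ = [
    "ScoreReport",
    "BootstrapResult",
    "bio_conservation",
    "batch_correction_scores",
    "overall_score",
    "resolution_search",
    "score_embedding",
    "bootstrap_compare",
    "percentile_ci",
    "ci_inversion_pvalue",
]

DEFAULT_RESOLUTIONS = np.round(np.arange(0.1, 3.01, 0.1), 2)


def bio_conservation(
    embedding: np.ndarray,
    cluster_labels: np.ndarray,
    cell_types: np.ndarray,
    metric: str = "euclidean",
) -> dict:
    """Cell-type conservation scores of an embedding + clustering.

    ASW = (mean silhouette of cell types in the embedding + 1) / 2;
    NMI/ARI/homogeneity compare the clustering with the cell types.
    """
    cell_types = np.asarray(cell_types)
    cluster_labels = np.asarray(cluster_labels)
    if len(np.unique(cell_types)) < 2:
        raise ValueError("silhouette undefined with a single cell type")
    asw = (silhouette_score(embedding, cell_types, metric=metric) + 1) / 2
    nmi = normalized_mutual_info_score(cell_types, cluster_labels)
    ari = float(np.clip(adjusted_rand_score(cell_types, cluster_labels), 0, 1))
    hom = homogeneity_score(cell_types, cluster_labels)
    out = {"asw": float(asw), "nmi": float(nmi), "ari": ari,
           "homogeneity": float(hom)}
    out["mean"] = float(np.mean(list(out.values())))
    return out


def _graph_connectivity(embedding, cell_types, K):
    """Per cell type, fraction of cells in the largest connected component of
    the type's KNN subgraph; averaged over types."""
    fracs = []
    for t in np.unique(cell_types):
        idx = np.flatnonzero(cell_types == t)
        nt = len(idx)
        if nt == 1:
            fracs.append(1.0)
            continue
        kt = min(K, nt - 1)
        from sklearn.neighbors import kneighbors_graph

        g = kneighbors_graph(
            embedding[idx], n_neighbors=kt, metric="euclidean", mode="connectivity"
        )
        ncomp, comp = connected_components(g, directed=False)
        fracs.append(np.bincount(comp).max() / nt)
    return float(np.mean(fracs))


def _kbet_acceptance(embedding, batches, K, max_tested=1000, alpha=0.05,
                     seed=0):
    """Fraction of tested neighborhoods whose batch composition passes a
    chi-squared goodness-of-fit against the global batch proportions."""
    n = len(batches)
    uniq, inv = np.unique(batches, return_inverse=True)
    props = np.bincount(inv) / n
    mean_batch = n / len(uniq)
    m = int(min(50, mean_batch // 2))
    if m < len(uniq) + 1:
        m = len(uniq) + 1  # need a minimally informative neighborhood
    rng = np.random.default_rng(seed)
    tested = (
        np.arange(n)
        if n <= max_tested
        else rng.choice(n, size=max_tested, replace=False)
    )
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=m, algorithm="brute").fit(embedding)
    _, idx = nn.kneighbors(embedding[tested])
    dof = len(uniq) - 1
    accept = 0
    for row in idx:
        obs = np.bincount(inv[row], minlength=len(uniq))
        expected = m * props
        stat = ((obs - expected) ** 2 / expected).sum()
        p = chi2.sf(stat, dof)
        accept += p >= alpha
    return accept / len(tested)


def batch_correction_scores(
    embedding: np.ndarray,
    batches: np.ndarray,
    cell_types: np.ndarray,
    cluster_labels: np.ndarray,
    K: int = 20,
    seed: int = 0,
) -> dict:
    """Batch-mixing scores of an embedding (all in [0,1], higher = better).

    Cell types present in a single batch are excluded from batch ASW, kBET
    and batch NMI with a warning.
    """
    batches = np.asarray(batches)
    cell_types = np.asarray(cell_types)
    cluster_labels = np.asarray(cluster_labels)
    if len(np.unique(batches)) < 2:
        raise ValueError("batch scores need at least 2 batches")

    multi_batch_types = []
    for t in np.unique(cell_types):
        idx = np.flatnonzero(cell_types == t)
        if len(np.unique(batches[idx])) >= 2:
            multi_batch_types.append(t)
        else:
            warnings.warn(
                f"cell type {t!r} present in one batch only; excluded from "
                "kBET / batch ASW / batch NMI"
            )

    asw_parts, nmi_parts, kbet_parts = [], [], []
    for t in multi_batch_types:
        idx = np.flatnonzero(cell_types == t)
        sil = silhouette_samples(embedding[idx], batches[idx])
        asw_parts.append(np.mean(1 - np.abs(sil)))
        nmi_parts.append(
            1 - normalized_mutual_info_score(cluster_labels[idx], batches[idx])
        )
        kbet_parts.append(
            _kbet_acceptance(embedding[idx], batches[idx], K, seed=seed)
        )
    if not multi_batch_types:
        raise ValueError("no cell type spans two batches; nothing to score")

    out = {
        "batch_asw": float(np.mean(asw_parts)),
        "graph_connectivity": _graph_connectivity(embedding, cell_types, K),
        "kbet_acceptance": float(np.mean(kbet_parts)),
        "batch_nmi": float(np.mean(nmi_parts)),
    }
    out["mean"] = float(np.mean(list(out.values())))
    return out


def overall_score(bio_mean: float, batch_mean: float) -> float:
    """Weighted overall score: 0.6 * biological + 0.4 * batch correction."""
    return 0.6 * bio_mean + 0.4 * batch_mean


def resolution_search(
    graph: CellGraph | sp.spmatrix,
    target_k: int,
    resolutions: np.ndarray = DEFAULT_RESOLUTIONS,
) -> tuple[float, np.ndarray]:
    """Find the clustering resolution yielding `target_k` clusters.

    The first (lowest) grid value giving exactly ``target_k`` clusters wins.
    If every candidate overshoots, the closest-above candidate is reduced by
    merging its smallest clusters into their most-connected neighbors; if
    all candidates undershoot, that is an error.
    """
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    snn = graph.snn if isinstance(graph, CellGraph) else sp.csr_matrix(graph)
    above = []  # (n_clusters, resolution, labels)
    for r in resolutions:
        labels = cluster_cells(snn, resolution=float(r))
        k = len(np.unique(labels))
        if k == target_k:
            return float(r), labels
        if k > target_k:
            above.append((k, float(r), labels))
    if not above:
        raise ValueError(
            f"no resolution in the grid produced >= {target_k} clusters; "
            "try a finer or higher grid"
        )
    above.sort(key=lambda x: (x[0], x[1]))
    k, r, labels = above[0]
    merged = merge_small_clusters(labels, snn, target_k=target_k)
    return r, merged


@dataclass
class ScoreReport:
    """Benchmark scores of one embedding."""

    bio: dict
    batch: dict | None
    overall: float
    metadata: dict = field(default_factory=dict)


def score_embedding(
    embedding: np.ndarray,
    cell_types: np.ndarray,
    batches: np.ndarray | None = None,
    K: int = 20,
    metric: str = "cosine",
    resolution: float | None = None,
    seed: int = 0,
) -> ScoreReport:
    """Cluster an embedding and compute its full benchmark report.

    When ``resolution`` is None it is searched so that the number of clusters
    matches the number of cell types. Without batch labels the overall score
    equals the biological-conservation mean.
    """
    cell_types = np.asarray(cell_types)
    graph = build_graphs(embedding, K=K, metric=metric)
    target_k = len(np.unique(cell_types))
    if resolution is None:
        resolution, labels = resolution_search(graph, target_k)
    else:
        labels = cluster_cells(graph, resolution=resolution)
    bio = bio_conservation(embedding, labels, cell_types)
    if batches is not None:
        batch = batch_correction_scores(
            embedding, batches, cell_types, labels, K=K, seed=seed
        )
        overall = overall_score(bio["mean"], batch["mean"])
    else:
        batch = None
        overall = bio["mean"]
    return ScoreReport(
        bio=bio, batch=batch, overall=overall,
        metadata={"K": K, "resolution": float(resolution),
                  "n_clusters": int(len(np.unique(labels)))},
    )


def percentile_ci(samples: np.ndarray, alpha: float) -> tuple[float, float]:
    """Percentile bootstrap CI: the alpha/2 and 1-alpha/2 sample quantiles."""
    lo, hi = np.quantile(samples, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def ci_inversion_pvalue(thetas: np.ndarray, theta0: float = 0.0) -> float:
    """Two-sided p-value by confidence-interval inversion.

    The smallest alpha in [1/B, 1] such that theta0 falls outside the
    1-alpha percentile CI of the bootstrap distribution.
    """
    thetas = np.asarray(thetas, dtype=np.float64)
    B = len(thetas)
    p = 2 * min(np.mean(thetas <= theta0), np.mean(thetas >= theta0))
    return float(np.clip(p, 1.0 / B, 1.0))


@dataclass
class BootstrapResult:
    """Bootstrap comparison of methods' benchmark scores."""

    B: int
    alpha: float
    scores: dict  # method -> (B,) bootstrap score distribution
    point: dict  # method -> full-data score
    cis: dict  # method -> (lo, hi)
    pvalues: dict  # (method_a, method_b) -> raw p
    pvalues_adjusted: dict  # (method_a, method_b) -> BH-adjusted p


def bootstrap_compare(
    embeddings: dict,
    cell_types: np.ndarray,
    batches: np.ndarray | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    K: int = 20,
    metrics: dict | None = None,
    seed: int = 0,
    statistic: str = "overall",
) -> BootstrapResult:
    """Compare methods' scores over B bootstrap resamples of the cells.

    The same resampled cell indices are applied to every method in each
    replicate; clustering is re-run per replicate at the resolution found
    once on the full data (per method). ``metrics`` maps method name to the
    neighbor metric used for its graph (default cosine). p-values come from
    CI inversion on the bootstrap distribution of pairwise score
    differences, Benjamini-Hochberg-adjusted across all pairs.
    """
    if B < 2 / alpha:
        raise ValueError(f"B={B} < 2/alpha={2 / alpha:.0f}: CI not estimable")
    cell_types = np.asarray(cell_types)
    n = len(cell_types)
    metrics = metrics or {}
    rng = np.random.default_rng(seed)

    def _score(name, emb, ct, bt, resolution):
        rep = score_embedding(
            emb, ct, bt, K=K, metric=metrics.get(name, "cosine"),
            resolution=resolution, seed=seed,
        )
        if statistic == "overall":
            return rep.overall
        if statistic == "bio":
            return rep.bio["mean"]
        if statistic == "batch":
            if rep.batch is None:
                raise ValueError("batch statistic requested without batches")
            return rep.batch["mean"]
        raise ValueError(f"unknown statistic {statistic!r}")

    # full-data pass fixes the per-method resolution
    resolutions, point = {}, {}
    for name, emb in embeddings.items():
        graph = build_graphs(emb, K=K, metric=metrics.get(name, "cosine"))
        r, _ = resolution_search(graph, len(np.unique(cell_types)))
        resolutions[name] = r
        point[name] = _score(name, emb, cell_types, batches, r)

    names = list(embeddings)
    scores = {name: np.empty(B) for name in names}
    for b in range(B):
        idx = rng.integers(0, n, size=n)  # shared across methods
        ct = cell_types[idx]
        bt = batches[idx] if batches is not None else None
        for name in names:
            try:
                scores[name][b] = _score(
                    name, np.asarray(embeddings[name])[idx], ct, bt,
                    resolutions[name],
                )
            except ValueError:
                # degenerate resample (e.g. a single cell type drawn)
                scores[name][b] = np.nan

    cis = {
        name: percentile_ci(s[np.isfinite(s)], alpha)
        for name, s in scores.items()
    }
    raw = {}
    for i, a in enumerate(names):
        for bname in names[i + 1 :]:
            theta = scores[a] - scores[bname]
            theta = theta[np.isfinite(theta)]
            raw[(a, bname)] = ci_inversion_pvalue(theta)
    if raw:
        from statsmodels.stats.multitest import multipletests

        keys = list(raw)
        _, adj, _, _ = multipletests([raw[k] for k in keys], method="fdr_bh")
        adjusted = {k: float(p) for k, p in zip(keys, adj)}
    else:
        adjusted = {}
    return BootstrapResult(
        B=B, alpha=alpha, scores=scores, point=point, cis=cis,
        pvalues=raw, pvalues_adjusted=adjusted,
    )
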