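"""De novo motif discovery from the trained latent space.

All canonical 10-mers are embedded as the plain average of their three
constituent canonical 8-mer rows (for a model trained with k=8; other k
generalize to (k+2)-mers). A bipartite K-nearest-neighbor relation between
cells and 10-mers (cosine distance, one vertex per {10-mer, reverse
complement} pair) associates 10-mers with groups of cells: a 10-mer belongs
to a group if it neighbors at least 20% of the group's cells. Associated
10-mers are clustered by an ungapped best-overlap sequence dissimilarity
(tree cut at 0.5); every cluster of size greater than three is star-aligned
into a PWM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .features import _tables, encode_bases
from .motifs import MotifModel

__all__ = [
    "TenmerTable",
    "DeNovoMotif",
    "embed_all_10mers",
    "group_associated_10mers",
    "kmer_dissimilarity_matrix",
    "cluster_10mers",
    "align_and_build_pwm",
    "discover_motifs",
]

_BASES = np.array(list("ACGT"))


def _decode(code: int, w: int) -> str:
    return "".join(_BASES[(code >> (2 * (w - 1 - j))) & 3] for j in range(w))


@dataclass
class TenmerTable:
    """Embeddings of all canonical (k+2)-mers (one row per strand pair)."""

    codes: np.ndarray  # canonical representative codes, sorted
    embeddings: np.ndarray  # len(codes) x d
    width: int

    def __len__(self) -> int:
        return len(self.codes)

    def string(self, i: int) -> str:
        return _decode(int(self.codes[i]), self.width)

    def strings(self, idx) -> list[str]:
        return [self.string(i) for i in np.asarray(idx)]


def embed_all_10mers(results, strict: bool = True) -> TenmerTable:
    """Embed every canonical 10-mer as the mean of its three 8-mer rows.

    No 1/M**P scaling is applied — a plain average of the constituent
    canonical k-mer embeddings. For models trained with k != 8 the table
    generalizes to (k+2)-mers; with ``strict=True`` that is an error.
    """
    k = results.spec.k
    if k != 8:
        if strict:
            raise ValueError(
                f"10-mer table expects k=8 (got k={k}); pass strict=False "
                f"to build the ({k}+2)-mer analogue"
            )
        warnings.warn(f"model has k={k}; building ({k + 2})-mer table")
    w = k + 2
    canon_w_table, rc_w = _tables(w)
    codes = np.arange(4**w, dtype=np.int64)
    reps = codes[codes <= rc_w]  # one vertex per strand pair
    canon_k = results.spec.canon_table()
    mask_k = (1 << (2 * k)) - 1
    r1 = canon_k[reps >> 4]
    r2 = canon_k[(reps >> 2) & mask_k]
    r3 = canon_k[reps & mask_k]
    feats = results.feature_embeddings
    emb = (feats[r1] + feats[r2] + feats[r3]) / 3.0
    return TenmerTable(codes=reps, embeddings=emb, width=w)


def group_associated_10mers(
    table: TenmerTable,
    cell_embeddings: np.ndarray,
    groups: np.ndarray,
    K: int = 50,
    freq: float = 0.20,
) -> dict:
    """10-mers recurrently near a group's cells in the latent space.

    For each cell, its K nearest 10-mers by cosine distance are found
    (bipartite neighbors). A 10-mer joins group g's set iff it is a neighbor
    of at least ceil(freq * |g|) of g's cells. Returns
    {group label: sorted array of table row indices}.
    """
    cells = np.asarray(cell_embeddings, dtype=np.float64)
    T = np.asarray(table.embeddings, dtype=np.float64)
    tn = np.linalg.norm(T, axis=1)
    tn[tn == 0] = 1.0
    Tu = (T / tn[:, None]).T  # d x n_10mers
    cn = np.linalg.norm(cells, axis=1)
    cn[cn == 0] = 1.0
    Cu = cells / cn[:, None]

    n = cells.shape[0]
    nbrs = np.empty((n, K), dtype=np.int64)
    chunk = 256
    for i0 in range(0, n, chunk):
        sims = Cu[i0 : i0 + chunk] @ Tu
        part = np.argpartition(-sims, K - 1, axis=1)[:, :K]
        nbrs[i0 : i0 + chunk] = part

    groups = np.asarray(groups)
    out = {}
    for g in _unique_in_order(groups):
        members = np.flatnonzero(groups == g)
        if len(members) == 0:
            warnings.warn(f"group {g!r} has no cells; skipped")
            continue
        thresh = math.ceil(freq * len(members))
        counts = np.bincount(nbrs[members].ravel(), minlength=len(table))
        out[g] = np.flatnonzero(counts >= max(thresh, 1))
    return out


def _unique_in_order(arr):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for v in arr:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _best_overlap(a: np.ndarray, bs: np.ndarray) -> tuple[int, int, int]:
    """Best ungapped alignment of b (both strands) against a.

    Returns (matches, offset, strand) where b's position j aligns to a's
    position j + offset, strand in {+1, -1} (reverse complement). Ties keep
    the first candidate scanned (offset ascending, forward strand first).
    """
    w = len(a)
    b_rc = 3 - bs[::-1]
    best = (-1, 0, 1)
    for off in range(-(w - 1), w):
        lo_a, hi_a = max(0, off), min(w, w + off)
        seg_a = a[lo_a:hi_a]
        for strand, b in ((1, bs), (-1, b_rc)):
            seg_b = b[lo_a - off : hi_a - off]
            m = int((seg_a == seg_b).sum())
            if m > best[0]:
                best = (m, off, strand)
    return best


def kmer_dissimilarity_matrix(strings: list[str]) -> np.ndarray:
    """Pairwise 1 - (best ungapped overlap matches over offsets and strands)/w.

    Strand-aware: a sequence and its reverse complement are at distance 0.
    """
    arrs = [encode_bases(s).astype(np.int8) for s in strings]
    w = len(arrs[0])
    if any(len(a) != w for a in arrs):
        raise ValueError("all sequences must have equal length")
    A = np.stack(arrs)
    Arc = 3 - A[:, ::-1]
    n = len(strings)
    best = np.zeros((n, n), dtype=np.int64)
    for off in range(-(w - 1), w):
        lo, hi = max(0, off), min(w, w + off)
        seg = A[:, lo:hi]
        for B in (A, Arc):
            segB = B[:, lo - off : hi - off]
            m = (seg[:, None, :] == segB[None, :, :]).sum(axis=2)
            np.maximum(best, m, out=best)
    D = 1.0 - best / w
    np.fill_diagonal(D, 0.0)
    return D


def cluster_10mers(strings: list[str], cut: float = 0.5) -> np.ndarray:
    """Hierarchical clustering of equal-length k-mers, tree cut at `cut`.

    Average linkage on the ungapped best-overlap dissimilarity. A singleton
    input is one cluster. Returns 0-based cluster labels.
    """
    if len(strings) == 0:
        raise ValueError("empty 10-mer set")
    if len(strings) == 1:
        return np.zeros(1, dtype=np.int64)
    D = kmer_dissimilarity_matrix(strings)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=cut, criterion="distance").astype(np.int64) - 1


@dataclass
class DeNovoMotif:
    """A discovered motif: PWM, member 10-mers, latent embedding, source."""

    motif: MotifModel
    member_10mers: list[str]
    embedding: np.ndarray
    source_cell_group: object

    @property
    def pwm(self) -> np.ndarray:
        return self.motif.pwm


def align_and_build_pwm(
    strings: list[str],
    name: str = "denovo",
    pseudocount: float = 0.01,
) -> MotifModel:
    """Star-align a cluster of equal-length k-mers and derive a PWM.

    The anchor is the member minimizing total dissimilarity to the rest;
    every other member is placed at its best ungapped offset/strand against
    the anchor. PWM columns cover positions hit by at least half the
    members; base frequencies get a 0.01 pseudocount per base.
    """
    m = len(strings)
    if m <= 3:
        raise ValueError(
            f"cluster of size {m} <= 3 is discarded (no motif emitted)"
        )
    arrs = [encode_bases(s).astype(np.int8) for s in strings]
    w = len(arrs[0])
    D = kmer_dissimilarity_matrix(strings)
    anchor = int(np.argmin(D.sum(axis=1)))
    a = arrs[anchor]

    placements = []  # (offset, oriented bases)
    for i, b in enumerate(arrs):
        if i == anchor:
            placements.append((0, b))
            continue
        _, off, strand = _best_overlap(a, b)
        placements.append((off, b if strand == 1 else 3 - b[::-1]))

    offs = np.array([p[0] for p in placements])
    lo, hi = int(offs.min()), int(offs.max()) + w
    width = hi - lo
    counts = np.zeros((4, width))
    cover = np.zeros(width, dtype=np.int64)
    for off, b in placements:
        for j in range(w):
            col = off - lo + j
            counts[b[j], col] += 1
            cover[col] += 1
    keep = cover * 2 >= m  # columns covered by at least half the members
    counts = counts[:, keep] + pseudocount
    return MotifModel(name, counts / counts.sum(axis=0), source="denovo")


def discover_motifs(
    results,
    groups: np.ndarray,
    K: int = 50,
    freq: float = 0.20,
    cut: float = 0.5,
    strict: bool = True,
) -> dict:
    """Full de novo pipeline: per cell group, emit clustered 10-mer motifs.

    Deterministic given a trained model (no randomness in this module).
    Returns {group label: [DeNovoMotif, ...]}.
    """
    table = embed_all_10mers(results, strict=strict)
    assoc = group_associated_10mers(
        table, results.cell_embeddings, groups, K=K, freq=freq
    )
    out: dict = {}
    for g, idx in assoc.items():
        motifs = []
        if len(idx) == 0:
            out[g] = motifs
            continue
        strings = table.strings(idx)
        labels = cluster_10mers(strings, cut=cut)
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) <= 3:
                continue
            member_strings = [strings[i] for i in members]
            pwm = align_and_build_pwm(
                member_strings, name=f"{g}_denovo{len(motifs)}"
            )
            emb = table.embeddings[idx[members]].mean(axis=0)
            motifs.append(
                DeNovoMotif(
                    motif=pwm,
                    member_10mers=member_strings,
                    embedding=emb,
                    source_cell_group=g,
                )
            )
        out[g] = motifs
    return out
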