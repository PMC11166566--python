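"""Model/Results objects for the sequence-informed cell embedding.

:class:`CellEmbeddingModel` holds one or more scATAC-seq datasets (binary
cell-by-event matrices plus event DNA sequences) and a
:class:`TrainingConfig`. Its :meth:`~CellEmbeddingModel.fit` runs the
StarSpace-style streaming optimization — sampled event subsequences as
bags of canonical k-mers and context pairs, K-negative sampling over cells
lacking the event, cosine margin ranking loss — and returns a
:class:`CellEmbeddingResults` carrying the trained cell and feature
embeddings, the loss trace and diagnostics. Downstream analyses (TF activity
scores, neighbor graphs, clustering, de novo motifs) hang off the Results
object.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .features import (
    FeatureBag,
    FeatureSpec,
    induced_embedding,
    sequence_features,
)

__all__ = [
    "TrainingConfig",
    "Dataset",
    "DatasetCollection",
    "CellEmbeddingModel",
    "CellEmbeddingResults",
    "margin_ranking_loss",
    "select_variable_events",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the embedding optimization.

    Defaults follow the published tool: a d=30 latent space trained for 50
    epochs on 20 examples per event per epoch, sampling L=150 bp
    subsequences featurized with k=8 canonical k-mers and N=3 context
    windows. The similarity is cosine; the entity normalization exponent P
    lives on :class:`FeatureSpec`.
    """

    d: int = 30
    L: int = 150
    epochs: int = 50
    examples_per_event: int = 20
    K_neg: int = 10
    margin: float = 0.05
    lr0: float = 0.01
    similarity: str = "cosine"
    batch_aware: bool = False
    adagrad: bool = True
    seed: int = 0
    threads: int = 1
    spec: FeatureSpec = field(default_factory=FeatureSpec)

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"d must be >= 2, got {self.d}")
        if self.L < self.spec.k:
            raise ValueError(f"L={self.L} < k={self.spec.k}")
        if self.K_neg < 1:
            raise ValueError(f"K_neg must be >= 1, got {self.K_neg}")
        if self.margin <= 0:
            raise ValueError(f"margin must be > 0, got {self.margin}")
        if self.examples_per_event < 1:
            raise ValueError("examples_per_event must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.similarity != "cosine":
            raise ValueError("only cosine similarity is supported")

    def snapshot(self) -> dict:
        return {
            "d": self.d, "L": self.L, "epochs": self.epochs,
            "examples_per_event": self.examples_per_event,
            "K_neg": self.K_neg, "margin": self.margin, "lr0": self.lr0,
            "similarity": self.similarity, "batch_aware": self.batch_aware,
            "adagrad": self.adagrad,
            "seed": self.seed, "threads": self.threads,
            "k": self.spec.k, "N": self.spec.N, "bucket": self.spec.bucket,
            "P": self.spec.P,
        }


@dataclass
class Dataset:
    """One dataset: binary cells x events matrix, event sequences, batches."""

    matrix: sp.csr_matrix
    cell_ids: list[str]
    event_names: list[str]
    sequences: list[str]
    batch: np.ndarray | None = None
    dataset_id: str = "dataset0"

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.matrix.data = (self.matrix.data > 0).astype(np.int8)
        self.matrix.eliminate_zeros()
        n_cells, n_events = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.event_names) != n_events:
            raise ValueError("event_names length does not match matrix columns")
        if len(self.sequences) != n_events:
            raise ValueError("one sequence per event is required")
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if len(self.batch) != n_cells:
                raise ValueError("batch labels length does not match cells")

    @classmethod
    def from_cell_event_matrix(cls, cem, sequences: dict[str, str],
                               dataset_id: str | None = None) -> "Dataset":
        """Build from an io.CellEventMatrix and a name -> sequence map."""
        return cls(
            matrix=cem.matrix,
            cell_ids=list(cem.cell_ids),
            event_names=list(cem.event_names),
            sequences=[sequences[n] for n in cem.event_names],
            batch=cem.batch,
            dataset_id=dataset_id or cem.dataset_id,
        )


class DatasetCollection:
    """One or more datasets co-embedded into the same latent space."""

    def __init__(self, datasets: list[Dataset]):
        if not datasets:
            raise ValueError("need at least one dataset")
        ids = [d.dataset_id for d in datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_ids must be unique")
        self.datasets = list(datasets)

    @property
    def n_cells(self) -> int:
        return sum(d.matrix.shape[0] for d in self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)


def margin_ranking_loss(
    lhs: np.ndarray,
    pos: np.ndarray,
    negs: np.ndarray,
    margin: float,
) -> tuple[float, np.ndarray]:
    """Hinge ranking loss (1/K) sum_k max(0, margin - cos(l,p) + cos(l,n_k)).

    Returns the loss and the per-negative hinge values (used for selective
    updates: a negative with zero hinge is not touched). Cosine with a
    zero-norm vector is defined as 0.
    """
    negs = np.atleast_2d(np.asarray(negs, dtype=np.float64))
    lhs = np.asarray(lhs, dtype=np.float64)
    pos = np.asarray(pos, dtype=np.float64)

    def _cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(a @ b / (na * nb))

    cos_p = _cos(lhs, pos)
    hinges = np.array(
        [max(0.0, margin - cos_p + _cos(lhs, n)) for n in negs]
    )
    return float(hinges.mean()), hinges


def select_variable_events(
    matrix: sp.spmatrix, n_top: int, n_components: int = 30, seed: int = 0
) -> np.ndarray:
    """Rank events by informativeness and return the top `n_top` indices.

    TF-IDF transform of the binary matrix, truncated SVD, then events ranked
    by their loading variance across the top components excluding the first
    (which tracks sequencing depth). A simplified variable-feature selector;
    iterative LSI pipelines are deliberately out of scope.
    """
    from sklearn.decomposition import TruncatedSVD

    X = sp.csr_matrix(matrix, dtype=np.float64)
    n_cells, n_events = X.shape
    if n_top > n_events:
        import warnings

        warnings.warn(
            f"n_top={n_top} > {n_events} events; returning all events"
        )
        n_top = n_events
    rowsum = np.asarray(X.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1
    colsum = np.asarray(X.sum(axis=0)).ravel()
    idf = np.log1p(n_cells / np.maximum(colsum, 1))
    tf = sp.diags(1.0 / rowsum) @ X
    tfidf = tf @ sp.diags(idf)
    k = min(n_components, min(n_cells, n_events) - 1)
    svd = TruncatedSVD(n_components=k, random_state=seed)
    svd.fit(tfidf)
    loadings = svd.components_ * svd.singular_values_[:, None]
    score = loadings[1:].var(axis=0)  # drop the depth-correlated component
    order = np.argsort(-score, kind="stable")
    return order[:n_top]


class CellEmbeddingModel:
    """Joint cell / k-mer embedding model for one or more scATAC datasets.

    Parameters
    ----------
    data : Dataset, list of Dataset, or DatasetCollection
    config : TrainingConfig, optional

    Events unusable for contrastive training (accessible in no cell or in
    every cell, or with a sequence shorter than k) are dropped up front; the
    counts are recorded in ``dropped_events``.
    """

    def __init__(self, data, config: TrainingConfig | None = None):
        if isinstance(data, Dataset):
            data = DatasetCollection([data])
        elif isinstance(data, (list, tuple)):
            data = DatasetCollection(list(data))
        if not isinstance(data, DatasetCollection):
            raise TypeError("data must be Dataset(s) or a DatasetCollection")
        self.config = config or TrainingConfig()
        k = self.config.spec.k

        self.datasets: list[Dataset] = []
        self.dropped_events: dict[str, int] = {}
        for ds in data:
            csc = sp.csc_matrix(ds.matrix)
            colsum = np.asarray(csc.sum(axis=0)).ravel()
            n_cells = csc.shape[0]
            seq_ok = np.array([len(s) >= k for s in ds.sequences])
            keep = (colsum > 0) & (colsum < n_cells) & seq_ok
            self.dropped_events[ds.dataset_id] = int((~keep).sum())
            if keep.sum() == 0:
                raise ValueError(
                    f"dataset {ds.dataset_id!r} has 0 usable events "
                    "(every event all-zero, all-one, or too short)"
                )
            kept = np.flatnonzero(keep)
            # canonical strand orientation (lexicographic min of the two
            # strands): featurization is strand-invariant by construction,
            # and orienting the stored sequence makes subsequence sampling —
            # hence the whole training trajectory — exactly invariant to the
            # strand events were written in
            from .features import reverse_complement

            seqs = []
            for i in kept:
                s = ds.sequences[i].upper()
                seqs.append(min(s, reverse_complement(s)))
            self.datasets.append(
                Dataset(
                    matrix=csc[:, kept].tocsr(),
                    cell_ids=ds.cell_ids,
                    event_names=[ds.event_names[i] for i in kept],
                    sequences=seqs,
                    batch=ds.batch,
                    dataset_id=ds.dataset_id,
                )
            )
        if self.config.batch_aware and not any(
            ds.batch is not None for ds in self.datasets
        ):
            raise ValueError("batch_aware=True but no dataset has batch labels")

    @classmethod
    def from_files(
        cls,
        mtx_path,
        cells_path,
        events_path,
        genome_path=None,
        sequences_path=None,
        batch_path=None,
        config: TrainingConfig | None = None,
        dataset_id: str = "dataset0",
    ) -> "CellEmbeddingModel":
        """Construct from an MTX triplet plus a genome FASTA or sequence file."""
        from . import io as _io

        cem = _io.read_cell_event_matrix(
            mtx_path, cells_path, events_path, batch_path, dataset_id
        )
        if sequences_path is not None:
            seqs = _io.read_event_sequences(sequences_path)
        elif genome_path is not None:
            if cem.events is None:
                raise ValueError(
                    "events sidecar is not BED; genome extraction needs "
                    "intervals — provide sequences_path instead"
                )
            seqs = _io.extract_event_sequences(cem.events, genome_path)
        else:
            raise ValueError("provide genome_path or sequences_path")
        return cls(Dataset.from_cell_event_matrix(cem, seqs), config)

    # -- training ----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "CellEmbeddingResults":
        """Train the embedding; bit-reproducible for a fixed seed."""
        from ._train import train_kernel

        cfg = self.config
        if seed is None:
            seed = cfg.seed
        spec = cfg.spec
        rng = np.random.default_rng(seed)

        n_cells = sum(ds.matrix.shape[0] for ds in self.datasets)
        n_rows = spec.n_feature_rows
        # Asymmetric init scales. Cells accumulate orders of magnitude more
        # updates than any single feature row, so they start near zero: a
        # 1/d-scale random start would dominate their trained displacement
        # and blur within-cluster geometry. Feature rows keep the 1/d scale:
        # the residual random component acts as a noise floor that keeps
        # rarely-updated (uninformative) k-mers away from any cell's
        # neighborhood, while recurrent k-mers earn displacements well above
        # it.
        cell_emb = rng.uniform(-1e-3, 1e-3, (n_cells, cfg.d)).astype(
            np.float32
        )
        bound = 1.0 / cfg.d
        feat_emb = rng.uniform(-bound, bound, (n_rows, cfg.d)).astype(
            np.float32
        )

        # global cell numbering: datasets concatenated in order
        cell_ids: list[str] = []
        cell_dataset = np.empty(n_cells, dtype=np.int32)
        batch_all: list = []
        have_batch = any(ds.batch is not None for ds in self.datasets)
        offset = 0
        seq_chunks: list[np.ndarray] = []
        seq_lens: list[int] = []
        pos_lists: list[np.ndarray] = []
        event_dataset: list[int] = []
        from .features import encode_bases

        for di, ds in enumerate(self.datasets):
            nc = ds.matrix.shape[0]
            cell_ids.extend(ds.cell_ids)
            cell_dataset[offset : offset + nc] = di
            if have_batch:
                batch_all.extend(
                    ds.batch if ds.batch is not None else ["__none__"] * nc
                )
            csc = sp.csc_matrix(ds.matrix)
            for e in range(csc.shape[1]):
                cells = csc.indices[csc.indptr[e] : csc.indptr[e + 1]]
                pos_lists.append(np.sort(cells.astype(np.int32)) + offset)
                event_dataset.append(di)
                seq = ds.sequences[e]
                seq_chunks.append(encode_bases(seq))
                seq_lens.append(len(seq))
            offset += nc

        n_events = len(seq_lens)
        seq_codes = np.concatenate(seq_chunks)
        seq_off = np.zeros(n_events + 1, dtype=np.int64)
        seq_off[1:] = np.cumsum(seq_lens)
        pos_indptr = np.zeros(n_events + 1, dtype=np.int64)
        pos_indptr[1:] = np.cumsum([len(p) for p in pos_lists])
        pos_cells = (
            np.concatenate(pos_lists).astype(np.int32)
            if pos_lists
            else np.empty(0, dtype=np.int32)
        )

        # negative-sampling pools: per dataset, or per (dataset, batch)
        if cfg.batch_aware and have_batch:
            keys = [
                (int(cell_dataset[i]), str(batch_all[i]))
                for i in range(n_cells)
            ]
        else:
            keys = [(int(cell_dataset[i]), "") for i in range(n_cells)]
        uniq = sorted(set(keys))
        key_id = {kv: i for i, kv in enumerate(uniq)}
        group_of_cell = np.array([key_id[kv] for kv in keys], dtype=np.int32)
        pools: list[list[int]] = [[] for _ in uniq]
        for i, g in enumerate(group_of_cell):
            pools[g].append(i)
        pool_indptr = np.zeros(len(uniq) + 1, dtype=np.int64)
        pool_indptr[1:] = np.cumsum([len(p) for p in pools])
        pool_cells = np.array(
            [c for p in pools for c in p], dtype=np.int32
        )

        t0 = time.time()
        if cfg.epochs > 0:
            kernel_seed = int(rng.integers(0, 2**31 - 1))
            epoch_loss, epoch_skipped, zero_flags = train_kernel(
                cell_emb, feat_emb,
                spec.canon_table(), spec.rc_table(),
                seq_codes, seq_off,
                pos_indptr, pos_cells,
                group_of_cell, pool_indptr, pool_cells,
                spec.k, spec.N, max(spec.bucket, 1), spec.n_kmer_rows,
                cfg.L, cfg.epochs, cfg.examples_per_event, cfg.K_neg,
                cfg.margin, cfg.lr0, kernel_seed, cfg.adagrad,
            )
        else:
            epoch_loss = np.zeros(0)
            epoch_skipped = np.zeros(0, dtype=np.int64)
            zero_flags = 0
        if not (np.isfinite(cell_emb).all() and np.isfinite(feat_emb).all()):
            raise FloatingPointError(
                "non-finite values in trained embeddings; lower lr0"
            )

        return CellEmbeddingResults(
            cell_embeddings=cell_emb,
            feature_embeddings=feat_emb,
            cell_ids=cell_ids,
            spec=spec,
            config=replace(cfg, seed=seed),
            dataset_ids=[ds.dataset_id for ds in self.datasets],
            cell_dataset=cell_dataset,
            batch=(np.array(batch_all, dtype=object) if have_batch else None),
            loss_trace=np.asarray(epoch_loss),
            skipped_examples=np.asarray(epoch_skipped),
            zero_norm_flags=int(zero_flags),
            n_events=n_events,
            fit_seconds=time.time() - t0,
        )


@dataclass
class CellEmbeddingResults:
    """Trained co-embedding of cells and sequence features.

    ``cell_embeddings`` is cells x d (rows aligned with ``cell_ids``);
    ``feature_embeddings`` stacks the canonical k-mer rows first, then the
    n-gram hash bucket.
    """

    cell_embeddings: np.ndarray
    feature_embeddings: np.ndarray
    cell_ids: list[str]
    spec: FeatureSpec
    config: TrainingConfig
    dataset_ids: list[str] = field(default_factory=lambda: ["dataset0"])
    cell_dataset: np.ndarray | None = None
    batch: np.ndarray | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    skipped_examples: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64)
    )
    zero_norm_flags: int = 0
    n_events: int = 0
    fit_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.cell_embeddings = np.asarray(self.cell_embeddings)
        self.feature_embeddings = np.asarray(self.feature_embeddings)
        if self.cell_embeddings.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids must align 1:1 with embedding rows")
        if not np.isfinite(self.cell_embeddings).all():
            raise ValueError("non-finite cell embeddings")
        if self.cell_dataset is None:
            self.cell_dataset = np.zeros(
                self.cell_embeddings.shape[0], dtype=np.int32
            )

    @property
    def n_cells(self) -> int:
        return self.cell_embeddings.shape[0]

    @property
    def d(self) -> int:
        return self.cell_embeddings.shape[1]

    @property
    def config_snapshot(self) -> dict:
        return self.config.snapshot()

    # -- sequence / motif embedding ---------------------------------------

    def induce(self, sequence: str, include_ngrams: bool = True) -> np.ndarray:
        """Embedding of an arbitrary DNA sequence via its feature bag."""
        if include_ngrams and self.spec.N > 1:
            bag = sequence_features(sequence, self.spec)
        else:
            from .features import kmer_bag

            bag = FeatureBag(kmer_indices=kmer_bag(sequence, self.spec))
        return induced_embedding(bag, self.feature_embeddings, self.spec.P)

    def embed_motif(self, motif, include_ngrams: bool = False) -> np.ndarray:
        from .downstream import embed_motif

        return embed_motif(motif, self, include_ngrams=include_ngrams)

    def tf_activity_scores(self, motifs):
        from .downstream import tf_activity_scores

        return tf_activity_scores(self, motifs)

    def build_graphs(self, K: int = 20, metric: str = "cosine"):
        from .downstream import build_graphs

        return build_graphs(self.cell_embeddings, K=K, metric=metric)

    def joint_cell_tf_table(self, motifs):
        from .downstream import joint_cell_tf_table

        return joint_cell_tf_table(self, motifs)

    def discover_motifs(self, groups, **kwargs):
        """De novo motif discovery from cell-associated 10-mers per group."""
        from .denovo import discover_motifs

        return discover_motifs(self, groups, **kwargs)

    def save(self, path) -> None:
        from .io import save_model

        save_model(self, path)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Sequence-informed cell embedding",
            "=" * 44,
            f"cells                 {self.n_cells}",
            f"datasets              {len(self.dataset_ids)}"
            f" ({', '.join(self.dataset_ids)})",
            f"events trained on     {self.n_events}",
            f"latent dimension d    {self.d}",
            f"k-mer length k        {self.spec.k}",
            f"context window N      {self.spec.N}",
            f"hash bucket           {self.spec.bucket}",
            f"sampled length L      {cfg.L}",
            f"epochs                {cfg.epochs}",
            f"examples per event    {cfg.examples_per_event}",
            f"negatives per example {cfg.K_neg}",
            f"margin                {cfg.margin}",
            f"batch-aware negatives {cfg.batch_aware}",
            f"seed                  {cfg.seed}",
        ]
        if self.loss_trace.size:
            lines += [
                f"first-epoch mean loss {self.loss_trace[0]:.6f}",
                f"final-epoch mean loss {self.loss_trace[-1]:.6f}",
                f"skipped examples      {int(self.skipped_examples.sum())}",
                f"fit time              {self.fit_seconds:.1f} s",
            ]
        return "\n".join(lines)
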