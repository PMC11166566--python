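"""Readers and writers for the standard formats the tool touches.

Coordinates are 0-based half-open (BED convention) throughout. Accessibility
matrices are binarized on read (any count > 0 becomes 1). Trained models are
serialized as a labelled TSV matrix plus a JSON config sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pyfaidx import Fasta

from .features import FeatureSpec

__all__ = [
    "EventSet",
    "CellEventMatrix",
    "read_bed",
    "read_cell_event_matrix",
    "extract_event_sequences",
    "read_event_sequences",
    "save_model",
    "load_model",
    "write_dataset",
]


@dataclass
class EventSet:
    """Genomic intervals of accessible events (peaks or tiles)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    names: list[str]
    dataset_id: str = "dataset0"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if not (self.starts < self.ends).all():
            bad = int(np.argmax(self.starts >= self.ends))
            raise ValueError(
                f"event {self.names[bad]!r}: start {self.starts[bad]} >= end "
                f"{self.ends[bad]} (coordinates are 0-based half-open)"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("event names are not unique within the dataset")

    def __len__(self) -> int:
        return len(self.names)


def read_bed(path: str | Path, dataset_id: str = "dataset0") -> EventSet:
    """Read a BED3+ file into an EventSet (name column used when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    chroms = df[0].to_numpy(dtype=object)
    starts = df[1].to_numpy(dtype=np.int64)
    ends = df[2].to_numpy(dtype=np.int64)
    if df.shape[1] >= 4:
        names = df[3].astype(str).tolist()
    else:
        names = [f"{c}:{s}-{e}" for c, s, e in zip(chroms, starts, ends)]
    return EventSet(chroms, starts, ends, names, dataset_id)


@dataclass
class CellEventMatrix:
    """Sparse binary cells x events accessibility matrix with sidecars."""

    matrix: sp.csr_matrix
    cell_ids: list[str]
    event_names: list[str]
    events: EventSet | None = None
    batch: np.ndarray | None = None
    dataset_id: str = "dataset0"
    degenerate_events: np.ndarray = field(default=None)  # all-0 or all-1 cols

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix)
        m.data = (m.data > 0).astype(np.int8)
        m.eliminate_zeros()
        self.matrix = m
        n_cells, n_events = m.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} cell rows but {len(self.cell_ids)} barcodes"
            )
        if n_events != len(self.event_names):
            raise ValueError(
                f"matrix has {n_events} event columns but "
                f"{len(self.event_names)} event names"
            )
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if len(self.batch) != n_cells:
                raise ValueError(
                    f"{len(self.batch)} batch labels for {n_cells} cells"
                )
        col = np.asarray(m.sum(axis=0)).ravel()
        self.degenerate_events = (col == 0) | (col == n_cells)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_events(self) -> int:
        return self.matrix.shape[1]


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_cell_event_matrix(
    mtx_path: str | Path,
    cells_path: str | Path,
    events_path: str | Path,
    batch_path: str | Path | None = None,
    dataset_id: str = "dataset0",
) -> CellEventMatrix:
    """Read a Matrix Market triplet (matrix + barcode and event sidecars).

    Counts are binarized. Orientation (cells x events vs events x cells) is
    auto-detected from the sidecar lengths; a shape matching neither raises an
    error naming the offending sidecar.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    cell_ids = [ln.split("\t")[0] for ln in _read_lines(cells_path)]
    event_lines = _read_lines(events_path)
    events: EventSet | None = None
    first = event_lines[0].split("\t")
    if len(first) >= 3 and first[1].isdigit() and first[2].isdigit():
        events = read_bed(events_path, dataset_id)
        event_names = events.names
    else:
        event_names = [ln.split("\t")[0] for ln in event_lines]

    nr, nc = mat.shape
    if nr == len(cell_ids) and nc == len(event_names):
        pass
    elif nr == len(event_names) and nc == len(cell_ids):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {cells_path} "
            f"({len(cell_ids)} barcodes) nor {events_path} "
            f"({len(event_names)} events) in either orientation"
        )

    batch = None
    if batch_path is not None:
        batch = np.array(
            [ln.split("\t")[-1] for ln in _read_lines(batch_path)], dtype=object
        )
        if len(batch) != len(cell_ids):
            raise ValueError(
                f"{batch_path}: {len(batch)} batch labels for "
                f"{len(cell_ids)} cells"
            )
    return CellEventMatrix(
        mat, cell_ids, event_names, events=events, batch=batch,
        dataset_id=dataset_id,
    )


def extract_event_sequences(
    events: EventSet, genome_path: str | Path
) -> dict[str, str]:
    """Extract event sequences from an indexed FASTA genome, uppercased.

    Soft-masked (lowercase) bases are uppercased and used; intervals running
    past the chromosome end or naming a missing chromosome are errors.
    """
    fasta = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    out: dict[str, str] = {}
    for chrom, start, end, name in zip(
        events.chroms, events.starts, events.ends, events.names
    ):
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} not found in {genome_path}")
        clen = len(fasta[chrom])
        if end > clen:
            raise ValueError(
                f"event {name!r} [{start},{end}) extends past {chrom} "
                f"length {clen}"
            )
        out[name] = str(fasta[chrom][int(start):int(end)])
    return out


def read_event_sequences(path: str | Path) -> dict[str, str]:
    """Read pre-extracted event sequences from FASTA or 2-column TSV."""
    lines = _read_lines(path)
    out: dict[str, str] = {}
    if lines[0].startswith(">"):
        name, chunks = None, []
        for ln in lines:
            if ln.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks).upper()
                name, chunks = ln[1:].split()[0], []
            else:
                chunks.append(ln.strip())
        out[name] = "".join(chunks).upper()
    else:
        for ln in lines:
            name, seq = ln.split("\t")[:2]
            out[name] = seq.upper()
    return out


# ---------------------------------------------------------------------------
# model serialization


def save_model(results, path: str | Path) -> None:
    """Serialize a trained embedding to `<path>` (TSV) + `<path>.json`.

    Rows are labelled ``cell:<id>``, ``kmer:<canonical seq>`` or
    ``bucket:<i>``. Values are printed with 9 significant digits, which
    round-trips float32 exactly.
    """
    from .features import n_canonical_kmers

    path = Path(path)
    spec: FeatureSpec = results.spec
    cells = np.asarray(results.cell_embeddings, dtype=np.float32)
    feats = np.asarray(results.feature_embeddings, dtype=np.float32)
    if cells.shape[0] == 0:
        raise ValueError("refusing to save a model with 0 cells")
    kmers = _canonical_kmer_strings(spec.k)
    assert feats.shape[0] == len(kmers) + (spec.bucket if spec.N > 1 else 0)
    with open(path, "w") as fh:
        for cid, row in zip(results.cell_ids, cells):
            fh.write("cell:" + cid + "\t" + _fmt(row) + "\n")
        for i, row in enumerate(feats):
            label = (
                "kmer:" + kmers[i]
                if i < len(kmers)
                else f"bucket:{i - len(kmers)}"
            )
            fh.write(label + "\t" + _fmt(row) + "\n")
    config = {
        "k": spec.k,
        "N": spec.N,
        "bucket": spec.bucket,
        "P": spec.P,
        "d": int(cells.shape[1]),
        "n_cells": int(cells.shape[0]),
        "n_feature_rows": int(feats.shape[0]),
        "n_kmer_rows": n_canonical_kmers(spec.k),
        "dataset_ids": list(getattr(results, "dataset_ids", ["dataset0"])),
        "cell_dataset": [int(x) for x in getattr(
            results, "cell_dataset", np.zeros(cells.shape[0], dtype=int)
        )],
        "batch": (
            [str(b) for b in results.batch]
            if getattr(results, "batch", None) is not None
            else None
        ),
        "config": getattr(results, "config_snapshot", {}),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(config, fh, indent=1)


def _fmt(row: np.ndarray) -> str:
    return "\t".join(np.format_float_scientific(v, precision=8) for v in row)


def _canonical_kmer_strings(k: int) -> list[str]:
    """Canonical representative strings in row order (sorted canonical codes)."""
    from .features import FeatureSpec as _FS

    spec = _FS(k=k, N=1, bucket=0)
    table = spec.canon_table()
    codes = np.arange(4**k, dtype=np.int64)
    rc = spec.rc_table()
    reps = np.unique(np.minimum(codes, rc))
    bases = np.array(list("ACGT"))
    out = []
    for code in reps:
        s = "".join(
            bases[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k)
        )
        out.append(s)
    assert len(out) == table.max() + 1
    return out


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; inverse up to float32 bits."""
    from .model import CellEmbeddingResults, TrainingConfig

    path = Path(path)
    with open(str(path) + ".json") as fh:
        config = json.load(fh)
    spec = FeatureSpec(
        k=config["k"], N=config["N"], bucket=config["bucket"], P=config["P"]
    )
    n_cells, n_rows, d = (
        config["n_cells"], config["n_feature_rows"], config["d"],
    )
    cell_ids: list[str] = []
    cells = np.empty((n_cells, d), dtype=np.float32)
    feats = np.empty((n_rows, d), dtype=np.float32)
    kmer_rows = config["n_kmer_rows"]
    from .features import n_canonical_kmers

    if kmer_rows != n_canonical_kmers(config["k"]):
        raise ValueError(
            f"sidecar k={config['k']} implies {n_canonical_kmers(config['k'])} "
            f"k-mer rows but records {kmer_rows}"
        )
    i_cell = i_feat = 0
    with open(path) as fh:
        for ln in fh:
            label, *vals = ln.rstrip("\n").split("\t")
            row = np.array(vals, dtype=np.float32)
            if row.size != d:
                raise ValueError(f"row {label} has {row.size} values, not {d}")
            if label.startswith("cell:"):
                cell_ids.append(label[5:])
                cells[i_cell] = row
                i_cell += 1
            else:
                feats[i_feat] = row
                i_feat += 1
    if i_cell != n_cells or i_feat != n_rows:
        raise ValueError(
            f"{path}: found {i_cell} cell rows / {i_feat} feature rows, "
            f"sidecar says {n_cells} / {n_rows} (truncated file?)"
        )
    cfg = TrainingConfig(spec=spec, d=d, **{
        key: val for key, val in config.get("config", {}).items()
        if key in TrainingConfig.__dataclass_fields__
        and key not in ("spec", "d")
    })
    return CellEmbeddingResults(
        cell_embeddings=cells,
        feature_embeddings=feats,
        cell_ids=cell_ids,
        spec=spec,
        config=cfg,
        dataset_ids=config.get("dataset_ids", ["dataset0"]),
        cell_dataset=np.array(
            config.get("cell_dataset", [0] * n_cells), dtype=np.int32
        ),
        batch=(
            np.array(config["batch"], dtype=object)
            if config.get("batch") is not None
            else None
        ),
    )


# ---------------------------------------------------------------------------
# dataset bundle writer (used by the simulate CLI and tests)


def write_dataset(
    out_dir: str | Path,
    matrix: sp.spmatrix,
    cell_ids: list[str],
    event_names: list[str],
    sequences: dict[str, str] | None = None,
    batch: np.ndarray | None = None,
) -> None:
    """Write MTX + sidecars (+ FASTA of event sequences, + batch TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(matrix))
    (out / "cells.tsv").write_text("\n".join(cell_ids) + "\n")
    (out / "events.tsv").write_text("\n".join(event_names) + "\n")
    if sequences is not None:
        with open(out / "sequences.fa", "w") as fh:
            for name in event_names:
                fh.write(f">{name}\n{sequences[name]}\n")
    if batch is not None:
        (out / "batches.tsv").write_text(
            "\n".join(str(b) for b in batch) + "\n"
        )
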