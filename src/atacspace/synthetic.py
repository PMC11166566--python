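"""Self-contained scATAC-like data generator with known ground truth.

Emulates the features the embedding method exploits: several cell types,
each with a block of type-specific accessible events whose sequences carry a
distinct planted motif; shared and background events; sparse binary
accessibility with dropout; optional technical batch structure (batch-biased
events, i.e. accessibility shifts without any sequence difference); and a
fraction of events shorter than the sampled length L to exercise the
short-event rule. Background sequence composition is uniform over ACGT (no
GC modelling). Regeneration from (config, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .model import Dataset
from .motifs import MotifModel

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "default_benchmark_config",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters. Defaults give a small but non-trivial dataset."""

    n_cells: int = 300
    n_types: int = 3
    n_events: int = 1000
    event_len: int = 500
    motif_insert_rate: float = 0.9
    dropout: float = 0.5
    n_batches: int = 1
    batch_strength: float = 0.0
    seed: int = 7
    # composition of the event universe
    specific_frac: float = 0.6  # split equally among types
    shared_frac: float = 0.2
    batch_artifact_frac: float = 0.05  # only with n_batches > 1
    short_event_frac: float = 0.1  # events shorter than L
    short_len_range: tuple = (50, 149)
    motif_width: int = 10
    motif_mutation_rate: float = 0.05
    out_of_type_rate: float = 0.02
    shared_open_rate: float = 0.3
    background_open_rate: float = 0.05
    artifact_base_rate: float = 0.1
    # per-batch sequencing-depth (coverage) shift: the odds of every event
    # being open are scaled by exp(+/- coverage_shift * batch_strength / 2)
    # in alternating batches, emulating technical depth differences
    coverage_shift: float = 0.15
    # events are slices of a shared uniform-random mini-genome, so that any
    # background k-mer recurs across several events of mixed cell types, as
    # in real data; a private-per-event background would act as an
    # accessibility barcode no real k-mer can be
    genome_size: int = 100_000

    def __post_init__(self) -> None:
        if self.n_cells < self.n_types * 10:
            raise ValueError(
                f"n_cells={self.n_cells} < 10 per type ({self.n_types} types)"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def default_benchmark_config(batch_strength: float = 0.0) -> SimConfig:
    """The frozen small benchmark: 300 cells, 3 types, 1,000 events of
    500 bp, insert rate 0.9, dropout 0.5, 2 batches, seed 7."""
    return SimConfig(
        n_cells=300, n_types=3, n_events=1000, event_len=500,
        motif_insert_rate=0.9, dropout=0.5, n_batches=2,
        batch_strength=batch_strength, seed=7,
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    cell_types: np.ndarray  # per-cell "type<i>" labels
    planted_motifs: dict  # type label -> MotifModel (width-10 PWM)
    planted_consensus: dict  # type label -> consensus string
    event_roles: np.ndarray  # "type<i>" | "shared" | "background" | "batch<j>"
    batch: np.ndarray | None
    seed: int
    config: SimConfig = field(default=None)
    motif_planted: np.ndarray | None = None  # per-event: motif was inserted


def _random_consensus(rng, width, existing, min_hamming=4):
    """A random consensus sufficiently unlike existing ones (both strands)."""
    from .features import reverse_complement

    while True:
        s = "".join(rng.choice(_BASES, size=width))
        ok = True
        for e in existing:
            for t in (e, reverse_complement(e)):
                if sum(a != b for a, b in zip(s, t)) < min_hamming:
                    ok = False
        if ok:
            return s


def _interleave_roles(roles: list) -> list:
    """Order a role multiset so each role is evenly spaced along the list."""
    from collections import Counter

    counts = Counter(roles)
    n = len(roles)
    order = sorted(counts)  # deterministic
    # Bresenham-style largest-remainder scheduling
    assigned = {r: 0 for r in order}
    out = []
    for i in range(n):
        best, best_deficit = None, -1.0
        for r in order:
            deficit = counts[r] * (i + 1) / n - assigned[r]
            if deficit > best_deficit and assigned[r] < counts[r]:
                best, best_deficit = r, deficit
        out.append(best)
        assigned[best] += 1
    return out


def _consensus_pwm(consensus: str, mutation_rate: float) -> np.ndarray:
    pwm = np.full((4, len(consensus)), mutation_rate / 3)
    for j, b in enumerate(consensus):
        pwm["ACGT".index(b), j] = 1 - mutation_rate
    return pwm


def simulate_dataset(
    config: SimConfig | None = None, **overrides
) -> tuple[Dataset, SyntheticTruth]:
    """Generate (Dataset, SyntheticTruth) from a config (plus overrides)."""
    cfg = config or SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)

    # cells: balanced types (shuffled), batches independent of type
    base_types = np.arange(cfg.n_cells) % cfg.n_types
    cell_type_idx = rng.permutation(base_types)
    cell_types = np.array([f"type{t}" for t in cell_type_idx], dtype=object)
    if cfg.n_batches > 1:
        batch_idx = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
        batch = np.array([f"batch{b}" for b in batch_idx], dtype=object)
    else:
        batch_idx = np.zeros(cfg.n_cells, dtype=int)
        batch = None

    # planted motifs: one distinct consensus per type
    consensus, motifs = {}, {}
    for t in range(cfg.n_types):
        c = _random_consensus(rng, cfg.motif_width,
                              list(consensus.values()))
        consensus[f"type{t}"] = c
        motifs[f"type{t}"] = MotifModel(
            f"planted_type{t}", _consensus_pwm(c, cfg.motif_mutation_rate),
            source="synthetic",
        )

    # event roles
    n_specific = int(cfg.specific_frac * cfg.n_events / cfg.n_types)
    n_shared = int(cfg.shared_frac * cfg.n_events)
    n_artifact = (
        int(cfg.batch_artifact_frac * cfg.n_events) * cfg.n_batches
        if cfg.n_batches > 1
        else 0
    )
    roles = []
    for t in range(cfg.n_types):
        roles += [f"type{t}"] * n_specific
    roles += ["shared"] * n_shared
    if cfg.n_batches > 1:
        per_b = n_artifact // cfg.n_batches
        for b in range(cfg.n_batches):
            roles += [f"batch{b}"] * per_b
    roles += ["background"] * (cfg.n_events - len(roles))

    # event lengths: a fraction shorter than the default sampled length
    lengths = np.full(cfg.n_events, cfg.event_len, dtype=np.int64)
    n_short = int(cfg.short_event_frac * cfg.n_events)
    short_idx = rng.choice(cfg.n_events, size=n_short, replace=False)
    lengths[short_idx] = rng.integers(
        cfg.short_len_range[0], cfg.short_len_range[1] + 1, size=n_short
    )

    # genomic positions, role-stratified: roles are interleaved along the
    # genome (evenly spaced per role) so events overlapping the same locus
    # carry different roles. Without this, loci covered by several
    # same-type events by chance would make background sequence
    # type-coherent, whereas the planted motif must be the only
    # type-specific sequence feature.
    starts = np.sort(
        rng.integers(0, cfg.genome_size - lengths.max() + 1, size=cfg.n_events)
    )
    event_roles = np.array(_interleave_roles(roles), dtype=object)

    # sequences: slices of one shared uniform mini-genome; type-specific
    # events additionally carry the planted motif
    genome = rng.choice(_BASES, size=cfg.genome_size)
    sequences = []
    motif_planted = np.zeros(cfg.n_events, dtype=bool)
    for e in range(cfg.n_events):
        seq = genome[starts[e] : starts[e] + lengths[e]].copy()
        role = event_roles[e]
        if role.startswith("type") and rng.random() < cfg.motif_insert_rate:
            c = consensus[role]
            mut = np.array(list(c), dtype=object)
            for j in range(len(c)):
                if rng.random() < cfg.motif_mutation_rate:
                    mut[j] = rng.choice(
                        [b for b in "ACGT" if b != c[j]]
                    )
            pos = rng.integers(0, lengths[e] - len(c) + 1)
            seq[pos : pos + len(c)] = mut
            motif_planted[e] = True
        sequences.append("".join(seq))

    # accessibility
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    open_prob = np.empty((cfg.n_cells, cfg.n_events))
    for e in range(cfg.n_events):
        role = event_roles[e]
        if role.startswith("type"):
            t = int(role[4:])
            p = np.where(
                cell_type_idx == t, 1 - cfg.dropout, cfg.out_of_type_rate
            )
        elif role == "shared":
            p = np.full(cfg.n_cells, cfg.shared_open_rate)
        elif role.startswith("batch"):
            b = int(role[5:])
            logit0 = np.log(
                cfg.artifact_base_rate / (1 - cfg.artifact_base_rate)
            )
            p_in = _sigmoid(logit0 + cfg.batch_strength)
            p = np.where(batch_idx == b, p_in, cfg.artifact_base_rate)
        else:
            p = np.full(cfg.n_cells, cfg.background_open_rate)
        open_prob[:, e] = p
    if cfg.n_batches > 1 and cfg.batch_strength != 0:
        # batch coverage shift on the odds scale
        shift = cfg.coverage_shift * cfg.batch_strength / 2
        sign = np.where(batch_idx % 2 == 0, 1.0, -1.0)
        odds = open_prob / (1 - np.clip(open_prob, None, 1 - 1e-9))
        odds *= np.exp(sign * shift)[:, None]
        open_prob = odds / (1 + odds)
    matrix = sp.csr_matrix(
        (rng.random((cfg.n_cells, cfg.n_events)) < open_prob).astype(np.int8)
    )

    dataset = Dataset(
        matrix=matrix,
        cell_ids=[f"cell{i:04d}" for i in range(cfg.n_cells)],
        event_names=[f"event{e:05d}" for e in range(cfg.n_events)],
        sequences=sequences,
        batch=batch,
        dataset_id="synthetic",
    )
    truth = SyntheticTruth(
        cell_types=cell_types,
        planted_motifs=motifs,
        planted_consensus=consensus,
        event_roles=event_roles,
        batch=batch,
        seed=cfg.seed,
        config=cfg,
        motif_planted=motif_planted,
    )
    return dataset, truth
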