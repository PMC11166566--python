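"""DNA featurization: canonical k-mers, context n-gram pairs, induced embeddings.

A DNA sequence is represented as a bag of features. The primary features are
its overlapping k-mers, where each k-mer and its reverse complement are hashed
to the same embedding row ("canonical" k-mers). Local context is captured by
n-gram pair features: within every window of ``N`` consecutive k-mers, each
pair of k-mers contributes one extra feature, mapped by a hashing trick into a
fixed number of ``bucket`` rows. The embedding of a sequence with M features is
``sum(w_i) / M**P`` over its feature vectors, with ``P = 0.5`` by default.

All featurization is strand-invariant: a sequence and its reverse complement
produce identical feature multisets and therefore bit-identical induced
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "FeatureSpec",
    "FeatureBag",
    "reverse_complement",
    "canonical_kmer_index",
    "kmer_bag",
    "ngram_pair_features",
    "sequence_features",
    "induced_embedding",
    "n_canonical_kmers",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; anything not ACGT (case-insensitive) -> 4 (ambiguous)
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_MAX_TABLE_K = 12


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def n_canonical_kmers(k: int) -> int:
    """Number of {k-mer, reverse complement} equivalence classes.

    Even k admits palindromes (a k-mer equal to its own reverse complement),
    which form singleton classes: (4**k + 4**(k//2)) / 2. Odd k has none
    (the middle base would have to equal its complement): 4**k / 2.
    """
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=8)
def _tables(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical row table, reverse-complement code table) over all 4**k codes.

    A k-mer code is its base-4 value with the first base most significant.
    The canonical row of a code is the dense rank of min(code, rc_code)
    among all canonical representatives.
    """
    if not 1 <= k <= _MAX_TABLE_K:
        raise ValueError(
            f"k={k} outside supported table range 1..{_MAX_TABLE_K} "
            "(dense canonical index table)"
        )
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    for j in range(k):
        digit = (codes >> (2 * (k - 1 - j))) & 3  # j-th base from the left
        rc |= (3 - digit) << (2 * j)  # goes to j-th base from the right
    canon = np.minimum(codes, rc)
    reps = np.unique(canon)
    table = np.searchsorted(reps, canon).astype(np.int32)
    return table, rc


@dataclass(frozen=True)
class FeatureSpec:
    """Defines the feature universe of a model.

    Parameters
    ----------
    k : int
        k-mer length in bp (default 8).
    N : int
        context window size in k-mers (default 3). ``N=1`` disables pair
        features.
    bucket : int
        number of hashed rows reserved for n-gram pair features. May be 0
        only when ``N == 1``.
    P : float
        normalization exponent of the induced entity embedding (default 0.5).
    """

    k: int = 8
    N: int = 3
    bucket: int = 2_000_000
    P: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 15:
            raise ValueError(f"k must be in 1..15, got {self.k}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.bucket < 0:
            raise ValueError(f"bucket must be >= 0, got {self.bucket}")
        if self.bucket == 0 and self.N > 1:
            raise ValueError("bucket may be 0 only when N == 1")

    @property
    def n_kmer_rows(self) -> int:
        return n_canonical_kmers(self.k)

    @property
    def n_feature_rows(self) -> int:
        """Total embedding rows: canonical k-mers plus the hash bucket."""
        return self.n_kmer_rows + (self.bucket if self.N > 1 else 0)

    def canon_table(self) -> np.ndarray:
        return _tables(self.k)[0]

    def rc_table(self) -> np.ndarray:
        return _tables(self.k)[1]


@dataclass
class FeatureBag:
    """Feature multiset of one sequence: k-mer rows plus hashed pair rows."""

    kmer_indices: np.ndarray
    ngram_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def M(self) -> int:
        return len(self.kmer_indices) + len(self.ngram_indices)

    def all_indices(self) -> np.ndarray:
        return np.concatenate(
            [np.asarray(self.kmer_indices, dtype=np.int64),
             np.asarray(self.ngram_indices, dtype=np.int64)]
        )


def canonical_kmer_index(kmer: str, k: int | None = None) -> int | None:
    """Dense 0-based row index of a k-mer, shared with its reverse complement.

    Returns None (a "skip" sentinel) for windows containing ambiguous bases.
    """
    if k is None:
        k = len(kmer)
    elif len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {kmer!r}")
    codes = encode_bases(kmer)
    if (codes >= 4).any():
        return None
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return int(_tables(k)[0][code])


def _raw_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 codes of retained (ACGT-only) k-mer windows, in sequence order."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    arr = encode_bases(seq).astype(np.int64)
    n = len(arr) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        d = arr[j : j + n]
        codes = (codes << 2) | np.where(d >= 4, 0, d)
        bad |= d >= 4
    return codes[~bad]


def kmer_bag(seq: str, spec: FeatureSpec) -> np.ndarray:
    """Ordered canonical row indices of a sequence's retained k-mer windows.

    Windows containing a non-ACGT base are skipped; order is preserved.
    """
    codes = _raw_kmer_codes(seq, spec.k)
    return spec.canon_table()[codes].astype(np.int64)


def _pair_hashes(
    raw_codes: np.ndarray, spec: FeatureSpec
) -> np.ndarray:
    """Hashed pair-feature rows for full windows of N consecutive k-mers.

    Every unordered-under-reverse-complement pair {(a,b), (rc(b),rc(a))}
    within a window yields one row. The canonical representative is the
    lexicographic min of the two concatenation codes, taken modulo the bucket
    size and offset past the k-mer rows, so full-sequence bags are
    strand-invariant.
    """
    N, k = spec.N, spec.k
    m = len(raw_codes)
    if N < 2 or m < N:
        return np.empty(0, dtype=np.int64)
    rc = spec.rc_table()[raw_codes]
    shift = 2 * k
    out = []
    for p in range(N - 1):
        for q in range(p + 1, N):
            # pair (i+p, i+q) over all full windows starting at i
            a = raw_codes[p : m - N + 1 + p]
            b = raw_codes[q : m - N + 1 + q]
            c1 = (a << shift) | b
            c2 = (rc[q : m - N + 1 + q] << shift) | rc[p : m - N + 1 + p]
            out.append(np.minimum(c1, c2))
    pooled = np.concatenate(out)
    return spec.n_kmer_rows + pooled % spec.bucket


def ngram_pair_features(seq: str, spec: FeatureSpec) -> np.ndarray:
    """Hashed context-pair feature rows of a sequence (empty when N=1)."""
    return _pair_hashes(_raw_kmer_codes(seq, spec.k), spec)


def sequence_features(seq: str, spec: FeatureSpec) -> FeatureBag:
    """Full feature bag of a sequence: canonical k-mers + n-gram pairs."""
    codes = _raw_kmer_codes(seq, spec.k)
    return FeatureBag(
        kmer_indices=spec.canon_table()[codes].astype(np.int64),
        ngram_indices=_pair_hashes(codes, spec),
    )


def induced_embedding(
    bag: FeatureBag | np.ndarray, feature_matrix: np.ndarray, P: float = 0.5
) -> np.ndarray:
    """Entity embedding ``sum(w_i) / M**P`` over the bag's feature rows.

    Rows are accumulated in sorted index order, which makes the result
    bit-identical for any two bags with equal feature multisets (in
    particular, for a sequence and its reverse complement).
    """
    idx = bag.all_indices() if isinstance(bag, FeatureBag) else np.asarray(bag)
    if idx.size == 0:
        raise ValueError("no embeddable features (all windows masked?)")
    idx = np.sort(idx)
    total = feature_matrix[idx].sum(axis=0)
    return total / idx.size**P
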