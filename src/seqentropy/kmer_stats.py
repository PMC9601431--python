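"""Overlapping k-mer counting and relative-frequency distributions.

A sequence of length N has N-k+1 overlapping windows of length k. Counting
is strand-specific: no reverse-complement canonicalization, so all |A|^k
words are indexed separately. Windows containing the alphabet's ambiguity
symbol (N or X) are excluded and the denominator shrinks to the number of
valid windows, keeping the frequencies a true probability distribution; a
``strict_denominator`` switch restores the fixed N-k+1 denominator for
exact-replication runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .sequence_io import AMBIGUITY, SYMBOL_ORDER, Alphabet, SequenceRecord

__all__ = ["KmerDistribution", "count_kmers", "kmer_frequency_vector", "kmer_frequency_matrix"]

#: Refuse to build a dense frequency vector wider than this; use the sparse
#: matrix route (or a smaller k_max) instead.
DENSE_DIM_CAP = 200_000


@dataclass
class KmerDistribution:
    """Counts and relative frequencies of one sequence's k-mers at one k.

    ``support_size`` — the number of distinct observed words, i.e. events
    with nonzero probability — is the N that bounds the entropy values.
    """

    k: int
    counts: dict[str, int]
    total_windows: int

    @property
    def probs(self) -> dict[str, float]:
        if self.total_windows == 0:
            return {}
        return {m: c / self.total_windows for m, c in self.counts.items()}

    @property
    def support_size(self) -> int:
        return len(self.counts)

    def prob_array(self) -> np.ndarray:
        """Probabilities of the observed k-mers, in sorted k-mer order."""
        if self.total_windows == 0:
            return np.empty(0)
        keys = sorted(self.counts)
        return np.array([self.counts[m] for m in keys], dtype=float) / self.total_windows


def count_kmers(
    record: SequenceRecord,
    k: int,
    strict_denominator: bool = False,
) -> KmerDistribution:
    """Count the overlapping k-mers of ``record``.

    Windows are the contiguous substrings of length k at offsets
    0..length-k. Windows containing the ambiguity symbol are skipped; with
    ``strict_denominator`` the denominator stays length-k+1 regardless. A
    sequence shorter than k yields an empty distribution.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = record.residues
    n = len(seq)
    if n < k:
        return KmerDistribution(k=k, counts={}, total_windows=0)
    amb = record.ambiguity_symbol() if record.alphabet is not None else None
    counts: Counter[str] = Counter()
    if amb is None or amb not in seq:
        for i in range(n - k + 1):
            counts[seq[i : i + k]] += 1
        total = n - k + 1
    else:
        total = 0
        for i in range(n - k + 1):
            window = seq[i : i + k]
            if amb in window:
                continue
            counts[window] += 1
            total += 1
    if strict_denominator:
        total = n - k + 1
    return KmerDistribution(k=k, counts=dict(counts), total_windows=total)


def _kmer_index(word: str, rank: dict[str, int], base: int) -> int:
    idx = 0
    for c in word:
        idx = idx * base + rank[c]
    return idx


def _block_dims(alphabet: Alphabet, k_min: int, k_max: int) -> list[int]:
    base = len(SYMBOL_ORDER[alphabet])
    return [base**k for k in range(k_min, k_max + 1)]


def kmer_frequency_vector(
    record: SequenceRecord,
    k_min: int,
    k_max: int,
    strict_denominator: bool = False,
) -> np.ndarray:
    """Dense relative-frequency vector over all possible k-mers, k_min..k_max.

    Blocks are concatenated in increasing k; within a block, k-mers are in
    lexicographic order under the alphabet's fixed symbol order (A<C<G<T for
    DNA). Absent k-mers are 0. The total dimension is sum(|A|^k); beyond
    :data:`DENSE_DIM_CAP` a ValueError advises the sparse route.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got k_min={k_min}, k_max={k_max}")
    if record.alphabet is None:
        raise ValueError("record needs an assigned alphabet")
    dims = _block_dims(record.alphabet, k_min, k_max)
    dim = sum(dims)
    if dim > DENSE_DIM_CAP:
        raise ValueError(
            f"dense k-mer vector would have {dim} dimensions (> {DENSE_DIM_CAP}); "
            "use kmer_frequency_matrix (sparse) or a smaller k_max"
        )
    symbols = SYMBOL_ORDER[record.alphabet]
    rank = {c: i for i, c in enumerate(symbols)}
    base = len(symbols)
    vec = np.zeros(dim)
    offset = 0
    for k, block in zip(range(k_min, k_max + 1), dims):
        dist = count_kmers(record, k, strict_denominator=strict_denominator)
        if dist.total_windows > 0:
            for word, c in dist.counts.items():
                vec[offset + _kmer_index(word, rank, base)] = c / dist.total_windows
        offset += block
    return vec


def kmer_frequency_matrix(
    records: list[SequenceRecord],
    k_min: int,
    k_max: int,
    strict_denominator: bool = False,
) -> sparse.csr_matrix:
    """Sparse CSR matrix of k-mer frequency vectors, one row per record.

    Same layout as :func:`kmer_frequency_vector` but with no dimension cap;
    intended for the high-k dimensionality-reduction baseline (DNA up to
    k=10, protein up to k=5).
    """
    if not records:
        raise ValueError("empty record list")
    alphabet = records[0].alphabet
    if alphabet is None or any(r.alphabet != alphabet for r in records):
        raise ValueError("all records must share one assigned alphabet")
    symbols = SYMBOL_ORDER[alphabet]
    rank = {c: i for i, c in enumerate(symbols)}
    base = len(symbols)
    dims = _block_dims(alphabet, k_min, k_max)
    dim = sum(dims)
    rows, cols, vals = [], [], []
    for ri, rec in enumerate(records):
        offset = 0
        for k, block in zip(range(k_min, k_max + 1), dims):
            dist = count_kmers(rec, k, strict_denominator=strict_denominator)
            if dist.total_windows > 0:
                for word, c in dist.counts.items():
                    rows.append(ri)
                    cols.append(offset + _kmer_index(word, rank, base))
                    vals.append(c / dist.total_windows)
            offset += block
    return sparse.csr_matrix((vals, (rows, cols)), shape=(len(records), dim))
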