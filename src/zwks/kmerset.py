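"""Canonical k-mer counting and exact multiset algebra.

A :class:`KmerSet` is the unit every screening step operates on: a map
from canonical k-mer (lexicographic min of a k-mer and its reverse
complement) to occurrence count.  Internally k-mers are 2-bit packed
``uint64`` codes kept sorted and unique, so set operations reduce to
sorted-array merges; the 2-bit encoding preserves lexicographic order,
hence the on-disk TSV (sorted by code) is also sorted by k-mer string.

Counting is exact — no sketching or streaming approximation — which is
what the female-panel intersection / male-panel difference procedure
requires: a single spurious male k-mer must be able to veto a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _seqs

MAX_K = 31  # one k-mer must pack into a single uint64 (2 bits/base)
MIN_K = 3


class KmerParameterError(ValueError):
    """Invalid k or mismatched k between operands."""


@dataclass
class KmerSet:
    """Canonical k-mer -> count multiset with fixed k.

    ``kmers`` is an ascending unique uint64 array of 2-bit packed
    canonical k-mers; ``counts`` the parallel positive counts.
    """

    k: int
    kmers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.kmers.shape != self.counts.shape:
            raise ValueError("kmers and counts must be parallel arrays")

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        packed = np.array([_seqs.pack_kmer(kmer)], dtype=np.uint64)
        canon, _ = _seqs.canonical_packed(packed, self.k)
        return bool(_seqs.in_sorted(canon, self.kmers)[0])

    def get(self, kmer: str) -> int:
        packed = np.array([_seqs.pack_kmer(kmer)], dtype=np.uint64)
        canon, _ = _seqs.canonical_packed(packed, self.k)
        idx = np.searchsorted(self.kmers, canon[0])
        if idx < len(self.kmers) and self.kmers[idx] == canon[0]:
            return int(self.counts[idx])
        return 0

    @property
    def total(self) -> int:
        """Sum of all counts (total k-mer occurrences)."""
        return int(self.counts.sum())

    def to_dict(self) -> dict[str, int]:
        return dict(zip(_seqs.unpack_kmers(self.kmers, self.k),
                        (int(c) for c in self.counts)))

    @classmethod
    def from_dict(cls, d: dict[str, int], k: int) -> "KmerSet":
        if not d:
            return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64))
        packed = np.array([_seqs.pack_kmer(s) for s in d], dtype=np.uint64)
        canon, _ = _seqs.canonical_packed(packed, k)
        if len(np.unique(canon)) != len(canon):
            raise ValueError("dict keys collapse under canonicalization")
        order = np.argsort(canon)
        return cls(k, canon[order],
                   np.array(list(d.values()), dtype=np.int64)[order])

    # -- on-disk format -----------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the set as ``#zwks-kmerset k=<k>`` header + KMER<TAB>COUNT."""
        with open(path, "w") as fh:
            fh.write(f"#zwks-kmerset k={self.k}\n")
            for s, c in zip(_seqs.unpack_kmers(self.kmers, self.k), self.counts):
                fh.write(f"{s}\t{c}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KmerSet":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#zwks-kmerset k="):
                raise ValueError(f"{path}: not a zwks k-mer set file")
            k = int(header.split("k=")[1])
            kmers: list[int] = []
            counts: list[int] = []
            for line in fh:
                if not line.strip():
                    continue
                s, c = line.rstrip("\n").split("\t")
                kmers.append(_seqs.pack_kmer(s))
                counts.append(int(c))
        return cls(k, np.array(kmers, dtype=np.uint64),
                   np.array(counts, dtype=np.int64))


def _empty(k: int) -> KmerSet:
    return KmerSet(k, np.empty(0, np.uint64), np.empty(0, np.int64))


def _check_k(k: int) -> None:
    if not (MIN_K <= k <= MAX_K):
        raise KmerParameterError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")


def _common_k(sets: Sequence[KmerSet]) -> int:
    ks = {s.k for s in sets}
    if len(ks) != 1:
        raise KmerParameterError(f"mixed k among operands: {sorted(ks)}")
    return ks.pop()


def _iter_code_chunks(source, chunk_bases: int = 16_000_000) -> Iterator[np.ndarray]:
    """Yield uint8 code arrays with 255 separators between sequences.

    Accepts an iterable of DNA strings / code arrays, a FASTA/FASTQ path,
    or an object exposing ``iter_codes()`` (a simulated read set).
    """
    if isinstance(source, (str, Path)):
        source = (seq for _, seq in _seqs.read_fastx_seqs(source))
    elif hasattr(source, "iter_codes"):
        source = source.iter_codes()
    buf: list[np.ndarray] = []
    size = 0
    sep = np.array([255], dtype=np.uint8)
    for seq in source:
        codes = seq if isinstance(seq, np.ndarray) else _seqs.encode(seq)
        buf.append(codes)
        buf.append(sep)
        size += len(codes) + 1
        if size >= chunk_bases:
            yield np.concatenate(buf)
            buf, size = [], 0
    if buf:
        yield np.concatenate(buf)


def count_kmers(source, k: int) -> KmerSet:
    """Count canonical k-mers over sequences, skipping non-ACGT windows.

    ``source`` may be an iterable of DNA strings or code arrays, a
    FASTA/FASTQ(.gz) path, or a simulated read set.
    """
    _check_k(k)
    parts: list[np.ndarray] = []
    for chunk in _iter_code_chunks(source):
        fwd, _ = _seqs.packed_kmers(chunk, k)
        if len(fwd):
            canon, _ = _seqs.canonical_packed(fwd, k)
            parts.append(canon)
    if not parts:
        return _empty(k)
    kmers, counts = np.unique(np.concatenate(parts), return_counts=True)
    return KmerSet(k, kmers, counts.astype(np.int64))


def filter_min_count(s: KmerSet, t: int) -> KmerSet:
    """Keep entries with count >= t (the panel frequency filter)."""
    if t < 1:
        raise KmerParameterError(f"threshold must be >= 1, got {t}")
    keep = s.counts >= t
    return KmerSet(s.k, s.kmers[keep], s.counts[keep])


def union_sum(sets: Sequence[KmerSet]) -> KmerSet:
    """Key union with counts summed across all inputs."""
    if not sets:
        raise KmerParameterError("union_sum of an empty list")
    k = _common_k(sets)
    kmers = np.concatenate([s.kmers for s in sets])
    counts = np.concatenate([s.counts for s in sets])
    if len(kmers) == 0:
        return _empty(k)
    uniq, inv = np.unique(kmers, return_inverse=True)
    summed = np.bincount(inv, weights=counts.astype(np.float64))
    return KmerSet(k, uniq, summed.astype(np.int64))


def intersect_all(sets: Sequence[KmerSet]) -> KmerSet:
    """Keys present in every input; counts summed across inputs."""
    if not sets:
        raise KmerParameterError("intersect_all of an empty list")
    k = _common_k(sets)
    keys = sets[0].kmers
    for s in sets[1:]:
        keys = keys[_seqs.in_sorted(keys, s.kmers)]
        if len(keys) == 0:
            return _empty(k)
    counts = np.zeros(len(keys), dtype=np.int64)
    for s in sets:
        idx = np.searchsorted(s.kmers, keys)
        counts += s.counts[idx]
    return KmerSet(k, keys, counts)


def difference(a: KmerSet, b: KmerSet) -> KmerSet:
    """Entries of ``a`` whose key is absent from ``b`` (counts from ``a``)."""
    _common_k([a, b])
    keep = ~_seqs.in_sorted(a.kmers, b.kmers)
    return KmerSet(a.k, a.kmers[keep], a.counts[keep])
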