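"""Chromosome-level identification and assembly QC.

Three alignment-free diagnostics:

* **k-mer painting** — counting occurrences of a k-mer set (typically
  the sex-specific set) along genomic windows, which localizes the
  set's source chromosome: with a differentiated W, specific k-mers
  paint only the W.
* **MinHash sketch identity** — bottom-s sketches of two sequences'
  canonical k-mer sets give a Jaccard estimate j, converted to average
  nucleotide identity via the Mash relation
  ``identity = 1 + (1/k) * ln(2j / (1 + j))``.  Used to find the Z
  candidate: the reference chromosome with maximal identity to the
  recovered W.
* **k-mer QV** — assembly k-mer positions unsupported by the read
  k-mer set estimate the per-base consensus error
  ``E = 1 - (1 - b/T)**(1/k)``, reported as QV = -10*log10(E) and
  accuracy% = 100*(1 - E); plus the homozygous-SNP accuracy
  complement 100*(1 - n_hom/L).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seqs
from .kmerset import KmerSet


class ChromIdError(ValueError):
    pass


# ---------------------------------------------------------------------------
# painting


def paint_kmers(assembly, painted: KmerSet, window: int = 1_000) -> pd.DataFrame:
    """Per-window counts of positions whose canonical k-mer is in ``painted``.

    Returns a frame (chrom, start, end, n_hits); window coordinates are
    0-based half-open and a k-mer counts in the window containing its
    start position.
    """
    if window < painted.k:
        raise ChromIdError(f"window ({window}) must be >= k ({painted.k})")
    from .mapdepth import _as_ref_dict

    asm = _as_ref_dict(assembly)
    rows = []
    for name, codes in asm.items():
        L = len(codes)
        starts = np.arange(0, L, window, dtype=np.int64)
        ends = np.minimum(starts + window, L)
        hits = np.zeros(len(starts), dtype=np.int64)
        fwd, pos = _seqs.packed_kmers(codes, painted.k)
        if len(fwd) and len(painted):
            canon, _ = _seqs.canonical_packed(fwd, painted.k)
            hit_pos = pos[_seqs.in_sorted(canon, painted.kmers)]
            hits += np.bincount(hit_pos // window, minlength=len(starts))
        for s, e, h in zip(starts, ends, hits):
            rows.append((name, int(s), int(e), int(h)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_hits"])


def paint_totals(track: pd.DataFrame) -> pd.Series:
    """Per-chromosome painted-k-mer totals of a paint track."""
    return track.groupby("chrom")["n_hits"].sum()


# ---------------------------------------------------------------------------
# MinHash identity

# splitmix64 finalizer: fixed, platform-independent 64-bit mixing
_SM_C1 = np.uint64(0x9E3779B97F4A7C15)
_SM_C2 = np.uint64(0xBF58476D1CE4E5B9)
_SM_C3 = np.uint64(0x94D049BB133111EB)


def _hash64(x: np.ndarray) -> np.ndarray:
    z = (x + _SM_C1).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= _SM_C2
    z ^= z >> np.uint64(27)
    z *= _SM_C3
    z ^= z >> np.uint64(31)
    return z


@dataclass
class SketchPair:
    """Bottom-s MinHash comparison of two sequences."""

    sketch_size: int
    shared: int
    jaccard: float
    identity: float
    degenerate: bool = False  # j == 0: identity floored at 0


def identity_from_jaccard(j: float, k: int) -> float:
    """Mash relation: identity = 1 + (1/k) ln(2j/(1+j)), floored at 0."""
    if j <= 0:
        return 0.0
    return max(1.0 + math.log(2 * j / (1 + j)) / k, 0.0)


def _sketch(codes: np.ndarray, k: int, s: int) -> np.ndarray:
    fwd, _ = _seqs.packed_kmers(codes, k)
    if len(fwd) == 0:
        raise ChromIdError("sequence shorter than k or all-N")
    canon, _ = _seqs.canonical_packed(fwd, k)
    hashes = np.unique(_hash64(np.unique(canon)))
    return hashes[:s]


def sketch_identity(seq_a, seq_b, k: int = 17,
                    sketch_size: int = 1_000) -> SketchPair:
    """Alignment-free identity of two sequences from bottom-s MinHash.

    Jaccard is estimated on the merged bottom-s sketch; identity uses
    the Mash relation (distance = -(1/k) ln(2j/(1+j))), floored at 0.
    """
    if sketch_size < 100:
        raise ChromIdError("sketch_size must be >= 100")
    a = seq_a if isinstance(seq_a, np.ndarray) else _seqs.encode(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else _seqs.encode(seq_b)
    sa = _sketch(a, k, sketch_size)
    sb = _sketch(b, k, sketch_size)
    merged = np.unique(np.concatenate((sa, sb)))[:sketch_size]
    shared = int(np.intersect1d(np.intersect1d(merged, sa), sb).size)
    j = shared / len(merged)
    if j <= 0:
        return SketchPair(sketch_size, 0, 0.0, 0.0, degenerate=True)
    return SketchPair(sketch_size, shared, j, identity_from_jaccard(j, k))


def rank_identity(query_seq, reference, k: int = 17,
                  sketch_size: int = 1_000) -> pd.DataFrame:
    """Sketch identity of a query against every reference chromosome.

    Sorted descending by identity; the top row is the homolog candidate
    (the Z candidate when the query is a recovered W).
    """
    from .mapdepth import _as_ref_dict

    q = query_seq if isinstance(query_seq, np.ndarray) else _seqs.encode(query_seq)
    rows = []
    for name, codes in _as_ref_dict(reference).items():
        sp = sketch_identity(q, codes, k=k, sketch_size=sketch_size)
        rows.append((name, sp.jaccard, sp.identity, sp.shared, sp.sketch_size))
    df = pd.DataFrame(rows, columns=["chrom", "jaccard", "identity",
                                     "shared", "sketch_size"])
    return df.sort_values("identity", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# assembly accuracy


@dataclass
class QVResult:
    """K-mer-based consensus accuracy estimate."""

    T: int            # total assembly k-mer positions
    b: int            # positions whose canonical k-mer is absent from reads
    k: int
    E: float          # per-base error estimate
    qv: float         # -10 log10 E (inf when b == 0)
    accuracy_pct: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["qv"] = None if math.isinf(self.qv) else self.qv
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def qv_from_counts(T: int, b: int, k: int) -> QVResult:
    """Closed-form QV from k-mer totals: E = 1 - (1 - b/T)^(1/k)."""
    if T <= 0:
        raise ChromIdError("no assembly k-mers (T = 0)")
    if not (0 <= b <= T):
        raise ChromIdError("b must be in [0, T]")
    if b == 0:
        return QVResult(T, 0, k, 0.0, float("inf"), 100.0)
    E = 1.0 - (1.0 - b / T) ** (1.0 / k)
    return QVResult(T, b, k, E, -10.0 * math.log10(E), 100.0 * (1.0 - E))


def qv_estimate(assembly, read_kmers: KmerSet, k: int | None = None,
                distinct: bool = False) -> QVResult:
    """Estimate assembly consensus accuracy from read k-mer support.

    Counts assembly k-mer positions (with multiplicity unless
    ``distinct``) whose canonical k-mer never occurs in the read set;
    those are attributed to consensus errors.
    """
    if len(read_kmers) == 0:
        raise ChromIdError("empty read k-mer set")
    k = k or read_kmers.k
    if k != read_kmers.k:
        raise ChromIdError("k does not match the read k-mer set")
    from .mapdepth import _as_ref_dict

    T = 0
    b = 0
    for _, codes in _as_ref_dict(assembly).items():
        fwd, _ = _seqs.packed_kmers(codes, k)
        if len(fwd) == 0:
            continue
        canon, _ = _seqs.canonical_packed(fwd, k)
        if distinct:
            canon = np.unique(canon)
        T += len(canon)
        b += int((~_seqs.in_sorted(canon, read_kmers.kmers)).sum())
    return qv_from_counts(T, b, k)


def hom_snp_accuracy(n_hom_snps: int, genome_length: int) -> float:
    """Base accuracy (%) implied by homozygous SNPs against own reads.

    Each homozygous variant call marks one assembled base unsupported by
    the sample's reads, so accuracy% = 100 * (1 - n / L).
    """
    if genome_length <= 0:
        raise ChromIdError("genome_length must be positive")
    if n_hom_snps < 0 or n_hom_snps > genome_length:
        raise ChromIdError("n_hom_snps must be in [0, genome_length]")
    return 100.0 * (1.0 - n_hom_snps / genome_length)
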