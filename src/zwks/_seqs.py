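"""Low-level DNA sequence plumbing shared across modules.

Sequences are handled internally as numpy ``uint8`` code arrays with
A=0, C=1, G=2, T=3 and 255 for anything else (N etc.).  The 2-bit code
order matches the lexicographic order of the bases, so packed k-mer
integers sort in the same order as their string form.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (255 = invalid base)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a code array (all codes < 4) back to an ACGT string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array; invalid codes stay invalid."""
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def random_codes(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


# ---------------------------------------------------------------------------
# packed k-mers


def packed_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid forward k-mers of ``codes`` as packed 2-bit uint64 integers.

    Returns ``(packed, positions)`` where windows containing a non-ACGT
    code are dropped.  Positions are 0-based window starts.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    valid = (codes < 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(valid)))
    ok = (cs[k:] - cs[:-k]) == k
    c = np.where(codes < 4, codes, 0).astype(np.uint64)
    packed = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        packed |= c[j : j + n] << np.uint64(2 * (k - 1 - j))
    pos = np.nonzero(ok)[0].astype(np.int64)
    return packed[ok], pos


def revcomp_packed(packed: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed k-mers."""
    p = (~packed).astype(np.uint64)  # complement: 3 - code == ~code & 3
    out = np.zeros_like(p)
    two = np.uint64(2)
    three = np.uint64(3)
    for _ in range(k):
        out = (out << two) | (p & three)
        p = p >> two
    return out


def canonical_packed(packed: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical form (min of forward and reverse complement) of packed k-mers.

    Returns ``(canonical, forward_is_canonical)``.
    """
    rc = revcomp_packed(packed, k)
    fwd_canon = packed <= rc
    return np.where(fwd_canon, packed, rc), fwd_canon


def unpack_kmers(packed: np.ndarray, k: int) -> list[str]:
    """Decode packed k-mers to ACGT strings."""
    n = len(packed)
    if n == 0:
        return []
    mat = np.empty((n, k), dtype=np.uint8)
    p = packed.copy()
    two = np.uint64(2)
    three = np.uint64(3)
    for j in range(k - 1, -1, -1):
        mat[:, j] = (p & three).astype(np.uint8)
        p = p >> two
    flat = _DECODE[mat].tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(n)]


def pack_kmer(kmer: str) -> int:
    codes = encode(kmer)
    if np.any(codes >= 4):
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    v = 0
    for c in codes:
        v = (v << 2) | int(c)
    return v


# ---------------------------------------------------------------------------
# sorted-array membership


def in_sorted(values: np.ndarray, sorted_keys: np.ndarray) -> np.ndarray:
    """Boolean membership of ``values`` in an ascending unique key array."""
    if len(sorted_keys) == 0 or len(values) == 0:
        return np.zeros(len(values), dtype=bool)
    idx = np.searchsorted(sorted_keys, values)
    inside = idx < len(sorted_keys)
    idx_c = np.minimum(idx, len(sorted_keys) - 1)
    return inside & (sorted_keys[idx_c] == values)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O

class _GzipSink(gzip.GzipFile):
    """Gzip writer with fixed mtime and no embedded filename, so identical
    content always yields byte-identical archives."""

    def __init__(self, path: Path, mode: str):
        self._raw = open(path, mode)
        super().__init__(filename="", mode=mode, fileobj=self._raw, mtime=0)

    def close(self) -> None:
        super().close()
        self._raw.close()


def _opener(path: str | Path, mode: str = "wt"):
    path = Path(path)
    bmode = mode.replace("t", "b") if "b" not in mode else mode
    if path.suffix == ".gz":
        return _GzipSink(path, bmode)
    return open(path, bmode)


def write_fasta(path: str | Path, records: Iterable[tuple[str, np.ndarray | str]],
                width: int = 80) -> None:
    with _opener(path) as fh:
        for name, seq in records:
            s = seq if isinstance(seq, str) else decode(seq)
            fh.write(f">{name}\n".encode())
            for i in range(0, len(s), width):
                fh.write((s[i : i + width] + "\n").encode())


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    import pysam

    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            yield entry.name, entry.sequence


def read_fastx_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Name/sequence pairs from FASTA or FASTQ, gz-transparent."""
    import pysam

    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            yield entry.name, entry.sequence
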