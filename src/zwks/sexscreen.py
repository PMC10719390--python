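"""Derivation of sex-specific k-mers and k-mer-based read partitioning.

The core procedure: per-individual canonical k-mer sets from a female
and a male resequencing panel are reduced to the k-mers that are seen
at least ``min_count_female`` times in *every* female and never (or
below ``min_count_male`` summed occurrences) in *any* male.  In a ZW
system those k-mers tag the W chromosome, and long (or Hi-C) reads
containing them can be binned out for a W-only assembly.

Everything is built from the exact :mod:`zwks.kmerset` primitives —
filter, intersect-across-panel, union of the other sex, difference — in
that order, so the derivation is reproducible set algebra rather than a
heuristic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seqs, kmerset
from .kmerset import KmerSet
from .simdata import ReadSet, W_NAME

log = logging.getLogger(__name__)


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the sex-specific k-mer screen.

    ``min_count_female`` is the per-individual frequency filter applied
    before the all-female intersection (default 5: k-mers supported by
    fewer than 5 read occurrences in an individual are treated as noise).
    ``min_count_male`` = 1 means any male occurrence disqualifies a
    k-mer.  ``min_hits_per_read`` is the number of specific-k-mer
    positions a read must contain to be binned; 1 corresponds to keeping
    any read containing a female-specific k-mer, while values above k
    reject reads whose hits could stem from a single sequencing-error
    event (one substitution can forge at most k consecutive hits).
    """

    k: int = 17
    min_count_female: int = 5
    min_count_male: int = 1
    min_hits_per_read: int = 1
    distinct_hits: bool = False  # count distinct k-mers instead of positions

    def validate(self) -> None:
        for name in ("k", "min_count_female", "min_count_male",
                     "min_hits_per_read"):
            if getattr(self, name) < 1:
                raise ScreenError(f"{name} must be >= 1")


def derive_sex_specific_kmers(female_sets: Sequence[KmerSet],
                              male_sets: Sequence[KmerSet],
                              params: ScreenParams | None = None) -> KmerSet:
    """K-mers present (>= min_count_female) in all females, absent from males.

    Equals ``difference(intersect_all(filter_min_count(f_i)), union_sum(males))``
    with the male union optionally thresholded at ``min_count_male``.
    """
    params = params or ScreenParams()
    params.validate()
    if not female_sets or not male_sets:
        raise ScreenError("need at least one k-mer set per sex")
    for s in (*female_sets, *male_sets):
        if s.k != params.k:
            raise ScreenError(f"k-mer set k={s.k} does not match params k={params.k}")
    filtered = [kmerset.filter_min_count(f, params.min_count_female)
                for f in female_sets]
    shared = kmerset.intersect_all(filtered)
    male_union = kmerset.union_sum(list(male_sets))
    if params.min_count_male > 1:
        male_union = kmerset.filter_min_count(male_union, params.min_count_male)
    spec = kmerset.difference(shared, male_union)
    log.info("sex-specific k-mers: %d (from %d shared female k-mers, "
             "%d male union k-mers)", len(spec), len(shared), len(male_union))
    return spec


@dataclass
class ReadPartition:
    """Disjoint kept/rest split of a read set with per-read hit counts."""

    params: ScreenParams
    frame: pd.DataFrame = field(repr=False)  # read_id, n_hits, kept

    @property
    def kept_ids(self) -> list[str]:
        return self.frame.loc[self.frame["kept"] == 1, "read_id"].tolist()

    @property
    def n_kept(self) -> int:
        return int(self.frame["kept"].sum())

    @property
    def n_total(self) -> int:
        return len(self.frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 params: ScreenParams | None = None) -> "ReadPartition":
        return cls(params or ScreenParams(), pd.read_csv(path, sep="\t"))


def _read_hits(codes: np.ndarray, spec: KmerSet, distinct: bool) -> int:
    fwd, _ = _seqs.packed_kmers(codes, spec.k)
    if len(fwd) == 0:
        return 0
    canon, _ = _seqs.canonical_packed(fwd, spec.k)
    if distinct:
        canon = np.unique(canon)
    return int(_seqs.in_sorted(canon, spec.kmers).sum())


def screen_reads(reads, spec: KmerSet,
                 params: ScreenParams | None = None) -> ReadPartition:
    """Partition reads by specific-k-mer content.

    A read is kept iff the number of its canonical k-mer positions found
    in ``spec`` reaches ``min_hits_per_read``.  ``reads`` may be a
    simulated :class:`ReadSet` or a FASTQ/FASTA path.
    """
    params = params or ScreenParams(k=spec.k)
    params.validate()
    if len(spec) == 0:
        raise ScreenError("empty specific k-mer set: nothing to screen against")
    if params.k != spec.k:
        raise ScreenError("params k does not match the specific k-mer set")
    ids: list[str] = []
    hits: list[int] = []
    if isinstance(reads, ReadSet):
        ids = list(reads.ids)
        if reads.matrix is not None and not params.distinct_hits:
            hits_arr = _matrix_hits(reads.matrix, spec)
            hits = hits_arr.tolist()
        else:
            hits = [_read_hits(reads.read_codes(i), spec, params.distinct_hits)
                    for i in range(reads.n_reads)]
    else:
        for name, seq in _seqs.read_fastx_seqs(reads):
            ids.append(name)
            hits.append(_read_hits(_seqs.encode(seq), spec,
                                   params.distinct_hits))
    n_hits = np.array(hits, dtype=np.int64)
    kept = (n_hits >= params.min_hits_per_read).astype(np.int8)
    frame = pd.DataFrame({"read_id": ids, "n_hits": n_hits, "kept": kept})
    return ReadPartition(params, frame)


def _matrix_hits(matrix: np.ndarray, spec: KmerSet,
                 batch: int = 200_000) -> np.ndarray:
    n, L = matrix.shape
    out = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, batch):
        m = matrix[lo : lo + batch]
        flat = np.concatenate(
            [m, np.full((len(m), 1), 255, dtype=np.uint8)], axis=1).ravel()
        fwd, wpos = _seqs.packed_kmers(flat, spec.k)
        if len(fwd) == 0:
            continue
        canon, _ = _seqs.canonical_packed(fwd, spec.k)
        hit = _seqs.in_sorted(canon, spec.kmers)
        rows = wpos[hit] // (L + 1)
        out[lo : lo + len(m)] += np.bincount(rows, minlength=len(m))
    return out


def write_kept_fastq(reads: ReadSet, partition: ReadPartition,
                     path: str | Path) -> None:
    """Write the kept reads as FASTQ, preserving input order and ids."""
    from .simdata import _qual_line

    kept = set(partition.frame.loc[partition.frame["kept"] == 1, "read_id"])
    with _seqs._opener(path) as fh:
        for i, rid in enumerate(reads.ids):
            if rid not in kept:
                continue
            codes = reads.read_codes(i)
            fh.write(b"@" + rid.encode() + b"\n"
                     + _seqs._DECODE[codes].tobytes() + b"\n+\n"
                     + _qual_line(len(codes)) + b"\n")


def pair_rescue(partition: ReadPartition) -> ReadPartition:
    """Keep a mate pair when either mate passes (ids ending /1 and /2)."""
    frame = partition.frame.copy()
    base = frame["read_id"].str.replace(r"/[12]$", "", regex=True)
    kept_pairs = set(base[frame["kept"] == 1])
    frame["kept"] = base.isin(kept_pairs).astype(np.int8)
    return ReadPartition(partition.params, frame)


def evaluate_partition(partition: ReadPartition, truth: pd.DataFrame,
                       target_chrom: str = W_NAME) -> dict:
    """Precision/recall/F1 of the kept set against truth read origins.

    ``truth`` maps read_id to chromosome of origin (the simulator's read
    table).  Raises if any partitioned read lacks a truth record.
    """
    t = truth.set_index("read_id")["chromosome"] if "read_id" in truth.columns \
        else truth["chromosome"]
    ids = partition.frame["read_id"]
    missing = ids[~ids.isin(t.index)]
    if len(missing):
        raise KeyError(f"reads without truth records: {missing.tolist()[:5]}"
                       f"{'...' if len(missing) > 5 else ''}")
    origin = t.loc[ids].to_numpy()
    kept = partition.frame["kept"].to_numpy().astype(bool)
    is_target = origin == target_chrom
    tp = int((kept & is_target).sum())
    n_kept = int(kept.sum())
    n_target = int(is_target.sum())
    if n_kept == 0:
        warnings.warn("empty kept set: precision undefined (NaN)")
        precision = float("nan")
    else:
        precision = tp / n_kept
    recall = tp / n_target if n_target else float("nan")
    if precision > 0 and recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if (n_kept and n_target) else float("nan")
    confusion = (pd.DataFrame({"chromosome": origin, "kept": kept})
                 .groupby(["chromosome", "kept"]).size()
                 .unstack(fill_value=0))
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_kept": n_kept, "n_target": n_target, "tp": tp,
            "confusion": confusion}
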