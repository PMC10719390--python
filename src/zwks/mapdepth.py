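"""Unique-anchor read placement and sex-comparison depth diagnostics.

Instead of wrapping an external aligner, reads are placed against the
reference with exact unique k-mer anchors: every canonical k-mer that
occurs exactly once in the reference votes for the (chromosome, start,
strand) it implies, and a read is placed where the majority of its
anchors agree.  This is sufficient for substitution-only reads and
mirrors the MAPQ-style filtering of a production aligner: ambiguous or
repeat-only reads stay unplaced and are dropped from depth.

On top of the placements the module computes the two sex-comparison
diagnostics used to judge Z/W differentiation:

* the per-window log2(M/F) normalized depth ratio (expected ~1 on a
  fully differentiated Z, ~0 when W is undifferentiated from Z), and
* per-sample heterozygous-site counts, either from a naive pileup of
  the placed reads or from the GT fields of a VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seqs
from .simdata import ReadSet

log = logging.getLogger(__name__)


class MapParameterError(ValueError):
    pass


@dataclass
class ReferenceIndex:
    """Unique canonical k-mers of a reference with their coordinates."""

    k: int
    kmers: np.ndarray            # sorted unique uint64
    chrom_id: np.ndarray         # int16
    pos: np.ndarray              # int64, 0-based k-mer start
    fwd_is_canonical: np.ndarray  # bool: forward reference k-mer == canonical
    chrom_names: list[str]
    chrom_lengths: np.ndarray

    def __len__(self) -> int:
        return len(self.kmers)


def _as_ref_dict(reference) -> dict[str, np.ndarray]:
    if isinstance(reference, (str, Path)):
        return {name: _seqs.encode(seq)
                for name, seq in _seqs.read_fasta(reference)}
    return {name: (seq if isinstance(seq, np.ndarray) else _seqs.encode(seq))
            for name, seq in reference.items()}


def build_index(reference, k: int) -> ReferenceIndex:
    """Index the canonical k-mers that occur exactly once in the reference.

    A k-mer seen more than once (counting a k-mer and its reverse
    complement as one canonical occurrence) is excluded, so anchors are
    unambiguous by construction.
    """
    if not (3 <= k <= 31):
        raise MapParameterError(f"index k must be in [3, 31], got {k}")
    ref = _as_ref_dict(reference)
    names = list(ref.keys())
    lengths = np.array([len(c) for c in ref.values()], dtype=np.int64)
    if any(L < k for L in lengths):
        raise MapParameterError("reference sequence shorter than k")
    kmers, chrom_id, pos, fc = [], [], [], []
    for ci, codes in enumerate(ref.values()):
        fwd, p = _seqs.packed_kmers(codes, k)
        canon, fwd_canon = _seqs.canonical_packed(fwd, k)
        kmers.append(canon)
        chrom_id.append(np.full(len(p), ci, dtype=np.int16))
        pos.append(p)
        fc.append(fwd_canon)
    kmers = np.concatenate(kmers)
    chrom_id = np.concatenate(chrom_id)
    pos = np.concatenate(pos)
    fc = np.concatenate(fc)
    order = np.argsort(kmers, kind="stable")
    kmers, chrom_id, pos, fc = kmers[order], chrom_id[order], pos[order], fc[order]
    # keep singletons only
    if len(kmers):
        first = np.concatenate(([True], kmers[1:] != kmers[:-1]))
        last = np.concatenate((kmers[1:] != kmers[:-1], [True]))
        unique = first & last
        kmers, chrom_id, pos, fc = (kmers[unique], chrom_id[unique],
                                    pos[unique], fc[unique])
    return ReferenceIndex(k, kmers, chrom_id, pos, fc, names, lengths)


@dataclass
class Placements:
    """Per-read placement results; chrom == -1 means unplaced."""

    chrom_names: list[str]
    chrom_lengths: np.ndarray
    chrom: np.ndarray    # int32
    start: np.ndarray    # int64
    strand: np.ndarray   # int8 (0 '+', 1 '-')
    n_anchors: np.ndarray
    read_len: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.chrom)

    @property
    def placed(self) -> np.ndarray:
        return self.chrom >= 0

    @property
    def frac_placed(self) -> float:
        return float(self.placed.mean()) if len(self.chrom) else float("nan")


def _anchor_votes(canon: np.ndarray, offsets: np.ndarray,
                  read_fwd_canon: np.ndarray, read_len: int,
                  index: ReferenceIndex):
    """Map anchor k-mers to implied (chrom, start, strand) votes."""
    hit = _seqs.in_sorted(canon, index.kmers)
    if not hit.any():
        return None
    idx = np.searchsorted(index.kmers, canon[hit])
    off = offsets[hit]
    ref_pos = index.pos[idx]
    same = index.fwd_is_canonical[idx] == read_fwd_canon[hit]
    start = np.where(same, ref_pos - off, ref_pos + off + index.k - read_len)
    strand = np.where(same, 0, 1).astype(np.int8)
    return index.chrom_id[idx].astype(np.int64), start, strand, hit


def _vote_codes(chrom: np.ndarray, start: np.ndarray, strand: np.ndarray,
                read_len: int, index: ReferenceIndex) -> np.ndarray:
    base = int(index.chrom_lengths.max()) + 2 * read_len + 2
    return (chrom * base + (start + read_len)) * 2 + strand


def _decode_vote(code: int, read_len: int, index: ReferenceIndex):
    strand = code & 1
    v = code >> 1
    base = int(index.chrom_lengths.max()) + 2 * read_len + 2
    return v // base, v % base - read_len, strand


def place_read(codes: np.ndarray | str, index: ReferenceIndex,
               min_anchors: int = 3):
    """Place one read; returns (chrom_id, start, strand, n_anchors) or None.

    The winning (chromosome, start, strand) must collect at least
    ``min_anchors`` anchors and a strict majority of all anchor votes.
    """
    if isinstance(codes, str):
        codes = _seqs.encode(codes)
    L = len(codes)
    fwd, off = _seqs.packed_kmers(codes, index.k)
    if len(fwd) == 0:
        return None
    canon, fwd_canon = _seqs.canonical_packed(fwd, index.k)
    votes = _anchor_votes(canon, off, fwd_canon, L, index)
    if votes is None:
        return None
    chrom, start, strand, _ = votes
    code = _vote_codes(chrom, start, strand, L, index)
    uniq, counts = np.unique(code, return_counts=True)
    best = int(np.argmax(counts))
    if counts[best] < min_anchors or 2 * counts[best] <= counts.sum():
        return None
    c, s, st = _decode_vote(int(uniq[best]), L, index)
    return int(c), int(s), int(st), int(counts[best])


def _majority_by_row(vrow: np.ndarray, code: np.ndarray, n: int,
                     min_anchors: int, L: int, index: ReferenceIndex
                     ) -> tuple[np.ndarray, ...]:
    """Per-row strict-majority vote over (row, vote-code) pairs.

    ``vrow`` must be non-decreasing (window order within a flattened
    batch guarantees this).  Returns chrom/start/strand/n_anchor arrays
    of length ``n`` with chrom == -1 where no vote wins.
    """
    chrom = np.full(n, -1, dtype=np.int32)
    start = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    nanch = np.zeros(n, dtype=np.int32)
    if len(vrow) == 0:
        return chrom, start, strand, nanch
    shift = int(code.max()) + 1
    combo = np.sort(vrow * shift + code)
    new = np.concatenate(([True], combo[1:] != combo[:-1]))
    starts_idx = np.nonzero(new)[0]
    gr_row = combo[starts_idx] // shift
    gr_code = combo[starts_idx] % shift
    gr_cnt = np.diff(np.concatenate((starts_idx, [len(combo)])))

    order2 = np.lexsort((gr_code, gr_cnt, gr_row))
    rows2 = gr_row[order2]
    seg_new = np.concatenate(([True], rows2[1:] != rows2[:-1]))
    seg_start = np.nonzero(seg_new)[0]
    seg_end = np.concatenate((seg_start[1:], [len(rows2)])) - 1
    best = order2[seg_end]
    totals = np.add.reduceat(gr_cnt[order2], seg_start)
    best_cnt = gr_cnt[best]
    ok = (best_cnt >= min_anchors) & (2 * best_cnt > totals)
    rws = rows2[seg_start][ok].astype(np.int64)
    bcode = gr_code[best][ok]
    base = int(index.chrom_lengths.max()) + 2 * L + 2
    v = bcode >> 1
    chrom[rws] = (v // base).astype(np.int32)
    start[rws] = v % base - L
    strand[rws] = (bcode & 1).astype(np.int8)
    nanch[rws] = best_cnt[ok]
    return chrom, start, strand, nanch


def _votes_for_windows(fwd: np.ndarray, wpos: np.ndarray, L: int,
                       index: ReferenceIndex):
    canon, fwd_canon = _seqs.canonical_packed(fwd, index.k)
    off = wpos % (L + 1)
    votes = _anchor_votes(canon, off, fwd_canon, L, index)
    if votes is None:
        return None
    vchrom, vstart, vstrand, hit = votes
    vrow = (wpos[hit] // (L + 1)).astype(np.int64)
    return vrow, _vote_codes(vchrom, vstart, vstrand, L, index)


def _place_matrix(matrix: np.ndarray, index: ReferenceIndex,
                  min_anchors: int, anchor_stride: int) -> tuple[np.ndarray, ...]:
    """Two-pass placement of a uniform-length read batch.

    Pass 1 votes with anchors sampled every ``anchor_stride`` positions
    (seed sampling); reads without a winning majority are re-anchored
    exhaustively in pass 2, so sampling only ever costs speed on clean
    reads, never a placement the full anchor set would have found.
    """
    n, L = matrix.shape
    flat = np.concatenate(
        [matrix, np.full((n, 1), 255, dtype=np.uint8)], axis=1).ravel()
    fwd, wpos = _seqs.packed_kmers(flat, index.k)
    if len(fwd) == 0:
        return (np.full(n, -1, dtype=np.int32), np.zeros(n, dtype=np.int64),
                np.zeros(n, dtype=np.int8), np.zeros(n, dtype=np.int32))

    sampled = (wpos % (L + 1)) % anchor_stride == 0
    votes = _votes_for_windows(fwd[sampled], wpos[sampled], L, index)
    if votes is None:
        chrom = np.full(n, -1, dtype=np.int32)
        start = np.zeros(n, dtype=np.int64)
        strand = np.zeros(n, dtype=np.int8)
        nanch = np.zeros(n, dtype=np.int32)
    else:
        chrom, start, strand, nanch = _majority_by_row(
            votes[0], votes[1], n, min_anchors, L, index)

    if anchor_stride > 1:
        redo = np.nonzero(chrom < 0)[0]
        if len(redo):
            sel = np.isin(wpos // (L + 1), redo)
            votes = _votes_for_windows(fwd[sel], wpos[sel], L, index)
            if votes is not None:
                c2, s2, st2, a2 = _majority_by_row(
                    votes[0], votes[1], n, min_anchors, L, index)
                upd = c2 >= 0
                chrom[upd], start[upd] = c2[upd], s2[upd]
                strand[upd], nanch[upd] = st2[upd], a2[upd]
    return chrom, start, strand, nanch


def place_reads(reads: ReadSet, index: ReferenceIndex, min_anchors: int = 3,
                anchor_stride: int = 8,
                batch_size: int = 100_000) -> Placements:
    """Place all reads of a read set (vectorised for uniform-length reads).

    ``anchor_stride`` samples every s-th anchor first and falls back to
    the full anchor set for reads the sample cannot place; stride 1 is
    the exhaustive mapper.  Variable-length (long) reads always use the
    full anchor set.
    """
    n = reads.n_reads
    chrom = np.full(n, -1, dtype=np.int32)
    start = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    nanch = np.zeros(n, dtype=np.int32)
    read_len = np.zeros(n, dtype=np.int64)
    if reads.matrix is not None:
        read_len[:] = reads.matrix.shape[1]
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            c, s, st, a = _place_matrix(reads.matrix[lo:hi], index,
                                        min_anchors, anchor_stride)
            chrom[lo:hi], start[lo:hi] = c, s
            strand[lo:hi], nanch[lo:hi] = st, a
    else:
        for i in range(n):
            codes = reads.seqs[i]
            read_len[i] = len(codes)
            res = place_read(codes, index, min_anchors)
            if res is not None:
                chrom[i], start[i], strand[i], nanch[i] = res
    return Placements(index.chrom_names, index.chrom_lengths,
                      chrom, start, strand, nanch, read_len)


# ---------------------------------------------------------------------------
# depth


def _coverage_by_chrom(placements: Sequence[Placements],
                       chrom_names: list[str],
                       chrom_lengths: np.ndarray) -> dict[str, np.ndarray]:
    cov = {name: np.zeros(int(L) + 1, dtype=np.int64)
           for name, L in zip(chrom_names, chrom_lengths)}
    for pl in placements:
        for ci, name in enumerate(chrom_names):
            L = int(chrom_lengths[ci])
            sel = pl.chrom == ci
            if not sel.any():
                continue
            s = np.clip(pl.start[sel], 0, L)
            e = np.clip(pl.start[sel] + pl.read_len[sel], 0, L)
            d = cov[name]
            np.add.at(d, s, 1)
            np.add.at(d, e, -1)
    return {name: np.cumsum(d[:-1]) for name, d in cov.items()}


def _window_means(depth: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = len(depth)
    starts = np.arange(0, L, window, dtype=np.int64)
    ends = np.minimum(starts + window, L)
    cs = np.concatenate(([0], np.cumsum(depth)))
    means = (cs[ends] - cs[starts]) / (ends - starts)
    return starts, ends, means


@dataclass
class DepthTrack:
    """Per-window placed-read depth per sex group with log2(M/F) ratio."""

    frame: pd.DataFrame  # chrom, start, end, M, F, norm_M, norm_F, log2_ratio

    def chrom_mean(self, chrom: str) -> float:
        sel = self.frame["chrom"] == chrom
        vals = self.frame.loc[sel, "log2_ratio"]
        return float(np.nanmean(vals)) if sel.any() else float("nan")

    def mean_over(self, chroms: Sequence[str]) -> float:
        sel = self.frame["chrom"].isin(list(chroms))
        return float(np.nanmean(self.frame.loc[sel, "log2_ratio"]))

    def per_chromosome(self) -> pd.Series:
        return self.frame.groupby("chrom")["log2_ratio"].mean()

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DepthTrack":
        return cls(pd.read_csv(path, sep="\t"))


def depth_log2_ratio(male_placements: Sequence[Placements],
                     female_placements: Sequence[Placements],
                     window: int = 1_000,
                     autosome_names: Sequence[str] | None = None) -> DepthTrack:
    """Windowed log2 ratio of male over female normalized placed-read depth.

    Each sex group is normalized by the median of its autosomal window
    depths, so the statistic reads ~1 on a fully differentiated Z (males
    carry two Z copies, females one) and ~0 everywhere copy number is
    equal.  Windows where either normalized depth is zero get NaN.
    """
    if not male_placements or not female_placements:
        raise MapParameterError("both sex groups need at least one placement set")
    names = male_placements[0].chrom_names
    lengths = male_placements[0].chrom_lengths
    if autosome_names is None:
        autosome_names = [n for n in names
                          if n not in ("chrZ", "chrW", "Z", "W")]
    cov_m = _coverage_by_chrom(male_placements, names, lengths)
    cov_f = _coverage_by_chrom(female_placements, names, lengths)
    rows = []
    for name in names:
        starts, ends, m = _window_means(cov_m[name], window)
        _, _, f = _window_means(cov_f[name], window)
        for s, e, mm, ff in zip(starts, ends, m, f):
            rows.append((name, int(s), int(e), mm, ff))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "M", "F"])
    auto = df["chrom"].isin(autosome_names)
    if not auto.any():
        raise MapParameterError("no autosomal windows available for normalization")
    med_m = float(df.loc[auto, "M"].median())
    med_f = float(df.loc[auto, "F"].median())
    if med_m <= 0 or med_f <= 0:
        raise MapParameterError("zero median autosomal depth; cannot normalize")
    df["norm_M"] = df["M"] / med_m
    df["norm_F"] = df["F"] / med_f
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(df["norm_M"] / df["norm_F"])
    ratio[(df["norm_M"] <= 0) | (df["norm_F"] <= 0)] = np.nan
    df["log2_ratio"] = ratio
    return DepthTrack(df)


# ---------------------------------------------------------------------------
# heterozygosity


def _pileup_counts(reads: ReadSet, placements: Placements, ci: int,
                   L: int) -> np.ndarray:
    """Base-count matrix (L, 4) from reads placed on chromosome ``ci``."""
    counts = np.zeros(L * 4, dtype=np.int64)
    sel = np.nonzero(placements.chrom == ci)[0]
    if len(sel) == 0:
        return counts.reshape(L, 4)
    if reads.matrix is not None:
        rl = reads.matrix.shape[1]
        ar = np.arange(rl)
        for lo in range(0, len(sel), 200_000):
            part = sel[lo : lo + 200_000]
            mats = reads.matrix[part].copy()
            rev = placements.strand[part] == 1
            mats[rev] = (3 - mats[rev][:, ::-1])
            pos = placements.start[part][:, None] + ar
            ok = (pos >= 0) & (pos < L)
            key = pos * 4 + mats
            counts += np.bincount(key[ok].ravel(), minlength=L * 4)[: L * 4]
    else:
        for i in sel:
            codes = reads.seqs[i]
            if placements.strand[i] == 1:
                codes = (3 - codes[::-1]).astype(np.uint8)
            s = placements.start[i]
            pos = np.arange(s, s + len(codes))
            ok = (pos >= 0) & (pos < L)
            counts += np.bincount(pos[ok] * 4 + codes[ok], minlength=L * 4)[: L * 4]
    return counts.reshape(L, 4)


def call_het_sites(placed: Sequence[tuple[ReadSet, Placements]],
                   reference, min_depth: int = 5,
                   min_allele_frac: float = 0.3) -> pd.DataFrame:
    """Naive pileup heterozygous-site counts per sample and chromosome.

    A column is heterozygous when its depth is at least ``min_depth``
    and the second-most-frequent base has fraction within
    [min_allele_frac, 1 - min_allele_frac].  Not a production variant
    caller: valid only for the simulator's substitution-only reads.
    """
    ref = _as_ref_dict(reference)
    rows = []
    for reads, placements in placed:
        for ci, name in enumerate(placements.chrom_names):
            if name not in ref:
                continue
            L = len(ref[name])
            counts = _pileup_counts(reads, placements, ci, L)
            depth = counts.sum(axis=1)
            part = np.partition(counts, 2, axis=1)
            second = part[:, 2]
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(depth > 0, second / depth, 0.0)
            het = ((depth >= min_depth) & (frac >= min_allele_frac)
                   & (frac <= 1 - min_allele_frac))
            rows.append((reads.individual, name, int(het.sum()), "pileup"))
    return pd.DataFrame(rows, columns=["sample", "chrom", "n_het", "source"])


def count_het_from_vcf(vcf_path: str | Path,
                       samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per sample x chromosome heterozygous-genotype counts from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    all_samples = list(vcf.samples)
    if samples is None:
        samples = all_samples
    missing = [s for s in samples if s not in all_samples]
    if missing:
        raise KeyError(f"samples absent from VCF: {missing}")
    cols = [all_samples.index(s) for s in samples]
    counts: dict[tuple[str, str], int] = {}
    for v in vcf:
        gts = v.genotypes
        for s, ci in zip(samples, cols):
            a = gts[ci]
            if len(a) >= 2 and a[0] >= 0 and a[1] >= 0 and a[0] != a[1]:
                key = (s, v.CHROM)
                counts[key] = counts.get(key, 0) + 1
    rows = [(s, c, n, "vcf") for (s, c), n in sorted(counts.items())]
    # samples with zero het calls still get a row (count 0, no chrom split)
    seen = {s for s, _, _, _ in rows}
    for s in samples:
        if s not in seen:
            rows.append((s, ".", 0, "vcf"))
    return pd.DataFrame(rows, columns=["sample", "chrom", "n_het", "source"])


# ---------------------------------------------------------------------------
# coverage summary


@dataclass
class CoverageStats:
    frac_bases_covered: float
    frac_reads_placed: float
    min_depth: int
    total_bases: int
    covered_bases: int


def coverage_stats(placements: Sequence[Placements], reference,
                   min_depth: int = 5) -> CoverageStats:
    """Fraction of reference bases at depth >= min_depth and reads placed."""
    ref = _as_ref_dict(reference)
    names = list(ref.keys())
    lengths = np.array([len(c) for c in ref.values()], dtype=np.int64)
    cov = _coverage_by_chrom(placements, names, lengths)
    total = int(lengths.sum())
    covered = int(sum(int((d >= min_depth).sum()) for d in cov.values()))
    n_reads = sum(p.n_reads for p in placements)
    n_placed = sum(int(p.placed.sum()) for p in placements)
    frac_placed = n_placed / n_reads if n_reads else float("nan")
    frac_cov = covered / total if total else 0.0
    return CoverageStats(frac_cov, frac_placed, min_depth, total, covered)
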