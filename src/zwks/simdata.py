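"""Synthetic ZW genomes, diploid populations and reads with truth labels.

The generator emulates the study design the screening procedure was
built for: a male reference (autosomes + Z), a female W derived from Z
by point substitutions (~4% divergence by default, i.e. ~96% Z-W
identity) plus a repeat expansion unique to W, a resequencing panel of
ZW females and ZZ males carrying population heterozygous sites, and
substitution-only short paired reads and HiFi-like long reads.  Every
read carries a truth record (individual, chromosome, haplotype, span,
strand) and every planted variant is ledgered, so each downstream stage
can be scored exactly.

All randomness flows from ``SimConfig.seed`` through fixed-offset
substreams (``default_rng([seed, stage, index])``), making every output
byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import _seqs
from ._seqs import random_codes

log = logging.getLogger(__name__)

# substream offsets, one per generation stage
_STAGE_GENOME = 1
_STAGE_INDIVIDUALS = 2
_STAGE_SHORT = 3
_STAGE_LONG = 4

Z_NAME = "chrZ"
W_NAME = "chrW"


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic ZW system.

    Defaults are the desk-scale panel all diagnostics are exercised on:
    a ~1 Mb male reference (two 300 kb autosomes + 300 kb Z), 4% Z-W
    divergence with a 5% repeat expansion on W, 5 females / 5 males at
    20x short-read coverage, and HiFi-like long reads (lognormal mean
    15 kb, 0.2% substitution error).
    """

    seed: int = 0
    k: int = 17
    autosome_lengths: tuple[int, ...] = (300_000, 300_000)
    z_length: int = 300_000
    zw_divergence: float = 0.04
    w_fully_differentiated: bool = False
    w_repeat_fraction: float = 0.05
    repeat_unit_length: int = 500
    n_females: int = 5
    n_males: int = 5
    pop_het_rate: float = 1e-3
    short_read_length: int = 150
    short_insert_mean: float = 350.0
    short_insert_sd: float = 35.0
    short_coverage: float = 20.0
    short_error: float = 0.002
    long_read_mean: float = 15_000.0
    long_read_sd: float = 5_000.0
    long_min_length: int = 1_000
    long_max_length: int = 50_000
    long_coverage: float = 15.0
    long_error: float = 0.002

    def validate(self) -> None:
        k = self.k
        if not (3 <= k <= 31):
            raise SimConfigError(f"k must be in [3, 31], got {k}")
        for name, L in [("z_length", self.z_length),
                        ("repeat_unit_length", self.repeat_unit_length),
                        *[(f"autosome {i}", L)
                          for i, L in enumerate(self.autosome_lengths)]]:
            if L <= 2 * k:
                raise SimConfigError(f"{name} must exceed 2k={2 * k}, got {L}")
        for name, r in [("zw_divergence", self.zw_divergence),
                        ("w_repeat_fraction", self.w_repeat_fraction),
                        ("pop_het_rate", self.pop_het_rate),
                        ("short_error", self.short_error),
                        ("long_error", self.long_error)]:
            if not (0.0 <= r < 1.0):
                raise SimConfigError(f"{name} must be in [0, 1), got {r}")
        if self.n_females < 1 or self.n_males < 1:
            raise SimConfigError("need at least one individual per sex")
        if self.short_read_length < k:
            raise SimConfigError("short_read_length must be >= k")
        if self.long_min_length < k or self.long_max_length < self.long_min_length:
            raise SimConfigError("invalid long-read length truncation bounds")

    def with_updates(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class Haplotype:
    chrom: str
    copy: int  # 0/1 within a pair, 0 for single-copy Z/W in females
    codes: np.ndarray


@dataclass
class Individual:
    name: str
    sex: str  # "F" or "M"
    haplotypes: list[Haplotype]

    @property
    def chromosomes(self) -> set[str]:
        return {h.chrom for h in self.haplotypes}


@dataclass
class SimGenome:
    """Male reference + W + (once populated) per-individual haplotypes."""

    config: SimConfig
    male_reference: dict[str, np.ndarray]  # autosomes + Z, code arrays
    w_sequence: np.ndarray
    zw_divergent_sites: np.ndarray  # Z coords differing in W (pre-insertion)
    w_insertions: list[tuple[int, int]]  # (start in final W coords, length)
    repeat_unit: np.ndarray | None
    individuals: list[Individual] = field(default_factory=list)

    @property
    def chrom_names(self) -> list[str]:
        return [*self.male_reference.keys(), W_NAME]

    def chrom_length(self, name: str) -> int:
        if name == W_NAME:
            return len(self.w_sequence)
        return len(self.male_reference[name])

    def reference_with_w(self) -> dict[str, np.ndarray]:
        return {**self.male_reference, W_NAME: self.w_sequence}


@dataclass
class ReadSet:
    """Reads of one individual with embedded truth labels.

    Short paired reads live in a uniform-length ``matrix`` (mates
    interleaved: rows 2i, 2i+1 are fragment i); long reads in ``seqs``.
    Truth arrays are parallel to reads: chromosome index (into
    ``chrom_names``), haplotype copy, 0-based half-open span on that
    haplotype, and strand (0='+', 1='-').
    """

    individual: str
    sex: str
    kind: str  # "short" | "long"
    ids: list[str]
    chrom_names: list[str]
    truth_chrom: np.ndarray
    truth_hap: np.ndarray
    truth_start: np.ndarray
    truth_end: np.ndarray
    truth_strand: np.ndarray
    matrix: np.ndarray | None = None
    seqs: list[np.ndarray] | None = None

    @property
    def n_reads(self) -> int:
        return len(self.ids)

    def read_codes(self, i: int) -> np.ndarray:
        if self.matrix is not None:
            return self.matrix[i]
        return self.seqs[i]

    def iter_codes(self) -> Iterator[np.ndarray]:
        for i in range(self.n_reads):
            yield self.read_codes(i)

    def truth_frame(self) -> pd.DataFrame:
        names = np.array(self.chrom_names)
        return pd.DataFrame({
            "read_id": self.ids,
            "individual": self.individual,
            "chromosome": names[self.truth_chrom],
            "haplotype": self.truth_hap,
            "start": self.truth_start,
            "end": self.truth_end,
            "strand": np.where(self.truth_strand == 0, "+", "-"),
        })


@dataclass
class SimTruth:
    """Read-origin table plus planted-variant ledgers."""

    reads: pd.DataFrame
    het_sites: pd.DataFrame
    zw_divergent_sites: np.ndarray

    @classmethod
    def build(cls, genome: SimGenome, readsets: list[ReadSet],
              het_sites: pd.DataFrame | None = None) -> "SimTruth":
        frames = [rs.truth_frame() for rs in readsets]
        reads = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["read_id", "individual", "chromosome",
                                            "haplotype", "start", "end", "strand"]))
        if het_sites is None:
            het_sites = pd.DataFrame(
                columns=["individual", "sex", "chrom", "hap", "pos", "ref", "alt"])
        return cls(reads, het_sites, genome.zw_divergent_sites)

    def write_reads_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_reads_tsv(cls, path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genome


def _substitute(codes: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Replace bases at ``positions`` with a uniformly different base."""
    if len(positions) == 0:
        return codes
    shift = rng.integers(1, 4, size=len(positions)).astype(np.uint8)
    codes[positions] = (codes[positions] + shift) % 4
    return codes


def _reference_canonical_kmers(ref: dict[str, np.ndarray], k: int) -> np.ndarray:
    parts = []
    for codes in ref.values():
        fwd, _ = _seqs.packed_kmers(codes, k)
        canon, _ = _seqs.canonical_packed(fwd, k)
        parts.append(canon)
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)


def _scrub_shared_kmers(w: np.ndarray, ref_kmers: np.ndarray, k: int,
                        rng: np.random.Generator, max_rounds: int = 100) -> np.ndarray:
    """Mutate W until it shares no canonical k-mer with the reference set."""
    for _ in range(max_rounds):
        fwd, pos = _seqs.packed_kmers(w, k)
        canon, _ = _seqs.canonical_packed(fwd, k)
        shared = pos[_seqs.in_sorted(canon, ref_kmers)]
        if len(shared) == 0:
            return w
        # one substitution per offending window, at its centre
        targets = np.unique(shared + k // 2)
        _substitute(w, targets, rng)
    raise RuntimeError("could not scrub shared k-mers from W")


def simulate_genome(config: SimConfig) -> SimGenome:
    """Build the male reference (autosomes + Z) and the female W.

    W starts as a copy of Z with point substitutions at
    ``zw_divergence`` per site (sites ledgered), or as an independent
    random sequence sharing no canonical k-mer with the reference when
    ``w_fully_differentiated`` is set.  Repeat expansion then inserts
    tandem copies of a single random unit totalling
    ``w_repeat_fraction * z_length`` bases at uniform positions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_GENOME])
    ref: dict[str, np.ndarray] = {}
    for i, L in enumerate(config.autosome_lengths):
        ref[f"chr{i + 1}"] = random_codes(L, rng)
    ref[Z_NAME] = random_codes(config.z_length, rng)

    divergent = np.empty(0, dtype=np.int64)
    if config.w_fully_differentiated:
        w = random_codes(config.z_length, rng)
    elif config.zw_divergence > 0:
        w = ref[Z_NAME].copy()
        divergent = np.nonzero(rng.random(len(w)) < config.zw_divergence)[0]
        _substitute(w, divergent, rng)
    else:
        w = ref[Z_NAME].copy()

    unit = None
    insertions: list[tuple[int, int]] = []
    if config.w_repeat_fraction > 0:
        unit = random_codes(config.repeat_unit_length, rng)
        n_copies = int(round(config.w_repeat_fraction * config.z_length
                             / config.repeat_unit_length))
        if n_copies:
            sites = np.sort(rng.integers(0, len(w) + 1, size=n_copies))
            pieces, prev = [], 0
            for j, s in enumerate(sites):
                pieces.append(w[prev:s])
                pieces.append(unit)
                # final coordinate accounts for previously inserted copies
                insertions.append((int(s) + j * len(unit), len(unit)))
                prev = s
            pieces.append(w[prev:])
            w = np.concatenate(pieces)

    if config.w_fully_differentiated:
        ref_kmers = _reference_canonical_kmers(ref, config.k)
        w = _scrub_shared_kmers(w, ref_kmers, config.k, rng)

    return SimGenome(config=config, male_reference=ref, w_sequence=w,
                     zw_divergent_sites=divergent, w_insertions=insertions,
                     repeat_unit=unit)


# ---------------------------------------------------------------------------
# individuals


def simulate_individuals(genome: SimGenome,
                         config: SimConfig | None = None
                         ) -> tuple[SimGenome, pd.DataFrame]:
    """Populate the genome with diploid individuals and plant het sites.

    Chromosome pairs (autosomes; the male ZZ pair) receive substitutions
    at ``pop_het_rate`` per site, each on one randomly chosen haplotype,
    so a pair is heterozygous at those sites.  Single-copy chromosomes
    (female Z and W) are mutated at half that rate per copy, keeping
    per-copy variant density equal across karyotypes.

    Returns the populated genome and the planted-variant ledger
    (individual, sex, chrom, hap, pos, ref, alt).
    """
    config = config or genome.config
    rows: list[tuple] = []
    individuals: list[Individual] = []
    roster = ([("F", i) for i in range(config.n_females)]
              + [("M", i) for i in range(config.n_males)])
    bases = "ACGT"
    for idx, (sex, i) in enumerate(roster):
        rng = np.random.default_rng([config.seed, _STAGE_INDIVIDUALS, idx])
        name = f"{sex}{i + 1}"
        haps: list[Haplotype] = []

        def plant(chrom: str, source: np.ndarray, copy: int, rate: float) -> Haplotype:
            codes = source.copy()
            pos = np.nonzero(rng.random(len(codes)) < rate)[0]
            refb = codes[pos].copy()
            _substitute(codes, pos, rng)
            for p, rb, ab in zip(pos, refb, codes[pos]):
                rows.append((name, sex, chrom, copy, int(p),
                             bases[rb], bases[ab]))
            return Haplotype(chrom, copy, codes)

        for chrom, ref_codes in genome.male_reference.items():
            if chrom == Z_NAME:
                continue
            # pair-level het rate: plant all sites once, split between copies
            codes0, codes1 = ref_codes.copy(), ref_codes.copy()
            pos = np.nonzero(rng.random(len(ref_codes)) < config.pop_het_rate)[0]
            which = rng.integers(0, 2, size=len(pos))
            for copy, codes in ((0, codes0), (1, codes1)):
                p = pos[which == copy]
                refb = codes[p].copy()
                _substitute(codes, p, rng)
                for pp, rb, ab in zip(p, refb, codes[p]):
                    rows.append((name, sex, chrom, copy, int(pp),
                                 bases[rb], bases[ab]))
            haps.append(Haplotype(chrom, 0, codes0))
            haps.append(Haplotype(chrom, 1, codes1))

        z_ref = genome.male_reference[Z_NAME]
        if sex == "M":
            codes0, codes1 = z_ref.copy(), z_ref.copy()
            pos = np.nonzero(rng.random(len(z_ref)) < config.pop_het_rate)[0]
            which = rng.integers(0, 2, size=len(pos))
            for copy, codes in ((0, codes0), (1, codes1)):
                p = pos[which == copy]
                refb = codes[p].copy()
                _substitute(codes, p, rng)
                for pp, rb, ab in zip(p, refb, codes[p]):
                    rows.append((name, sex, Z_NAME, copy, int(pp),
                                 bases[rb], bases[ab]))
            haps.append(Haplotype(Z_NAME, 0, codes0))
            haps.append(Haplotype(Z_NAME, 1, codes1))
        else:
            haps.append(plant(Z_NAME, z_ref, 0, config.pop_het_rate / 2))
            haps.append(plant(W_NAME, genome.w_sequence, 0,
                              config.pop_het_rate / 2))
        individuals.append(Individual(name, sex, haps))

    genome.individuals = individuals
    ledger = pd.DataFrame(
        rows, columns=["individual", "sex", "chrom", "hap", "pos", "ref", "alt"])
    return genome, ledger


# ---------------------------------------------------------------------------
# reads


def _apply_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    err = rng.random(arr.shape) < rate
    n = int(err.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        arr[err] = (arr[err] + shift) % 4


def _hap_layout(ind: Individual) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([len(h.codes) for h in ind.haplotypes], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    cat = np.concatenate([h.codes for h in ind.haplotypes])
    return lengths, offsets, cat


def _simulate_short(ind: Individual, config: SimConfig, chrom_names: list[str],
                    rng: np.random.Generator) -> ReadSet:
    rl = config.short_read_length
    lengths, offsets, cat = _hap_layout(ind)
    total = int(lengths.sum())
    n_frag = int(round(config.short_coverage * (total / 2) / (2 * rl)))
    if n_frag == 0:
        log.warning("zero short-read coverage for %s: emitting no reads", ind.name)
    frag_len = np.clip(
        np.rint(rng.normal(config.short_insert_mean, config.short_insert_sd,
                           n_frag)).astype(np.int64),
        2 * rl, None)
    hap_idx = rng.choice(len(lengths), size=n_frag, p=lengths / total)
    frag_len = np.minimum(frag_len, lengths[hap_idx])
    start = np.floor(rng.random(n_frag)
                     * (lengths[hap_idx] - frag_len + 1)).astype(np.int64)
    minus = rng.integers(0, 2, size=n_frag).astype(np.int8)

    g = offsets[hap_idx] + start
    ar = np.arange(rl)
    left = cat[g[:, None] + ar]
    right = cat[(g + frag_len - rl)[:, None] + ar]
    rc_right = (3 - right[:, ::-1]).astype(np.uint8)
    plus = (minus == 0)[:, None]
    # plus fragment: R1 = forward left end, R2 = revcomp right end;
    # minus fragment: sequencing starts from the other end, so the roles swap
    r1 = np.where(plus, left, rc_right).astype(np.uint8)
    r2 = np.where(plus, rc_right, left).astype(np.uint8)

    _apply_errors(r1, config.short_error, rng)
    _apply_errors(r2, config.short_error, rng)

    matrix = np.empty((2 * n_frag, rl), dtype=np.uint8)
    matrix[0::2] = r1
    matrix[1::2] = r2

    cidx = np.array([chrom_names.index(h.chrom) for h in ind.haplotypes],
                    dtype=np.int16)
    hcopy = np.array([h.copy for h in ind.haplotypes], dtype=np.int8)
    tchrom = np.empty(2 * n_frag, dtype=np.int16)
    thap = np.empty(2 * n_frag, dtype=np.int8)
    tstart = np.empty(2 * n_frag, dtype=np.int64)
    tstrand = np.empty(2 * n_frag, dtype=np.int8)
    tchrom[0::2] = tchrom[1::2] = cidx[hap_idx]
    thap[0::2] = thap[1::2] = hcopy[hap_idx]
    left_start, right_start = start, start + frag_len - rl
    tstart[0::2] = np.where(minus == 0, left_start, right_start)
    tstart[1::2] = np.where(minus == 0, right_start, left_start)
    tstrand[0::2] = minus
    tstrand[1::2] = 1 - minus
    ids = [f"{ind.name}_s{i:07d}/{m}" for i in range(n_frag) for m in (1, 2)]
    return ReadSet(individual=ind.name, sex=ind.sex, kind="short", ids=ids,
                   chrom_names=chrom_names, truth_chrom=tchrom, truth_hap=thap,
                   truth_start=tstart, truth_end=tstart + rl,
                   truth_strand=tstrand, matrix=matrix)


def _simulate_long(ind: Individual, config: SimConfig, chrom_names: list[str],
                   rng: np.random.Generator) -> ReadSet:
    lengths, offsets, cat = _hap_layout(ind)
    total = int(lengths.sum())
    n = int(round(config.long_coverage * (total / 2) / config.long_read_mean))
    if n == 0:
        log.warning("zero long-read coverage for %s: emitting no reads", ind.name)
    sigma2 = np.log(1 + (config.long_read_sd / config.long_read_mean) ** 2)
    mu = np.log(config.long_read_mean) - sigma2 / 2
    lens = np.rint(rng.lognormal(mu, np.sqrt(sigma2), size=n)).astype(np.int64)
    lens = np.clip(lens, config.long_min_length, config.long_max_length)
    hap_idx = rng.choice(len(lengths), size=n, p=lengths / total)
    lens = np.minimum(lens, lengths[hap_idx])
    start = np.floor(rng.random(n) * (lengths[hap_idx] - lens + 1)).astype(np.int64)
    minus = rng.integers(0, 2, size=n).astype(np.int8)

    seqs: list[np.ndarray] = []
    for i in range(n):
        g = offsets[hap_idx[i]] + start[i]
        codes = cat[g : g + lens[i]].copy()
        if minus[i]:
            codes = (3 - codes[::-1]).astype(np.uint8)
        _apply_errors(codes, config.long_error, rng)
        seqs.append(codes)

    cidx = np.array([chrom_names.index(h.chrom) for h in ind.haplotypes],
                    dtype=np.int16)
    hcopy = np.array([h.copy for h in ind.haplotypes], dtype=np.int8)
    ids = [f"{ind.name}_l{i:06d}" for i in range(n)]
    return ReadSet(individual=ind.name, sex=ind.sex, kind="long", ids=ids,
                   chrom_names=chrom_names, truth_chrom=cidx[hap_idx],
                   truth_hap=hcopy[hap_idx], truth_start=start,
                   truth_end=start + lens, truth_strand=minus, seqs=seqs)


def simulate_reads(genome: SimGenome, config: SimConfig | None = None,
                   kind: str = "short") -> list[ReadSet]:
    """Simulate reads for every individual; one :class:`ReadSet` each.

    Fragments/reads are drawn uniformly across both haplotypes, so each
    haplotype copy is covered at half the configured coverage.  Errors
    are substitutions only at the configured per-base rate.
    """
    config = config or genome.config
    if not genome.individuals:
        raise SimConfigError("simulate_individuals must run before simulate_reads")
    if kind not in ("short", "long"):
        raise SimConfigError(f"unknown read kind {kind!r}")
    stage = _STAGE_SHORT if kind == "short" else _STAGE_LONG
    chrom_names = genome.chrom_names
    out = []
    for idx, ind in enumerate(genome.individuals):
        rng = np.random.default_rng([config.seed, stage, idx])
        fn = _simulate_short if kind == "short" else _simulate_long
        out.append(fn(ind, config, chrom_names, rng))
    return out


# ---------------------------------------------------------------------------
# on-disk artifacts


_Q30_LINE_CACHE: dict[int, bytes] = {}


def _qual_line(n: int) -> bytes:
    if n not in _Q30_LINE_CACHE:
        _Q30_LINE_CACHE[n] = b"?" * n  # constant Q30, Phred+33
    return _Q30_LINE_CACHE[n]


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """Write reads as FASTQ (gzipped if the path ends in .gz), Q30 qualities."""
    with _seqs._opener(path) as fh:
        buf = bytearray()
        for i, rid in enumerate(readset.ids):
            codes = readset.read_codes(i)
            buf += b"@" + rid.encode() + b"\n"
            buf += _seqs._DECODE[codes].tobytes() + b"\n+\n"
            buf += _qual_line(len(codes)) + b"\n"
            if len(buf) > 8_000_000:
                fh.write(bytes(buf))
                buf.clear()
        fh.write(bytes(buf))


def write_reference_fasta(genome: SimGenome, directory: str | Path) -> dict[str, Path]:
    """Write male_reference.fa (autosomes + Z) and w_chromosome.fa."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref_path = directory / "male_reference.fa"
    w_path = directory / "w_chromosome.fa"
    _seqs.write_fasta(ref_path, genome.male_reference.items())
    _seqs.write_fasta(w_path, [(W_NAME, genome.w_sequence)])
    return {"male_reference": ref_path, "w_chromosome": w_path}


def write_het_vcf(genome: SimGenome, het_ledger: pd.DataFrame,
                  path: str | Path) -> None:
    """Write the planted het sites as a minimal VCFv4.2 with GT fields.

    Each planted site is heterozygous (0/1 or higher ALT index) in its
    carrier and homozygous reference in everyone else.
    """
    samples = [ind.name for ind in genome.individuals]
    ref_seqs = genome.reference_with_w()
    bases = "ACGT"
    by_site: dict[tuple[str, int], dict] = {}
    for row in het_ledger.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        site = by_site.setdefault(key, {"alts": [], "gt": {}})
        if row.alt not in site["alts"]:
            site["alts"].append(row.alt)
        site["gt"][row.individual] = site["alts"].index(row.alt) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, codes in ref_seqs.items():
            fh.write(f"##contig=<ID={name},length={len(codes)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos) in sorted(by_site, key=lambda x: (x[0], x[1])):
            site = by_site[(chrom, pos)]
            ref_base = bases[ref_seqs[chrom][pos]]
            alts = ",".join(site["alts"])
            gts = []
            for s in samples:
                a = site["gt"].get(s)
                gts.append("0/0" if a is None else f"0/{a}")
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref_base}\t{alts}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
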