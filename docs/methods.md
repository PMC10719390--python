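# Methods

## Problem setting

In a ZZ/ZW system, females are the heterogametic sex: they carry one Z
and one W chromosome, males two Z. When the W is young ("nascent"), it
is nearly identical to Z in sequence, so a standard assembly collapses
Z and W into a single mosaic chromosome and the W cannot be phased out
by coverage alone. `zwks` implements the population-k-mer route around
this: k-mers carried by every female but by no male are necessarily
W-linked, and reads containing them can be binned out for a W-only
assembly. The package provides that screen exactly, plus the
diagnostics used to judge how differentiated the pair actually is.

## The sex-specific k-mer screen

For female panel k-mer sets `f_1..f_n` and male sets `m_1..m_n` (all
canonical, exact counts), the specific set is

```
spec = difference( intersect_all( filter_min_count(f_i, c_F) for all i ),
                   union_sum(m_1..m_n) )
```

* `k = 17` by default. A 17-mer is long enough that a random collision
  across a sub-gigabase genome is rare (4^17 ≈ 1.7×10^10) and short
  enough to be well sampled at 20x coverage.
* `c_F = 5` (`min_count_female`): a k-mer seen fewer than 5 times in an
  individual is indistinguishable from sequencing-error noise at
   double-digit coverage, so it cannot attest presence.
* Male side: any single occurrence disqualifies (`min_count_male = 1`).
  This is the conservative choice — a W-linked k-mer can only be lost
  this way if a male read *errors into* exactly that k-mer, whereas any
  relaxation admits male-genome k-mers wholesale. The threshold is
  configurable because at very deep male coverage error-derived
  collisions do become the dominant false-negative mode.

Canonicalization (lexicographic min of a k-mer and its reverse
complement) is always on: reads are strand-agnostic, so any screen that
must find a genomic k-mer in a read has to count both strands as one.

### Read binning

A read is kept when it contains at least `min_hits_per_read` positions
whose canonical k-mer lies in the specific set. Hit counting is
positional — a k-mer occurring twice counts twice — which is the robust
choice for a repeat-expanded W (a distinct-k-mer mode exists behind
`distinct_hits`). The default threshold is 1 ("contains a specific
k-mer").

For noisy data there is a sharp a-priori argument for a higher
threshold: with substitution-type errors, a *single* error event can
forge at most k consecutive specific-k-mer hits (the k windows covering
the errored base), while a true W-origin read of ≥ 1 kb at a few
percent Z–W divergence carries hundreds of hits (tens of divergent
sites × up to k windows each). Any threshold just above k therefore
rejects single-event artefacts at essentially no recall cost; the
noisy-screen tests use `min_hits_per_read = 20 = k + 3`. Paired short
reads can be rescued as pairs (`pair_rescue`): a pair is kept when
either mate passes.

## Unique-anchor placement and the depth ratio

Rather than wrapping an external aligner, reads are placed with exact
unique k-mer anchors: the reference index stores every canonical k-mer
occurring exactly once in the reference with its (chromosome, position,
strand); each anchor in a read votes for the placement it implies, and
the read is placed where a strict majority (> 50% of votes, and at
least `min_anchors = 3` anchors) agrees. Repeat-only or ambiguous
reads stay unplaced and are dropped from depth — the moral equivalent
of a MAPQ filter. This is exact for the simulator's substitution-only
reads; it makes no attempt at gapped alignment.

For speed, placement samples every 8th anchor first and re-anchors
exhaustively any read the sample cannot place (`anchor_stride`,
stride 1 = exhaustive). A read placed by the sampled anchors would
receive the same strict majority from the full set on clean data, so
sampling trades time, not placements; the differentiated-Z study gives
a bit-identical depth track under stride 1 and stride 8.

The depth diagnostic bins placed-read depth into 1 kb windows per sex
group, normalizes each group by the **median autosomal window depth**
of that group (robust to sex-linked windows; how the original ratio
was normalized is not something the procedure fixes, so the package
makes its own choice and states it), and reports
`log2(norm_M / norm_F)` per window. Expected values: ≈ 1 on a fully
differentiated Z (males carry two Z copies, females one), ≈ 0
everywhere copy number is equal — including on Z when the W is
undifferentiated, because female W reads then place onto Z and refill
its depth. Windows with zero depth in either group report NaN, not ±∞.

## Heterozygosity differential

The earliest detectable signature of Z–W differentiation is not
coverage but apparent heterozygosity: female reads from the diverging W
place onto Z and create balanced mismatch columns at every divergent
site, so females show an excess of het calls on Z long before coverage
separates. Two counters are provided:

* a naive pileup over the unique-anchor placements: a column is
  heterozygous when depth ≥ 5 (`min_depth`) and the second-most-frequent
  base holds a fraction in [0.3, 0.7] (`min_allele_frac`). These
  thresholds are the package's own; the counter is explicitly *not* a
  production variant caller and is valid only for substitution-only
  reads;
* a VCF GT-field counter (via cyvcf2) for externally called genotypes.

The report compares female vs male per-sample Z het counts with a
two-sided Mann–Whitney rank-sum test.

## Sketch identity and Z-candidate detection

Sequence identity between W and each reference chromosome is estimated
alignment-free: bottom-s MinHash sketches (s = 1000) of the distinct
canonical k-mer sets, Jaccard `j` estimated on the merged bottom-s
sketch, converted by the Mash relation

```
identity = 1 + (1/k) · ln( 2j / (1+j) )
```

floored at 0, and flagged degenerate when j = 0. The hash is a fixed
splitmix64 finalizer (vectorised, platform-independent), so sketches
are reproducible everywhere. For point divergence d the estimator's
systematic error is `1 + ln(1-d) − (1-d) ≈ d²/2` (< 0.004 at d = 0.08),
and sketch noise at s = 1000 contributes a standard deviation of
roughly 0.004 at d = 0.08 — hence the ±0.01 calibration band used in
the tests. The reference chromosome maximizing identity with the
recovered W is reported as the Z candidate. This deliberately
substitutes sketching for alignment-based identity (MashMap/nucmer in
the original workflow): no gapped aligner is implemented, and for
point-divergence comparisons the sketch estimate measures the same
quantity.

## Assembly accuracy estimators

* **k-mer QV** (Merqury-style): with `T` assembly k-mer positions
  (counted with multiplicity; a distinct mode exists) and `b` of them
  whose canonical k-mer never occurs in the read set, the per-base
  error is `E = 1 − (1 − b/T)^(1/k)`, `QV = −10·log10 E` (∞ when
  b = 0), accuracy% = 100·(1 − E).
* **Homozygous-SNP accuracy**: each homozygous variant of a sample's
  own reads against its assembly marks one wrong assembled base, so
  accuracy% = 100·(1 − n_hom/L).

## The synthetic ZW generator

The generator is first-class, tested code; it emulates the study design
the screen targets, with full truth labels.

* **Genome**: uniform-random autosomes (default two of 300 kb) and Z
  (300 kb) form the male reference; ~1 Mb total. W is derived from Z by
  point substitutions at `zw_divergence` (default 0.04, i.e. ~96% Z–W
  identity; every site ledgered), plus a repeat expansion: one random
  unit (500 bp) inserted at uniform positions until
  `w_repeat_fraction × |Z|` bases are added (default 5% — repeats on
  the W of a nascent pair are expanded relative to Z but still a minor
  fraction of the chromosome). A `w_fully_differentiated` mode
  generates W independently and scrubs any canonical k-mer it shares
  with the reference, giving the fully-diverged end member.
* **Population**: `n_females = n_males = 5` by default.  Chromosome
  pairs receive heterozygous substitutions at `pop_het_rate = 1e-3`
  per site (one randomly chosen haplotype mutated); single-copy
  chromosomes (female Z, W) are mutated at half that rate per copy so
  per-copy variant density is uniform across karyotypes.
* **Reads**: substitution-only errors (no indels), which keeps the
  anchor mapper and the pileup exact — a deliberate idealization of
  HiFi/Illumina error modes. Short reads: 150 bp pairs, insert
  350 ± 35 bp, 20x per individual (each haplotype at half coverage),
  error 0.002. Long reads: lognormal lengths with mean 15 kb / sd 5 kb
  truncated to [1 kb, 50 kb] (a ~20 kb size-selected HiFi library
  motivates the mean), 15x, error 0.002. Constant Q30 qualities.
* **Determinism**: all randomness flows from `SimConfig.seed` through
  fixed-offset substreams (`default_rng([seed, stage, individual])`);
  identical configs give byte-identical FASTQ (gzip written with fixed
  mtime and no filename field).

What the generator does **not** model — and what passing tests
therefore cannot show about real data: indels and structural variants,
sequencing-machine error profiles and quality distributions, GC/coverage
bias, heterogeneous repeat families (one unit stands in for a
retrotransposon expansion), Hi-C contact structure (screened Hi-C is
represented as ordinary paired short reads), and gene content. Results
on real libraries additionally depend on a production aligner and
variant caller, which this package intentionally does not contain.

## Numerical and degenerate-input choices

* k ≤ 31 so a k-mer packs into one 64-bit word; the 2-bit encoding
  (A<C<G<T) preserves lexicographic order, so the sorted on-disk TSV is
  also string-sorted and round-trips bit-exactly.
* Windows containing non-ACGT bases are skipped in counting, indexing,
  painting and QV.
* Empty kept set in partition evaluation: precision NaN with a warning,
  never a crash; empty specific set: screening refuses to run.
* Ties in placement voting cannot win: a tied maximum never exceeds 50%
  of votes, so tied reads are unplaced rather than arbitrarily placed.
* Window coordinates are 0-based half-open (BED convention) everywhere;
  terminal windows may be short and are averaged over their true width.

## Desk-scale study sizes

All bundled studies run on a ~1 Mb genome with 5 + 5 individuals at
20x short / 15x long coverage — sizes chosen so the full suite and the
reproduction script each complete in minutes on one CPU while every
rate being tested (coverage per window, divergent sites per read,
k-mers per panel) stays in the regime the method actually relies on.
The headline numbers of the original study (573,403 specific k-mers,
a 20.48 Mb W) require its deposited resequencing data and external
assemblers, and are out of scope here.
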