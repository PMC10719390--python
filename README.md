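# zwks

Sex-specific k-mer screening and diagnostics for recovering a poorly
differentiated W (or Y) chromosome from mixed sequencing data.

## The problem

In female-heterogametic (ZZ/ZW) species, a *young* W chromosome is
nearly identical in sequence to Z. Standard assemblies therefore
collapse Z and W into one mosaic chromosome, and coverage-based sexing
of scaffolds fails because male and female depth look the same. The
population-genomic way around this: a k-mer present — above a noise
threshold — in **every** female of a resequencing panel but in **no**
male is necessarily W-linked, and long reads containing such k-mers can
be binned out and assembled into a W on their own.

`zwks` implements that screen exactly, plus the diagnostics used to
validate the result:

* **exact canonical k-mer set algebra** (count / filter / union-sum /
  intersect / difference) with a sorted, bit-stable TSV format;
* the **specific-k-mer derivation**
  `difference(intersect_all(filter_min_count(fᵢ, 5)), union_sum(mⱼ))`
  at k = 17, and **read binning** by specific-k-mer content;
* **k-mer painting** of an assembly in windows (where does the specific
  set land?);
* the **log2(M/F) depth-ratio track** from a built-in unique-anchor
  read placer (expected ≈ 1 on a fully differentiated Z — males carry
  two Z — and ≈ 0 when W is undifferentiated);
* the **heterozygosity differential**: females show excess apparent het
  sites on Z (W reads piling onto Z) long before coverage separates —
  counted from a naive pileup or from VCF genotypes;
* **MinHash sketch identity** (`identity = 1 + ln(2j/(1+j))/k`) for
  Z-candidate detection, and **k-mer QV**
  (`E = 1 − (1 − b/T)^(1/k)`, `QV = −10·log₁₀E`) plus homozygous-SNP
  accuracy (`100·(1 − n/L)`) for assembly QC;
* a **synthetic ZW generator** (male reference, divergent +
  repeat-expanded W, diploid panels, short/long reads) with complete
  truth labels, so the whole pipeline is testable end to end with no
  downloads.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Run the full synthetic study — simulate a 300 kb-Z genome at 4% Z–W
divergence with 5 ZW females and 5 ZZ males, derive specific k-mers
from the short-read panels, bin the female long reads, and compute
every diagnostic:

```toml
# example.toml
window = 1000
[simulate]
seed = 7
autosome_lengths = [100000, 100000]
z_length = 100000
[screen]
min_hits_per_read = 20
```

```console
$ zwks run --config example.toml --out demo
specific k-mers: 32395
screen precision/recall: 0.996/1.000
mean Z log2(M/F): 0.047
report: demo/report.json
```

What the numbers in `demo/report.json` mean:

* `n_specific_kmers: 32395` — k-mers carried by all 5 females (count
  ≥ 5 each) and absent from every male; at 4% divergence on a 100 kb Z
  these tag the ~4,000 divergent W sites plus the W repeat expansion.
* `screen: precision 0.996, recall 1.000` — judged against the
  simulator's truth labels, the kept long-read bin is essentially
  exactly the W-origin reads (263 of 1,510 female long reads kept).
* `paint: {chr1: 0, chr2: 0, chrZ: 0, chrW: 36771}` — painting the
  specific set on the assembly localizes it entirely to W.
* `depth.mean_Z_log2: 0.047` — no male/female coverage differential on
  Z: at 4% divergence female W reads still place onto Z, so the pair is
  *homomorphic by depth* (a fully differentiated W would read ≈ 1).
* `het: female_Z_mean 3923 vs male_Z_mean 93, ranksum_p 0.0079` — the
  het-site excess on Z in females is the signature that Z and W *have*
  started to differentiate, despite the flat depth.
* `identity: {best_chrom: chrZ, best_identity: 0.955}` — the reference
  chromosome most similar to W (the Z candidate), with sketch identity
  ≈ 1 − divergence.
* `qv: {b: 24, T: 404936, qv: 54.6, accuracy_pct: 99.9997}` — k-mer QV
  of the assembly against the pooled read k-mers.

Every stage is also a standalone subcommand (`zwks simulate / count /
setop / sexmers / screen / paint / depthratio / hets / identity / qv`)
operating on plain FASTA/FASTQ/TSV/VCF files, and a plain Python API
(`import zwks`) underneath.

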