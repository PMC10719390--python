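"""End-to-end orchestration: simulate -> screen -> diagnostics -> report.

Runs the whole synthetic study: generate a ZW population and reads,
derive sex-specific k-mers from the short-read panels, bin the long
reads, paint the specific k-mers on the assembly, compute the
log2(M/F) depth track and per-sample het counts from the unique-anchor
placements, estimate W-Z identity and assembly QV, and write one
machine-readable report tying the numbers together.

Stage artifacts are plain files (FASTA/FASTQ/TSV/VCF/JSON) in the
output directory.  A stage whose artifacts are already present is
reloaded instead of recomputed (delete an artifact, or pass ``force``,
to redo it); the simulation itself is regenerated deterministically
from the seed, so a fixed seed yields an identical report (minus
timestamps) whichever path is taken.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import chromid, kmerset, mapdepth, sexscreen, simdata
from .simdata import SimConfig, W_NAME, Z_NAME

log = logging.getLogger(__name__)

REPORT_SCHEMA_KEYS = [
    "seed", "config", "n_specific_kmers", "screen", "paint", "depth",
    "het", "identity", "qv", "coverage", "versions", "timestamps",
]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    screen: sexscreen.ScreenParams = field(default_factory=sexscreen.ScreenParams)
    window: int = 1_000
    min_anchors: int = 3
    min_depth: int = 5
    min_allele_frac: float = 0.3
    sketch_size: int = 1_000
    write_reads: bool = True
    out: Path = Path("zwks_out")

    @classmethod
    def from_toml(cls, path: str | Path, seed: int | None = None,
                  out: str | Path | None = None) -> "PipelineConfig":
        """Load a ``[simulate]`` / ``[screen]`` TOML config; overrides win."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_kw = raw.pop("simulate", {})
        if "autosome_lengths" in sim_kw:
            sim_kw["autosome_lengths"] = tuple(sim_kw["autosome_lengths"])
        screen_kw = raw.pop("screen", {})
        out_raw = raw.pop("out", None)
        cfg = cls(sim=SimConfig(**sim_kw),
                  screen=sexscreen.ScreenParams(**screen_kw), **raw)
        if out_raw is not None:
            cfg.out = Path(out_raw)
        if seed is not None:
            cfg.sim = cfg.sim.with_updates(seed=seed)
        if out is not None:
            cfg.out = Path(out)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["out"] = str(self.out)
        return d


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"zwks": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.echo(), indent=2) + "\n")
    sim = config.sim
    k = sim.k

    def fresh(*paths: Path) -> bool:
        return force or not all(p.exists() for p in paths)

    log.info("stage simulate: genome + %d females / %d males",
             sim.n_females, sim.n_males)
    genome = simdata.simulate_genome(sim)
    genome, het_ledger = simdata.simulate_individuals(genome, sim)
    simdata.write_reference_fasta(genome, out)
    simdata.write_het_vcf(genome, het_ledger, out / "planted_hets.vcf")

    short = simdata.simulate_reads(genome, sim, kind="short")
    long_reads = simdata.simulate_reads(genome, sim, kind="long")
    truth = simdata.SimTruth.build(genome, [*short, *long_reads], het_ledger)
    truth.write_reads_tsv(out / "truth_reads.tsv")
    if config.write_reads:
        for rs in (*short, *long_reads):
            simdata.write_fastq(rs, out / f"{rs.individual}.{rs.kind}.fq.gz")

    # --- sex-specific k-mers -------------------------------------------------
    spec_path = out / "specific.kmers.tsv"
    if fresh(spec_path):
        log.info("stage count+sexmers: counting %d individuals", len(short))
        female_sets = [kmerset.count_kmers(rs, k) for rs in short if rs.sex == "F"]
        male_sets = [kmerset.count_kmers(rs, k) for rs in short if rs.sex == "M"]
        spec = sexscreen.derive_sex_specific_kmers(female_sets, male_sets,
                                                   config.screen)
        spec.write_tsv(spec_path)
    else:
        spec = kmerset.KmerSet.read_tsv(spec_path)
        log.info("stage sexmers: reloaded %d k-mers", len(spec))

    # --- long-read screen ----------------------------------------------------
    part_path = out / "partition.tsv"
    if fresh(part_path):
        log.info("stage screen: %d female long-read sets", sim.n_females)
        female_long = [rs for rs in long_reads if rs.sex == "F"]
        partitions = [sexscreen.screen_reads(rs, spec, config.screen)
                      for rs in female_long]
        part_frame = pd.concat([p.frame for p in partitions], ignore_index=True)
        partition = sexscreen.ReadPartition(config.screen, part_frame)
        partition.write_tsv(part_path)
    else:
        partition = sexscreen.ReadPartition.read_tsv(part_path, config.screen)
    screen_eval = sexscreen.evaluate_partition(partition, truth.reads, W_NAME)

    # --- k-mer painting ------------------------------------------------------
    paint_path = out / "paint.tsv"
    if fresh(paint_path):
        log.info("stage paint")
        paint = chromid.paint_kmers(genome.reference_with_w(), spec,
                                    config.window)
        paint.to_csv(paint_path, sep="\t", index=False)
    else:
        paint = pd.read_csv(paint_path, sep="\t")
    paint_totals = chromid.paint_totals(paint)

    # --- mapping-backed diagnostics -----------------------------------------
    depth_path = out / "depth_track.tsv"
    het_path = out / "het_counts.tsv"
    cov_path = out / "coverage.json"
    if fresh(depth_path, het_path, cov_path):
        log.info("stage depthratio: unique-anchor mapping of short reads")
        index = mapdepth.build_index(genome.male_reference, k)
        placements = {rs.individual: mapdepth.place_reads(rs, index,
                                                          config.min_anchors)
                      for rs in short}
        males = [placements[rs.individual] for rs in short if rs.sex == "M"]
        females = [placements[rs.individual] for rs in short if rs.sex == "F"]
        track = mapdepth.depth_log2_ratio(males, females, config.window)
        track.write_tsv(depth_path)

        log.info("stage hets: naive pileup per sample")
        het = mapdepth.call_het_sites(
            [(rs, placements[rs.individual]) for rs in short],
            genome.male_reference, config.min_depth, config.min_allele_frac)
        het.to_csv(het_path, sep="\t", index=False)

        cov = mapdepth.coverage_stats(list(placements.values()),
                                      genome.male_reference, config.min_depth)
        cov_dict = dataclasses.asdict(cov)
        cov_path.write_text(json.dumps(cov_dict, indent=2) + "\n")
    else:
        log.info("stage depthratio/hets: reloading artifacts")
        track = mapdepth.DepthTrack.read_tsv(depth_path)
        het = pd.read_csv(het_path, sep="\t")
        cov_dict = json.loads(cov_path.read_text())

    sex_of = {rs.individual: rs.sex for rs in short}
    z_het = het[het["chrom"] == Z_NAME].copy()
    z_het["sex"] = z_het["sample"].map(sex_of)
    f_counts = z_het.loc[z_het["sex"] == "F", "n_het"].to_numpy()
    m_counts = z_het.loc[z_het["sex"] == "M", "n_het"].to_numpy()
    if len(f_counts) and len(m_counts):
        ranksum = stats.mannwhitneyu(f_counts, m_counts,
                                     alternative="two-sided")
        p_value = float(ranksum.pvalue)
    else:
        p_value = float("nan")

    # --- identity & QV -------------------------------------------------------
    ident_path = out / "identity.tsv"
    if fresh(ident_path):
        log.info("stage identity: W vs reference chromosomes")
        ident = chromid.rank_identity(genome.w_sequence, genome.male_reference,
                                      k=k, sketch_size=config.sketch_size)
        ident.to_csv(ident_path, sep="\t", index=False)
    else:
        ident = pd.read_csv(ident_path, sep="\t")

    qv_path = out / "qv.json"
    if fresh(qv_path):
        log.info("stage qv")
        all_read_kmers = kmerset.union_sum(
            [kmerset.count_kmers(rs, k) for rs in short])
        qv = chromid.qv_estimate(genome.reference_with_w(), all_read_kmers, k)
        qv.to_json(qv_path)
        qv_dict = json.loads(qv_path.read_text())
    else:
        qv_dict = json.loads(qv_path.read_text())

    report = {
        "seed": sim.seed,
        "config": config.echo(),
        "n_specific_kmers": len(spec),
        "screen": {
            "n_kept": partition.n_kept,
            "n_total": partition.n_total,
            "precision": screen_eval["precision"],
            "recall": screen_eval["recall"],
            "f1": screen_eval["f1"],
        },
        "paint": {c: int(v) for c, v in paint_totals.items()},
        "depth": {
            "per_chrom_log2": {c: float(v)
                               for c, v in track.per_chromosome().items()},
            "mean_Z_log2": track.chrom_mean(Z_NAME),
        },
        "het": {
            "female_Z_mean": float(f_counts.mean()) if len(f_counts) else None,
            "male_Z_mean": float(m_counts.mean()) if len(m_counts) else None,
            "ranksum_p": p_value,
        },
        "identity": {
            "best_chrom": str(ident.iloc[0]["chrom"]),
            "best_identity": float(ident.iloc[0]["identity"]),
        },
        "qv": qv_dict,
        "coverage": cov_dict,
        "versions": _versions(),
        "timestamps": {"started": t0, "finished": time.time()},
    }
    write_report(report, out)
    return report


def write_report(report: dict, out: str | Path) -> None:
    """Write report.json plus a flat key/value report.tsv."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True) + "\n")
    flat: list[tuple[str, object]] = []

    def _walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for kk, vv in obj.items():
                _walk(f"{prefix}.{kk}" if prefix else str(kk), vv)
        elif isinstance(obj, (list, tuple)):
            flat.append((prefix, json.dumps(obj)))
        else:
            flat.append((prefix, obj))

    _walk("", report)
    with open(out / "report.tsv", "w") as fh:
        for key, val in flat:
            fh.write(f"{key}\t{val}\n")


def read_report(out: str | Path) -> dict:
    return json.loads((Path(out) / "report.json").read_text())


def validate_report(report: dict) -> None:
    """Check the report carries every documented top-level key."""
    missing = [kk for kk in REPORT_SCHEMA_KEYS if kk not in report]
    if missing:
        raise KeyError(f"report missing keys: {missing}")
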