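"""Shared fixtures: desk-scale simulation studies reused across tests.

The three session-scoped studies are the expensive objects (a ~1 Mb
genome with 5 females / 5 males at 20x is >1M short reads); everything
derived from them (k-mer panels, placements, depth tracks) is also
session-scoped so each study is simulated and mapped exactly once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from zwks import kmerset, mapdepth, sexscreen, simdata


def count_kmers_oracle(seqs, k):
    """Brute-force enumerate-and-canonicalize canonical k-mer counter."""
    from collections import Counter

    comp = str.maketrans("ACGT", "TGCA")
    c: Counter = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                rc = w.translate(comp)[::-1]
                c[min(w, rc)] += 1
    return dict(c)


@pytest.fixture(scope="session")
def small_sim():
    """A fast ~150 kb study for unit-level checks."""
    cfg = simdata.SimConfig(seed=9, autosome_lengths=(50_000, 50_000),
                            z_length=50_000, short_coverage=15,
                            long_coverage=8)
    genome = simdata.simulate_genome(cfg)
    genome, het_ledger = simdata.simulate_individuals(genome, cfg)
    short = simdata.simulate_reads(genome, cfg, kind="short")
    long_reads = simdata.simulate_reads(genome, cfg, kind="long")
    truth = simdata.SimTruth.build(genome, [*short, *long_reads], het_ledger)
    return {"cfg": cfg, "genome": genome, "het_ledger": het_ledger,
            "short": short, "long": long_reads, "truth": truth}


# ---------------------------------------------------------------------------
# study 1: early differentiation (the paper's actual regime)


@pytest.fixture(scope="session")
def early_study():
    """Default study conditions: 4% Z-W divergence, 5F/5M, 20x, ~1 Mb."""
    cfg = simdata.SimConfig(seed=2)
    genome = simdata.simulate_genome(cfg)
    genome, het_ledger = simdata.simulate_individuals(genome, cfg)
    short = simdata.simulate_reads(genome, cfg, kind="short")
    long_reads = simdata.simulate_reads(genome, cfg, kind="long")
    truth = simdata.SimTruth.build(genome, [*short, *long_reads], het_ledger)
    return {"cfg": cfg, "genome": genome, "het_ledger": het_ledger,
            "short": short, "long": long_reads, "truth": truth}


@pytest.fixture(scope="session")
def early_panels(early_study):
    """Per-individual k-mer sets and the derived sex-specific set."""
    short = early_study["short"]
    k = early_study["cfg"].k
    female_sets = [kmerset.count_kmers(rs, k) for rs in short if rs.sex == "F"]
    male_sets = [kmerset.count_kmers(rs, k) for rs in short if rs.sex == "M"]
    male_union = kmerset.union_sum(male_sets)
    spec = sexscreen.derive_sex_specific_kmers(female_sets, male_sets)
    return {"female_sets": female_sets, "male_union": male_union, "spec": spec}


@pytest.fixture(scope="session")
def early_placements(early_study):
    """Unique-anchor placements of every individual's short reads."""
    genome = early_study["genome"]
    k = early_study["cfg"].k
    index = mapdepth.build_index(genome.male_reference, k)
    placements = {rs.individual: mapdepth.place_reads(rs, index)
                  for rs in early_study["short"]}
    return {"index": index, "placements": placements}


@pytest.fixture(scope="session")
def early_depth_track(early_study, early_placements):
    pls = early_placements["placements"]
    short = early_study["short"]
    males = [pls[rs.individual] for rs in short if rs.sex == "M"]
    females = [pls[rs.individual] for rs in short if rs.sex == "F"]
    return mapdepth.depth_log2_ratio(males, females, window=1_000)


# ---------------------------------------------------------------------------
# study 2: fully differentiated W (EZ ~ 1)


@pytest.fixture(scope="session")
def diff_study():
    """W sharing no canonical 17-mer with the male reference."""
    cfg = simdata.SimConfig(seed=1, w_fully_differentiated=True)
    genome = simdata.simulate_genome(cfg)
    genome, _ = simdata.simulate_individuals(genome, cfg)
    short = simdata.simulate_reads(genome, cfg, kind="short")
    return {"cfg": cfg, "genome": genome, "short": short}


@pytest.fixture(scope="session")
def diff_depth_track(diff_study):
    genome = diff_study["genome"]
    short = diff_study["short"]
    index = mapdepth.build_index(genome.male_reference, diff_study["cfg"].k)
    pls = {rs.individual: mapdepth.place_reads(rs, index) for rs in short}
    males = [pls[rs.individual] for rs in short if rs.sex == "M"]
    females = [pls[rs.individual] for rs in short if rs.sex == "F"]
    return mapdepth.depth_log2_ratio(males, females, window=1_000)


# ---------------------------------------------------------------------------
# study 3: undifferentiated baseline (W identical to Z, log2 ~ 0)


@pytest.fixture(scope="session")
def undiff_depth_track():
    cfg = simdata.SimConfig(seed=1, zw_divergence=0.0, w_repeat_fraction=0.0)
    genome = simdata.simulate_genome(cfg)
    genome, _ = simdata.simulate_individuals(genome, cfg)
    short = simdata.simulate_reads(genome, cfg, kind="short")
    index = mapdepth.build_index(genome.male_reference, cfg.k)
    pls = {rs.individual: mapdepth.place_reads(rs, index) for rs in short}
    males = [pls[rs.individual] for rs in short if rs.sex == "M"]
    females = [pls[rs.individual] for rs in short if rs.sex == "F"]
    return mapdepth.depth_log2_ratio(males, females, window=1_000)


# ---------------------------------------------------------------------------
# study 4: clean fully differentiated screen (exactness clause)


@pytest.fixture(scope="session")
def clean_screen_study():
    """Zero-error reads, fully differentiated W, read-panel-derived screen."""
    cfg = simdata.SimConfig(seed=4, autosome_lengths=(100_000, 100_000),
                            z_length=100_000, w_fully_differentiated=True,
                            short_error=0.0, long_error=0.0)
    genome = simdata.simulate_genome(cfg)
    genome, _ = simdata.simulate_individuals(genome, cfg)
    short = simdata.simulate_reads(genome, cfg, kind="short")
    long_reads = simdata.simulate_reads(genome, cfg, kind="long")
    truth = simdata.SimTruth.build(genome, long_reads)
    female_sets = [kmerset.count_kmers(rs, cfg.k) for rs in short if rs.sex == "F"]
    male_sets = [kmerset.count_kmers(rs, cfg.k) for rs in short if rs.sex == "M"]
    spec = sexscreen.derive_sex_specific_kmers(female_sets, male_sets)
    return {"cfg": cfg, "genome": genome, "long": long_reads,
            "truth": truth, "spec": spec}


def screen_female_longs(long_reads, spec, params):
    """Pool the female long-read partitions into one ReadPartition."""
    female = [rs for rs in long_reads if rs.sex == "F"]
    parts = [sexscreen.screen_reads(rs, spec, params) for rs in female]
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    return sexscreen.ReadPartition(params, frame)
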