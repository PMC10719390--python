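"""Unique-anchor placement, depth-ratio and het-count unit tests."""

import numpy as np
import pandas as pd
import pytest

from zwks import mapdepth, simdata
from zwks._seqs import encode, random_codes
from zwks.mapdepth import (MapParameterError, Placements, build_index,
                           call_het_sites, count_het_from_vcf, coverage_stats,
                           depth_log2_ratio, place_read, place_reads)


def test_index_of_repetitive_reference_is_empty():
    # every 3-mer of ACGTACGT repeats after canonicalization
    assert len(build_index({"c": "ACGTACGT"}, 3)) == 0
    # a duplicated segment excludes all its k-mers; only windows spanning
    # the copy junction (starts 88..99) are unique
    seg = "".join(np.random.default_rng(0).choice(list("ACGT"), 100))
    idx = build_index({"c": seg + seg}, 13)
    assert len(idx) == 12
    assert set(idx.pos.tolist()) == set(range(88, 100))


def test_index_bounds_and_errors():
    rng = np.random.default_rng(1)
    seq = random_codes(10_000, rng)
    idx = build_index({"c": seq}, 17)
    L = len(seq)
    assert len(idx) <= L - 17 + 1
    assert len(idx) >= 0.999 * (L - 17 + 1)  # collisions negligible
    with pytest.raises(MapParameterError):
        build_index({"c": "ACGT"}, 2)
    with pytest.raises(MapParameterError):
        build_index({"c": "ACGT"}, 17)


def test_clean_read_placed_at_true_coordinate():
    rng = np.random.default_rng(2)
    ref = {"chr1": random_codes(5_000, rng), "chr2": random_codes(5_000, rng)}
    idx = build_index(ref, 17)
    read = ref["chr2"][1000:1150]
    c, s, st, n = place_read(read, idx)
    assert (idx.chrom_names[c], s, st) == ("chr2", 1000, 0)
    assert n == 150 - 17 + 1
    # reverse-complemented copy places at the same spot, minus strand
    rc = (3 - read[::-1]).astype(np.uint8)
    c2, s2, st2, _ = place_read(rc, idx)
    assert (idx.chrom_names[c2], s2, st2) == ("chr2", 1000, 1)


def test_repeat_read_unplaced():
    rng = np.random.default_rng(3)
    seg = random_codes(300, rng)
    ref = {"c": np.concatenate([seg, random_codes(2_000, rng), seg])}
    idx = build_index(ref, 17)
    assert place_read(seg[50:250], idx) is None  # repeat-only region
    assert place_read(random_codes(100, rng), idx) is None  # foreign read


def test_noisy_reads_still_place_correctly():
    """150 bp reads with 1% substitutions: >= 99% placed at truth."""
    cfg = simdata.SimConfig(seed=5, autosome_lengths=(40_000,),
                            z_length=40_000, n_females=1, n_males=1,
                            short_error=0.01, short_coverage=10,
                            zw_divergence=0.0, w_repeat_fraction=0.0)
    g, _ = simdata.simulate_individuals(simdata.simulate_genome(cfg), cfg)
    male = simdata.simulate_reads(g, cfg, "short")[-1]
    idx = build_index(g.male_reference, 17)
    pl = place_reads(male, idx, min_anchors=3)
    names = np.array(pl.chrom_names)
    tnames = np.array(male.chrom_names)
    sel = pl.placed
    correct = ((names[pl.chrom[sel]] == tnames[male.truth_chrom[sel]])
               & (pl.start[sel] == male.truth_start[sel]))
    assert sel.mean() >= 0.99
    assert correct.mean() >= 0.99


def _uniform_placements(idx, chrom_id, n, read_len, spacing):
    starts = (np.arange(n) * spacing) % (int(idx.chrom_lengths[chrom_id])
                                         - read_len)
    return Placements(idx.chrom_names, idx.chrom_lengths,
                      np.full(n, chrom_id, np.int32), starts.astype(np.int64),
                      np.zeros(n, np.int8), np.full(n, 5, np.int32),
                      np.full(n, read_len, np.int64))


def test_depth_ratio_identity_and_antisymmetry():
    rng = np.random.default_rng(4)
    ref = {"chr1": random_codes(20_000, rng), "chrZ": random_codes(20_000, rng)}
    idx = build_index(ref, 17)
    a = [_uniform_placements(idx, 0, 400, 150, 37),
         _uniform_placements(idx, 1, 400, 150, 41)]
    b = [_uniform_placements(idx, 0, 200, 150, 53),
         _uniform_placements(idx, 1, 200, 150, 29)]
    same = depth_log2_ratio(a, a, window=1_000)
    assert np.allclose(same.frame["log2_ratio"].dropna(), 0.0)
    ab = depth_log2_ratio(a, b, window=1_000)
    ba = depth_log2_ratio(b, a, window=1_000)
    x, y = ab.frame["log2_ratio"], ba.frame["log2_ratio"]
    ok = x.notna() & y.notna()
    assert np.allclose(x[ok], -y[ok])


def test_depth_conservation():
    rng = np.random.default_rng(6)
    ref = {"chr1": random_codes(10_000, rng), "chrZ": random_codes(10_000, rng)}
    idx = build_index(ref, 17)
    pls = [_uniform_placements(idx, 0, 100, 150, 91),
           _uniform_placements(idx, 1, 50, 150, 77)]
    cov = mapdepth._coverage_by_chrom(pls, idx.chrom_names, idx.chrom_lengths)
    placed_bases = sum(int(p.read_len[p.placed].sum()) for p in pls)
    assert sum(int(c.sum()) for c in cov.values()) == placed_bases
    track = depth_log2_ratio(pls, pls, window=1_000)
    window_bases = (track.frame["M"] * (track.frame["end"]
                                        - track.frame["start"])).sum()
    assert window_bases == pytest.approx(placed_bases)


def test_depth_requires_autosomal_windows():
    rng = np.random.default_rng(7)
    ref = {"chrZ": random_codes(5_000, rng)}
    idx = build_index(ref, 17)
    p = [_uniform_placements(idx, 0, 10, 150, 97)]
    with pytest.raises(MapParameterError):
        depth_log2_ratio(p, p, window=1_000)


def _pileup_fixture(columns):
    """Build a one-chromosome ReadSet+Placements with prescribed columns.

    ``columns``: list of base-code lists; read i is the i-th row across
    columns (all reads span the whole reference).
    """
    depth = len(columns[0])
    L = len(columns)
    mat = np.array([[col[i] for col in columns] for i in range(depth)],
                   dtype=np.uint8)
    rs = simdata.ReadSet(
        individual="S", sex="F", kind="short",
        ids=[f"r{i}" for i in range(depth)], chrom_names=["c"],
        truth_chrom=np.zeros(depth, np.int16),
        truth_hap=np.zeros(depth, np.int8),
        truth_start=np.zeros(depth, np.int64),
        truth_end=np.full(depth, L, np.int64),
        truth_strand=np.zeros(depth, np.int8), matrix=mat)
    pl = Placements(["c"], np.array([L]), np.zeros(depth, np.int32),
                    np.zeros(depth, np.int64), np.zeros(depth, np.int8),
                    np.full(depth, 3, np.int32), np.full(depth, L, np.int64))
    return rs, pl


def test_het_caller_column_rules():
    # 10 columns: half 5xA/5xG (het), half 10xA (hom)
    het_col = [0] * 5 + [2] * 5
    hom_col = [0] * 10
    cols = [het_col, hom_col] * 5
    rs, pl = _pileup_fixture(cols)
    ref = {"c": np.zeros(len(cols), dtype=np.uint8)}
    table = call_het_sites([(rs, pl)], ref, min_depth=5, min_allele_frac=0.3)
    assert table.loc[0, "n_het"] == 5
    # below min_depth nothing is called
    shallow = call_het_sites([(rs, pl)], ref, min_depth=11)
    assert shallow.loc[0, "n_het"] == 0
    # a 9:1 column fails the allele-fraction band
    skew = [[0] * 9 + [2]] * 4
    rs2, pl2 = _pileup_fixture(skew)
    t2 = call_het_sites([(rs2, pl2)], {"c": np.zeros(4, np.uint8)},
                        min_depth=5, min_allele_frac=0.3)
    assert t2.loc[0, "n_het"] == 0


def test_vcf_het_counts(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text("\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
        "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1",
        "chr1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1",
        "chr1\t30\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0|1",
    ]) + "\n")
    table = count_het_from_vcf(vcf)
    by = table.set_index("sample")["n_het"].to_dict()
    assert by == {"S1": 1, "S2": 2}
    with pytest.raises(KeyError):
        count_het_from_vcf(vcf, ["S1", "nope"])


def test_planted_het_vcf_round_trips_to_ledger_counts(small_sim, tmp_path):
    genome = small_sim["genome"]
    ledger = small_sim["het_ledger"]
    vcf = tmp_path / "planted.vcf"
    simdata.write_het_vcf(genome, ledger, vcf)
    table = count_het_from_vcf(vcf)
    got = (table[table["chrom"] != "."]
           .groupby(["sample", "chrom"])["n_het"].sum())
    expect = ledger.groupby(["individual", "chrom"]).size()
    for (sample, chrom), n in expect.items():
        assert got.get((sample, chrom), 0) == n


def test_coverage_stats_degenerate_cases():
    rng = np.random.default_rng(8)
    ref = {"chr1": random_codes(2_000, rng)}
    idx = build_index(ref, 17)
    full = [_uniform_placements(idx, 0, 200, 150, 7)]
    cs = coverage_stats(full, ref, min_depth=5)
    assert cs.frac_reads_placed == 1.0
    empty = Placements(idx.chrom_names, idx.chrom_lengths,
                       np.empty(0, np.int32), np.empty(0, np.int64),
                       np.empty(0, np.int8), np.empty(0, np.int32),
                       np.empty(0, np.int64))
    cs0 = coverage_stats([empty], ref, min_depth=1)
    assert cs0.frac_bases_covered == 0.0
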