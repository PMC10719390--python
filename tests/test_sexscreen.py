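"""Sex-specific k-mer derivation and read-screening unit tests."""

import numpy as np
import pandas as pd
import pytest

from zwks import kmerset, sexscreen, simdata
from zwks.kmerset import KmerSet, count_kmers
from zwks.sexscreen import (ReadPartition, ScreenError, ScreenParams,
                            derive_sex_specific_kmers, evaluate_partition,
                            pair_rescue, screen_reads)

from conftest import count_kmers_oracle


def _sets(panels, k):
    return [count_kmers(seqs, k) for seqs in panels]


def test_marker_kmer_survives_toy_panels():
    # every female carries marker AACCG >= 5 times; males never do
    marker = "AACCG"
    females = [[marker * 6 + "T" + "ACGTACGT"] for _ in range(3)]
    males = [["ACGTACGTACGT"], ["TTTTTGGGGG"]]
    params = ScreenParams(k=5)
    spec = derive_sex_specific_kmers(_sets(females, 5), _sets(males, 5), params)
    assert marker in spec
    # identical panels -> nothing is specific
    same = _sets(females, 5)
    assert len(derive_sex_specific_kmers(same, same, params)) == 0


def test_derivation_equals_primitive_composition():
    rng = np.random.default_rng(0)
    k = 5
    panels = [["".join(rng.choice(list("ACGT"), 120)) for _ in range(2)]
              for _ in range(6)]
    fem, mal = panels[:3], panels[3:]
    params = ScreenParams(k=k, min_count_female=2)
    spec = derive_sex_specific_kmers(_sets(fem, k), _sets(mal, k), params)
    composed = kmerset.difference(
        kmerset.intersect_all([kmerset.filter_min_count(s, 2)
                               for s in _sets(fem, k)]),
        kmerset.union_sum(_sets(mal, k)))
    assert spec.to_dict() == composed.to_dict()
    # brute-force oracle over all candidate k-mers
    fem_oracles = [count_kmers_oracle(p, k) for p in fem]
    mal_keys = set().union(*(count_kmers_oracle(p, k) for p in mal))
    expected = {kk for kk in fem_oracles[0]
                if all(o.get(kk, 0) >= 2 for o in fem_oracles)
                and kk not in mal_keys}
    assert set(spec.to_dict()) == expected


def test_raising_female_threshold_never_grows_spec():
    rng = np.random.default_rng(1)
    k = 5
    fem = _sets([["".join(rng.choice(list("ACGT"), 300))] for _ in range(3)], k)
    mal = _sets([["".join(rng.choice(list("ACGT"), 300))] for _ in range(3)], k)
    prev = None
    for t in (1, 2, 4, 8):
        spec = derive_sex_specific_kmers(
            fem, mal, ScreenParams(k=k, min_count_female=t))
        keys = set(spec.to_dict())
        if prev is not None:
            assert keys <= prev
        prev = keys


def test_parameter_errors():
    s = [KmerSet.from_dict({"AAAAA": 5}, 5)]
    with pytest.raises(ScreenError):
        derive_sex_specific_kmers([], s, ScreenParams(k=5))
    with pytest.raises(ScreenError):
        derive_sex_specific_kmers(s, s, ScreenParams(k=7))
    with pytest.raises(ScreenError):
        ScreenParams(min_hits_per_read=0).validate()


def test_screen_toy_reads():
    spec = KmerSet.from_dict({"ACG": 1}, 3)
    params = ScreenParams(k=3, min_hits_per_read=1)
    # TTTACGTTT contains ACG and CGT; both canonicalize to ACG -> 2 hits
    part = screen_reads(_toy_readset(["TTTACGTTT", "TTTTTTTTT"]), spec, params)
    assert part.frame["n_hits"].tolist() == [2, 0]
    assert part.frame["kept"].tolist() == [1, 0]
    # positional counting: the same k-mer twice counts twice (ACG + CGT both
    # canonicalize to ACG, and ACGT contains both)
    part2 = screen_reads(_toy_readset(["ACGT"]), spec, params)
    assert part2.frame["n_hits"].tolist() == [2]
    distinct = screen_reads(_toy_readset(["ACGT"]), spec,
                            ScreenParams(k=3, distinct_hits=True))
    assert distinct.frame["n_hits"].tolist() == [1]


def _toy_readset(seqs):
    from zwks._seqs import encode

    n = len(seqs)
    return simdata.ReadSet(
        individual="T1", sex="F", kind="long",
        ids=[f"r{i+1}" for i in range(n)], chrom_names=["chrX"],
        truth_chrom=np.zeros(n, np.int16), truth_hap=np.zeros(n, np.int8),
        truth_start=np.zeros(n, np.int64),
        truth_end=np.array([len(s) for s in seqs], np.int64),
        truth_strand=np.zeros(n, np.int8),
        seqs=[encode(s) for s in seqs])


def test_screen_requires_nonempty_spec():
    with pytest.raises(ScreenError):
        screen_reads(_toy_readset(["ACGT"]), KmerSet.from_dict({}, 3),
                     ScreenParams(k=3))


def test_min_hits_monotonicity():
    spec = KmerSet.from_dict({"ACG": 1, "TTA": 1}, 3)
    reads = _toy_readset(["ACGACGACG", "TTTACG", "GGGGGG"])
    kept_sizes = []
    for h in (1, 2, 4, 8):
        part = screen_reads(reads, spec, ScreenParams(k=3, min_hits_per_read=h))
        kept_sizes.append(part.n_kept)
    assert kept_sizes == sorted(kept_sizes, reverse=True)


def test_pair_rescue_keeps_both_mates():
    params = ScreenParams(k=3)
    frame = pd.DataFrame({"read_id": ["a/1", "a/2", "b/1", "b/2"],
                          "n_hits": [3, 0, 0, 0],
                          "kept": [1, 0, 0, 0]})
    rescued = pair_rescue(ReadPartition(params, frame))
    assert rescued.frame["kept"].tolist() == [1, 1, 0, 0]


def test_evaluate_partition_exact_and_degenerate():
    params = ScreenParams(k=3)
    truth = pd.DataFrame({"read_id": ["r1", "r2", "r3"],
                          "chromosome": ["chrW", "chr1", "chrW"]})
    frame = pd.DataFrame({"read_id": ["r1", "r2", "r3"],
                          "n_hits": [5, 0, 2], "kept": [1, 0, 1]})
    ev = evaluate_partition(ReadPartition(params, frame), truth)
    assert ev["precision"] == 1.0 and ev["recall"] == 1.0 and ev["f1"] == 1.0
    # empty kept set: NaN precision, zero recall, warning
    none_kept = frame.assign(kept=[0, 0, 0])
    with pytest.warns(UserWarning):
        ev0 = evaluate_partition(ReadPartition(params, none_kept), truth)
    assert np.isnan(ev0["precision"]) and ev0["recall"] == 0.0
    # missing truth record is an error naming the read
    with pytest.raises(KeyError, match="r9"):
        evaluate_partition(
            ReadPartition(params, frame.assign(read_id=["r1", "r2", "r9"])),
            truth)


def test_partition_tsv_round_trip(tmp_path):
    params = ScreenParams(k=3)
    frame = pd.DataFrame({"read_id": ["a", "b"], "n_hits": [2, 0],
                          "kept": [1, 0]})
    part = ReadPartition(params, frame)
    p = tmp_path / "part.tsv"
    part.write_tsv(p)
    back = ReadPartition.read_tsv(p, params)
    assert back.frame.equals(
        frame.astype({"n_hits": back.frame["n_hits"].dtype,
                      "kept": back.frame["kept"].dtype}))


def test_fully_differentiated_screen_is_exact():
    """Genome-derived specific k-mers recover exactly the W-origin reads."""
    cfg = simdata.SimConfig(seed=7, autosome_lengths=(30_000,),
                            z_length=30_000, w_fully_differentiated=True,
                            n_females=1, n_males=1, long_error=0.0,
                            long_coverage=6)
    g, _ = simdata.simulate_individuals(simdata.simulate_genome(cfg), cfg)
    spec = kmerset.difference(
        count_kmers([g.w_sequence], cfg.k),
        count_kmers(list(g.male_reference.values()), cfg.k))
    long_reads = simdata.simulate_reads(g, cfg, "long")
    female = next(rs for rs in long_reads if rs.sex == "F")
    part = screen_reads(female, spec, ScreenParams(k=cfg.k))
    truth = simdata.SimTruth.build(g, [female])
    ev = evaluate_partition(part, truth.reads)
    assert ev["precision"] == 1.0
    assert ev["recall"] == 1.0
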