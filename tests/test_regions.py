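import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcrsv.regions import (
    Region,
    RegionBuildConfig,
    RegionError,
    RegionSet,
    build_lcr_regions,
    filter_by_satellite,
    filter_min_length,
    lcr_segdup_overlap_stats,
    merge_with_polymorphic,
    pad_and_merge,
    total_coverage,
)

from _oracles import bitvec, bitvec_to_intervals, random_regionset

GENOME = {"chr1": 5_000, "chr2": 3_000}


def rs(tuples, genome=GENOME):
    return RegionSet.from_tuples(tuples, genome)


class TestValidation:
    def test_rejects_unknown_chromosome(self):
        with pytest.raises(RegionError, match="chrX"):
            rs([("chrX", 0, 10)])

    def test_rejects_inverted_and_out_of_bounds(self):
        with pytest.raises(RegionError):
            rs([("chr1", 10, 10)])
        with pytest.raises(RegionError):
            rs([("chr1", 4_999, 5_001)])

    def test_records_sorted_on_construction(self):
        s = rs([("chr2", 0, 5), ("chr1", 50, 60), ("chr1", 0, 10)])
        assert [(r.chrom, r.start) for r in s] == [("chr1", 0), ("chr1", 50), ("chr2", 0)]


class TestSatelliteFilter:
    def test_any_overlap_drops(self):
        cands = rs([("chr1", 100, 200)])
        sats = rs([("chr1", 150, 160)])
        assert len(filter_by_satellite(cands, sats)) == 0

    def test_disjoint_retained(self):
        cands = rs([("chr1", 100, 200)])
        sats = rs([("chr1", 300, 400)])
        assert len(filter_by_satellite(cands, sats)) == 1

    def test_count_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        cands = random_regionset(rng, GENOME, 10, max_len=200)
        sats = random_regionset(rng, GENOME, 4, max_len=300)
        got = filter_by_satellite(cands, sats)
        expected = [
            c
            for c in cands.records
            if not any(
                c.chrom == s.chrom and c.start < s.end and s.start < c.end
                for s in sats.records
            )
        ]
        assert list(got.records) == sorted(expected, key=lambda r: (r.chrom, r.start, r.end))

    def test_fraction_policy_keeps_lightly_touched(self):
        cands = rs([("chr1", 100, 200)])
        sats = rs([("chr1", 190, 210)])  # 10% of the candidate
        assert len(filter_by_satellite(cands, sats, policy="fraction", min_frac=0.5)) == 1
        assert len(filter_by_satellite(cands, sats, policy="any")) == 0


class TestMinLength:
    def test_boundary(self):
        s = rs([("chr1", 0, 49), ("chr1", 100, 150)])
        kept = filter_min_length(s, 50)
        assert [(r.start, r.end) for r in kept] == [(100, 150)]

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        s = random_regionset(rng, GENOME, 30, max_len=120)
        assert len(filter_min_length(s, 60)) == sum(1 for r in s if r.length >= 60)


class TestMergeAndPad:
    def test_overlapping_union(self):
        got = merge_with_polymorphic(rs([("chr1", 10, 20)]), rs([("chr1", 15, 30)]))
        assert [(r.start, r.end) for r in got] == [(10, 30)]

    def test_disjoint_union_counts(self):
        a = rs([("chr1", 0, 10), ("chr2", 0, 10)])
        b = rs([("chr1", 100, 110)])
        assert len(merge_with_polymorphic(a, b)) == 3

    def test_abutting_coalesced(self):
        got = rs([("chr1", 0, 10), ("chr1", 10, 20)]).merge()
        assert [(r.start, r.end) for r in got] == [(0, 20)]

    def test_pad_arithmetic(self):
        got = pad_and_merge(rs([("chr1", 10, 20)]), 5)
        assert [(r.start, r.end) for r in got] == [(5, 25)]

    def test_pad_clips_at_chromosome_start(self):
        got = pad_and_merge(rs([("chr1", 2, 8)]), 5)
        assert [(r.start, r.end) for r in got] == [(0, 13)]

    def test_pad_joins_near_neighbours(self):
        got = pad_and_merge(rs([("chr1", 10, 20), ("chr1", 26, 30)]), 5)
        assert [(r.start, r.end) for r in got] == [(5, 35)]

    def test_coverage_examples(self):
        assert total_coverage(rs([])) == 0
        assert total_coverage(rs([("chr1", 0, 10), ("chr1", 20, 25)])) == 15


@st.composite
def interval_sets(draw, max_n=15):
    genome = {"chr1": 1_000}
    n = draw(st.integers(0, max_n))
    recs = []
    for _ in range(n):
        start = draw(st.integers(0, 995))
        length = draw(st.integers(1, min(200, 1_000 - start)))
        recs.append(("chr1", start, start + length))
    return RegionSet.from_tuples(recs, genome)


@settings(derandomize=True, max_examples=60)
@given(a=interval_sets(), b=interval_sets(), pad=st.integers(0, 30))
def test_set_operations_match_bitvector_oracle(a, b, pad):
    """merge/union/subtract/pad agree per-base with an explicit bit vector."""
    va, vb = bitvec(a)["chr1"], bitvec(b)["chr1"]
    assert bitvec(a.merge())["chr1"].tolist() == va.tolist()
    assert bitvec(a.union(b))["chr1"].tolist() == (va | vb).tolist()
    assert bitvec(a.subtract(b))["chr1"].tolist() == (va & ~vb).tolist()
    # pad oracle: dilate the bit vector
    vp = np.zeros_like(va)
    for s, e in bitvec_to_intervals(va):
        vp[max(0, s - pad) : min(len(vp), e + pad)] = True
    assert bitvec(a.pad(pad))["chr1"].tolist() == vp.tolist()
    assert total_coverage(a) == int(va.sum())


@settings(derandomize=True, max_examples=60)
@given(a=interval_sets(), pad=st.integers(0, 30))
def test_pad_merge_idempotent_and_monotone(a, pad):
    once = pad_and_merge(a, pad)
    assert pad_and_merge(once, 0).records == once.records
    assert total_coverage(once) >= total_coverage(a)
    assert total_coverage(filter_min_length(a, 50)) <= total_coverage(a)


def test_build_recipe_order_and_summary():
    genome = {"chr1": 10_000}
    cands = RegionSet.from_tuples(
        [("chr1", 100, 200), ("chr1", 300, 340), ("chr1", 500, 700), ("chr1", 900, 960)],
        genome,
    )
    sats = RegionSet.from_tuples([("chr1", 150, 160)], genome)  # kills the first
    poly = RegionSet.from_tuples([("chr1", 695, 800)], genome)  # extends the third
    final, summary = build_lcr_regions(
        cands, sats, poly, RegionBuildConfig(min_lcr_len=50, pad=5)
    )
    # candidate [300,340) is shorter than 50 bp and dropped
    assert summary["n_after_satellite"] == 3
    assert summary["n_after_min_len"] == 2
    assert [(r.start, r.end) for r in final] == [(495, 805), (895, 965)]
    assert summary["coverage_final"] == total_coverage(final)


def test_lcr_segdup_overlap_reports_both_conventions():
    genome = {"chr1": 10_000}
    lcr = RegionSet.from_tuples([("chr1", 0, 100), ("chr1", 200, 300)], genome)
    segdup = RegionSet.from_tuples([("chr1", 90, 110)], genome)
    stats = lcr_segdup_overlap_stats(lcr, segdup)
    assert stats["record_fraction"] == pytest.approx(0.5)
    assert stats["base_fraction"] == pytest.approx(10 / 200)
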