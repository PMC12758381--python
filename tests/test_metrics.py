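import math

import numpy as np
import pytest

from lcrsv.matching import MatchResult
from lcrsv.metrics import (
    MetricsError,
    assign_lcr_regions,
    bin_by_max_allele_length,
    length_share,
    stratified_rates,
)
from lcrsv.regions import RegionSet
from lcrsv.stratify import SvRecord


def deletion(pos, size, chrom="chr1", id=None):
    return SvRecord(chrom=chrom, pos=pos, ref_len=size + 1, alt_len=1, id=id)


def simple_match(n_tp, n_fp, n_fn, cls="LCR"):
    classes = {}
    tp = []
    for i in range(n_tp):
        classes[f"t{i}"] = cls
        classes[f"c{i}"] = cls
        tp.append((f"t{i}", f"c{i}", 1.0))
    fp = [f"fp{i}" for i in range(n_fp)]
    fn = [f"fn{i}" for i in range(n_fn)]
    classes.update({k: cls for k in fp + fn})
    return MatchResult(tp, fp, fn), classes


class TestStratifiedRates:
    def test_single_class_arithmetic(self):
        res, classes = simple_match(90, 10, 10)
        rep = stratified_rates(res, classes)
        assert rep.fdr("LCR") == pytest.approx(0.10)
        assert rep.fnr("LCR") == pytest.approx(0.10)

    def test_zero_fp_means_zero_fdr(self):
        res, classes = simple_match(50, 0, 5)
        rep = stratified_rates(res, classes)
        assert rep.fdr("LCR") == 0.0

    def test_zero_denominator_emits_missing_not_zero(self):
        res, classes = simple_match(0, 0, 3)
        rep = stratified_rates(res, classes)
        assert math.isnan(rep.fdr("LCR"))
        assert rep.fnr("LCR") == 1.0

    def test_missing_class_is_error(self):
        res, classes = simple_match(1, 0, 0)
        del classes["c0"]
        with pytest.raises(MetricsError, match="no class"):
            stratified_rates(res, classes)

    def test_class_sums_equal_totals(self):
        rng = np.random.default_rng(2)
        tp, fp, fn = [], [], []
        classes = {}
        for i in range(200):
            c = str(rng.choice(["LCR", "SegDup", "Other"]))
            kind = rng.random()
            if kind < 0.6:
                tp.append((f"t{i}", f"c{i}", 1.0))
                classes[f"t{i}"] = c
                classes[f"c{i}"] = str(rng.choice(["LCR", "SegDup", "Other"]))
            elif kind < 0.8:
                fp.append(f"c{i}")
                classes[f"c{i}"] = c
            else:
                fn.append(f"t{i}")
                classes[f"t{i}"] = c
        rep = stratified_rates(MatchResult(tp, fp, fn), classes)
        f = rep.frame.drop(index="Total")
        assert f["tp_call"].sum() == len(tp) == f["tp_truth"].sum()
        assert f["fp"].sum() == len(fp) and f["fn"].sum() == len(fn)

    def test_invariant_to_input_order(self):
        res, classes = simple_match(10, 3, 2)
        rev = MatchResult(res.tp_pairs[::-1], res.fp[::-1], res.fn[::-1])
        assert stratified_rates(res, classes).frame.equals(
            stratified_rates(rev, classes).frame
        )


class TestLengthShare:
    def test_single_class_share_is_one(self):
        truth = [deletion(100, 60, id="t0"), deletion(900, 80, id="t1")]
        shares = length_share(truth, {"t0": "LCR", "t1": "LCR"})
        assert shares["LCR"] == 1.0

    def test_three_to_seven_split(self):
        truth = [deletion(100, 300, id="t0"), deletion(9_000, 700, id="t1")]
        shares = length_share(truth, {"t0": "LCR", "t1": "Other"})
        assert shares["LCR"] == pytest.approx(0.3)
        assert shares["Other"] == pytest.approx(0.7)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(4)
        truth = [deletion(500 * i + 1, int(rng.integers(50, 400)), id=f"t{i}")
                 for i in range(50)]
        classes = {t.id: str(rng.choice(["LCR", "Other"])) for t in truth}
        shares = length_share(truth, classes)
        total = sum(t.size for t in truth)
        expect = sum(t.size for t in truth if classes[t.id] == "LCR") / total
        assert shares["LCR"] == pytest.approx(expect)

    def test_empty_truth_errors(self):
        with pytest.raises(MetricsError):
            length_share([], {})


class TestAssignRegions:
    def test_max_overlap_wins(self):
        genome = {"chr1": 10_000}
        lcr = RegionSet.from_tuples([("chr1", 100, 160), ("chr1", 180, 400)], genome)
        sv = deletion(150, 100, id="d")  # interval [150,250): 10 bp vs 70 bp
        assert assign_lcr_regions([sv], lcr)["d"] == ("chr1", 180, 400)

    def test_no_overlap_absent(self):
        genome = {"chr1": 10_000}
        lcr = RegionSet.from_tuples([("chr1", 100, 160)], genome)
        assert assign_lcr_regions([deletion(5_000, 60, id="d")], lcr) == {}


class TestLengthBins:
    def test_single_bin_equals_global_rates(self):
        res, classes = simple_match(90, 10, 10)
        region = ("chr1", 100, 400)
        region_of = {k: region for k in classes}
        rep = bin_by_max_allele_length(res, classes, region_of, {region: 150})
        row = rep.frame.loc["[100,250)"]
        assert row["fdr"] == pytest.approx(0.10)
        assert row["fnr"] == pytest.approx(0.10)
        assert rep.frame["n"].sum() == 100  # truth side fully assigned

    def test_edge_value_falls_in_upper_bin(self):
        res, classes = simple_match(1, 0, 0)
        region = ("chr1", 0, 3_000)
        region_of = {k: region for k in classes}
        rep = bin_by_max_allele_length(res, classes, region_of, {region: 2_000})
        assert rep.frame.loc[">=2000", "tp_truth"] == 1

    def test_monotone_error_model_gives_monotone_fnr(self):
        # planted: longer max-allele regions miss more truth SVs
        edges = (0, 100, 250, 500, 1000, 2000)
        tp, fn = [], []
        classes, region_of, max_len = {}, {}, {}
        fnr_by_bin = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        lengths = [50, 150, 300, 700, 1_500, 5_000]
        n = 40
        k = 0
        for b, (L, fnr) in enumerate(zip(lengths, fnr_by_bin)):
            region = ("chr1", 10_000 * b, 10_000 * b + 100)
            max_len[region] = L
            n_fn = int(round(fnr * n))
            for i in range(n):
                tid = f"t{k}"
                classes[tid] = "LCR"
                region_of[tid] = region
                if i < n_fn:
                    fn.append(tid)
                else:
                    cid = f"c{k}"
                    classes[cid] = "LCR"
                    region_of[cid] = region
                    tp.append((tid, cid, 1.0))
                k += 1
        rep = bin_by_max_allele_length(MatchResult(tp, [], fn), classes, region_of,
                                       max_len, edges)
        fnrs = rep.frame["fnr"].tolist()
        assert fnrs == sorted(fnrs)

    def test_lcr_variant_without_region_errors(self):
        res, classes = simple_match(1, 0, 0)
        with pytest.raises(MetricsError, match="no associated"):
            bin_by_max_allele_length(res, classes, {}, {})
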