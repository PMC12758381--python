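import dataclasses

import numpy as np
import pytest

from lcrsv.matching import match
from lcrsv.simulate import (
    ClassError,
    SimConfig,
    SimulationError,
    default_partition,
    generate_bubble_table,
    generate_reference,
    plant_truth_svs,
    simulate_caller,
)
from lcrsv.stratify import classify_sv


def small_cfg(**overrides):
    base = dict(
        seed=0,
        n_chroms=2,
        chrom_len=200_000,
        lcr_count=60,
        segdup_count=1,
        segdup_len=5_000,
        truth_sv_counts={
            "LCR": {"INS": 30, "DEL": 15},
            "SegDup": {"INS": 3, "DEL": 2},
            "Other": {"INS": 10, "DEL": 10},
        },
    )
    base.update(overrides)
    return SimConfig(**base)


class TestGenerateReference:
    def test_empty_case(self):
        cfg = small_cfg(lcr_count=0, segdup_count=0, notconf_fraction=0.0,
                        truth_sv_counts={})
        ref = generate_reference(cfg)
        assert len(ref.lcr) == 0 and len(ref.segdup) == 0 and len(ref.notconf) == 0
        assert all(len(s) == cfg.chrom_len for s in ref.sequences.values())

    def test_planted_lcr_lengths_match_construction(self):
        cfg = small_cfg(lcr_count=10, lcr_unit_len_range=(20, 20),
                        lcr_copies_range=(10, 10), segdup_count=0)
        ref = generate_reference(cfg)
        assert len(ref.lcr) == 10
        assert all(r.length == 200 for r in ref.lcr)

    def test_lcr_interval_holds_a_tandem_repeat(self):
        cfg = small_cfg(lcr_count=5, lcr_impurity=0.0,
                        lcr_unit_len_range=(10, 10), lcr_copies_range=(12, 12),
                        segdup_count=0)
        ref = generate_reference(cfg)
        r = ref.lcr.records[0]
        s = ref.sequences[r.chrom][r.start : r.end]
        unit = s[:10]
        assert s == unit * 12

    def test_segdup_pairs_are_near_identical(self):
        cfg = small_cfg(segdup_count=1, lcr_count=0)
        ref = generate_reference(cfg)
        (a, b) = ref.segdup.records
        sa = ref.sequences[a.chrom][a.start : a.end]
        sb = ref.sequences[b.chrom][b.start : b.end]
        ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
        assert ident > 0.97

    def test_determinism_byte_identical(self):
        cfg = small_cfg()
        r1 = generate_reference(cfg)
        r2 = generate_reference(cfg)
        assert r1.sequences == r2.sequences
        assert r1.lcr.records == r2.lcr.records
        assert r1.notconf.records == r2.notconf.records

    def test_infeasible_packing_names_deficit(self):
        cfg = small_cfg(chrom_len=30_000, lcr_count=200)
        with pytest.raises(SimulationError, match="bp more"):
            generate_reference(cfg)


class TestPlantTruth:
    def test_zero_counts_give_empty_truth(self):
        cfg = small_cfg(truth_sv_counts={})
        ref = generate_reference(cfg)
        assert plant_truth_svs(cfg, ref) == []

    def test_planted_class_fidelity_is_total(self):
        cfg = small_cfg()
        ref = generate_reference(cfg)
        partition = default_partition(ref)
        truth = plant_truth_svs(cfg, ref, partition)
        wanted = sum(v for c in cfg.truth_sv_counts.values() for v in c.values())
        assert len(truth) == wanted
        assert all(classify_sv(t, partition) == t.sim_class for t in truth)

    def test_requested_lcr_count_exact(self):
        cfg = small_cfg(truth_sv_counts={"LCR": {"INS": 40, "DEL": 0}})
        ref = generate_reference(cfg)
        partition = default_partition(ref)
        truth = plant_truth_svs(cfg, ref, partition)
        assert sum(1 for t in truth if classify_sv(t, partition) == "LCR") == 40

    def test_sv_length_bounds_respected(self):
        cfg = small_cfg(sv_len_range=(50, 60))
        ref = generate_reference(cfg)
        truth = plant_truth_svs(cfg, ref)
        assert all(50 <= t.size <= 60 for t in truth)

    def test_insertions_carry_sequence_deletions_span_ref(self):
        cfg = small_cfg()
        ref = generate_reference(cfg)
        truth = plant_truth_svs(cfg, ref)
        for t in truth:
            if t.svtype == "INS":
                assert t.seq is not None and len(t.seq) == t.size
            else:
                assert t.ref_len == t.size + 1


class TestSimulateCaller:
    def test_zero_error_identity(self):
        cfg = small_cfg()
        ref = generate_reference(cfg)
        partition = default_partition(ref)
        truth = plant_truth_svs(cfg, ref, partition)
        zero = {c: ClassError(0.0, 0.0, 0.0, 0.0) for c in ("LCR", "SegDup", "Other")}
        calls = simulate_caller(truth, zero, 1, partition, ref.sequences)
        assert len(calls) == len(truth)
        assert [(c.chrom, c.pos, c.sv_len) for c in calls] == [
            (t.chrom, t.pos, t.sv_len) for t in truth
        ]

    def test_fnr_within_binomial_interval(self):
        # drop-only path needs no reference; synthetic truth records suffice
        from lcrsv.stratify import SvRecord
        from lcrsv.regions import RegionSet
        from lcrsv.stratify import build_partition

        genome = {"chr1": 10_000_000}
        conf = RegionSet.from_tuples([("chr1", 0, 10_000_000)], genome)
        partition = build_partition(conf, RegionSet.empty(genome), RegionSet.empty(genome))
        truth = [
            SvRecord("chr1", 1_000 + 800 * i, 101, 1, id=f"t{i}", sim_class="Other")
            for i in range(1_000)
        ]
        em = {"Other": ClassError(fdr=0.0, fnr=0.5, jitter_sd=0.0, length_sd=0.0)}
        calls = simulate_caller(truth, em, 123, partition)
        # 99% binomial interval around 500 for n=1000, p=0.5
        assert 459 <= len(calls) <= 541

    def test_fp_count_targets_fdr(self):
        cfg = small_cfg(truth_sv_counts={"Other": {"INS": 0, "DEL": 60}},
                        lcr_count=0, segdup_count=0)
        ref = generate_reference(cfg)
        partition = default_partition(ref)
        truth = plant_truth_svs(cfg, ref, partition)
        em = {"Other": ClassError(fdr=0.2, fnr=0.0, jitter_sd=0.0, length_sd=0.0)}
        n_fp = []
        for seed in range(20):
            calls = simulate_caller(truth, em, seed, partition, ref.sequences)
            n_fp.append(len(calls) - len(truth))
        # each draw ~ Poisson(60 * 0.25) = Poisson(15)
        assert 10 <= np.mean(n_fp) <= 20

    def test_perturbed_calls_remain_matchable(self):
        cfg = small_cfg()
        ref = generate_reference(cfg)
        partition = default_partition(ref)
        truth = plant_truth_svs(cfg, ref, partition)
        em = {c: ClassError(fdr=0.0, fnr=0.0, jitter_sd=25.0, length_sd=10.0)
              for c in ("LCR", "SegDup", "Other")}
        calls = simulate_caller(truth, em, 7, partition, ref.sequences)
        res = match(calls, truth)
        assert res.fp == [] and res.fn == []


class TestBubbleTable:
    def test_zero_polymorphic_fraction_is_empty(self):
        cfg = small_cfg(polymorphic_fraction=0.0)
        ref = generate_reference(cfg)
        assert generate_bubble_table(cfg, ref.lcr) == []

    def test_fraction_of_lcrs_get_bubbles(self):
        cfg = small_cfg(polymorphic_fraction=0.5)
        ref = generate_reference(cfg)
        bubbles = generate_bubble_table(cfg, ref.lcr)
        assert len(bubbles) == round(0.5 * len(ref.lcr))
        assert all(len(b.alleles) >= 2 for b in bubbles)

    def test_support_mix_straddles_threshold(self):
        cfg = small_cfg(polymorphic_fraction=1.0)
        ref = generate_reference(cfg)
        bubbles = generate_bubble_table(cfg, ref.lcr, min_support=5)
        supports = [a.support(("HG002",)) for b in bubbles for a in b.alt_alleles]
        assert any(s < 5 for s in supports) and any(s >= 5 for s in supports)

    def test_determinism(self):
        cfg = small_cfg()
        ref = generate_reference(cfg)
        assert generate_bubble_table(cfg, ref.lcr) == generate_bubble_table(cfg, ref.lcr)


def test_config_validation():
    with pytest.raises(ValueError, match="sv_len_range"):
        small_cfg(sv_len_range=(40, 100))
    with pytest.raises(ValueError):
        small_cfg(lcr_impurity=1.5)
    with pytest.raises(ValueError):
        ClassError(fdr=1.0)
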