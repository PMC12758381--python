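"""End-to-end synthetic pipeline: simulate -> build regions -> annotate
bubbles -> partition -> plant truth -> emulate caller -> classify -> match
-> stratified reports.

Every stage is the library function the CLI exposes; this module only
sequences them, derives per-stage random streams from the single seed, and
writes the machine-readable summary.  Running twice with the same config
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .bubbles import max_allele_length_map, project_polymorphic_lcrs, write_bubble_table
from .matching import MatchParams, MatchResult, match
from .metrics import (
    DEFAULT_BIN_EDGES,
    LengthBinReport,
    StratifiedReport,
    assign_lcr_regions,
    bin_by_max_allele_length,
    length_share,
    stratified_rates,
)
from .regions import RegionBuildConfig, RegionSet, build_lcr_regions, total_coverage
from .simulate import (
    ReferenceBundle,
    SimConfig,
    generate_bubble_table,
    generate_reference,
    plant_truth_svs,
    simulate_caller,
)
from .stratify import (
    ClassifyConfig,
    GenomePartition,
    SvRecord,
    build_partition,
    classify_sv,
    filter_truth,
    overlap_fractions,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    build: RegionBuildConfig = field(default_factory=RegionBuildConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    match: MatchParams = field(default_factory=MatchParams)
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES


@dataclass
class PipelineResult:
    ref: ReferenceBundle
    final_lcr: RegionSet
    partition: GenomePartition
    bubbles: list
    truth: list[SvRecord]
    calls: list[SvRecord]
    classes: dict[str, str]
    match_result: MatchResult
    stratified: StratifiedReport
    shares: pd.Series
    bins: LengthBinReport
    summary: dict


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    return obj


def run_pipeline(cfg: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    seed = cfg.sim.seed

    ref = generate_reference(cfg.sim, np.random.default_rng(seed))
    bubbles = generate_bubble_table(
        cfg.sim, ref.lcr, np.random.default_rng(seed + 2), cfg.build.min_support
    )
    poly = project_polymorphic_lcrs(
        bubbles,
        ref.genome,
        min_support=cfg.build.min_support,
        excluded_samples=cfg.build.excluded_samples,
    )
    final_lcr, region_summary = build_lcr_regions(ref.lcr, None, poly, cfg.build)
    confident = ref.notconf.complement("Confident")
    partition = build_partition(confident, final_lcr, ref.segdup, ref.genome)

    truth_all = plant_truth_svs(
        cfg.sim, ref, partition, np.random.default_rng(seed + 1), cfg.classify
    )
    truth, truth_report = filter_truth(truth_all, cfg.classify, confident)
    calls_all = simulate_caller(
        truth,
        cfg.sim.error_model,
        np.random.default_rng(seed + 3),
        partition,
        ref.sequences,
        params=cfg.match,
        sv_len_range=cfg.sim.sv_len_range,
        spacing=cfg.sim.sv_spacing,
        margin=cfg.sim.sv_margin,
        min_sv_len=cfg.classify.min_sv_len,
    )
    calls, call_report = filter_truth(calls_all, cfg.classify, confident)

    classes = {
        sv.id: classify_sv(sv, partition, cfg.classify) for sv in [*truth, *calls]
    }
    match_result = match(calls, truth, cfg.match)
    stratified = stratified_rates(match_result, classes)
    shares = length_share(truth, classes)

    maxlen = max_allele_length_map(
        final_lcr, bubbles, cfg.build.min_support, cfg.build.excluded_samples
    )
    region_of = assign_lcr_regions([*truth, *calls], final_lcr, cfg.classify)
    bins = bin_by_max_allele_length(
        match_result, classes, region_of, maxlen, cfg.bin_edges
    )

    coverage = partition.coverage()
    genome_len = sum(ref.genome.values())
    truth_class_counts = {
        c: sum(1 for sv in truth if classes[sv.id] == c)
        for c in ("LCR", "SegDup", "Other")
    }
    strat = stratified.frame
    summary = {
        "seed": seed,
        "genome_length": genome_len,
        "partition_coverage": coverage,
        "lcr_genome_fraction": coverage["LCR"] / genome_len,
        "lcr_final_records": len(final_lcr),
        "lcr_final_coverage": total_coverage(final_lcr),
        "region_build": region_summary,
        "truth_filter": truth_report,
        "call_filter": call_report,
        "n_truth": len(truth),
        "n_calls": len(calls),
        "truth_class_counts": truth_class_counts,
        "truth_lcr_fraction": (
            truth_class_counts["LCR"] / len(truth) if truth else None
        ),
        "length_share": {k: float(v) for k, v in shares.items()},
        "rates": {
            c: {
                "tp": int(strat.loc[c, "tp_call"]) if c in strat.index else 0,
                "fp": int(strat.loc[c, "fp"]) if c in strat.index else 0,
                "fn": int(strat.loc[c, "fn"]) if c in strat.index else 0,
                "fdr": float(strat.loc[c, "fdr"]) if c in strat.index else None,
                "fnr": float(strat.loc[c, "fnr"]) if c in strat.index else None,
            }
            for c in ("LCR", "SegDup", "Other", "Total")
        },
        "discordant_tp_pairs": stratified.discordant_pairs,
        "thresholds": {
            "overlap_threshold": cfg.classify.overlap_threshold,
            "min_sv_len": cfg.classify.min_sv_len,
            "insertion_interval_mode": cfg.classify.insertion_interval_mode,
            "confident_overlap": cfg.classify.confident_overlap,
            "min_lcr_len": cfg.build.min_lcr_len,
            "pad": cfg.build.pad,
            "min_support": cfg.build.min_support,
            "excluded_samples": list(cfg.build.excluded_samples),
            "refdist": cfg.match.refdist,
            "pctsize": cfg.match.pctsize,
            "pctseq": cfg.match.pctseq,
            "bin_edges": list(cfg.bin_edges),
            "error_model": {c: asdict(e) for c, e in cfg.sim.error_model.items()},
        },
    }
    result = PipelineResult(
        ref=ref,
        final_lcr=final_lcr,
        partition=partition,
        bubbles=bubbles,
        truth=truth,
        calls=calls,
        classes=classes,
        match_result=match_result,
        stratified=stratified,
        shares=shares,
        bins=bins,
        summary=_jsonable(summary),
    )
    if outdir is not None:
        write_outputs(result, cfg, Path(outdir))
    return result


def match_to_frame(res: MatchResult) -> pd.DataFrame:
    rows = [
        {"variant": t, "status": "TP-base", "partner": c, "score": s}
        for t, c, s in res.tp_pairs
    ]
    rows += [
        {"variant": c, "status": "TP-call", "partner": t, "score": s}
        for t, c, s in res.tp_pairs
    ]
    rows += [{"variant": c, "status": "FP", "partner": ".", "score": float("nan")} for c in res.fp]
    rows += [{"variant": t, "status": "FN", "partner": ".", "score": float("nan")} for t in res.fn]
    return pd.DataFrame(rows, columns=["variant", "status", "partner", "score"])


def classes_to_frame(
    svs: list[SvRecord], classes: dict[str, str], role: str,
    partition: GenomePartition, cfg: ClassifyConfig,
) -> pd.DataFrame:
    rows = []
    for sv in svs:
        fr = overlap_fractions(sv, partition, cfg)
        rows.append(
            {
                "id": sv.id, "role": role, "chrom": sv.chrom, "pos": sv.pos,
                "svtype": sv.svtype, "sv_len": sv.sv_len, "class": classes[sv.id],
                "overlap_frac": round(fr[classes[sv.id]], 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "role", "chrom", "pos", "svtype", "sv_len", "class", "overlap_frac"],
    )


def write_outputs(result: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_fasta(result.ref.sequences, outdir / "reference.fa")
    lio.write_genome(result.ref.genome, outdir / "genome.tsv")
    lio.write_bed(result.ref.lcr, outdir / "lcr_candidates.bed")
    lio.write_bed(result.ref.segdup, outdir / "segdup.bed")
    lio.write_bed(result.ref.notconf, outdir / "notconf.bed")
    lio.write_bed(result.final_lcr, outdir / "lcr_final.bed")
    write_bubble_table(result.bubbles, outdir / "bubbles.tsv")
    lio.write_sv_vcf(result.truth, outdir / "truth.vcf", result.ref.genome, result.ref.sequences)
    lio.write_sv_vcf(result.calls, outdir / "calls.vcf", result.ref.genome, result.ref.sequences)
    match_to_frame(result.match_result).to_csv(outdir / "match.tsv", sep="\t", index=False)
    pd.concat(
        [
            classes_to_frame(result.truth, result.classes, "truth", result.partition, cfg.classify),
            classes_to_frame(result.calls, result.classes, "call", result.partition, cfg.classify),
        ]
    ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
    result.stratified.frame.to_csv(outdir / "stratified.tsv", sep="\t")
    result.bins.frame.to_csv(outdir / "length_bins.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
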