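"""Genome partitioning and per-SV classification.

Every reference base receives exactly one of four labels, assigned in
priority order NotConf > LCR > SegDup > Other: bases outside the
benchmark's confident regions are NotConf regardless of annotation; LCR
bases are low-complexity bases inside confident regions; SegDup bases are
segmental-duplication bases not already taken; everything else is Other.

An SV is classified by the fraction of its reference interval covered by
each label: it belongs to a label when at least 70% of the interval
(inclusive) carries that label, evaluated in the same priority order.  A
deletion's interval is the deleted bases (the VCF anchor base excluded);
an insertion's interval is, by default, the single anchor base — the
stratification BED is padded, so the anchor suffices — with an optional
symmetric-flank mode for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import RegionSet, overlap_length

__all__ = [
    "LABELS",
    "SvRecord",
    "ClassifyConfig",
    "GenomePartition",
    "build_partition",
    "sv_interval",
    "classify_sv",
    "overlap_fractions",
    "filter_truth",
]

LABELS = ("NotConf", "LCR", "SegDup", "Other")


class StratifyError(ValueError):
    pass


@dataclass
class SvRecord:
    """One structural variant (single ALT).

    ``pos`` is the 1-based VCF position of the anchor base.  ``sv_len`` is
    signed: positive for insertions, negative for deletions.  ``seq``
    optionally carries the inserted sequence (insertions only) for
    sequence-aware matching.
    """

    chrom: str
    pos: int
    ref_len: int
    alt_len: int
    id: str | None = None
    alt_is_star: bool = False
    genotype: str = "./."
    filter: str = "PASS"
    seq: str | None = None
    sim_class: str | None = None  # intended class, set by the simulator only

    @property
    def sv_len(self) -> int:
        return self.alt_len - self.ref_len

    @property
    def svtype(self) -> str:
        return "INS" if self.sv_len > 0 else "DEL"

    @property
    def size(self) -> int:
        return abs(self.sv_len)


@dataclass
class ClassifyConfig:
    """Classification thresholds.

    overlap_threshold     label fraction needed to claim an SV (default 0.70,
                          inclusive).
    min_sv_len            minimum |sv_len| kept by the truth/call filters
                          (default 50 bp, the SV definition).
    insertion_interval_mode  "anchor" (single base at the anchor, default) or
                          "padded" (anchor +/- insertion_flank).
    confident_overlap     fraction of the SV interval that must lie inside
                          confident regions for the SV to be scored
                          (default 1.0: fully contained).
    """

    overlap_threshold: float = 0.70
    min_sv_len: int = 50
    insertion_interval_mode: str = "anchor"
    insertion_flank: int = 5
    confident_overlap: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.min_sv_len < 1:
            raise ValueError("min_sv_len must be >= 1")
        if self.insertion_interval_mode not in ("anchor", "padded"):
            raise ValueError(
                f"unknown insertion_interval_mode {self.insertion_interval_mode!r}"
            )


_EMPTY = (np.empty(0, np.int64), np.empty(0, np.int64))


@dataclass
class GenomePartition:
    """Disjoint labeling of every base: label -> chrom -> merged arrays."""

    genome: dict[str, int]
    arrays: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]

    def coverage(self) -> dict[str, int]:
        out = {}
        for label in LABELS:
            per = self.arrays.get(label, {})
            out[label] = sum(int(np.sum(e - s)) for s, e in per.values())
        return out

    def label_regions(self, label: str) -> RegionSet:
        return RegionSet.from_arrays(self.arrays.get(label, {}), self.genome, label)

    def overlap(self, label: str, chrom: str, start: int, end: int) -> int:
        starts, ends = self.arrays.get(label, {}).get(chrom, _EMPTY)
        return overlap_length(starts, ends, start, end)


def build_partition(
    confident: RegionSet,
    lcr: RegionSet,
    segdup: RegionSet,
    genome: Mapping[str, int] | None = None,
) -> GenomePartition:
    """Paint the genome NotConf/LCR/SegDup/Other in priority order.

    NotConf is the complement of the confident regions; LCR excludes
    NotConf bases; SegDup excludes NotConf and LCR bases; Other is the
    remainder.  Coverages sum exactly to the genome length.
    """
    genome = dict(genome) if genome is not None else dict(confident.genome)
    for rs in (confident, lcr, segdup):
        for chrom in rs.genome:
            if chrom not in genome:
                raise StratifyError(f"chromosome {chrom!r} has no length in the genome map")
    notconf = confident.complement()
    lcr_part = lcr.merge().subtract(notconf)
    segdup_part = segdup.merge().subtract(notconf).subtract(lcr_part)
    taken = notconf.union(lcr_part).union(segdup_part)
    other = taken.complement()
    arrays = {
        "NotConf": notconf.chrom_arrays(merged=True),
        "LCR": lcr_part.chrom_arrays(merged=True),
        "SegDup": segdup_part.chrom_arrays(merged=True),
        "Other": other.chrom_arrays(merged=True),
    }
    return GenomePartition(genome=genome, arrays=arrays)


def sv_interval(sv: SvRecord, cfg: ClassifyConfig | None = None) -> tuple[int, int]:
    """Reference interval of an SV, 0-based half-open.

    Deletions: the deleted bases, excluding the VCF anchor base (the record
    is assumed left-aligned; no re-normalization is performed).  Insertions:
    the anchor base alone, or anchor +/- flank in "padded" mode.
    """
    cfg = cfg or ClassifyConfig()
    if sv.svtype == "DEL":
        return (sv.pos, sv.pos - 1 + sv.ref_len)
    if cfg.insertion_interval_mode == "anchor":
        return (sv.pos - 1, sv.pos)
    return (sv.pos - 1 - cfg.insertion_flank, sv.pos + cfg.insertion_flank)


def overlap_fractions(
    sv: SvRecord, partition: GenomePartition, cfg: ClassifyConfig | None = None
) -> dict[str, float]:
    cfg = cfg or ClassifyConfig()
    s, e = sv_interval(sv, cfg)
    chrom_len = partition.genome.get(sv.chrom)
    if chrom_len is None:
        raise StratifyError(f"SV {sv.id or ''} on unknown chromosome {sv.chrom!r}")
    if cfg.insertion_interval_mode == "padded" and sv.svtype == "INS":
        s, e = max(0, s), min(chrom_len, e)
    if not (0 <= s < e <= chrom_len):
        raise StratifyError(
            f"SV {sv.id or ''} interval {sv.chrom}:{s}-{e} outside genome bounds"
        )
    length = e - s
    return {
        label: partition.overlap(label, sv.chrom, s, e) / length for label in LABELS
    }


def classify_sv(
    sv: SvRecord, partition: GenomePartition, cfg: ClassifyConfig | None = None
) -> str:
    """Assign the SV a partition label by the >=70% interval-overlap rule.

    Labels are tried in priority order; an SV reaching the threshold for
    LCR is never classified SegDup.  An SV reaching no label's threshold
    is Other.
    """
    cfg = cfg or ClassifyConfig()
    fracs = overlap_fractions(sv, partition, cfg)
    for label in ("NotConf", "LCR", "SegDup"):
        if fracs[label] >= cfg.overlap_threshold:
            return label
    return "Other"


def filter_truth(
    records: Iterable[SvRecord],
    cfg: ClassifyConfig | None = None,
    confident: RegionSet | None = None,
) -> tuple[list[SvRecord], dict[str, int]]:
    """Apply the truth-set filters; return (kept records, rejects report).

    Removes '*'-allele records (redundant encodings of alleles hidden by an
    overlapping deletion), records shorter than ``min_sv_len``, and — when
    ``confident`` is given — records whose interval is not sufficiently
    contained in the confident regions (default: fully contained).
    """
    cfg = cfg or ClassifyConfig()
    conf_arrays = confident.chrom_arrays(merged=True) if confident is not None else None
    kept: list[SvRecord] = []
    report = {"input": 0, "star": 0, "short": 0, "non_confident": 0, "kept": 0}
    for sv in records:
        report["input"] += 1
        if sv.alt_is_star:
            report["star"] += 1
            continue
        if sv.size < cfg.min_sv_len:
            report["short"] += 1
            continue
        if conf_arrays is not None:
            s, e = sv_interval(sv, cfg)
            starts, ends = conf_arrays.get(sv.chrom, _EMPTY)
            frac = overlap_length(starts, ends, s, e) / (e - s)
            if frac < cfg.confident_overlap:
                report["non_confident"] += 1
                continue
        kept.append(sv)
        report["kept"] += 1
    return kept, report
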