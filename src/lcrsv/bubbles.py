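"""Pangenome variant bubbles: polymorphic-LCR annotation and allele lengths.

A *bubble* is a site where assembly paths through a pangenome graph diverge
and rejoin; its alleles are the alternative traversals, each carrying the
fraction of its bases annotated as low-complexity (LCR) or segmental
duplication (SegDup) in the source assemblies, and the list of assemblies
supporting it.  A bubble is called a polymorphic LCR when at least 70% of
its sequence is low-complexity and it is not dominated by SegDup — SegDup
takes priority because an LCR inside a long polymorphic SegDup would have
most of its bubble sequence annotated as SegDup.

Rare alternate alleles (supported by fewer than ``min_support`` assemblies,
not counting excluded samples such as the benchmarked one) are dropped so
only common polymorphisms enter the stratification.

The per-LCR *maximum allele length* used for length-binned accuracy is the
longest retained allele of any qualifying bubble intersecting the region,
falling back to the reference length of the region when no common
polymorphic bubble overlaps it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import Region, RegionSet, overlap_length

__all__ = [
    "Allele",
    "Bubble",
    "annotate_lcr_bubbles",
    "filter_rare_alleles",
    "max_allele_length",
    "max_allele_length_map",
    "project_polymorphic_lcrs",
    "read_bubble_table",
    "write_bubble_table",
]

REFERENCE_SAMPLE = "GRCh38"

BUBBLE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "bubble_id",
    "allele_id",
    "allele_len",
    "lcr_frac",
    "segdup_frac",
    "assemblies",
)


@dataclass(frozen=True)
class Allele:
    allele_id: str
    length: int
    lcr_frac: float | None
    segdup_frac: float | None
    assemblies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("allele length must be >= 0")
        for f in (self.lcr_frac, self.segdup_frac):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError("allele base fractions must lie in [0, 1]")

    @property
    def is_reference(self) -> bool:
        return REFERENCE_SAMPLE in self.assemblies

    def support(self, excluded: Sequence[str] = ()) -> int:
        """Number of supporting assemblies, excluding reference and excluded samples."""
        drop = set(excluded) | {REFERENCE_SAMPLE}
        return len(set(self.assemblies) - drop)


@dataclass(frozen=True)
class Bubble:
    chrom: str
    start: int
    end: int
    bubble_id: str
    alleles: tuple[Allele, ...]
    label: str | None = None  # set by annotate_lcr_bubbles

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"bubble {self.bubble_id} has no alleles")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bubble {self.bubble_id} has an invalid reference interval")

    @property
    def alt_alleles(self) -> tuple[Allele, ...]:
        return tuple(a for a in self.alleles if not a.is_reference)


# ---------------------------------------------------------------------------
# annotation and filtering


def _weighted_fraction(bubble: Bubble, attr: str) -> float:
    """Length-weighted mean of an allele base fraction over all alleles."""
    num = 0.0
    den = 0.0
    for a in bubble.alleles:
        f = getattr(a, attr)
        if f is None:
            raise ValueError(
                f"allele {a.allele_id} of bubble {bubble.bubble_id} is missing {attr}"
            )
        num += f * a.length
        den += a.length
    return num / den if den > 0 else 0.0


def _count_fraction(bubble: Bubble, attr: str) -> float:
    """Fraction of allele sequences that are majority-annotated for ``attr``."""
    flags = []
    for a in bubble.alleles:
        f = getattr(a, attr)
        if f is None:
            raise ValueError(
                f"allele {a.allele_id} of bubble {bubble.bubble_id} is missing {attr}"
            )
        flags.append(f > 0.5)
    return sum(flags) / len(flags)


def annotate_lcr_bubbles(
    bubbles: Iterable[Bubble],
    lcr_threshold: float = 0.70,
    segdup_threshold: float = 0.5,
    mode: str = "base",
) -> list[Bubble]:
    """Label each bubble LCR, SegDup, or Other.

    A bubble is SegDup when the (length-weighted, ``mode="base"``) mean
    segdup fraction of its allele sequences reaches ``segdup_threshold``;
    otherwise it is LCR when the mean lcr fraction reaches
    ``lcr_threshold`` (inclusive).  SegDup has priority over LCR.  With
    ``mode="count"`` the unweighted fraction of majority-annotated allele
    sequences is used instead.
    """
    if mode not in ("base", "count"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    frac = _weighted_fraction if mode == "base" else _count_fraction
    out = []
    for b in bubbles:
        segdup_f = frac(b, "segdup_frac")
        lcr_f = frac(b, "lcr_frac")
        if segdup_f >= segdup_threshold:
            label = "SegDup"
        elif lcr_f >= lcr_threshold:
            label = "LCR"
        else:
            label = "Other"
        out.append(replace(b, label=label))
    return out


def filter_rare_alleles(
    bubbles: Iterable[Bubble],
    min_support: int = 5,
    excluded_samples: Sequence[str] = ("HG002",),
) -> list[Bubble]:
    """Drop non-reference alleles supported by fewer than ``min_support``
    assemblies (excluded samples do not count), then drop bubbles left with
    only the reference allele."""
    out = []
    for b in bubbles:
        kept = tuple(
            a
            for a in b.alleles
            if a.is_reference or a.support(excluded_samples) >= min_support
        )
        if any(not a.is_reference for a in kept):
            out.append(replace(b, alleles=kept))
    return out


def project_polymorphic_lcrs(
    bubbles: Iterable[Bubble],
    genome: Mapping[str, int],
    lcr_threshold: float = 0.70,
    segdup_threshold: float = 0.5,
    min_support: int = 5,
    excluded_samples: Sequence[str] = ("HG002",),
    mode: str = "base",
) -> RegionSet:
    """Reference intervals of common polymorphic LCR bubbles, as a RegionSet.

    Runs the support filter, then annotation, then keeps LCR-labeled
    bubbles; the result feeds the stratification-BED union step.
    """
    common = filter_rare_alleles(bubbles, min_support, excluded_samples)
    labeled = annotate_lcr_bubbles(common, lcr_threshold, segdup_threshold, mode)
    recs = [
        Region(b.chrom, b.start, b.end, "LCR") for b in labeled if b.label == "LCR"
    ]
    return RegionSet(recs, dict(genome))


# ---------------------------------------------------------------------------
# maximum allele length


def max_allele_length(
    region: Region | tuple,
    bubbles: Iterable[Bubble],
    min_support: int = 5,
    excluded_samples: Sequence[str] = ("HG002",),
) -> int:
    """Maximum allele length of an LCR region.

    If the region intersects (>= 1 bp) any bubble that retains at least one
    common alternate allele, return the longest retained allele (reference
    allele included) over all such bubbles; otherwise return the region's
    own reference length.
    """
    chrom, start, end = region[0], int(region[1]), int(region[2])
    best: int | None = None
    for b in bubbles:
        if b.chrom != chrom or b.end <= start or b.start >= end:
            continue
        kept = [
            a
            for a in b.alleles
            if a.is_reference or a.support(excluded_samples) >= min_support
        ]
        if not any(not a.is_reference for a in kept):
            continue  # bubble failed the support filter
        m = max(a.length for a in kept)
        best = m if best is None else max(best, m)
    return best if best is not None else end - start


def max_allele_length_map(
    lcr: RegionSet,
    bubbles: Sequence[Bubble],
    min_support: int = 5,
    excluded_samples: Sequence[str] = ("HG002",),
) -> dict[tuple[str, int, int], int]:
    """``max_allele_length`` for every record of the final LCR set."""
    by_chrom: dict[str, list[Bubble]] = {}
    for b in bubbles:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = {}
    for r in lcr.records:
        out[(r.chrom, r.start, r.end)] = max_allele_length(
            r, by_chrom.get(r.chrom, ()), min_support, excluded_samples
        )
    return out


# ---------------------------------------------------------------------------
# TSV round trip


def write_bubble_table(bubbles: Iterable[Bubble], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(BUBBLE_COLUMNS) + "\n")
        for b in bubbles:
            for a in b.alleles:
                asm = ",".join(a.assemblies) if a.assemblies else "."
                fh.write(
                    f"{b.chrom}\t{b.start}\t{b.end}\t{b.bubble_id}\t{a.allele_id}\t"
                    f"{a.length}\t{a.lcr_frac:.4f}\t{a.segdup_frac:.4f}\t{asm}\n"
                )


def read_bubble_table(path) -> list[Bubble]:
    opener = gzip.open if str(path).endswith(".gz") else open
    groups: dict[str, tuple[str, int, int, list[Allele]]] = {}
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != BUBBLE_COLUMNS:
            raise ValueError(f"unexpected bubble-table header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(BUBBLE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(BUBBLE_COLUMNS)} columns")
            chrom, start, end, bid, aid, alen, lf, sf, asm = fields
            allele = Allele(
                allele_id=aid,
                length=int(alen),
                lcr_frac=float(lf),
                segdup_frac=float(sf),
                assemblies=() if asm == "." else tuple(asm.split(",")),
            )
            if bid in groups:
                groups[bid][3].append(allele)
            else:
                groups[bid] = (chrom, int(start), int(end), [allele])
    return [
        Bubble(chrom, start, end, bid, tuple(alleles))
        for bid, (chrom, start, end, alleles) in groups.items()
    ]
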