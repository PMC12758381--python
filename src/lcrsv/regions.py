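"""Labeled genomic interval sets and the LCR stratification builder.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  A
:class:`RegionSet` is a sorted collection of intervals tied to a genome
(chromosome-length map); set operations (merge, union, subtract,
complement, padding) coalesce abutting intervals, so ``[a,b) + [b,c)``
becomes ``[a,c)`` — a single low-complexity region should never be split
at an arbitrary boundary.

The module also hosts the recipe that turns raw low-complexity candidates
into the final stratification BED: drop candidates touching centromeric
satellite repeats, keep candidates of at least 50 bp, fold in polymorphic
LCRs projected from pangenome bubbles, pad every interval by 5 bp (LCR
boundaries are fuzzy and insertions tend to be placed right before exact
tandem repeats), and merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Region",
    "RegionSet",
    "RegionBuildConfig",
    "filter_by_satellite",
    "filter_min_length",
    "merge_with_polymorphic",
    "pad_and_merge",
    "total_coverage",
    "build_lcr_regions",
    "lcr_segdup_overlap_stats",
]


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionError(ValueError):
    """Invalid interval or genome mismatch."""


# ---------------------------------------------------------------------------
# array kernels; all expect intervals sorted by start, merged where noted


def merge_sorted_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce overlapping *or abutting* sorted intervals."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        s, e = int(s), int(e)
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def subtract_arrays(
    as_: np.ndarray, ae: np.ndarray, bs: np.ndarray, be: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """a \\ b for merged interval arrays."""
    out_s: list[int] = []
    out_e: list[int] = []
    for s, e in zip(as_, ae):
        cur = int(s)
        e = int(e)
        j = int(np.searchsorted(be, cur, side="right"))
        while j < len(bs) and int(bs[j]) < e:
            if int(bs[j]) > cur:
                out_s.append(cur)
                out_e.append(int(bs[j]))
            cur = max(cur, int(be[j]))
            if cur >= e:
                break
            j += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def intersect_arrays(
    as_: np.ndarray, ae: np.ndarray, bs: np.ndarray, be: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """a ∩ b for merged interval arrays."""
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < len(as_) and j < len(bs):
        s = max(int(as_[i]), int(bs[j]))
        e = min(int(ae[i]), int(be[j]))
        if s < e:
            out_s.append(s)
            out_e.append(e)
        if int(ae[i]) < int(be[j]):
            i += 1
        else:
            j += 1
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def overlap_length(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> int:
    """Total overlap of ``[s, e)`` with a merged, sorted interval array."""
    if len(starts) == 0 or s >= e:
        return 0
    i = int(np.searchsorted(ends, s, side="right"))
    j = int(np.searchsorted(starts, e, side="left"))
    if i >= j:
        return 0
    return int(np.sum(np.minimum(ends[i:j], e) - np.maximum(starts[i:j], s)))


# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """A validated, sorted set of labeled intervals over a genome."""

    records: list[Region]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        self.genome = dict(self.genome)
        recs = [Region(*r) if not isinstance(r, Region) else r for r in self.records]
        for r in recs:
            if r.chrom not in self.genome:
                raise RegionError(f"chromosome {r.chrom!r} not in genome map")
            if not (0 <= r.start < r.end <= self.genome[r.chrom]):
                raise RegionError(
                    f"invalid interval {r.chrom}:{r.start}-{r.end} "
                    f"(chromosome length {self.genome[r.chrom]})"
                )
        self.records = sorted(recs, key=lambda r: (r.chrom, r.start, r.end))

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[tuple],
        genome: Mapping[str, int],
        label: str | None = None,
    ) -> "RegionSet":
        recs = []
        for t in tuples:
            if len(t) >= 4:
                recs.append(Region(t[0], int(t[1]), int(t[2]), t[3]))
            else:
                recs.append(Region(t[0], int(t[1]), int(t[2]), label))
        return cls(recs, dict(genome))

    @classmethod
    def empty(cls, genome: Mapping[str, int]) -> "RegionSet":
        return cls([], dict(genome))

    @classmethod
    def from_arrays(
        cls,
        per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
        genome: Mapping[str, int],
        label: str | None = None,
    ) -> "RegionSet":
        recs = []
        for chrom in sorted(per_chrom):
            starts, ends = per_chrom[chrom]
            for s, e in zip(starts, ends):
                recs.append(Region(chrom, int(s), int(e), label))
        return cls(recs, dict(genome))

    # -- views ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.records)

    def chrom_arrays(self, merged: bool = False) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for r in self.records:
            out.setdefault(r.chrom, ([], []))  # type: ignore[arg-type]
        by: dict[str, tuple[list[int], list[int]]] = {}
        for r in self.records:
            by.setdefault(r.chrom, ([], []))
            by[r.chrom][0].append(r.start)
            by[r.chrom][1].append(r.end)
        for chrom, (ss, ee) in by.items():
            starts = np.asarray(ss, np.int64)
            ends = np.asarray(ee, np.int64)
            if merged:
                starts, ends = merge_sorted_arrays(starts, ends)
            out[chrom] = (starts, ends)
        return out

    # -- set operations (all return merged, label-free sets) -----------------

    def merge(self, label: str | None = None) -> "RegionSet":
        return RegionSet.from_arrays(self.chrom_arrays(merged=True), self.genome, label)

    def pad(self, pad: int, label: str | None = None) -> "RegionSet":
        """Expand every record by ``pad`` on each side, clip, merge."""
        if pad < 0:
            raise RegionError("pad must be >= 0")
        recs = [
            Region(
                r.chrom,
                max(0, r.start - pad),
                min(self.genome[r.chrom], r.end + pad),
                label,
            )
            for r in self.records
        ]
        return RegionSet(recs, self.genome).merge(label)

    def union(self, other: "RegionSet", label: str | None = None) -> "RegionSet":
        self._check_same_genome(other)
        return RegionSet(
            [Region(r.chrom, r.start, r.end, label) for r in [*self.records, *other.records]],
            self.genome,
        ).merge(label)

    def subtract(self, other: "RegionSet", label: str | None = None) -> "RegionSet":
        self._check_same_genome(other)
        a = self.chrom_arrays(merged=True)
        b = other.chrom_arrays(merged=True)
        out = {}
        for chrom, (as_, ae) in a.items():
            bs, be = b.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            out[chrom] = subtract_arrays(as_, ae, bs, be)
        return RegionSet.from_arrays(out, self.genome, label)

    def intersect(self, other: "RegionSet", label: str | None = None) -> "RegionSet":
        self._check_same_genome(other)
        a = self.chrom_arrays(merged=True)
        b = other.chrom_arrays(merged=True)
        out = {}
        for chrom, (as_, ae) in a.items():
            bs, be = b.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            out[chrom] = intersect_arrays(as_, ae, bs, be)
        return RegionSet.from_arrays(out, self.genome, label)

    def complement(self, label: str | None = None) -> "RegionSet":
        a = self.chrom_arrays(merged=True)
        out = {}
        for chrom, length in self.genome.items():
            as_, ae = a.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            whole = (np.asarray([0], np.int64), np.asarray([length], np.int64))
            out[chrom] = subtract_arrays(*whole, as_, ae)
        return RegionSet.from_arrays(out, self.genome, label)

    def filter_length(self, min_len: int) -> "RegionSet":
        return RegionSet([r for r in self.records if r.length >= min_len], self.genome)

    def coverage(self) -> int:
        """Total bases covered (computed on the merged set)."""
        return sum(
            int(np.sum(e - s)) for s, e in self.chrom_arrays(merged=True).values()
        )

    def with_label(self, label: str | None) -> "RegionSet":
        return RegionSet(
            [Region(r.chrom, r.start, r.end, label) for r in self.records], self.genome
        )

    def _check_same_genome(self, other: "RegionSet") -> None:
        if self.genome != other.genome:
            raise RegionError("region sets are defined on different genomes")


# ---------------------------------------------------------------------------
# stratification-BED construction


@dataclass
class RegionBuildConfig:
    """Knobs of the stratification-BED recipe.

    min_lcr_len    minimum candidate length kept (bp); default 50, matching
                   the minimum SV size so every LCR can in principle host one.
    pad            bases added to both ends of each interval before the final
                   merge; default 5.
    satellite_policy  "any" drops a candidate overlapping a satellite by >=1 bp;
                   "fraction" drops when overlap/len >= satellite_min_frac.
    min_support    assemblies (excluding ``excluded_samples``) an alternate
                   allele needs for its bubble to count as a common
                   polymorphism; default 5.
    excluded_samples  samples ignored when counting allele support; defaults to
                   the benchmarked sample so the truth set cannot vote for
                   itself.
    """

    min_lcr_len: int = 50
    pad: int = 5
    satellite_policy: str = "any"
    satellite_min_frac: float = 0.5
    min_support: int = 5
    excluded_samples: tuple[str, ...] = ("HG002",)

    def __post_init__(self) -> None:
        if self.min_lcr_len < 1:
            raise ValueError("min_lcr_len must be >= 1")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.satellite_policy not in ("any", "fraction"):
            raise ValueError(f"unknown satellite_policy {self.satellite_policy!r}")


def filter_by_satellite(
    candidates: RegionSet,
    satellites: RegionSet,
    policy: str = "any",
    min_frac: float = 0.5,
) -> RegionSet:
    """Drop candidates that overlap satellite repeats.

    Default policy drops a candidate touching any satellite interval by at
    least one base; the "fraction" policy drops only when the overlapped
    fraction of the candidate reaches ``min_frac``.
    """
    candidates._check_same_genome(satellites)
    sat = satellites.chrom_arrays(merged=True)
    kept = []
    for r in candidates.records:
        ss, se = sat.get(r.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        ov = overlap_length(ss, se, r.start, r.end)
        if policy == "any":
            drop = ov >= 1
        else:
            drop = ov / r.length >= min_frac
        if not drop:
            kept.append(r)
    return RegionSet(kept, candidates.genome)


def filter_min_length(rs: RegionSet, min_len: int) -> RegionSet:
    """Keep records with ``end - start >= min_len`` (boundary inclusive)."""
    return rs.filter_length(min_len)


def merge_with_polymorphic(grch38_lcrs: RegionSet, poly_lcrs: RegionSet) -> RegionSet:
    """Union of reference LCRs with reference-projected polymorphic LCRs."""
    return grch38_lcrs.union(poly_lcrs)


def pad_and_merge(rs: RegionSet, pad: int) -> RegionSet:
    """Expand records by ``pad`` on each side, clip to the chromosome, merge."""
    return rs.pad(pad)


def total_coverage(rs: RegionSet) -> int:
    """Total bases covered; unmerged input is merged first."""
    return rs.coverage()


def build_lcr_regions(
    candidates: RegionSet,
    satellites: RegionSet | None,
    poly: RegionSet | None,
    cfg: RegionBuildConfig | None = None,
) -> tuple[RegionSet, dict]:
    """Run the full stratification recipe and return (final set, summary).

    Order: satellite filter -> minimum-length filter -> union with
    polymorphic LCRs -> pad -> final merge.  Padding can make previously
    disjoint intervals overlap or abut, hence the closing merge.
    """
    cfg = cfg or RegionBuildConfig()
    summary: dict = {"n_candidates": len(candidates)}
    rs = candidates
    if satellites is not None and len(satellites):
        rs = filter_by_satellite(rs, satellites, cfg.satellite_policy, cfg.satellite_min_frac)
    summary["n_after_satellite"] = len(rs)
    rs = filter_min_length(rs, cfg.min_lcr_len)
    summary["n_after_min_len"] = len(rs)
    summary["coverage_after_min_len"] = total_coverage(rs)
    if poly is not None and len(poly):
        rs = merge_with_polymorphic(rs, poly)
    rs = pad_and_merge(rs, cfg.pad)
    summary["n_final"] = len(rs)
    summary["coverage_final"] = total_coverage(rs)
    return rs, summary


def lcr_segdup_overlap_stats(lcr: RegionSet, segdup: RegionSet) -> dict:
    """Fraction of LCR records touching SegDup, and base-level fraction.

    Both conventions are reported because either could be meant by an
    "X% of LCRs intersect SegDup" statement.
    """
    sd = segdup.chrom_arrays(merged=True)
    n_touch = 0
    for r in lcr.records:
        ss, se = sd.get(r.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        if overlap_length(ss, se, r.start, r.end) >= 1:
            n_touch += 1
    inter = lcr.intersect(segdup)
    cov = total_coverage(lcr)
    return {
        "record_fraction": n_touch / len(lcr) if len(lcr) else float("nan"),
        "base_fraction": total_coverage(inter) / cov if cov else float("nan"),
    }
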