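"""Synthetic references, truth SVs, bubbles, and error-injected call sets.

The generator builds a toy genome with planted features whose coordinates
are known exactly, so every downstream stage of the pipeline can be tested
against construction:

* low-complexity regions are impure tandem repeats (a random unit tiled a
  known number of times, with independent per-base substitutions at the
  configured impurity rate — real LCR units are typically ~90% identical);
* segmental duplications are pairs of near-identical blocks;
* not-confident blocks are carved as whole intervals from the remaining
  sequence;
* truth SVs (insertions and deletions of >= 50 bp) are planted fully inside
  the partition bases of their intended class, so classification recovers
  the intended label by construction;
* a caller is emulated statistically: per class, truth SVs are dropped with
  the target false-negative rate, survivors get truncated Gaussian
  breakpoint and length noise, and spurious calls are added at a Poisson
  rate targeting the class false-discovery rate.  Noise truncation keeps
  every surviving call matchable, so the injected FDR/FNR are the only
  error sources; disable it to stress-test the matcher.

Nothing here models read-level signal or caller internals — the error
model is a statistical stand-in that makes injected rates recoverable, not
a claim about how callers fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bubbles import Allele, Bubble
from .matching import MatchParams
from .regions import Region, RegionSet, merge_sorted_arrays, subtract_arrays
from .stratify import (
    ClassifyConfig,
    GenomePartition,
    SvRecord,
    build_partition,
    classify_sv,
    sv_interval,
)

__all__ = [
    "ClassError",
    "SimConfig",
    "ReferenceBundle",
    "SimulationError",
    "generate_reference",
    "plant_truth_svs",
    "simulate_caller",
    "generate_bubble_table",
    "default_partition",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CLASS_ORDER = ("LCR", "SegDup", "Other", "NotConf")


class SimulationError(RuntimeError):
    pass


@dataclass
class ClassError:
    """Per-class caller error targets.

    fdr / fnr   targeted false-discovery / false-negative rates in [0, 1).
    jitter_sd   Gaussian sd of breakpoint displacement, bp.
    length_sd   Gaussian sd of allele-length perturbation, bp.
    """

    fdr: float = 0.1
    fnr: float = 0.1
    jitter_sd: float = 10.0
    length_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("fdr", "fnr"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.jitter_sd < 0 or self.length_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _default_truth_counts() -> dict[str, dict[str, int]]:
    # composition mirrors the benchmarked sample: ~69% of truth SVs in LCR,
    # few in SegDup, and about two insertions per deletion
    return {
        "LCR": {"INS": 120, "DEL": 60},
        "SegDup": {"INS": 7, "DEL": 3},
        "Other": {"INS": 45, "DEL": 25},
    }


def _default_error_model() -> dict[str, ClassError]:
    # LCR and SegDup SVs are an order of magnitude harder than Other
    return {
        "LCR": ClassError(fdr=0.15, fnr=0.15),
        "SegDup": ClassError(fdr=0.20, fnr=0.20),
        "Other": ClassError(fdr=0.02, fnr=0.02),
    }


@dataclass
class SimConfig:
    """Study conditions of a synthetic run; same seed, same bytes out."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 500_000
    lcr_count: int = 200
    lcr_unit_len_range: tuple[int, int] = (10, 40)
    lcr_copies_range: tuple[int, int] = (15, 60)
    lcr_impurity: float = 0.09
    segdup_count: int = 3  # pairs of duplicated blocks
    segdup_len: int = 8_000
    notconf_fraction: float = 0.05
    truth_sv_counts: dict[str, dict[str, int]] = field(default_factory=_default_truth_counts)
    sv_len_range: tuple[int, int] = (50, 200)
    error_model: dict[str, ClassError] = field(default_factory=_default_error_model)
    n_assemblies: int = 20
    polymorphic_fraction: float = 0.3
    # placement geometry: margin keeps an SV away from partition boundaries
    # (so truncated noise cannot move it across), spacing separates SVs so
    # one-to-one matching is unambiguous
    sv_margin: int = 65
    sv_spacing: int = 300
    feature_gap: int = 300

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_len < 1:
            raise ValueError("n_chroms and chrom_len must be positive")
        for name in ("lcr_count", "segdup_count", "n_assemblies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.lcr_impurity < 1.0):
            raise ValueError("lcr_impurity must lie in [0, 1)")
        if not (0.0 <= self.notconf_fraction < 1.0):
            raise ValueError("notconf_fraction must lie in [0, 1)")
        if not (0.0 <= self.polymorphic_fraction <= 1.0):
            raise ValueError("polymorphic_fraction must lie in [0, 1]")
        if self.sv_len_range[0] < 50:
            raise ValueError("sv_len_range minimum must be >= 50 (the SV size definition)")
        if self.sv_len_range[0] > self.sv_len_range[1]:
            raise ValueError("sv_len_range must be (min, max) with min <= max")
        for lo, hi in (self.lcr_unit_len_range, self.lcr_copies_range):
            if lo < 1 or lo > hi:
                raise ValueError("LCR unit/copy ranges must be positive and ordered")
        for cls, counts in self.truth_sv_counts.items():
            for k, v in counts.items():
                if v < 0:
                    raise ValueError(f"truth_sv_counts[{cls}][{k}] must be >= 0")


@dataclass
class ReferenceBundle:
    """A generated toy reference and its planted annotations."""

    sequences: dict[str, str]
    genome: dict[str, int]
    lcr: RegionSet
    segdup: RegionSet
    notconf: RegionSet


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# reference generation


def _layout(rng: np.random.Generator, chrom_len: int, lengths: list[int], gap: int,
            chrom: str) -> list[int]:
    """Random non-overlapping starts for blocks of the given lengths,
    keeping at least ``gap`` between blocks and chromosome ends."""
    k = len(lengths)
    if k == 0:
        return []
    slack = chrom_len - sum(lengths) - gap * (k + 1)
    if slack < 0:
        raise SimulationError(
            f"planted features exceed chromosome {chrom}: need {-slack} bp more "
            f"({k} features totalling {sum(lengths)} bp in {chrom_len} bp)"
        )
    extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
    starts = []
    pos = gap + int(extra[0])
    for i, L in enumerate(lengths):
        starts.append(pos)
        pos += L + gap + int(extra[i + 1])
    return starts


def generate_reference(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> ReferenceBundle:
    """Generate a toy reference with planted LCRs, SegDups, and NotConf blocks.

    Returns the sequences plus BED-style region sets that exactly delimit
    the planted features; sequence outside features is i.i.d. uniform.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome = {c: cfg.chrom_len for c in chroms}

    # feature inventory: (kind, length, payload)
    features: list[tuple[str, int, tuple]] = []
    for _ in range(cfg.lcr_count):
        unit = int(rng.integers(cfg.lcr_unit_len_range[0], cfg.lcr_unit_len_range[1] + 1))
        copies = int(rng.integers(cfg.lcr_copies_range[0], cfg.lcr_copies_range[1] + 1))
        features.append(("LCR", unit * copies, (unit, copies)))
    for pair in range(cfg.segdup_count):
        features.append(("SEGDUP", cfg.segdup_len, (pair, 0)))
        features.append(("SEGDUP", cfg.segdup_len, (pair, 1)))
    nc_total = int(cfg.notconf_fraction * cfg.chrom_len * cfg.n_chroms)
    if nc_total > 0:
        block = min(10_000, max(1, nc_total))
        n_blocks = max(1, nc_total // block)
        for i in range(n_blocks):
            features.append(("NOTCONF", block, ()))

    # spread features over chromosomes: greedy least-loaded after a shuffle
    order = rng.permutation(len(features))
    loads = {c: 0 for c in chroms}
    per_chrom: dict[str, list[tuple[str, int, tuple]]] = {c: [] for c in chroms}
    for idx in order:
        kind, length, payload = features[int(idx)]
        target = min(chroms, key=lambda c: loads[c])
        per_chrom[target].append((kind, length, payload))
        loads[target] += length + cfg.feature_gap

    sequences: dict[str, str] = {}
    lcr_recs: list[Region] = []
    segdup_recs: list[Region] = []
    notconf_recs: list[Region] = []
    segdup_sources: dict[int, np.ndarray] = {}
    for chrom in chroms:
        arr = rng.integers(0, 4, cfg.chrom_len, dtype=np.int8)
        feats = per_chrom[chrom]
        starts = _layout(rng, cfg.chrom_len, [f[1] for f in feats], cfg.feature_gap, chrom)
        for (kind, length, payload), start in zip(feats, starts):
            end = start + length
            if kind == "LCR":
                unit_len, copies = payload
                unit = rng.integers(0, 4, unit_len, dtype=np.int8)
                tiled = np.tile(unit, copies)
                mask = rng.random(length) < cfg.lcr_impurity
                if mask.any():
                    tiled[mask] = (tiled[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
                arr[start:end] = tiled
                lcr_recs.append(Region(chrom, start, end, "LCR"))
            elif kind == "SEGDUP":
                pair, member = payload
                if pair not in segdup_sources:
                    segdup_sources[pair] = rng.integers(0, 4, length, dtype=np.int8)
                block = segdup_sources[pair].copy()
                if member == 1:  # near-identical copy, ~1% divergence
                    mask = rng.random(length) < 0.01
                    if mask.any():
                        block[mask] = (block[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
                arr[start:end] = block
                segdup_recs.append(Region(chrom, start, end, "SegDup"))
            else:
                notconf_recs.append(Region(chrom, start, end, "NotConf"))
        sequences[chrom] = _BASES[arr].tobytes().decode()

    return ReferenceBundle(
        sequences=sequences,
        genome=genome,
        lcr=RegionSet(lcr_recs, genome),
        segdup=RegionSet(segdup_recs, genome),
        notconf=RegionSet(notconf_recs, genome),
    )


def default_partition(ref: ReferenceBundle) -> GenomePartition:
    """Partition from the raw planted sets (confident = complement of NotConf)."""
    return build_partition(ref.notconf.complement(), ref.lcr, ref.segdup, ref.genome)


# ---------------------------------------------------------------------------
# truth SV planting


def _pack_spans(
    rng: np.random.Generator,
    segments: list[tuple[str, int, int]],
    footprints: list[int],
    margin: int,
    spacing: int,
    what: str,
) -> list[tuple[str, int]]:
    """Place spans of the given footprints inside the segments, keeping
    ``margin`` from segment ends and ``spacing`` between spans.  Segments
    are visited in random order; spans get small random offsets so
    positions are not lattice-like.  Raises when capacity runs out,
    naming the deficit."""
    placed: list[tuple[str, int]] = []
    order = rng.permutation(len(segments))
    i = 0
    for seg_idx in order:
        if i >= len(footprints):
            break
        chrom, s, e = segments[int(seg_idx)]
        cursor = s + margin + int(rng.integers(0, spacing + 1))
        while i < len(footprints):
            L = footprints[i]
            if cursor + L > e - margin:
                break
            placed.append((chrom, cursor))
            cursor += L + spacing + int(rng.integers(0, spacing + 1))
            i += 1
    if i < len(footprints):
        missing = len(footprints) - i
        need = sum(footprints[i:]) + missing * (spacing + 2 * margin)
        raise SimulationError(
            f"could not place {missing} {what}: roughly {need} bp of additional "
            f"target-class sequence required"
        )
    return placed


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length, dtype=np.int8)].tobytes().decode()


def plant_truth_svs(
    cfg: SimConfig,
    ref: ReferenceBundle,
    partition: GenomePartition | None = None,
    rng: np.random.Generator | None = None,
    classify_cfg: ClassifyConfig | None = None,
) -> list[SvRecord]:
    """Plant truth SVs so each is assigned its intended class.

    Deletions are placed fully inside partition bases of the intended
    class; insertions are anchored on such a base, with a margin from
    segment boundaries larger than the truncated caller noise so class
    labels survive jitter.  The output is verified against the classifier
    record by record.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    partition = partition if partition is not None else default_partition(ref)
    classify_cfg = classify_cfg or ClassifyConfig()
    lo, hi = cfg.sv_len_range
    records: list[SvRecord] = []
    for cls in [c for c in _CLASS_ORDER if c in cfg.truth_sv_counts]:
        counts = cfg.truth_sv_counts[cls]
        n_ins = int(counts.get("INS", 0))
        n_del = int(counts.get("DEL", 0))
        if n_ins + n_del == 0:
            continue
        types = ["INS"] * n_ins + ["DEL"] * n_del
        rng.shuffle(types)
        lengths = rng.integers(lo, hi + 1, size=len(types))
        segments = [
            (chrom, int(s), int(e))
            for chrom, (ss, ee) in sorted(partition.arrays[cls].items())
            for s, e in zip(ss, ee)
        ]
        footprints = [int(L) if t == "DEL" else 1 for t, L in zip(types, lengths)]
        spots = _pack_spans(
            rng, segments, footprints, cfg.sv_margin, cfg.sv_spacing, f"{cls} truth SVs"
        )
        for (chrom, start), t, L in zip(spots, types, lengths):
            L = int(L)
            if t == "DEL":
                rec = SvRecord(
                    chrom=chrom, pos=start, ref_len=L + 1, alt_len=1,
                    genotype=str(rng.choice(["0/1", "1/1"])), sim_class=cls,
                )
            else:
                anchor0 = start  # 0-based anchor base inside the class segment
                if cls == "LCR" and anchor0 + 1 - L >= 0:
                    seq = ref.sequences[chrom][anchor0 + 1 - L : anchor0 + 1]
                else:
                    seq = _random_seq(rng, L)
                rec = SvRecord(
                    chrom=chrom, pos=anchor0 + 1, ref_len=1, alt_len=L + 1,
                    genotype=str(rng.choice(["0/1", "1/1"])), seq=seq, sim_class=cls,
                )
            got = classify_sv(rec, partition, classify_cfg)
            if got != cls:
                raise SimulationError(
                    f"planted {t} at {chrom}:{rec.pos} intended {cls} but classified {got}"
                )
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    for i, rec in enumerate(records):
        rec.id = f"t{i:06d}"
    return records


# ---------------------------------------------------------------------------
# caller emulation


def simulate_caller(
    truth: Sequence[SvRecord],
    error_model: Mapping[str, ClassError],
    seed: int | np.random.Generator,
    partition: GenomePartition,
    sequences: Mapping[str, str] | None = None,
    params: MatchParams | None = None,
    sv_len_range: tuple[int, int] = (50, 200),
    truncate: bool = True,
    clearance: int | None = None,
    spacing: int = 300,
    margin: int = 65,
    min_sv_len: int = 50,
) -> list[SvRecord]:
    """Emulate a caller with class-conditional error rates.

    Per class C: each truth SV is dropped with probability ``fnr[C]``;
    survivors get Gaussian breakpoint jitter and length error (truncated by
    default so they stay matchable under ``params``); spurious calls are
    added in C's partition bases — at least ``clearance`` bp away from any
    truth SV so they can never be rescued as TPs — at a Poisson rate whose
    mean makes E[FP/(FP+TP)] equal ``fdr[C]``.
    """
    rng = _rng(seed)
    params = params or MatchParams()
    clearance = clearance if clearance is not None else params.refdist + 100
    calls: list[SvRecord] = []
    tp_count: dict[str, int] = {}
    for t in truth:
        cls = t.sim_class
        if cls is None:
            raise SimulationError("truth records must carry sim_class for caller emulation")
        em = error_model[cls]
        if rng.random() < em.fnr:
            continue
        chrom_len = partition.genome[t.chrom]
        L = t.size
        jitter = int(round(rng.normal(0.0, em.jitter_sd))) if em.jitter_sd > 0 else 0
        if truncate:
            bound = params.refdist // 2
            jitter = max(-bound, min(bound, jitter))
        eps = int(round(rng.normal(0.0, em.length_sd))) if em.length_sd > 0 else 0
        new_len = L + eps
        if truncate:
            new_len = max(new_len, max(min_sv_len, math.ceil(L * params.pctsize)))
            new_len = min(new_len, math.floor(L / params.pctsize))
        new_len = max(1, new_len)
        if t.svtype == "DEL":
            pos = min(max(1, t.pos + jitter), chrom_len - new_len)
            rec = SvRecord(
                chrom=t.chrom, pos=pos, ref_len=new_len + 1, alt_len=1,
                genotype=t.genotype, sim_class=cls,
            )
        else:
            pos = min(max(2, t.pos + jitter), chrom_len - 1)
            base = t.seq or ""
            if len(base) == 0:
                seq = _random_seq(rng, new_len)
            elif len(base) >= new_len:
                seq = base[:new_len]
            else:
                seq = (base * (new_len // len(base) + 1))[:new_len]
            rec = SvRecord(
                chrom=t.chrom, pos=pos, ref_len=1, alt_len=new_len + 1,
                genotype=t.genotype, seq=seq, sim_class=cls,
            )
        tp_count[cls] = tp_count.get(cls, 0) + 1
        calls.append(rec)

    # inflate truth spans by the clearance; FP placement avoids these bases
    spans_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for t in truth:
        s, e = sv_interval(t)
        spans_by_chrom.setdefault(t.chrom, ([], []))
        spans_by_chrom[t.chrom][0].append(max(0, s - clearance))
        spans_by_chrom[t.chrom][1].append(min(partition.genome[t.chrom], e + clearance))
    blocked: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (ss, ee) in spans_by_chrom.items():
        idx = np.argsort(ss)
        blocked[chrom] = merge_sorted_arrays(
            np.asarray(ss, np.int64)[idx], np.asarray(ee, np.int64)[idx]
        )

    lo, hi = sv_len_range
    for cls in [c for c in _CLASS_ORDER if c in error_model]:
        em = error_model[cls]
        if em.fdr <= 0.0:
            continue
        lam = tp_count.get(cls, 0) * em.fdr / (1.0 - em.fdr)
        n_fp = int(rng.poisson(lam)) if lam > 0 else 0
        if n_fp == 0:
            continue
        free_segments: list[tuple[str, int, int]] = []
        for chrom, (ss, ee) in sorted(partition.arrays.get(cls, {}).items()):
            bs, be = blocked.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            fs, fe = subtract_arrays(ss, ee, bs, be)
            free_segments.extend((chrom, int(s), int(e)) for s, e in zip(fs, fe))
        types = [str(x) for x in rng.choice(["INS", "DEL"], n_fp)]
        lengths = rng.integers(lo, hi + 1, size=n_fp)
        footprints = [int(L) if t == "DEL" else 1 for t, L in zip(types, lengths)]
        spots = _pack_spans(rng, free_segments, footprints, margin, spacing, f"{cls} FP calls")
        for (chrom, start), t, L in zip(spots, types, lengths):
            L = int(L)
            if t == "DEL":
                calls.append(
                    SvRecord(chrom=chrom, pos=start, ref_len=L + 1, alt_len=1,
                             genotype="0/1", sim_class=cls)
                )
            else:
                if sequences is not None and cls == "LCR" and start + 1 - L >= 0:
                    seq = sequences[chrom][start + 1 - L : start + 1]
                else:
                    seq = _random_seq(rng, L)
                calls.append(
                    SvRecord(chrom=chrom, pos=start + 1, ref_len=1, alt_len=L + 1,
                             genotype="0/1", seq=seq, sim_class=cls)
                )

    calls.sort(key=lambda r: (r.chrom, r.pos, r.sv_len))
    for i, rec in enumerate(calls):
        rec.id = f"c{i:06d}"
    return calls


def rate_recovery_config(seed: int = 0) -> SimConfig:
    """Study conditions for checking that stratified FDR/FNR estimates
    recover injected targets: 1,000 truth SVs per class on a genome large
    enough to host them plus the spurious calls, with injected per-class
    rates spanning low/medium/high (0.05, 0.2, 0.5).  SV spacing is halved
    relative to the default so the genome stays compact; it still exceeds
    the truncated breakpoint noise by an order of magnitude."""
    return SimConfig(
        seed=seed,
        n_chroms=2,
        chrom_len=1_200_000,
        lcr_count=480,
        lcr_unit_len_range=(10, 30),
        lcr_copies_range=(50, 100),
        segdup_count=20,
        segdup_len=12_000,
        truth_sv_counts={
            "LCR": {"INS": 500, "DEL": 500},
            "SegDup": {"INS": 500, "DEL": 500},
            "Other": {"INS": 500, "DEL": 500},
        },
        sv_len_range=(50, 100),
        error_model={
            "LCR": ClassError(fdr=0.5, fnr=0.2),
            "SegDup": ClassError(fdr=0.2, fnr=0.05),
            "Other": ClassError(fdr=0.05, fnr=0.5),
        },
        sv_spacing=150,
    )


# ---------------------------------------------------------------------------
# bubbles


def generate_bubble_table(
    cfg: SimConfig,
    lcr: RegionSet,
    rng: np.random.Generator | None = None,
    min_support: int = 5,
) -> list[Bubble]:
    """Attach variant bubbles to a fraction of the planted LCRs.

    Each bubble spans its LCR's reference interval and carries the
    reference allele plus 1–3 alternate alleles with lengths spread around
    the reference length; support counts are drawn half below and half at
    or above ``min_support`` so the rarity filter has work to do, and the
    benchmarked sample (HG002) appears in some support lists.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n_poly = int(round(cfg.polymorphic_fraction * len(lcr)))
    if n_poly == 0 or len(lcr) == 0:
        return []
    chosen = sorted(int(i) for i in rng.choice(len(lcr), size=n_poly, replace=False))
    pool = [f"asm{i:02d}" for i in range(1, cfg.n_assemblies + 1)]
    bubbles: list[Bubble] = []
    for j, idx in enumerate(chosen):
        r = lcr.records[idx]
        alleles = [
            Allele(
                allele_id="ref",
                length=r.length,
                lcr_frac=float(rng.uniform(0.85, 1.0)),
                segdup_frac=float(rng.uniform(0.0, 0.05)),
                assemblies=("GRCh38",),
            )
        ]
        n_alt = int(rng.integers(1, 4))
        for k in range(n_alt):
            length = max(1, int(r.length * rng.uniform(0.3, 4.0)))
            if rng.random() < 0.5:
                support = int(rng.integers(1, min_support))
            else:
                support = int(rng.integers(min_support, cfg.n_assemblies + 1))
            names = [str(x) for x in rng.choice(pool, size=support, replace=False)]
            if rng.random() < 0.3:
                names.append("HG002")
            alleles.append(
                Allele(
                    allele_id=f"alt{k + 1}",
                    length=length,
                    lcr_frac=float(rng.uniform(0.75, 1.0)),
                    segdup_frac=float(rng.uniform(0.0, 0.1)),
                    assemblies=tuple(names),
                )
            )
        bubbles.append(
            Bubble(r.chrom, r.start, r.end, f"b{j:05d}", tuple(alleles))
        )
    return bubbles
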