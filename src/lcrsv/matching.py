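"""Pairing called SVs with truth SVs into TP/FP/FN designations.

Two routes produce a :class:`MatchResult`:

* :func:`match` — a built-in, deliberately simple one-to-one matcher:
  candidate pairs must share svtype and chromosome, lie within ``refdist``
  of each other, have size similarity ``min/max >= pctsize`` and (when
  insertion sequences are available) sequence similarity ``>= pctseq``;
  pairs are then assigned greedily by descending composite score.  This is
  a stand-in for full benchmarking tools that additionally normalize
  variant representations by multi-sequence alignment; it is exact when
  breakpoint jitter is small relative to variant spacing.

* :func:`ingest_truvari` — reads the tp-base/fp/fn VCFs written by an
  external truvari run and converts file membership into a MatchResult,
  checking the conservation identities.

Genotype is ignored for TP status: matching evaluates variant presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_left, bisect_right
from typing import Iterable, Sequence

import edlib

from .stratify import SvRecord

__all__ = ["MatchParams", "MatchResult", "match", "ingest_truvari", "ensure_ids"]


class MatchingError(ValueError):
    pass


@dataclass
class MatchParams:
    """Matcher thresholds (defaults mirror common SV-benchmarking practice).

    refdist   maximum breakpoint distance in bp.
    pctsize   minimum size similarity min(|a|,|b|)/max(|a|,|b|).
    pctseq    minimum sequence similarity, applied only when both records
              carry an insertion sequence.
    """

    refdist: int = 500
    pctsize: float = 0.7
    pctseq: float = 0.7
    use_seq: bool = True

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        for name in ("pctsize", "pctseq"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class MatchResult:
    """One-to-one pairing: each variant id appears at most once overall."""

    tp_pairs: list[tuple[str, str, float]]
    fp: list[str]
    fn: list[str]

    @property
    def n_truth(self) -> int:
        return len(self.tp_pairs) + len(self.fn)

    @property
    def n_calls(self) -> int:
        return len(self.tp_pairs) + len(self.fp)

    def validate(self) -> None:
        truth_ids = [t for t, _, _ in self.tp_pairs] + list(self.fn)
        call_ids = [c for _, c, _ in self.tp_pairs] + list(self.fp)
        if len(set(truth_ids)) != len(truth_ids):
            raise MatchingError("a truth id appears more than once in the match result")
        if len(set(call_ids)) != len(call_ids):
            raise MatchingError("a call id appears more than once in the match result")


def ensure_ids(records: Sequence[SvRecord], prefix: str) -> None:
    """Assign deterministic ids (in genomic order) to records lacking one."""
    ordered = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    for n, i in enumerate(ordered):
        if records[i].id is None:
            records[i].id = f"{prefix}{n:06d}"


def _seq_similarity(a: str, b: str) -> float:
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / m


def match(
    calls: Sequence[SvRecord], truth: Sequence[SvRecord], params: MatchParams | None = None
) -> MatchResult:
    """Greedy one-to-one matching of calls against truth."""
    params = params or MatchParams()
    calls = list(calls)
    truth = list(truth)
    ensure_ids(calls, "call")
    ensure_ids(truth, "truth")

    call_chroms = {c.chrom for c in calls}
    truth_chroms = {t.chrom for t in truth}
    if calls and truth and not (call_chroms & truth_chroms):
        raise MatchingError(
            "call and truth chromosome namespaces do not overlap: "
            f"calls use {sorted(call_chroms)}, truth uses {sorted(truth_chroms)}"
        )

    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for idx, t in enumerate(truth):
        by_key.setdefault((t.chrom, t.svtype), []).append((t.pos, idx))
    for lst in by_key.values():
        lst.sort()

    candidates: list[tuple[float, tuple, int, int]] = []
    for ci, c in enumerate(calls):
        bucket = by_key.get((c.chrom, c.svtype))
        if not bucket:
            continue
        positions = [p for p, _ in bucket]
        lo = bisect_left(positions, c.pos - params.refdist)
        hi = bisect_right(positions, c.pos + params.refdist)
        for p, ti in bucket[lo:hi]:
            t = truth[ti]
            dist = abs(c.pos - t.pos)
            size_sim = min(c.size, t.size) / max(c.size, t.size)
            if size_sim < params.pctsize:
                continue
            parts = [1.0 - dist / params.refdist if params.refdist else 1.0, size_sim]
            if params.use_seq and c.seq is not None and t.seq is not None:
                seq_sim = _seq_similarity(c.seq, t.seq)
                if seq_sim < params.pctseq:
                    continue
                parts.append(seq_sim)
            score = sum(parts) / len(parts)
            # symmetric tie-break key so swapping calls/truth swaps FP and FN
            tie = (c.chrom, min(c.pos, t.pos), max(c.pos, t.pos), min(c.id, t.id), max(c.id, t.id))
            candidates.append((score, tie, ti, ci))

    candidates.sort(key=lambda x: (-x[0], x[1]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    tp_pairs: list[tuple[str, str, float]] = []
    for score, _, ti, ci in candidates:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        tp_pairs.append((truth[ti].id, calls[ci].id, score))
    fp = [c.id for i, c in enumerate(calls) if i not in used_c]
    fn = [t.id for i, t in enumerate(truth) if i not in used_t]
    result = MatchResult(tp_pairs=tp_pairs, fp=fp, fn=fn)
    result.validate()
    return result


def _variant_key(sv: SvRecord) -> str:
    return f"{sv.chrom}:{sv.pos}:{sv.svtype}:{sv.size}"


def ingest_truvari(
    tp_base: Sequence[SvRecord],
    fp: Sequence[SvRecord],
    fn: Sequence[SvRecord],
) -> MatchResult:
    """Build a MatchResult from the record sets of a truvari-style run.

    ``tp_base`` holds matched truth representations, ``fp`` unmatched calls
    and ``fn`` unmatched truth.  TP pairs reuse the truth-side key for both
    sides because the matched call representation lives in a separate file
    not required here.  Duplicate variant keys across the three sets are
    rejected.
    """
    seen: set[str] = set()

    def keys(records: Sequence[SvRecord]) -> list[str]:
        out = []
        for sv in records:
            k = sv.id if sv.id else _variant_key(sv)
            if k in seen:
                raise MatchingError(f"duplicate variant key {k!r} across truvari files")
            seen.add(k)
            out.append(k)
        return out

    tp_keys = keys(tp_base)
    fp_keys = keys(fp)
    fn_keys = keys(fn)
    result = MatchResult(
        tp_pairs=[(k, k, 1.0) for k in tp_keys], fp=fp_keys, fn=fn_keys
    )
    result.validate()
    return result
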