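"""Stratified accuracy tables: per-class FDR/FNR, SV length shares, and
accuracy binned by the maximum allele length of the hosting LCR.

FDR = FP / (FP + TP) over called variants; FNR = FN / (FN + TP) over truth
variants.  A matched (TP) pair contributes to the FDR table under the
*call's* class and to the FNR table under the *truth* variant's class;
the two can disagree when jitter moves a call across a region boundary —
such discordant pairs are counted and reported.  Rates with a zero
denominator are emitted as missing (NaN), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import MatchResult
from .regions import RegionSet
from .stratify import ClassifyConfig, SvRecord, sv_interval

__all__ = [
    "StratifiedReport",
    "LengthBinReport",
    "stratified_rates",
    "length_share",
    "assign_lcr_regions",
    "bin_by_max_allele_length",
    "DEFAULT_BIN_EDGES",
]

CLASS_ORDER = ("LCR", "SegDup", "Other")
DEFAULT_BIN_EDGES = (0, 100, 250, 500, 1000, 2000)


class MetricsError(ValueError):
    pass


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def _class_of(classes: Mapping[str, str], vid: str, side: str) -> str:
    try:
        return classes[vid]
    except KeyError:
        raise MetricsError(f"{side} variant {vid!r} has no class assignment") from None


@dataclass
class StratifiedReport:
    frame: pd.DataFrame  # index: class + Total; columns: tp_call, fp, fdr, tp_truth, fn, fnr
    discordant_pairs: int

    def fdr(self, cls: str) -> float:
        return float(self.frame.loc[cls, "fdr"])

    def fnr(self, cls: str) -> float:
        return float(self.frame.loc[cls, "fnr"])


def stratified_rates(
    match: MatchResult,
    classes: Mapping[str, str],
    class_order: Sequence[str] = CLASS_ORDER,
) -> StratifiedReport:
    """Per-class TP/FP/FN counts and FDR/FNR from a match result.

    ``classes`` maps every variant id appearing in the match result to its
    partition label; a missing id is an error.
    """
    tp_call: dict[str, int] = {}
    tp_truth: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    discordant = 0
    for tid, cid, _ in match.tp_pairs:
        ct = _class_of(classes, tid, "truth")
        cc = _class_of(classes, cid, "call")
        if ct != cc:
            discordant += 1
        tp_truth[ct] = tp_truth.get(ct, 0) + 1
        tp_call[cc] = tp_call.get(cc, 0) + 1
    for cid in match.fp:
        c = _class_of(classes, cid, "call")
        fp[c] = fp.get(c, 0) + 1
    for tid in match.fn:
        c = _class_of(classes, tid, "truth")
        fn[c] = fn.get(c, 0) + 1

    seen = set(tp_call) | set(tp_truth) | set(fp) | set(fn)
    order = [c for c in class_order if c in seen or c in CLASS_ORDER]
    order += sorted(seen - set(order))
    rows = []
    for c in order:
        rows.append(
            {
                "class": c,
                "tp_call": tp_call.get(c, 0),
                "fp": fp.get(c, 0),
                "tp_truth": tp_truth.get(c, 0),
                "fn": fn.get(c, 0),
            }
        )
    total = {
        "class": "Total",
        "tp_call": len(match.tp_pairs),
        "fp": len(match.fp),
        "tp_truth": len(match.tp_pairs),
        "fn": len(match.fn),
    }
    frame = pd.DataFrame(rows + [total]).set_index("class")
    frame["fdr"] = [
        _rate(r.fp, r.fp + r.tp_call) for r in frame.itertuples()
    ]
    frame["fnr"] = [
        _rate(r.fn, r.fn + r.tp_truth) for r in frame.itertuples()
    ]
    frame = frame[["tp_call", "fp", "fdr", "tp_truth", "fn", "fnr"]]
    return StratifiedReport(frame=frame, discordant_pairs=discordant)


def length_share(
    truth: Sequence[SvRecord], classes: Mapping[str, str]
) -> pd.Series:
    """Per-class share of the summed |sv_len| of the truth set."""
    if not truth:
        raise MetricsError("length_share of an empty truth set is undefined")
    sums: dict[str, int] = {}
    for sv in truth:
        c = _class_of(classes, sv.id, "truth")
        sums[c] = sums.get(c, 0) + sv.size
    total = sum(sums.values())
    order = [c for c in CLASS_ORDER if c in sums] + sorted(set(sums) - set(CLASS_ORDER))
    return pd.Series({c: sums[c] / total for c in order}, name="length_share")


# ---------------------------------------------------------------------------
# max-allele-length binning


def assign_lcr_regions(
    svs: Sequence[SvRecord],
    lcr: RegionSet,
    cfg: ClassifyConfig | None = None,
) -> dict[str, tuple[str, int, int]]:
    """Associate each SV with the LCR record it overlaps most (ties: first).

    Returns a map from variant id to the region key ``(chrom, start, end)``;
    SVs overlapping no LCR record are simply absent from the map.
    """
    cfg = cfg or ClassifyConfig()
    arrays = lcr.chrom_arrays(merged=False)
    out: dict[str, tuple[str, int, int]] = {}
    for sv in svs:
        starts_ends = arrays.get(sv.chrom)
        if starts_ends is None:
            continue
        starts, ends = starts_ends
        s, e = sv_interval(sv, cfg)
        i = int(np.searchsorted(ends, s, side="right"))
        j = int(np.searchsorted(starts, e, side="left"))
        best = None
        best_ov = 0
        for k in range(i, j):
            ov = min(int(ends[k]), e) - max(int(starts[k]), s)
            if ov > best_ov:
                best_ov = ov
                best = (sv.chrom, int(starts[k]), int(ends[k]))
        if best is not None:
            out[sv.id] = best
    return out


@dataclass
class LengthBinReport:
    frame: pd.DataFrame  # index: bin label; columns tp_call, fp, fdr, tp_truth, fn, fnr, n
    edges: tuple[int, ...]


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    for lo, hi in zip(edges, list(edges[1:]) + [None]):
        labels.append(f"[{lo},{hi})" if hi is not None else f">={lo}")
    return labels


def bin_by_max_allele_length(
    match: MatchResult,
    classes: Mapping[str, str],
    region_of: Mapping[str, tuple[str, int, int]],
    max_len: Mapping[tuple[str, int, int], int],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> LengthBinReport:
    """FDR/FNR of LCR-classified SVs binned by their LCR's max allele length.

    Bins partition ``[0, inf)``: inner edges are inclusive on the right bin,
    so a region whose max allele length equals an edge (e.g. 2000) falls in
    the bin starting at that edge.  Every LCR-classified variant must map
    to a region with a known max allele length.
    """
    edges = tuple(bin_edges)
    if edges[0] != 0:
        edges = (0,) + edges
    inner = np.asarray(edges[1:], dtype=np.int64)
    labels = _bin_labels(edges)

    def bin_of(vid: str) -> int:
        region = region_of.get(vid)
        if region is None:
            raise MetricsError(f"LCR-classified variant {vid!r} has no associated LCR region")
        try:
            ml = max_len[region]
        except KeyError:
            raise MetricsError(
                f"no max allele length for LCR region {region}"
            ) from None
        return int(np.searchsorted(inner, ml, side="right"))

    nb = len(labels)
    tp_call = np.zeros(nb, np.int64)
    tp_truth = np.zeros(nb, np.int64)
    fp = np.zeros(nb, np.int64)
    fn = np.zeros(nb, np.int64)
    for tid, cid, _ in match.tp_pairs:
        if _class_of(classes, tid, "truth") == "LCR":
            tp_truth[bin_of(tid)] += 1
        if _class_of(classes, cid, "call") == "LCR":
            tp_call[bin_of(cid)] += 1
    for cid in match.fp:
        if _class_of(classes, cid, "call") == "LCR":
            fp[bin_of(cid)] += 1
    for tid in match.fn:
        if _class_of(classes, tid, "truth") == "LCR":
            fn[bin_of(tid)] += 1

    frame = pd.DataFrame(
        {
            "tp_call": tp_call,
            "fp": fp,
            "fdr": [_rate(int(f), int(f + t)) for f, t in zip(fp, tp_call)],
            "tp_truth": tp_truth,
            "fn": fn,
            "fnr": [_rate(int(f), int(f + t)) for f, t in zip(fn, tp_truth)],
            "n": tp_truth + fn,
        },
        index=pd.Index(labels, name="max_allele_length_bin"),
    )
    return LengthBinReport(frame=frame, edges=edges)
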