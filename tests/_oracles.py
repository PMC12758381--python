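"""Independent per-base bit-vector oracles for interval operations.

Everything here works on explicit numpy boolean/label vectors over small
genomes, deliberately ignoring the package's interval arithmetic so the
two can be compared.
"""

from __future__ import annotations

import numpy as np

from lcrsv.regions import RegionSet

LABEL_CODES = {"NotConf": 0, "LCR": 1, "SegDup": 2, "Other": 3}


def bitvec(rs: RegionSet) -> dict[str, np.ndarray]:
    out = {chrom: np.zeros(length, dtype=bool) for chrom, length in rs.genome.items()}
    for r in rs.records:
        out[r.chrom][r.start : r.end] = True
    return out


def bitvec_to_intervals(vec: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], vec, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def regionset_intervals(rs: RegionSet) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in rs.records:
        out.setdefault(r.chrom, []).append((r.start, r.end))
    return out


def paint_labels(
    genome: dict[str, int],
    notconf: RegionSet,
    lcr: RegionSet,
    segdup: RegionSet,
) -> dict[str, np.ndarray]:
    """Priority paint: Other everywhere, then SegDup, LCR, NotConf on top."""
    out = {c: np.full(n, LABEL_CODES["Other"], dtype=np.int8) for c, n in genome.items()}
    for rs, name in ((segdup, "SegDup"), (lcr, "LCR"), (notconf, "NotConf")):
        for r in rs.records:
            out[r.chrom][r.start : r.end] = LABEL_CODES[name]
    return out


def brute_classify(
    labels: dict[str, np.ndarray], chrom: str, start: int, end: int, threshold: float
) -> str:
    """Per-base counting classification of an interval."""
    window = labels[chrom][start:end]
    n = end - start
    for name in ("NotConf", "LCR", "SegDup"):
        if np.count_nonzero(window == LABEL_CODES[name]) / n >= threshold:
            return name
    return "Other"


def random_regionset(
    rng: np.random.Generator,
    genome: dict[str, int],
    n: int,
    max_len: int = 2000,
) -> RegionSet:
    recs = []
    chroms = sorted(genome)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, max(1, genome[chrom] - length)))
        recs.append((chrom, start, start + length))
    return RegionSet.from_tuples(recs, genome)
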