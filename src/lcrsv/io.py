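"""Readers and writers: BED, genome maps, VCF, FASTA.

Coordinates are 0-based half-open internally (BED convention); VCF
positions are converted at this boundary and nowhere else.  VCF access
goes through pysam; multi-allelic records are split into per-ALT
pseudo-records, with '*' alternates flagged rather than silently dropped
so the truth filter can count them.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import Region, RegionSet
from .stratify import SvRecord

__all__ = [
    "read_bed",
    "write_bed",
    "read_genome",
    "write_genome",
    "read_sv_vcf",
    "write_sv_vcf",
    "write_fasta",
]

log = logging.getLogger("lcrsv")


class BedError(ValueError):
    pass


def _opener(path, mode: str):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_bed(path, genome: Mapping[str, int], label: str | None = None) -> RegionSet:
    """Read a 3+ column BED (optionally gzipped) into a validated RegionSet.

    Malformed lines raise with the offending line number; a fourth column,
    when present, is kept as the record label unless ``label`` overrides it.
    """
    records: list[Region] = []
    with _opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"{path}:{lineno}: expected at least 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if chrom not in genome:
                raise BedError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > genome[chrom]:
                raise BedError(
                    f"{path}:{lineno}: interval end {end} beyond chromosome "
                    f"length {genome[chrom]}"
                )
            rec_label = label if label is not None else (fields[3] if len(fields) > 3 else None)
            records.append(Region(chrom, start, end, rec_label))
    return RegionSet(records, dict(genome))


def write_bed(rs: RegionSet, path) -> None:
    with _opener(path, "wt") as fh:
        for r in rs.records:
            if r.label is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_genome(path) -> dict[str, int]:
    """Chromosome lengths from a FASTA index (.fai) or two-column file."""
    out: dict[str, int] = {}
    with _opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            out[fields[0]] = int(fields[1])
    return out


def write_genome(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def write_fasta(sequences: Mapping[str, str], path, index: bool = True) -> None:
    """Write a reference FASTA (and its .fai when ``index`` is true)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    if index:
        pysam.faidx(str(path))


# ---------------------------------------------------------------------------
# VCF


def _info_get(rec, key):
    # pysam raises on INFO keys absent from the header; treat as missing
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_sv_vcf(path, passonly: bool = False) -> list[SvRecord]:
    """Read a VCF into per-ALT SvRecords.

    Symbolic <DEL>/<INS> alternates are accepted when SVLEN (or END for
    deletions) is present; '*' alternates produce star-flagged records.
    Malformed records are skipped with a logged warning.
    """
    records: list[SvRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        for rec in vf:
            filters = list(rec.filter.keys())
            filter_str = ";".join(filters) if filters else "PASS"
            if passonly and filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            gt = "./."
            if has_samples:
                sample = rec.samples[0]
                if sample.get("GT") is not None:
                    sep = "|" if sample.phased else "/"
                    gt = sep.join("." if a is None else str(a) for a in sample["GT"])
            svlen_info = _info_get(rec, "SVLEN")
            if isinstance(svlen_info, (int, float)):
                svlen_info = (svlen_info,)
            for ai, alt in enumerate(rec.alts):
                base = rec.id or f"{rec.chrom}_{rec.pos}"
                rid = base if len(rec.alts) == 1 else f"{base}:{ai}"
                if alt == "*":
                    records.append(
                        SvRecord(chrom=rec.chrom, pos=rec.pos, ref_len=len(rec.ref),
                                 alt_len=len(rec.ref), id=rid, alt_is_star=True,
                                 genotype=gt, filter=filter_str)
                    )
                    continue
                if alt.startswith("<"):
                    tag = alt.strip("<>").split(":")[0]
                    svlen = None
                    if svlen_info is not None and ai < len(svlen_info):
                        svlen = int(svlen_info[ai])
                    if svlen is None and tag == "DEL" and rec.stop is not None:
                        svlen = -(rec.stop - rec.pos)
                    if svlen is None:
                        log.warning(
                            "skipping symbolic record %s:%d <%s> lacking SVLEN/END",
                            rec.chrom, rec.pos, tag,
                        )
                        continue
                    if tag in ("DEL",):
                        size = abs(svlen)
                        sv = SvRecord(chrom=rec.chrom, pos=rec.pos, ref_len=size + 1,
                                      alt_len=1, id=rid, genotype=gt, filter=filter_str)
                    elif tag in ("INS", "DUP"):  # duplications treated as insertions
                        size = abs(svlen)
                        sv = SvRecord(chrom=rec.chrom, pos=rec.pos, ref_len=1,
                                      alt_len=size + 1, id=rid, genotype=gt,
                                      filter=filter_str)
                    else:
                        log.warning("skipping unsupported symbolic ALT <%s> at %s:%d",
                                    tag, rec.chrom, rec.pos)
                        continue
                    sv.sim_class = _info_get(rec, "SIMCLASS")
                    records.append(sv)
                    continue
                sv = SvRecord(
                    chrom=rec.chrom, pos=rec.pos, ref_len=len(rec.ref),
                    alt_len=len(alt), id=rid, genotype=gt, filter=filter_str,
                    seq=alt[len(rec.ref):] if len(alt) > len(rec.ref) and
                    alt.startswith(rec.ref) else None,
                )
                sv.sim_class = _info_get(rec, "SIMCLASS")
                records.append(sv)
    return records


def write_sv_vcf(
    records: Sequence[SvRecord],
    path,
    genome: Mapping[str, int],
    sequences: Mapping[str, str] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write sequence-resolved VCF records.

    REF/ALT sequences are taken from the reference when available; without
    sequences, deletions fall back to symbolic <DEL> with SVLEN/END and
    insertions require an attached inserted sequence.
    """
    header = pysam.VariantHeader()
    for chrom, length in genome.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVLEN", "A", "Integer", "Signed length difference of ALT vs REF")
    header.info.add("SVTYPE", "1", "String", "Type of structural variant")
    header.info.add("SIMCLASS", "1", "String", "Intended simulated region class (debug)")
    header.formats.add("GT", "1", "String", "Genotype")
    header.add_sample(sample)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in ordered:
            pos0 = sv.pos - 1
            if sv.svtype == "DEL":
                if sequences is not None:
                    ref = sequences[sv.chrom][pos0 : pos0 + sv.ref_len]
                    alleles = (ref, ref[0])
                else:
                    alleles = ("N", "<DEL>")
            else:
                anchor = sequences[sv.chrom][pos0] if sequences is not None else "N"
                if sv.seq is None:
                    raise ValueError(
                        f"insertion {sv.id or ''} at {sv.chrom}:{sv.pos} has no sequence"
                    )
                alleles = (anchor, anchor + sv.seq)
            rec = out.new_record(
                contig=sv.chrom, start=pos0, alleles=alleles, id=sv.id, qual=60,
            )
            rec.info["SVLEN"] = sv.sv_len
            rec.info["SVTYPE"] = sv.svtype
            if sv.sim_class is not None:
                rec.info["SIMCLASS"] = sv.sim_class
            if sv.svtype == "DEL" and sequences is None:
                rec.stop = pos0 + sv.ref_len
            rec.filter.add("PASS")
            gt = sv.genotype.replace("|", "/").split("/")
            try:
                rec.samples[sample]["GT"] = tuple(
                    None if a == "." else int(a) for a in gt
                )
                rec.samples[sample].phased = "|" in sv.genotype
            except ValueError:
                rec.samples[sample]["GT"] = (None, None)
            out.write(rec)
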