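"""Readers and writers for the package's interchange formats.

FASTA/FASTQ go through Biopython; PAF (with a cg-style CIGAR tag) and
BED-like repeat tracks are simple columnar formats parsed here. All genomic
coordinates are 0-based half-open internally; PAF/VCF handle their own
conventions at the boundary. Every writer round-trips exactly through its
reader.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .alignments import (
    AlignmentRecord,
    cigar_spans,
    cigar_to_string,
    parse_cigar,
)
from .contiguity import GAP, ReadLengthDistribution, RepeatInterval
from .genotypes import GenotypeCall


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.startswith("@"):
        return "fastq"
    return "lengths"


def read_lengths(path: str, genome_size: int) -> ReadLengthDistribution:
    """Read lengths from FASTA, FASTQ, or a plain one-integer-per-line list."""
    fmt = _sniff_format(path)
    if fmt in ("fasta", "fastq"):
        lengths = [len(rec.seq) for rec in SeqIO.parse(path, fmt)]
    else:
        lengths = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    value = int(line)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from exc
                if value <= 0:
                    raise ValueError(f"{path}:{lineno}: non-positive length {value}")
                lengths.append(value)
    if not lengths:
        raise ValueError(f"{path}: no reads found")
    return ReadLengthDistribution(lengths, genome_size)


def read_paf(path: str) -> list[AlignmentRecord]:
    """Parse a PAF file with cg:Z: CIGAR tags into alignment records.

    CIGARs use =/X/I/D (M is accepted as match-or-mismatch); query/target
    span consumption is validated per record. Target coordinates are
    forward-strand as PAF defines them.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: truncated PAF line ({len(fields)} columns)")
            cigar = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = parse_cigar(tag[5:])
            try:
                rec = AlignmentRecord(
                    read_id=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    cigar=cigar or [],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            q, t = cigar_spans(rec.cigar) if rec.cigar else (0, 0)
            matches = sum(n for op, n in rec.cigar if op == "match")
            block = max(q, t)
            fields = [
                rec.read_id,
                str(rec.query_length if rec.query_length is not None else rec.query_end),
                str(rec.query_start),
                str(rec.query_end),
                rec.strand,
                rec.target,
                str(rec.target_length if rec.target_length is not None else rec.target_end),
                str(rec.target_start),
                str(rec.target_end),
                str(matches),
                str(block),
                "60",
            ]
            if rec.cigar:
                fields.append("cg:Z:" + cigar_to_string(rec.cigar))
            fh.write("\t".join(fields) + "\n")


def read_bed_track(
    path: str, identity_column: int = 4, default_kind: str = "segdup"
) -> list[RepeatInterval]:
    """Read a BED-like repeat track: chrom, start, end, name, identity.

    The interval kind is inferred from the name field (a name containing
    "gap" makes a gap interval, "selfchain"/"chainSelf" a self-chain),
    falling back to ``default_kind``. Header and comment lines are skipped.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3].lower() if len(fields) > 3 else default_kind
            if "gap" in name:
                kind = GAP
            elif "selfchain" in name or "chainself" in name:
                kind = "selfchain"
            else:
                kind = default_kind
            identity = 0.0
            if kind != GAP and len(fields) > identity_column:
                identity = float(fields[identity_column])
            intervals.append(RepeatInterval(chrom, start, end, identity, kind))
    return intervals


def write_bed_track(intervals: Iterable[RepeatInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.kind}\t{iv.identity:g}\n")


def read_genotype_calls(path: str) -> list[GenotypeCall]:
    """Read a genotype TSV: site_id, chrom, pos, genotype, llr (llr may be '.')."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("site_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 columns")
            llr = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                llr = float(fields[4])
            calls.append(
                GenotypeCall(fields[0], fields[1], int(fields[2]), fields[3], llr=llr)
            )
    return calls


def write_genotype_calls(calls: Iterable[GenotypeCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tchrom\tpos\tgenotype\tllr\n")
        for c in calls:
            llr = "." if c.llr is None else f"{c.llr:g}"
            fh.write(f"{c.site_id}\t{c.chrom}\t{c.pos}\t{c.genotype}\t{llr}\n")


_VCF_GT = {
    ("0", "0"): "homref",
    ("0", "1"): "het",
    ("1", "0"): "het",
    ("1", "1"): "homalt",
}


def read_vcf_genotypes(path: str) -> list[GenotypeCall]:
    """Read genotype calls from a minimal single-sample VCF (GT field).

    The LLR is taken from an INFO ``LLR=`` tag when present, else from
    QUAL. Missing genotypes (./.) become 'missing'.
    """
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: fewer than 10 VCF columns")
            chrom, pos, site_id = fields[0], int(fields[1]), fields[2]
            if site_id == ".":
                site_id = f"{chrom}:{pos}"
            llr = None
            for kv in fields[7].split(";"):
                if kv.startswith("LLR="):
                    llr = float(kv[4:])
            if llr is None and fields[5] not in (".", ""):
                llr = float(fields[5])
            fmt_keys = fields[8].split(":")
            sample = dict(zip(fmt_keys, fields[9].split(":")))
            gt = sample.get("GT", "./.").replace("|", "/")
            alleles = tuple(gt.split("/"))
            genotype = _VCF_GT.get(alleles, "missing")
            calls.append(GenotypeCall(site_id, chrom, pos, genotype, llr=llr))
    return calls


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable, path: str) -> None:
    """Write simulated reads (anything with read_id and sequence) as FASTQ."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_sv_bed(svs: Iterable, path: str) -> None:
    with open(path, "w") as fh:
        for sv in svs:
            fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_type}\t{sv.genotype}\n")


def read_sv_bed(path: str) -> list:
    from .genotypes import SvInterval

    svs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            svs.append(
                SvInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else "DEL",
                    f[4] if len(f) > 4 else "homref",
                )
            )
    return svs
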