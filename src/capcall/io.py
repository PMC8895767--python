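"""Shared genomic record types and readers/writers for FASTA, BED, SAM and VCF.

Coordinate conventions follow the file-format standards: BED intervals and
read alignment positions are 0-based half-open; VCF records and pileup
columns are 1-based.  Conversion happens exactly once, at the read/write
boundary of each format.

SAM and VCF parsing/serialisation is delegated to :mod:`pysam`; FASTA and
FASTQ to :mod:`Bio.SeqIO`.  BED is parsed directly so that malformed lines
can be reported with their line number.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicRegion",
    "AlignedRead",
    "VariantRecord",
    "ReferenceSequence",
    "BedParseError",
    "FastaAlphabetError",
    "read_bed",
    "write_bed",
    "merge_regions",
    "read_alignments",
    "write_alignments",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_vcf",
    "write_vcf",
]

# Query-consuming CIGAR ops; 'M' covers match and mismatch (also '='/'X').
_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MD")
_PYSAM_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
_OP_PYSAM = {"M": 0, "I": 1, "D": 2, "S": 4}


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class FastaAlphabetError(ValueError):
    """A FASTA sequence contained a symbol outside A/C/G/T/N."""


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A 0-based half-open interval on a named sequence.

    The unit of target capture: one BED line, one capture-panel region.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(slots=True)
class AlignedRead:
    """One aligned long read.

    ``pos`` is the 0-based leftmost reference position.  ``cigar`` is an
    ordered list of ``(op, length)`` with op in ``M`` (alignment-consuming,
    match or mismatch), ``I`` (insertion), ``D`` (deletion), ``S``
    (soft-clip).  Soft-clipped bases are present in ``seq`` but never
    contribute to pileups or depth.
    """

    read_id: str
    chrom: str
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    base_quals: list[int]
    mapq: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.seq) or len(self.seq) != len(self.base_quals):
            raise ValueError(
                f"read {self.read_id}: cigar query length {qlen} != "
                f"seq {len(self.seq)} / quals {len(self.base_quals)}"
            )
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def ref_end(self) -> int:
        """0-based exclusive rightmost reference position consumed."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    def aligned_length(self) -> int:
        """Number of reference bases consumed by match ops (depth weight)."""
        return sum(n for op, n in self.cigar if op == "M")


@dataclass(slots=True)
class VariantRecord:
    """One diploid variant call (or truth variant), 1-based position."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    qual: float = 0.0
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        for alt in self.alts:
            if not alt or alt == self.ref:
                raise ValueError(f"invalid alt {alt!r} against ref {self.ref!r}")
        if any(g >= 1 + len(self.alts) or g < 0 for g in self.genotype):
            raise ValueError(f"genotype {self.genotype} out of range")

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts)

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True, slots=True)
class ReferenceSequence:
    """A named reference sequence over the A/C/G/T/N alphabet."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise FastaAlphabetError(
                f"sequence {self.name!r} contains non-ACGTN symbol(s): "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read a BED3/BED4 file into a list of regions, in file order.

    Comment (``#``), ``track`` and ``browser`` lines and blank lines are
    skipped.  Malformed lines raise :class:`BedParseError` naming the line.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                regions.append(GenomicRegion(chrom, start, end, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def merge_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Sort regions by (chrom, start) and merge overlapping/adjacent ones.

    Merged regions lose their names.  The per-base union of the output
    equals that of the input.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicRegion] = []
    for r in ordered:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = GenomicRegion(last.chrom, last.start, r.end)
        else:
            merged.append(GenomicRegion(r.chrom, r.start, r.end))
    return merged


# ---------------------------------------------------------------------------
# SAM


def _from_pysam(aln: pysam.AlignedSegment) -> AlignedRead:
    cigar: list[tuple[str, int]] = []
    for code, length in aln.cigartuples or []:
        if code == 5:  # hard clip: no bases present, ignored
            continue
        try:
            cigar.append((_PYSAM_OP[code], length))
        except KeyError:
            raise ValueError(
                f"read {aln.query_name}: unsupported CIGAR op code {code}"
            ) from None
    quals = list(aln.query_qualities) if aln.query_qualities is not None else [0] * len(
        aln.query_sequence or ""
    )
    return AlignedRead(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        pos=aln.reference_start,
        cigar=cigar,
        seq=aln.query_sequence or "",
        base_quals=quals,
        mapq=aln.mapping_quality,
        is_primary=not (aln.is_secondary or aln.is_supplementary),
    )


def read_alignments(
    path: str | os.PathLike,
    regions: Sequence[GenomicRegion] | None = None,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM(/BAM) file, optionally region-filtered.

    A read passes the region filter if its reference span overlaps any of
    the given regions.  Unmapped reads are skipped.  A missing header or a
    read on a chromosome absent from the header is a format error (raised
    by pysam).
    """
    with pysam.AlignmentFile(os.fspath(path), check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no reference sequences")
        for aln in fh:
            if aln.is_unmapped:
                continue
            read = _from_pysam(aln)
            if regions is not None and not any(
                r.overlaps(read.chrom, read.pos, read.ref_end) for r in regions
            ):
                continue
            yield read


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
) -> None:
    """Write reads as SAM text with an @SQ header built from ``contigs``."""
    names = list(contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": contigs[n]} for n in names],
        }
    )
    index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.read_id
            seg.query_sequence = read.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in read.base_quals)
            )
            seg.reference_id = index[read.chrom]
            seg.reference_start = read.pos
            seg.mapping_quality = read.mapq
            seg.cigartuples = [(_OP_PYSAM[op], n) for op, n in read.cigar]
            seg.flag = 0 if read.is_primary else 256
            out.write(seg)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[ReferenceSequence]:
    """Read FASTA records, uppercasing sequences; names to first whitespace."""
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        out.append(ReferenceSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(
    seqs: Iterable[ReferenceSequence], path: str | os.PathLike, width: int = 80
) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(reads: Iterable[AlignedRead], path: str | os.PathLike) -> None:
    """Write read sequences and base qualities as FASTQ."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.seq), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.base_quals)
        records.append(rec)
    SeqIO.write(records, os.fspath(path), "fastq")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    sample: str = "SAMPLE",
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write sorted diploid variant records as VCF 4.2 with GT and QUAL.

    Raises ``ValueError`` on unsorted input.  ``extra_header_lines`` are
    added verbatim (e.g. a configuration echo for provenance).
    """
    keys = [r.sort_key() for r in records]
    if keys != sorted(keys):
        raise ValueError("VCF records must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=TASK_CONFLICT,Description="Classification tasks disagreed; see QUAL">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for line in extra_header_lines:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, *r.alts),
                qual=round(r.qual, 2),
                filter=r.filter,
            )
            rec.samples[sample]["GT"] = r.genotype
            rec.samples[sample].phased = False
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a single-sample VCF back into :class:`VariantRecord` objects."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as fh:
        for rec in fh:
            if rec.alts is None:
                continue
            filters = list(rec.filter)
            gt = (0, 0)
            if rec.samples:
                raw = rec.samples[0].get("GT")
                if raw is not None and all(g is not None for g in raw):
                    gt = tuple(raw)  # type: ignore[assignment]
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    genotype=gt,  # type: ignore[arg-type]
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    filter=filters[0] if filters else "PASS",
                )
            )
    return out
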