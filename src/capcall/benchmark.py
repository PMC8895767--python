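"""Variant-call benchmarking against a truth set inside confident regions.

Implements genotype-aware exact matching after allele normalisation:
both call sets are restricted to the intersection of the confident
regions and the target panel, each record is trimmed and left-aligned to
its canonical representation, multi-allelic records are decomposed, and
a true positive requires identical (chrom, pos, ref, alt, genotype
class).  Results are stratified overall / SNP / INDEL with
precision, recall and F1 per stratum.

This is deliberately simpler than haplotype-aware comparators: a
genotype mismatch at a true site counts as both a false positive and a
false negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .io import GenomicRegion, ReferenceSequence, VariantRecord

__all__ = [
    "StratumResult",
    "BenchmarkResult",
    "normalize_variant",
    "decompose",
    "compare",
]


@dataclass
class StratumResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    zero_denominator: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        self.zero_denominator = (self.tp + self.fp == 0) or (self.tp + self.fn == 0)
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "zero_denominator": self.zero_denominator,
        }


@dataclass
class BenchmarkResult:
    """TP/FP/FN and precision/recall/F1, overall and per variant class."""

    overall: StratumResult = field(default_factory=StratumResult)
    snp: StratumResult = field(default_factory=StratumResult)
    indel: StratumResult = field(default_factory=StratumResult)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "snp": self.snp.as_dict(),
            "indel": self.indel.as_dict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def normalize_variant(record: VariantRecord, ref: ReferenceSequence) -> VariantRecord:
    """Canonicalise a record: trim shared suffix, then prefix, left-align.

    The shared allele suffix is removed first, then the shared prefix
    (always keeping at least one base), and indels are shifted left one
    base at a time while the reference context allows an equivalent
    representation.  Raises ``ValueError`` when the REF allele does not
    match the reference sequence at the record position.
    """
    pos0 = record.pos - 1
    if ref.seq[pos0 : pos0 + len(record.ref)] != record.ref:
        raise ValueError(
            f"REF allele {record.ref!r} does not match reference at "
            f"{record.chrom}:{record.pos}"
        )
    alleles = [record.ref, *record.alts]
    pos = record.pos

    # Truncate the shared last base repeatedly; when an allele empties,
    # extend all alleles left with the preceding reference base.  This
    # both trims the shared suffix and left-aligns indels.
    while len({a[-1] if a else "" for a in alleles}) == 1 and alleles[0]:
        if any(len(a) == 1 for a in alleles):
            if pos == 1:
                break
            prev = ref.seq[pos - 2]
            alleles = [prev + a[:-1] for a in alleles]
            pos -= 1
        else:
            alleles = [a[:-1] for a in alleles]
    # trim the shared prefix, keeping at least one base
    while (
        all(len(a) > 1 for a in alleles)
        and len({a[0] for a in alleles}) == 1
    ):
        alleles = [a[1:] for a in alleles]
        pos += 1
    return VariantRecord(
        chrom=record.chrom,
        pos=pos,
        ref=alleles[0],
        alts=tuple(alleles[1:]),
        genotype=record.genotype,
        qual=record.qual,
        filter=record.filter,
    )


def decompose(record: VariantRecord) -> list[VariantRecord]:
    """Split a multi-allelic record into bi-allelic records.

    The genotype of each decomposed record reflects how many copies of
    that alt the sample carries (0/1 or 1/1).
    """
    if len(record.alts) == 1:
        return [record]
    out = []
    for i, alt in enumerate(record.alts, start=1):
        copies = sum(1 for g in record.genotype if g == i)
        gt = (1, 1) if copies == 2 else (0, 1)
        out.append(
            VariantRecord(
                record.chrom, record.pos, record.ref, (alt,), gt,
                record.qual, record.filter,
            )
        )
    return out


def _in_regions(
    record: VariantRecord, regions: Sequence[GenomicRegion] | None
) -> bool:
    if regions is None:
        return True
    p0 = record.pos - 1
    return any(
        r.chrom == record.chrom and r.start <= p0 < r.end for r in regions
    )


def _match_key(record: VariantRecord) -> tuple:
    gt = tuple(sorted(record.genotype))
    return (record.chrom, record.pos, record.ref, record.alts[0], gt)


def _prepare(
    records: Sequence[VariantRecord],
    ref: ReferenceSequence | None,
    confident: Sequence[GenomicRegion] | None,
    targets: Sequence[GenomicRegion] | None,
) -> list[VariantRecord]:
    keys = [r.sort_key() for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    out = []
    for rec in records:
        for sub in decompose(rec):
            norm = normalize_variant(sub, ref) if ref is not None else sub
            if _in_regions(norm, confident) and _in_regions(norm, targets):
                out.append(norm)
    return out


def compare(
    truth: Sequence[VariantRecord],
    called: Sequence[VariantRecord],
    confident_regions: Sequence[GenomicRegion] | None = None,
    target_regions: Sequence[GenomicRegion] | None = None,
    ref: ReferenceSequence | None = None,
) -> BenchmarkResult:
    """Genotype-aware exact comparison of called variants against truth.

    Records outside the confident ∩ target regions are excluded from
    both sides.  When ``ref`` is given, both sides are normalised first,
    making the comparison invariant to allele representation.  Stratum
    is INDEL when any allele length differs from the REF length, else
    SNP.  Zero-denominator metrics are reported as 0 with a flag.
    """
    truth_n = _prepare(truth, ref, confident_regions, target_regions)
    called_n = _prepare(called, ref, confident_regions, target_regions)

    truth_keys = {_match_key(r): r for r in truth_n}
    called_keys = {_match_key(r): r for r in called_n}

    result = BenchmarkResult()

    def stratum_of(rec: VariantRecord) -> StratumResult:
        return result.indel if rec.is_indel else result.snp

    for key, rec in called_keys.items():
        if key in truth_keys:
            result.overall.tp += 1
            stratum_of(rec).tp += 1
        else:
            result.overall.fp += 1
            stratum_of(rec).fp += 1
    for key, rec in truth_keys.items():
        if key not in called_keys:
            result.overall.fn += 1
            stratum_of(rec).fn += 1
    return result
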