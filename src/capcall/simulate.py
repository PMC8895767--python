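"""Synthetic capture-sequencing data: reference, targets, truth variants, reads.

The generator emulates ONT-like target-enrichment (capture) data: ~1 kb
reads, per-region capture/PCR depth bias modelled as a log-normal
multiplier, per-base qualities averaging ~Q11, and planted diploid SNVs
and small indels with a matching truth VCF.  Reads are emitted pre-aligned
at their true positions (CIGAR reflecting planted variants and injected
errors), so the downstream stages are testable without an external
aligner; a FASTQ is also written for users who prefer to realign.

Each haplotype is represented as a per-reference-base replacement table
(`rep[i]` = the string the haplotype carries in place of reference base
``i``: the base itself, a substituted base, ``""`` for a deleted base, or
base+insertion).  This makes the truth VCF, the haplotype sequences and
the simulated CIGARs mutually consistent by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    AlignedRead,
    GenomicRegion,
    ReferenceSequence,
    VariantRecord,
    write_alignments,
    write_bed,
    write_fasta,
    write_fastq,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "Haplotype",
    "SimulatedDataset",
    "generate_reference",
    "generate_target_bed",
    "plant_variants",
    "simulate_reads",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

# Buffer kept between planted variants so events never interact within a
# pileup column (max indel span 10 bp + anchor).
_VARIANT_SPACING = 12


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic capture-sequencing experiment.

    Defaults mirror a typical nanopore medical-exome capture run:
    ~1 kb reads over exon-sized targets (~164 bp), mean per-read quality
    around Q11, and region-to-region depth variation from capture/PCR
    efficiency modelled as a log-normal multiplier.
    """

    ref_length: int = 100_000
    n_regions: int = 100
    region_length_mean: int = 164
    read_length_mean: int = 1000
    read_length_sd: int = 200
    mean_depth: float = 100.0
    capture_bias_sigma: float = 0.6
    sub_error_rate: float = 0.05
    indel_error_rate: float = 0.02
    snv_rate: float = 0.005
    indel_rate: float = 0.001
    het_fraction: float = 0.5
    mean_read_phred: float = 11.0
    gc_fraction: float = 0.5
    chrom: str = "chr1"
    seed: int = 0
    # Exact planted-variant counts; when set they override the per-base rates.
    n_snvs: int | None = None
    n_indels: int | None = None

    def __post_init__(self) -> None:
        for name in ("sub_error_rate", "indel_error_rate", "snv_rate",
                     "indel_rate", "het_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.ref_length, self.n_regions, self.region_length_mean,
               self.read_length_mean) <= 0 or self.mean_depth <= 0:
            raise ValueError("lengths and depth must be positive")


@dataclass
class Haplotype:
    """One of the two chromosome copies, as a replacement table over the reference."""

    ref: ReferenceSequence
    rep: list[str]

    def sequence(self) -> str:
        return "".join(self.rep)

    @classmethod
    def identical_to(cls, ref: ReferenceSequence) -> "Haplotype":
        return cls(ref, list(ref.seq))


@dataclass
class TruthSet:
    """Planted variants (sorted, non-overlapping) with their genotypes."""

    records: list[VariantRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, in memory."""

    config: SimulationConfig
    reference: ReferenceSequence
    regions: list[GenomicRegion]
    truth: TruthSet
    haplotypes: tuple[Haplotype, Haplotype]
    reads: list[AlignedRead]

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        """Write FASTA/BED/VCF/SAM/FASTQ artifacts; returns their paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        contigs = {self.reference.name: len(self.reference)}
        paths = {
            "reference": out / "reference.fasta",
            "targets": out / "targets.bed",
            "truth": out / "truth.vcf",
            "alignments": out / "reads.sam",
            "fastq": out / "reads.fastq",
        }
        write_fasta([self.reference], paths["reference"])
        write_bed(self.regions, paths["targets"])
        write_vcf(self.truth.records, paths["truth"], contigs)
        write_alignments(self.reads, paths["alignments"], contigs)
        write_fastq(self.reads, paths["fastq"])
        return paths


def generate_reference(
    length: int, gc_fraction: float = 0.5, seed: int = 0, name: str = "chr1"
) -> ReferenceSequence:
    """I.i.d. random reference with P(G)+P(C) = ``gc_fraction``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ReferenceSequence(name, seq)


def generate_target_bed(
    ref_length: int,
    n_regions: int,
    region_length_mean: int = 164,
    seed: int = 0,
    chrom: str = "chr1",
    min_length: int = 50,
) -> list[GenomicRegion]:
    """Non-overlapping, sorted target regions with exon-like lengths.

    Lengths are geometric-like draws around ``region_length_mean`` (Gamma
    with shape 4, floored at ``min_length``), placed by distributing the
    unused reference length as random gaps.  Raises ``ValueError`` if the
    regions cannot be packed into the reference.
    """
    rng = np.random.default_rng(seed)
    shape = 4.0
    lengths = np.maximum(
        min_length,
        np.round(rng.gamma(shape, region_length_mean / shape, n_regions)).astype(int),
    )
    total = int(lengths.sum())
    slack = ref_length - total
    if slack < n_regions + 1:
        raise ValueError(
            f"cannot pack {n_regions} regions totalling {total} bp "
            f"into {ref_length} bp"
        )
    # n_regions+1 gaps, each >= 1, summing to slack.
    cuts = np.sort(rng.choice(slack - 1, size=n_regions, replace=False)) + 1
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    regions: list[GenomicRegion] = []
    cursor = 0
    for i, (gap, length) in enumerate(zip(gaps, lengths)):
        cursor += int(gap)
        regions.append(
            GenomicRegion(chrom, cursor, cursor + int(length), f"target_{i:04d}")
        )
        cursor += int(length)
    return regions


def _eligible_positions(regions: list[GenomicRegion], max_span: int) -> np.ndarray:
    """Reference positions where a variant anchor may be placed.

    The anchor and up to ``max_span`` following bases must stay inside the
    region, so a planted deletion never crosses the target boundary.
    """
    chunks = [
        np.arange(r.start + 1, r.end - max_span)
        for r in regions
        if r.end - max_span > r.start + 1
    ]
    return np.concatenate(chunks) if chunks else np.array([], dtype=int)


def plant_variants(
    ref: ReferenceSequence,
    regions: list[GenomicRegion],
    config: SimulationConfig,
) -> tuple[TruthSet, tuple[Haplotype, Haplotype]]:
    """Plant diploid SNVs and 1–10 bp indels uniformly inside the targets.

    Heterozygous variants are applied to one randomly chosen haplotype,
    homozygous ones to both.  Planted events are spaced so they never
    share a pileup column.  The truth VCF is sorted and uses the standard
    anchored representation for indels.
    """
    rng = np.random.default_rng([config.seed, 1])
    max_indel = 10
    covered = sum(len(r) for r in regions)
    n_snv = (config.n_snvs if config.n_snvs is not None
             else int(rng.poisson(config.snv_rate * covered)))
    n_indel = (config.n_indels if config.n_indels is not None
               else int(rng.poisson(config.indel_rate * covered)))

    eligible = _eligible_positions(regions, max_indel + 1)
    rng.shuffle(eligible)
    chosen: list[int] = []
    taken: set[int] = set()
    for p in eligible:
        if len(chosen) == n_snv + n_indel:
            break
        block = range(p - _VARIANT_SPACING, p + _VARIANT_SPACING + 1)
        if any(q in taken for q in block):
            continue
        chosen.append(int(p))
        taken.update(block)
    if len(chosen) < n_snv + n_indel:
        raise ValueError(
            f"could not place {n_snv + n_indel} variants in "
            f"{covered} target bases"
        )

    hap1 = Haplotype.identical_to(ref)
    hap2 = Haplotype.identical_to(ref)
    records: list[VariantRecord] = []
    kinds = ["snv"] * n_snv + ["indel"] * n_indel
    for pos0, kind in zip(chosen, kinds):
        is_het = rng.random() < config.het_fraction
        targets = [hap1 if rng.random() < 0.5 else hap2] if is_het else [hap1, hap2]
        gt = (0, 1) if is_het else (1, 1)
        ref_base = ref.seq[pos0]
        if kind == "snv":
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            for hap in targets:
                hap.rep[pos0] = alt
            records.append(VariantRecord(ref.name, pos0 + 1, ref_base, (alt,), gt))
        else:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # insertion after the anchor base
                ins = "".join(rng.choice(_BASES, size=size))
                for hap in targets:
                    hap.rep[pos0] = ref_base + ins
                records.append(
                    VariantRecord(ref.name, pos0 + 1, ref_base, (ref_base + ins,), gt)
                )
            else:  # deletion of `size` bases after the anchor
                for hap in targets:
                    for q in range(pos0 + 1, pos0 + 1 + size):
                        hap.rep[q] = ""
                records.append(
                    VariantRecord(
                        ref.name,
                        pos0 + 1,
                        ref.seq[pos0 : pos0 + 1 + size],
                        (ref_base,),
                        gt,
                    )
                )
    records.sort(key=lambda r: r.sort_key())
    return TruthSet(records), (hap1, hap2)


# Token encoding used by the vectorised read builder: per-token op codes
# (0 = match-consuming, 1 = insertion, 2 = deletion) and base codes 0-3
# over ACGT (deletions carry a dummy code).
_OP_M, _OP_I, _OP_D = 0, 1, 2
_OP_CHAR = {_OP_M: "M", _OP_I: "I", _OP_D: "D"}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BYTE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(s: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]


def _window_tokens(
    hap_codes: np.ndarray,
    rep_lens: np.ndarray,
    hap: Haplotype,
    w0: int,
    w1: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand the replacement table over [w0, w1) into token arrays.

    ``hap_codes[i]`` is the code of the *first* replacement base at
    reference position ``i`` (so substituted bases are already correct);
    only indel positions (``rep_lens != 1``) need expansion.
    """
    lens = rep_lens[w0:w1]
    if np.all(lens == 1):  # no indel in the window: pure match
        return np.zeros(w1 - w0, dtype=np.uint8), hap_codes[w0:w1]
    ops_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    prev = w0
    for off in np.flatnonzero(lens != 1):
        i = w0 + int(off)
        if i > prev:
            ops_chunks.append(np.zeros(i - prev, dtype=np.uint8))
            code_chunks.append(hap_codes[prev:i])
        s = hap.rep[i]
        if s == "":
            ops_chunks.append(np.array([_OP_D], dtype=np.uint8))
            code_chunks.append(np.array([0], dtype=np.uint8))
        else:
            ops = np.full(len(s), _OP_I, dtype=np.uint8)
            ops[0] = _OP_M
            ops_chunks.append(ops)
            code_chunks.append(_encode(s))
        prev = i + 1
    if w1 > prev:
        ops_chunks.append(np.zeros(w1 - prev, dtype=np.uint8))
        code_chunks.append(hap_codes[prev:w1])
    return np.concatenate(ops_chunks), np.concatenate(code_chunks)


def _inject_errors(
    ops: np.ndarray,
    codes: np.ndarray,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequencing-error process: substitutions first, then 1 bp indels.

    A deletion error drops a base (match token becomes a deletion,
    an inserted base vanishes); an insertion error adds one random base
    after the affected base.  Error bases are not quality-flagged.
    """
    codes = codes.copy()
    q_pos = np.flatnonzero(ops != _OP_D)
    if sub_rate > 0 and q_pos.size:
        sel = q_pos[rng.random(q_pos.size) < sub_rate]
        codes[sel] = (codes[sel] + rng.integers(1, 4, sel.size).astype(np.uint8)) % 4
    if indel_rate <= 0 or not q_pos.size:
        return ops, codes
    u = rng.random(q_pos.size)
    del_sel = q_pos[u < indel_rate / 2]
    ins_sel = q_pos[u >= 1 - indel_rate / 2]
    if not del_sel.size and not ins_sel.size:
        return ops, codes
    events = sorted(
        [(int(p), "D") for p in del_sel] + [(int(p), "I") for p in ins_sel]
    )
    ins_codes = iter(rng.integers(0, 4, ins_sel.size).astype(np.uint8))
    ops_out: list[np.ndarray] = []
    codes_out: list[np.ndarray] = []
    prev = 0
    one_d = np.array([_OP_D], dtype=np.uint8)
    one_i = np.array([_OP_I], dtype=np.uint8)
    zero = np.array([0], dtype=np.uint8)
    for p, typ in events:
        ops_out.append(ops[prev:p])
        codes_out.append(codes[prev:p])
        if typ == "D":
            if ops[p] == _OP_M:  # the reference base is skipped
                ops_out.append(one_d)
                codes_out.append(zero)
            # an erroneous deletion of an inserted base removes the token
        else:
            ops_out.append(ops[p : p + 1])
            codes_out.append(codes[p : p + 1])
            ops_out.append(one_i)
            codes_out.append(np.array([next(ins_codes)], dtype=np.uint8))
        prev = p + 1
    ops_out.append(ops[prev:])
    codes_out.append(codes[prev:])
    return np.concatenate(ops_out), np.concatenate(codes_out)


def _tokens_to_read(
    ops: np.ndarray,
    codes: np.ndarray,
    w0: int,
    read_id: str,
    chrom: str,
    base_quals: "callable",
) -> AlignedRead | None:
    """Trim non-match edges, compress runs to CIGAR, attach qualities."""
    m_idx = np.flatnonzero(ops == _OP_M)
    if not m_idx.size:
        return None
    first, last = int(m_idx[0]), int(m_idx[-1])
    pos = w0 + int(np.count_nonzero(ops[:first] != _OP_I))
    ops = ops[first : last + 1]
    codes = codes[first : last + 1]
    change = np.flatnonzero(np.diff(ops))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [ops.size]])
    cigar = [
        (_OP_CHAR[int(ops[s])], int(e - s)) for s, e in zip(starts, ends)
    ]
    seq = _BYTE_LUT[codes[ops != _OP_D]].tobytes().decode()
    return AlignedRead(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        cigar=cigar,
        seq=seq,
        base_quals=base_quals(len(seq)),
        mapq=60,
        is_primary=True,
    )


def simulate_reads(
    haplotypes: tuple[Haplotype, Haplotype],
    regions: list[GenomicRegion],
    config: SimulationConfig,
) -> list[AlignedRead]:
    """Sample error-bearing aligned reads with per-region capture bias.

    Per region, the expected depth is ``mean_depth`` times a
    LogNormal(0, capture_bias_sigma) multiplier.  Fragment midpoints are
    uniform over the region extended by half a read length on each side,
    which reproduces the flanking coverage of capture data around exons.
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng([config.seed, 2])
    ref = haplotypes[0].ref
    hap_codes = [
        _encode("".join(s[0] if s else "A" for s in h.rep)) for h in haplotypes
    ]
    rep_lens = [
        np.fromiter((len(s) for s in h.rep), dtype=np.int32, count=len(h.rep))
        for h in haplotypes
    ]
    reads: list[AlignedRead] = []
    counter = 0
    half = config.read_length_mean / 2
    for region in regions:
        depth = config.mean_depth * rng.lognormal(0.0, config.capture_bias_sigma)
        window = len(region) + config.read_length_mean
        n_reads = rng.poisson(depth * window / config.read_length_mean)
        for _ in range(n_reads):
            mid = rng.uniform(region.start - half, region.end + half)
            length = max(50, int(round(rng.normal(config.read_length_mean,
                                                  config.read_length_sd))))
            w0 = max(0, int(round(mid - length / 2)))
            w1 = min(len(ref), w0 + length)
            if w1 - w0 < 50:
                continue
            h = int(rng.integers(2))
            ops, codes = _window_tokens(
                hap_codes[h], rep_lens[h], haplotypes[h], w0, w1
            )
            ops, codes = _inject_errors(
                ops, codes, config.sub_error_rate, config.indel_error_rate, rng
            )
            read_mean_q = max(3.0, rng.normal(config.mean_read_phred, 3.0))

            def quals_for(n: int, q0: float = read_mean_q) -> list[int]:
                q = np.clip(np.round(rng.normal(q0, 2.0, size=n)), 3, 40)
                return [int(x) for x in q]

            read = _tokens_to_read(
                ops, codes, w0, f"read_{counter:07d}", ref.name, quals_for
            )
            counter += 1
            if read is not None:
                reads.append(read)
    reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    return reads


def simulate_dataset(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> SimulatedDataset:
    """Run the full generator: reference → targets → variants → reads."""
    ref = generate_reference(
        config.ref_length, config.gc_fraction, seed=config.seed, name=config.chrom
    )
    regions = generate_target_bed(
        config.ref_length,
        config.n_regions,
        config.region_length_mean,
        seed=config.seed,
        chrom=config.chrom,
    )
    truth, haps = plant_variants(ref, regions, config)
    reads = simulate_reads(haps, regions, config)
    ds = SimulatedDataset(config, ref, regions, truth, haps, reads)
    if outdir is not None:
        ds.write(outdir)
    return ds
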