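"""Ensemble variant calling over depth-capped pileup partitions.

A probability model maps one partition of pileup observations to four
per-position classification distributions (the tasks a genotyping
network emits): a 21-class genotype (base pairs plus insertion/deletion
pseudo-alleles), a 4-class zygosity, and two 33-bin indel-length
distributions, one per haplotype.  Every (partition × model) pair is
evaluated, the four task vectors are averaged element-wise across all
pairs, and a single decision is made from the averaged distributions.
Averaging across partitions and models is what stabilises calls in
regions whose depth had to be capped.

The trained network the scheme was designed around is replaced here by a
pluggable model contract plus ``NaiveDiploidModel``, an explicit
likelihood-based stand-in: a diploid genotype posterior from per-base
Phred error rates.  Any object with an ``identifier`` and a
``(partition, ref_base) -> TaskProbabilities`` call conforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import logsumexp

from .io import AlignedRead, GenomicRegion, ReferenceSequence, VariantRecord
from .resample import (
    ColumnPartitions,
    Observation,
    PileupColumn,
    ResampleConfig,
    build_pileup,
    filter_alignments,
    partition_column,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GT21_CLASSES",
    "ZYGOSITY_CLASSES",
    "N_LENGTH_BINS",
    "length_to_bin",
    "bin_to_length",
    "TaskProbabilities",
    "ProbabilityModel",
    "NaiveDiploidModel",
    "naive_model",
    "average_probabilities",
    "VariantDecision",
    "decide",
    "CallerConfig",
    "call_targets",
]

# ---------------------------------------------------------------------------
# Class layouts.  Defined once so an external model can be plugged in.

#: 21 genotype classes over base pairs and the insertion (I) / deletion (D)
#: pseudo-alleles.
GT21_CLASSES: tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT",
    "AI", "CI", "GI", "TI", "AD", "CD", "GD", "TD", "II", "ID", "DD",
)
GT21_INDEX = {c: i for i, c in enumerate(GT21_CLASSES)}

#: Diploid zygosity states: homozygous reference, homozygous variant,
#: heterozygous variant (one ref allele), heterozygous multi-variant
#: (two distinct non-ref alleles).
ZYGOSITY_CLASSES: tuple[str, ...] = ("hom_ref", "hom_alt", "het_alt", "het_multi")

#: Indel-length bins: {<=-16, -15..-1, 0, +1..+15, >=+16}.
N_LENGTH_BINS = 33
_LEN_OFFSET = 16


def length_to_bin(delta: int) -> int:
    """Map a length change (ins > 0, del < 0, substitution 0) to its bin."""
    return int(np.clip(delta, -_LEN_OFFSET, _LEN_OFFSET)) + _LEN_OFFSET


def bin_to_length(bin_index: int) -> int:
    """Centre length change of a bin (boundary bins return ±16)."""
    return bin_index - _LEN_OFFSET


_PAIR_TO_GT21 = {}
for _cls in GT21_CLASSES:
    _PAIR_TO_GT21[(_cls[0], _cls[1])] = _cls
    _PAIR_TO_GT21[(_cls[1], _cls[0])] = _cls


def gt21_class(sym1: str, sym2: str) -> str:
    """Canonical 21-class label for an unordered symbol pair."""
    try:
        return _PAIR_TO_GT21[(sym1, sym2)]
    except KeyError:
        raise ValueError(f"no genotype class for pair ({sym1}, {sym2})") from None


@dataclass
class TaskProbabilities:
    """The four per-position classification distributions of one model run."""

    gt21: np.ndarray
    zygosity: np.ndarray
    len1: np.ndarray
    len2: np.ndarray

    def validate(self, atol: float = 1e-6) -> None:
        for name, vec, size in (
            ("gt21", self.gt21, len(GT21_CLASSES)),
            ("zygosity", self.zygosity, len(ZYGOSITY_CLASSES)),
            ("len1", self.len1, N_LENGTH_BINS),
            ("len2", self.len2, N_LENGTH_BINS),
        ):
            if vec.shape != (size,):
                raise ValueError(f"{name} has shape {vec.shape}, expected ({size},)")
            if np.any(vec < -atol):
                raise ValueError(f"{name} has negative entries")
            if abs(float(vec.sum()) - 1.0) > atol:
                raise ValueError(f"{name} sums to {vec.sum()}, expected 1")


@runtime_checkable
class ProbabilityModel(Protocol):
    """Contract for a pluggable per-partition probability model."""

    identifier: str

    def __call__(
        self, partition: Sequence[Observation], ref_base: str
    ) -> TaskProbabilities: ...


# ---------------------------------------------------------------------------
# Likelihood-based stand-in model


def _obs_key(obs: Observation) -> tuple[str, str | int]:
    return (obs.kind, obs.allele)


def _allele_symbol(kind: str, value: str | int) -> str:
    if kind == "base":
        return str(value)
    return "I" if kind == "ins" else "D"


def _allele_delta(kind: str, value: str | int) -> int:
    if kind == "base":
        return 0
    if kind == "ins":
        return len(value)  # type: ignore[arg-type]
    return -int(value)


@dataclass
class NaiveDiploidModel:
    """Diploid genotype posterior from per-base Phred error rates.

    For a genotype ``g = {a1, a2}`` over the four bases plus any observed
    indel alleles, each observation contributes likelihood
    ``0.5·p(obs|a1) + 0.5·p(obs|a2)`` with ``p(obs|a) = 1 − ε`` when the
    observed allele equals ``a`` and ``ε/3`` otherwise; ``ε`` comes from
    the observation's Phred score, floored at ``error_rate_prior``.  A
    prior places ``het_prior`` total mass uniformly on heterozygous
    genotypes and the rest uniformly on homozygous ones.  The normalised
    posterior is marginalised into the four task distributions
    (non-indel alleles put their length mass on the 0 bin).
    """

    error_rate_prior: float = 0.01
    het_prior: float = 0.5
    identifier: str = "naive"

    def __call__(
        self, partition: Sequence[Observation], ref_base: str
    ) -> TaskProbabilities:
        if not partition:
            raise ValueError("cannot evaluate a model on an empty partition")
        # Allele universe: the four bases plus every observed indel allele.
        alleles: list[tuple[str, str | int]] = [("base", b) for b in "ACGT"]
        seen = set()
        for obs in partition:
            if obs.kind != "base":
                key = _obs_key(obs)
                if key not in seen:
                    seen.add(key)
                    alleles.append(key)
        n_all = len(alleles)
        allele_index = {a: i for i, a in enumerate(alleles)}

        # Per-observation allele match log-probabilities.
        # p_match[o, a] = 1-eps if obs o equals allele a else eps/3.
        eps = np.array(
            [
                min(0.75, max(10.0 ** (-obs.qual / 10.0), self.error_rate_prior))
                for obs in partition
            ]
        )
        obs_idx = np.array([allele_index[_obs_key(o)] for o in partition])
        p = np.tile((eps / 3.0)[:, None], (1, n_all))
        p[np.arange(len(partition)), obs_idx] = 1.0 - eps

        # Unordered genotype pairs and their posteriors.
        pairs = [(i, j) for i in range(n_all) for j in range(i, n_all)]
        n_het = sum(1 for i, j in pairs if i != j)
        n_hom = n_all
        log_post = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            mix = 0.5 * p[:, i] + 0.5 * p[:, j]
            prior = (self.het_prior / n_het) if i != j else ((1.0 - self.het_prior) / n_hom)
            log_post[k] = np.log(mix).sum() + np.log(prior)
        log_post -= logsumexp(log_post)
        post = np.exp(log_post)

        gt21 = np.zeros(len(GT21_CLASSES))
        zyg = np.zeros(len(ZYGOSITY_CLASSES))
        len1 = np.zeros(N_LENGTH_BINS)
        len2 = np.zeros(N_LENGTH_BINS)
        ref_key = ("base", ref_base)
        for (i, j), mass in zip(pairs, post):
            a1, a2 = alleles[i], alleles[j]
            gt21[GT21_INDEX[gt21_class(_allele_symbol(*a1), _allele_symbol(*a2))]] += mass
            ref1, ref2 = a1 == ref_key, a2 == ref_key
            if ref1 and ref2:
                zyg[0] += mass
            elif a1 == a2:
                zyg[1] += mass
            elif ref1 or ref2:
                zyg[2] += mass
            else:
                zyg[3] += mass
            d1, d2 = sorted((_allele_delta(*a1), _allele_delta(*a2)))
            len1[length_to_bin(d1)] += mass
            len2[length_to_bin(d2)] += mass
        tp = TaskProbabilities(gt21, zyg, len1, len2)
        tp.validate()
        return tp


def naive_model(
    partition: Sequence[Observation],
    ref_base: str,
    error_rate_prior: float = 0.01,
    het_prior: float = 0.5,
) -> TaskProbabilities:
    """Functional form of :class:`NaiveDiploidModel`."""
    return NaiveDiploidModel(error_rate_prior, het_prior)(partition, ref_base)


# ---------------------------------------------------------------------------
# Ensemble averaging


def average_probabilities(
    outputs: Sequence[TaskProbabilities],
) -> TaskProbabilities:
    """Element-wise arithmetic mean of task distributions.

    This is the ensemble step: probabilities of each task are averaged
    across all partitions and all models before any decision is made.
    """
    if not outputs:
        raise ValueError("average_probabilities requires at least one input")
    for tp in outputs:
        tp.validate()

    def mean(vectors: list[np.ndarray]) -> np.ndarray:
        # element-wise sort before summation makes the result exactly
        # invariant to the order of the inputs (floating-point addition
        # is not associative); averaging deviations from the smallest
        # addend makes the mean of identical inputs exactly idempotent
        stack = np.sort(np.stack(vectors), axis=0)
        base = stack[0]
        return base + (stack - base).sum(axis=0) / len(vectors)

    return TaskProbabilities(
        gt21=mean([tp.gt21 for tp in outputs]),
        zygosity=mean([tp.zygosity for tp in outputs]),
        len1=mean([tp.len1 for tp in outputs]),
        len2=mean([tp.len2 for tp in outputs]),
    )


# ---------------------------------------------------------------------------
# Decision logic


@dataclass
class VariantDecision:
    """Outcome of post-processing one averaged probability set.

    ``alt_descriptors`` holds up to two alternate alleles in abstract
    form — ``("snv", base)``, ``("ins", inserted_sequence)`` or
    ``("del", deleted_length)`` — anchored at the column position;
    conversion to VCF alleles (including the one-base-left anchoring of
    deletions) happens at record emission.
    """

    is_variant: bool
    genotype: str
    alt_descriptors: tuple[tuple[str, str | int], ...]
    qual: float
    conflict: bool = False


def _phred_from_prob(p: float, cap: float = 99.0) -> float:
    if p >= 1.0:
        return cap
    return float(min(cap, max(0.0, -10.0 * np.log10(1.0 - p))))


def _most_frequent(
    items: list, key=lambda x: x
) -> object | None:
    """Mode with deterministic tie-break (highest count, then smallest key)."""
    if not items:
        return None
    counts: dict = {}
    for it in items:
        counts[key(it)] = counts.get(key(it), 0) + 1
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def _realize_symbol(
    sym: str,
    ref_base: str,
    wanted_delta: int | None,
    column: PileupColumn,
) -> tuple[str, tuple[str, str | int] | None, bool]:
    """Turn a gt21 symbol into a concrete allele descriptor.

    Returns ``(status, descriptor, conflict)`` with status ``"ref"`` (the
    reference allele), ``"alt"`` (a realised alternate allele) or
    ``"fail"`` (an indel symbol with no supporting observation in the
    column; always a conflict).
    """
    if sym in "ACGT":
        if sym == ref_base:
            return "ref", None, False
        return "alt", ("snv", sym), False
    if sym == "I":
        ins_seqs = [o.allele for o in column.observations if o.kind == "ins"]
        if not ins_seqs:
            return "fail", None, True
        target_len = wanted_delta if (wanted_delta or 0) > 0 else None
        matching = [s for s in ins_seqs if target_len and len(s) == target_len]
        conflict = target_len is None or not matching
        pool = matching if matching else ins_seqs
        return "alt", ("ins", _most_frequent(pool)), conflict
    # deletion
    del_lens = [int(o.allele) for o in column.observations if o.kind == "del"]
    if not del_lens:
        return "fail", None, True
    target_len = -wanted_delta if (wanted_delta or 0) < 0 else None
    matching = [length for length in del_lens if length == target_len]
    conflict = target_len is None or not matching
    pool = matching if matching else del_lens
    return "alt", ("del", _most_frequent(pool)), conflict


def _deltas_for_pair(
    sym1: str, sym2: str, d1: int, d2: int
) -> tuple[int | None, int | None]:
    """Assign the two length-task argmax deltas to the symbol pair.

    Insertion symbols want a positive delta, deletion symbols a negative
    one, base symbols 0.  ``d1 <= d2`` by the len1/len2 convention.
    """
    def pick(sym: str, available: list[int]) -> int | None:
        if sym in "ACGT":
            return 0
        sign_ok = (lambda d: d > 0) if sym == "I" else (lambda d: d < 0)
        for d in (available if sym == "D" else reversed(available)):
            if sign_ok(d):
                available.remove(d)
                return d
        return None

    avail = [d1, d2]
    return pick(sym1, avail), pick(sym2, avail)


def decide(
    avg: TaskProbabilities,
    ref_base: str,
    column: PileupColumn,
) -> VariantDecision:
    """Post-process averaged task probabilities into one variant decision.

    Decision table (ties always break to the lowest class index):

    1. zygosity argmax hom_ref → not a variant.
    2. Otherwise the gt21 argmax fixes the allele-symbol pair; zygosity
       wins on hom-ref-vs-variant, gt21 wins on allele identity.
    3. I/D symbols are realised as the most frequent insertion/deletion
       of the length given by the len1/len2 argmaxes among the column's
       observations (falling back to the most frequent of any length,
       flagged as a conflict).
    4. If the gt21 argmax yields no alternate allele while zygosity says
       variant, the best gt21 class that does yield one is used instead,
       flagged as a conflict.
    5. Genotype string from zygosity: hom_alt → 1/1, het_alt → 0/1,
       het_multi → 1/2 (downgraded with a conflict flag when fewer
       distinct alternate alleles are available).
    6. QUAL = −10·log10(1 − min over consulted tasks of their argmax
       probability), capped at 99; the length tasks are consulted only
       when an indel allele is involved.
    """
    avg.validate()
    z = int(np.argmax(avg.zygosity))
    p_z = float(avg.zygosity[z])
    if z == 0:
        return VariantDecision(False, "0/0", (), _phred_from_prob(p_z))

    d1 = bin_to_length(int(np.argmax(avg.len1)))
    d2 = bin_to_length(int(np.argmax(avg.len2)))
    order = np.argsort(-avg.gt21, kind="stable")

    chosen = None
    has_ref = False
    conflict = False
    for rank, gi in enumerate(order):
        sym1, sym2 = GT21_CLASSES[int(gi)]
        w1, w2 = _deltas_for_pair(sym1, sym2, d1, d2)
        s1, a1, c1 = _realize_symbol(sym1, ref_base, w1, column)
        s2, a2, c2 = _realize_symbol(sym2, ref_base, w2, column)
        if "fail" in (s1, s2) or (s1 == "ref" and s2 == "ref"):
            # unrealisable indel symbol, or a homozygous-reference pair
            # while zygosity says variant: try the next-best class
            conflict = True
            continue
        chosen = [a for a in (a1, a2) if a is not None]
        has_ref = "ref" in (s1, s2)
        conflict = conflict or c1 or c2 or rank > 0
        break
    if chosen is None:
        return VariantDecision(False, "0/0", (), _phred_from_prob(p_z), conflict=True)

    # distinct non-reference descriptors, order preserved
    alts: list[tuple[str, str | int]] = []
    for a in chosen:
        if a not in alts:
            alts.append(a)

    p_g = float(avg.gt21[int(order[0])])
    consulted = [p_z, p_g]
    if any(a[0] in ("ins", "del") for a in alts):
        consulted.append(float(avg.len1[np.argmax(avg.len1)]))
        consulted.append(float(avg.len2[np.argmax(avg.len2)]))
    qual = _phred_from_prob(min(consulted))

    if z == 1:  # hom_alt
        if len(alts) > 1 or has_ref:
            conflict = True
        return VariantDecision(True, "1/1", (alts[0],), qual, conflict)
    if z == 2:  # het_alt
        if len(alts) > 1 or not has_ref:
            conflict = True
        return VariantDecision(True, "0/1", (alts[0],), qual, conflict)
    # het_multi
    if len(alts) >= 2:
        if has_ref:
            conflict = True
        return VariantDecision(True, "1/2", (alts[0], alts[1]), qual, conflict)
    return VariantDecision(True, "0/1", (alts[0],), qual, conflict=True)


# ---------------------------------------------------------------------------
# End-to-end calling


@dataclass
class CallerConfig:
    """Candidate-selection thresholds and ensemble composition."""

    min_alt_fraction: float = 0.125
    min_alt_reads: int = 4
    models: list = field(default_factory=lambda: [NaiveDiploidModel()])
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    qual_floor: float = 2.0

    def __post_init__(self) -> None:
        if self.min_alt_fraction <= 0 or self.min_alt_reads <= 0:
            raise ValueError("candidate thresholds must be positive")


_GENOTYPE_TUPLES = {"0/1": (0, 1), "1/1": (1, 1), "1/2": (1, 2)}


def _candidate_positions(
    reads: Sequence[AlignedRead],
    ref: ReferenceSequence,
    regions: Sequence[GenomicRegion],
    config: CallerConfig,
) -> list[int]:
    """Cheap array scan for positions worth a full pileup + model pass.

    Counts, per reference base, the pileup depth (match- or
    deletion-consuming reads) and the non-reference observations
    (mismatches, anchored insertions, deletion spans), then applies the
    allele-fraction and read-count thresholds inside the target regions.
    """
    n = len(ref)
    depth = np.zeros(n, dtype=np.int32)
    nonref = np.zeros(n, dtype=np.int32)
    ref_arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    for read in reads:
        p, q = read.pos, 0
        seq_arr = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        cigar = read.cigar
        for i, (op, ln) in enumerate(cigar):
            if op == "S":
                q += ln
            elif op == "M":
                depth[p : p + ln] += 1
                mism = np.nonzero(seq_arr[q : q + ln] != ref_arr[p : p + ln])[0]
                nonref[p + mism] += 1
                if i + 1 < len(cigar) and cigar[i + 1][0] == "I":
                    anchor = p + ln - 1
                    # the anchor observation becomes an insertion: count it
                    # as non-reference unless its base already mismatched
                    if seq_arr[q + ln - 1] == ref_arr[anchor]:
                        nonref[anchor] += 1
                p += ln
                q += ln
            elif op == "I":
                q += ln
            elif op == "D":
                depth[p : p + ln] += 1
                nonref[p : p + ln] += 1
                p += ln
    out: list[int] = []
    for region in regions:
        if region.chrom != ref.name:
            continue
        sl = slice(region.start, region.end)
        d = depth[sl]
        nr = nonref[sl]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(d > 0, nr / np.maximum(d, 1), 0.0)
        hits = np.nonzero(
            (nr >= config.min_alt_reads) & (frac >= config.min_alt_fraction)
        )[0]
        for h in hits:
            p0 = region.start + int(h)
            if ref.seq[p0] != "N":
                out.append(p0 + 1)
    return sorted(set(out))


def decision_to_record(
    decision: VariantDecision,
    column: PileupColumn,
    ref: ReferenceSequence,
    min_del_support: int = 1,
) -> VariantRecord | None:
    """Convert a variant decision at a column into a VCF record.

    SNVs and insertions are emitted at the column position; deletions are
    anchored one base to the left with the deleted reference bases in the
    REF allele.  A deletion allele is emitted only where at least
    ``min_del_support`` observed deletion events *of the realised length*
    start at this column: each deletion event therefore yields exactly
    one record, and spans interior to a longer deletion never re-emit it.
    """
    if not decision.is_variant:
        return None
    pos0 = column.pos - 1
    kept: list[tuple[str, str | int]] = []
    for kind, value in decision.alt_descriptors:
        if kind == "del":
            support = sum(
                1
                for o in column.observations
                if o.kind == "del" and o.event_start and int(o.allele) == int(value)
            )
            if support < min_del_support or column.pos == 1:
                continue
        kept.append((kind, value))
    if not kept:
        return None

    if any(k == "del" for k, _ in kept):
        # anchored representation: REF spans anchor + longest deletion
        max_del = max(int(v) for k, v in kept if k == "del")
        anchor0 = pos0 - 1
        ref_allele = ref.seq[anchor0 : pos0 + max_del]
        pos = column.pos - 1
        alts = []
        for kind, value in kept:
            if kind == "del":
                alts.append(ref.seq[anchor0] + ref.seq[pos0 + int(value) : pos0 + max_del])
            elif kind == "snv":
                alts.append(ref.seq[anchor0] + str(value) + ref.seq[pos0 + 1 : pos0 + max_del])
            else:  # insertion alongside a deletion at the same site
                alts.append(
                    ref.seq[anchor0] + column.ref_base + str(value) + ref.seq[pos0 + 1 : pos0 + max_del]
                )
    else:
        pos = column.pos
        ref_allele = column.ref_base
        alts = []
        for kind, value in kept:
            alts.append(str(value) if kind == "snv" else column.ref_base + str(value))

    genotype = _GENOTYPE_TUPLES.get(decision.genotype, (0, 1))
    if len(kept) == 1 and genotype == (1, 2):
        genotype = (0, 1)
    # duplicate alt alleles after realisation collapse to one
    uniq: list[str] = []
    for a in alts:
        if a not in uniq and a != ref_allele:
            uniq.append(a)
    if not uniq:
        return None
    if len(uniq) == 1 and genotype == (1, 2):
        genotype = (1, 1)
    flt = "TASK_CONFLICT" if decision.conflict else "PASS"
    return VariantRecord(
        chrom=column.chrom,
        pos=pos,
        ref=ref_allele,
        alts=tuple(uniq),
        genotype=genotype,
        qual=decision.qual,
        filter=flt,
    )


def call_targets(
    reads: Sequence[AlignedRead],
    ref: ReferenceSequence,
    regions: Sequence[GenomicRegion],
    models: Sequence[ProbabilityModel] | None = None,
    config: CallerConfig | None = None,
) -> list[VariantRecord]:
    """Run the full calling pipeline over the target regions.

    Per candidate column: alignment filter → pileup → depth-capped
    partitioning → every (partition × model) produces task
    probabilities → element-wise averaging → decision → VCF record.
    """
    config = config or CallerConfig()
    models = list(models) if models is not None else list(config.models)
    if not models:
        raise ValueError("call_targets requires at least one model")

    filtered = filter_alignments(reads, config.resample)
    candidates = _candidate_positions(filtered, ref, regions, config)
    if not candidates:
        return []
    columns = build_pileup(filtered, ref, candidates)

    records: list[VariantRecord] = []
    for column in columns:
        if not column.observations:
            logger.info(
                "no observations after filtering at %s:%d; skipped",
                column.chrom, column.pos,
            )
            continue
        parts = partition_column(column, config.resample)
        outputs = []
        for partition in parts.partitions:
            if not partition:
                continue
            for model in models:
                outputs.append(model(partition, column.ref_base))
        if not outputs:
            logger.info(
                "all partitions empty after quality filtering at %s:%d; skipped",
                column.chrom, column.pos,
            )
            continue
        avg = average_probabilities(outputs)
        decision = decide(avg, column.ref_base, column)
        record = decision_to_record(
            decision, column, ref, min_del_support=config.min_alt_reads
        )
        if record is not None:
            if record.qual < config.qual_floor and record.filter == "PASS":
                record.filter = "LowQual"
            records.append(record)
    records.sort(key=lambda r: r.sort_key())
    return records
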