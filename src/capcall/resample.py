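"""By-position depth-capped resampling of pileup evidence.

Target-enrichment long-read data has wildly uneven depth across captured
regions.  Rather than globally downsampling (which starves low-depth
regions), each pileup column whose depth exceeds a cap is split into up
to ``max_partitions`` depth-capped partitions that are called
independently and later combined by the ensemble.  Columns at or below
the cap pass through untouched — no base-quality filtering, no loss of
information.

Partitioning of a deep column:

1. observations below the base-quality cutoff are dropped;
2. if more observations remain than the partitions can hold, the
   highest-quality ones are retained (quality-preferential retention;
   ties broken by ascending read id for determinism);
3. the retained pool is shuffled with a seeded generator and chunked
   into partitions of exactly ``max_depth``;
4. a short last chunk is refilled by seeded sampling, without
   replacement, from pool observations not already in it — so a read may
   appear in two partitions only via this refill.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, ReferenceSequence

__all__ = [
    "ResampleConfig",
    "Observation",
    "PileupColumn",
    "ColumnPartitions",
    "filter_alignments",
    "build_pileup",
    "partition_column",
    "column_rng",
]


@dataclass(frozen=True)
class ResampleConfig:
    """Depth cap and filters of the by-position resampler.

    Defaults follow the benchmark settings of the workflow this package
    implements: cap 100×, at most 5 partitions, base-quality cutoff Q5,
    and only primary alignments with MAPQ ≥ 60 enter the pileup.
    """

    max_depth: int = 100
    max_partitions: int = 5
    base_q_cutoff: int = 5
    min_mapq: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.max_partitions < 1 or self.base_q_cutoff < 0:
            raise ValueError("invalid resample configuration")


@dataclass(frozen=True, slots=True)
class Observation:
    """One read's evidence at one reference position.

    ``kind`` is ``base`` (allele = the base), ``ins`` (allele = inserted
    sequence following this position) or ``del`` (allele = full deletion
    length in bases).  ``qual`` is the Phred of the supporting base: for
    insertions the minimum over inserted bases, for deletions the Phred
    of the preceding aligned base.  ``event_start`` is True except at the
    second and later bases of a deletion, letting the caller emit each
    deletion event exactly once.
    """

    read_id: str
    kind: str
    allele: str | int
    qual: int
    event_start: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("base", "ins", "del"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if self.kind == "del" and not isinstance(self.allele, int):
            raise ValueError("deletion allele must be an integer length")
        if self.kind != "del" and not isinstance(self.allele, str):
            raise ValueError("base/insertion allele must be a string")


@dataclass(slots=True)
class PileupColumn:
    """All retained-read observations covering one 1-based position."""

    chrom: str
    pos: int
    ref_base: str
    observations: list[Observation]

    def depth(self) -> int:
        return len(self.observations)

    def nonref_count(self) -> int:
        return sum(
            1
            for o in self.observations
            if not (o.kind == "base" and o.allele == self.ref_base)
        )


@dataclass(slots=True)
class ColumnPartitions:
    """Depth-capped partitions of one column's observations."""

    column: PileupColumn
    partitions: list[list[Observation]]


def filter_alignments(
    reads: Iterable[AlignedRead], config: ResampleConfig
) -> list[AlignedRead]:
    """Keep only primary alignments with MAPQ at or above the cutoff."""
    return [r for r in reads if r.is_primary and r.mapq >= config.min_mapq]


def build_pileup(
    reads: Iterable[AlignedRead],
    ref: ReferenceSequence,
    positions: Sequence[int],
) -> list[PileupColumn]:
    """Assemble pileup columns at the given 1-based positions.

    Per position, each read whose alignment consumes the reference base
    contributes exactly one observation.  An insertion immediately after
    a consumed base attaches to that base (kind ``ins``).  A read whose
    alignment deletes the base contributes a ``del`` observation carrying
    the full event length, flagged ``event_start`` at the first deleted
    base only.  Soft-clipped bases contribute nothing.
    """
    for pos in positions:
        if not 1 <= pos <= len(ref):
            raise ValueError(f"position {pos} outside reference {ref.name}")
    wanted = set(int(p) - 1 for p in positions)
    columns: dict[int, list[Observation]] = {p: [] for p in wanted}

    for read in reads:
        if read.chrom != ref.name:
            continue
        p = read.pos
        q = 0
        cigar = read.cigar
        for i, (op, n) in enumerate(cigar):
            if op == "S":
                q += n
            elif op == "M":
                next_is_ins = i + 1 < len(cigar) and cigar[i + 1][0] == "I"
                for k in range(n):
                    ref0 = p + k
                    if ref0 in wanted:
                        if next_is_ins and k == n - 1:
                            ins_len = cigar[i + 1][1]
                            ins_seq = read.seq[q + n : q + n + ins_len]
                            qual = min(read.base_quals[q + n : q + n + ins_len])
                            columns[ref0].append(
                                Observation(read.read_id, "ins", ins_seq, qual)
                            )
                        else:
                            columns[ref0].append(
                                Observation(
                                    read.read_id,
                                    "base",
                                    read.seq[q + k],
                                    read.base_quals[q + k],
                                )
                            )
                p += n
                q += n
            elif op == "I":
                q += n  # anchored by the preceding M walk (or unanchorable)
            elif op == "D":
                anchor_qual = read.base_quals[q - 1] if q > 0 else 0
                for j in range(n):
                    ref0 = p + j
                    if ref0 in wanted:
                        columns[ref0].append(
                            Observation(
                                read.read_id, "del", n, anchor_qual,
                                event_start=(j == 0),
                            )
                        )
                p += n
            else:  # pragma: no cover - io layer only emits M/I/D/S
                raise ValueError(f"unsupported CIGAR op {op!r}")

    out = []
    for pos in positions:
        p0 = int(pos) - 1
        out.append(
            PileupColumn(ref.name, int(pos), ref.seq[p0], columns[p0])
        )
    return out


def column_rng(config: ResampleConfig, chrom: str, pos: int) -> np.random.Generator:
    """Deterministic per-column generator derived from the global seed."""
    return np.random.default_rng(
        [config.seed, zlib.crc32(chrom.encode()), int(pos)]
    )


def partition_column(
    column: PileupColumn,
    config: ResampleConfig,
    rng: np.random.Generator | None = None,
) -> ColumnPartitions:
    """Split one column into depth-capped partitions (see module docstring).

    Columns at or below ``max_depth`` are passed through as a single
    partition identical to the input — the quality filter is *not*
    applied, preserving all evidence at low depth.  Deterministic for a
    fixed config seed (the per-column generator is derived from seed,
    chromosome and position unless ``rng`` is supplied).
    """
    obs = column.observations
    d = len(obs)
    if d == 0:
        raise ValueError(f"empty pileup column at {column.chrom}:{column.pos}")
    if d <= config.max_depth:
        return ColumnPartitions(column, [list(obs)])

    if rng is None:
        rng = column_rng(config, column.chrom, column.pos)

    pool = [o for o in obs if o.qual >= config.base_q_cutoff]
    d_prime = len(pool)
    if d_prime <= config.max_depth:
        return ColumnPartitions(column, [pool])

    cap = config.max_depth
    n_parts = min(config.max_partitions, -(-d_prime // cap))
    if d_prime > n_parts * cap:
        pool = sorted(pool, key=lambda o: (-o.qual, o.read_id))[: n_parts * cap]
    else:
        pool = sorted(pool, key=lambda o: (-o.qual, o.read_id))

    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]
    partitions = [shuffled[i * cap : (i + 1) * cap] for i in range(n_parts)]

    last = partitions[-1]
    short = cap - len(last)
    if short > 0:
        in_last = set(id(o) for o in last)
        remaining = [o for o in shuffled if id(o) not in in_last]
        picks = rng.choice(len(remaining), size=short, replace=False)
        last.extend(remaining[i] for i in picks)
    return ColumnPartitions(column, partitions)
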