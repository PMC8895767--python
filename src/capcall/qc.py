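"""Capture QC: depth profiles, threshold exceedance, uniformity, site coverage.

These are the panel-level quality metrics of a target-enrichment run:
per-base depth of coverage (DoC) over the target regions, the percentage
of target bases reaching fixed DoC thresholds, coverage uniformity,
coverage of annotated sites with a flank (e.g. splice sites ±10 bp),
zero-coverage regions with their GC content, and read-level length and
quality statistics (N50, mean length, mean read Phred, on-target rate).

Depth counts match-consuming bases only: deletion gaps and clipped bases
contribute nothing, mirroring the pileup semantics used for calling.
"""

from __future__ import annotations

import bisect
import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, GenomicRegion, ReferenceSequence

__all__ = [
    "CoverageProfile",
    "QCReport",
    "SiteCoverage",
    "compute_depth",
    "coverage_summary",
    "site_coverage",
    "uncovered_regions",
    "read_stats",
    "gc_content",
    "compute_n50",
    "qc_report",
]


@dataclass
class CoverageProfile:
    """Per-target-region integer depth arrays, one entry per reference base."""

    regions: list[GenomicRegion]
    depths: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.depths):
            raise ValueError("regions and depth arrays must be parallel")
        for r, d in zip(self.regions, self.depths):
            if len(d) != len(r):
                raise ValueError(f"depth array length {len(d)} != region {r}")

    def total_bases(self) -> int:
        return sum(len(d) for d in self.depths)

    def all_depths(self) -> np.ndarray:
        if not self.depths:
            return np.array([], dtype=int)
        return np.concatenate(self.depths)

    def depth_at(self, chrom: str, pos1: int) -> int | None:
        """Depth at a 1-based position, or None if unprofiled."""
        p0 = pos1 - 1
        for r, d in zip(self.regions, self.depths):
            if r.chrom == chrom and r.start <= p0 < r.end:
                return int(d[p0 - r.start])
        return None


@dataclass
class QCReport:
    mean_on_target_doc: float
    pct_at_thresholds: dict[int, float]
    uniformity: float
    on_target_rate: float
    n50: int
    mean_read_length: float
    mean_read_q: float
    pct_reads_ge_q10: float
    uncovered_region_count: int

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["pct_at_thresholds"] = {
            str(k): v for k, v in self.pct_at_thresholds.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class SiteCoverage:
    """Fraction of flanked site positions at/above a DoC threshold.

    Window positions falling outside the profiled target bases are counted
    as below threshold; their number is reported separately.
    """

    fraction: float
    n_positions: int
    n_unprofiled: int


def _match_intervals(read: AlignedRead) -> list[tuple[int, int]]:
    """Reference intervals consumed by match ops (0-based half-open)."""
    out = []
    p = read.pos
    for op, n in read.cigar:
        if op == "M":
            out.append((p, p + n))
            p += n
        elif op == "D":
            p += n
    return out


class _RegionIndex:
    """Per-chromosome sorted region lookup for interval-overlap queries."""

    def __init__(self, regions: Sequence[GenomicRegion]):
        self.by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, r in enumerate(regions):
            self.by_chrom.setdefault(r.chrom, []).append((r.start, r.end, idx))
        for rows in self.by_chrom.values():
            rows.sort()
        self.starts = {c: [row[0] for row in rows] for c, rows in self.by_chrom.items()}
        # longest region per chrom bounds how far left an overlap can start
        self.max_len = {
            c: max(e - s for s, e, _ in rows) for c, rows in self.by_chrom.items()
        }

    def overlapping(self, chrom: str, start: int, end: int):
        rows = self.by_chrom.get(chrom)
        if not rows:
            return
        starts = self.starts[chrom]
        lo = bisect.bisect_left(starts, start - self.max_len[chrom])
        hi = bisect.bisect_left(starts, end)
        for r_start, r_end, idx in rows[lo:hi]:
            if r_end > start:
                yield r_start, r_end, idx


def compute_depth(
    reads: Iterable[AlignedRead],
    regions: Sequence[GenomicRegion],
    min_mapq: int = 0,
    primary_only: bool = False,
) -> CoverageProfile:
    """Per-base depth over the target regions.

    A read contributes +1 at every reference position consumed by a match
    op; deletions and clips contribute nothing.  Reads failing the
    mapq/primary filters are excluded entirely.
    """
    depths = [np.zeros(len(r), dtype=np.int32) for r in regions]
    index = _RegionIndex(regions)
    known = set(index.by_chrom)
    for read in reads:
        if primary_only and not read.is_primary:
            continue
        if read.mapq < min_mapq:
            continue
        if known and read.chrom not in known:
            raise ValueError(f"read {read.read_id}: unknown chrom {read.chrom!r}")
        for m_start, m_end in _match_intervals(read):
            for r_start, r_end, idx in index.overlapping(read.chrom, m_start, m_end):
                lo = max(m_start, r_start) - r_start
                hi = min(m_end, r_end) - r_start
                if lo < hi:
                    depths[idx][lo:hi] += 1
    return CoverageProfile(list(regions), depths)


def coverage_summary(
    profile: CoverageProfile,
    thresholds: Sequence[int] = (30, 60, 100),
    uniformity_factor: float = 0.2,
) -> dict:
    """Mean on-target DoC, threshold exceedance and uniformity.

    Uniformity is the percentage of target bases with depth at least
    ``uniformity_factor`` × the mean on-target depth (0.2 by default, a
    common capture-uniformity definition).
    """
    depths = profile.all_depths()
    if depths.size == 0:
        raise ValueError("empty coverage profile")
    mean = float(depths.mean())
    pct = {int(t): float((depths >= t).mean() * 100.0) for t in thresholds}
    uniformity = float((depths >= uniformity_factor * mean).mean() * 100.0)
    return {
        "mean_on_target_doc": mean,
        "pct_at_thresholds": pct,
        "uniformity": uniformity,
    }


def site_coverage(
    profile: CoverageProfile,
    sites: Sequence[tuple[str, int]],
    flank: int = 0,
    threshold: int = 30,
) -> SiteCoverage:
    """Coverage of flanked annotated sites (1-based positions).

    Evaluates the union of ``[site - flank, site + flank]`` windows; a
    window position outside every profiled region counts as below the
    threshold and is tallied in ``n_unprofiled``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not sites:
        warnings.warn("site_coverage called with no sites; defined as 1.0")
        return SiteCoverage(1.0, 0, 0)
    window_positions: set[tuple[str, int]] = set()
    for chrom, pos in sites:
        for p in range(pos - flank, pos + flank + 1):
            if p >= 1:
                window_positions.add((chrom, p))
    n_ok = 0
    n_unprofiled = 0
    for chrom, pos in window_positions:
        d = profile.depth_at(chrom, pos)
        if d is None:
            n_unprofiled += 1
        elif d >= threshold:
            n_ok += 1
    n = len(window_positions)
    return SiteCoverage(n_ok / n, n, n_unprofiled)


def uncovered_regions(
    reads: Iterable[AlignedRead],
    regions: Sequence[GenomicRegion],
    min_reads: int = 1,
) -> list[GenomicRegion]:
    """Target regions overlapped by fewer than ``min_reads`` distinct reads.

    A read overlaps a region when at least one of its match-consumed bases
    falls inside it.  With ``min_reads=1`` this is exactly "no read
    covered the region".
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    index = _RegionIndex(regions)
    counts: list[set[str]] = [set() for _ in regions]
    for read in reads:
        for m_start, m_end in _match_intervals(read):
            for _, _, idx in index.overlapping(read.chrom, m_start, m_end):
                counts[idx].add(read.read_id)
    return [r for r, ids in zip(regions, counts) if len(ids) < min_reads]


def _read_mean_phred(read: AlignedRead) -> float:
    """Per-read quality: mean error probability converted back to Phred."""
    q = np.asarray(read.base_quals, dtype=float)
    err = np.power(10.0, -q / 10.0).mean()
    return float(-10.0 * np.log10(err))


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that reads of length >= L contain >= half of all bases."""
    if len(lengths) == 0:
        raise ValueError("no reads")
    ordered = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(ordered)
    half = csum[-1] / 2.0
    idx = int(np.searchsorted(csum, half))
    return int(ordered[idx])


def read_stats(
    reads: Sequence[AlignedRead], regions: Sequence[GenomicRegion]
) -> dict:
    """Read-level N50, mean length, mean read quality and on-target rate."""
    if not reads:
        raise ValueError("read_stats requires at least one read")
    lengths = [len(r.seq) for r in reads]
    qs = np.array([_read_mean_phred(r) for r in reads])
    index = _RegionIndex(regions)
    aligned = 0
    on_target = 0
    for read in reads:
        for m_start, m_end in _match_intervals(read):
            aligned += m_end - m_start
            for r_start, r_end, _ in index.overlapping(read.chrom, m_start, m_end):
                on_target += min(m_end, r_end) - max(m_start, r_start)
    return {
        "n50": compute_n50(lengths),
        "mean_read_length": float(np.mean(lengths)),
        "mean_read_q": float(qs.mean()),
        "pct_reads_ge_q10": float((qs >= 10.0).mean() * 100.0),
        "on_target_rate": 100.0 * on_target / aligned if aligned else 0.0,
    }


def gc_content(ref: ReferenceSequence, region: GenomicRegion) -> float | None:
    """(G+C)/(A+C+G+T) over the region; N excluded; None if all-N."""
    if region.end > len(ref):
        raise ValueError(f"region {region} extends past reference {ref.name}")
    sub = ref.seq[region.start : region.end]
    acgt = sum(sub.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (sub.count("G") + sub.count("C")) / acgt


def qc_report(
    reads: Sequence[AlignedRead],
    regions: Sequence[GenomicRegion],
    thresholds: Sequence[int] = (30, 60, 100),
    min_mapq: int = 0,
    primary_only: bool = False,
    uniformity_factor: float = 0.2,
) -> tuple[QCReport, CoverageProfile]:
    """Assemble the full panel QC report from reads and target regions."""
    profile = compute_depth(reads, regions, min_mapq=min_mapq,
                            primary_only=primary_only)
    cov = coverage_summary(profile, thresholds, uniformity_factor)
    stats = read_stats(reads, regions)
    uncovered = uncovered_regions(reads, regions, min_reads=1)
    report = QCReport(
        mean_on_target_doc=cov["mean_on_target_doc"],
        pct_at_thresholds=cov["pct_at_thresholds"],
        uniformity=cov["uniformity"],
        on_target_rate=stats["on_target_rate"],
        n50=stats["n50"],
        mean_read_length=stats["mean_read_length"],
        mean_read_q=stats["mean_read_q"],
        pct_reads_ge_q10=stats["pct_reads_ge_q10"],
        uncovered_region_count=len(uncovered),
    )
    return report, profile
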