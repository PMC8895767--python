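"""Shared fixtures: small deterministic synthetic datasets and helpers."""

import numpy as np
import pytest

from capcall import (
    AlignedRead,
    GenomicRegion,
    ReferenceSequence,
    SimulationConfig,
    simulate_dataset,
)
from capcall.resample import Observation, PileupColumn


@pytest.fixture(scope="session")
def small_dataset():
    """A compact capture run: 20 kb reference, 20 targets, planted variants."""
    cfg = SimulationConfig(
        ref_length=20_000,
        n_regions=20,
        mean_depth=60,
        n_snvs=15,
        n_indels=5,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free homozygous-reference data: reads must match the reference."""
    cfg = SimulationConfig(
        ref_length=10_000,
        n_regions=8,
        mean_depth=30,
        sub_error_rate=0.0,
        indel_error_rate=0.0,
        snv_rate=0.0,
        indel_rate=0.0,
        n_snvs=0,
        n_indels=0,
        seed=7,
    )
    return simulate_dataset(cfg)


def make_read(
    read_id="r1",
    chrom="chr1",
    pos=0,
    cigar=None,
    seq="ACGT",
    quals=None,
    mapq=60,
    is_primary=True,
):
    cigar = cigar if cigar is not None else [("M", len(seq))]
    quals = quals if quals is not None else [20] * len(seq)
    return AlignedRead(read_id, chrom, pos, cigar, seq, quals, mapq, is_primary)


def make_column(
    base_counts: dict[str, int],
    ref_base: str = "A",
    qual: int = 20,
    chrom: str = "chr1",
    pos: int = 100,
    ins: list[tuple[str, int]] = (),
    dels: list[tuple[int, int]] = (),
) -> PileupColumn:
    """Build a pileup column from allele counts.

    ``ins`` holds (sequence, count) insertion observations and ``dels``
    (length, count) deletion observations, all marked event-start.
    """
    obs = []
    i = 0
    for base, count in base_counts.items():
        for _ in range(count):
            obs.append(Observation(f"rd{i:05d}", "base", base, qual))
            i += 1
    for seq, count in ins:
        for _ in range(count):
            obs.append(Observation(f"rd{i:05d}", "ins", seq, qual))
            i += 1
    for length, count in dels:
        for _ in range(count):
            obs.append(Observation(f"rd{i:05d}", "del", length, qual))
            i += 1
    return PileupColumn(chrom, pos, ref_base, obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
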