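"""End-to-end orchestration: simulate → qc → call → benchmark.

One global seed deterministically derives per-stage seeds, so an
identical configuration reproduces every artifact byte-for-byte (except
timestamps, which only appear in the run manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .benchmark import compare
from .ensemble import CallerConfig, NaiveDiploidModel, call_targets
from .io import read_vcf, write_vcf
from .qc import qc_report
from .resample import ResampleConfig
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


def _stage_seed(seed: int, stage: int) -> int:
    # distinct deterministic per-stage seeds, kept below 2**31
    return (seed * 1_000_003 + stage * 7919) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one full run needs; all stages share one global seed."""

    outdir: str = "capcall_run"
    seed: int = 0
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    n_models: int = 2

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.simulation, seed=_stage_seed(seed, 1))
        res = dataclasses.replace(self.resample, seed=_stage_seed(seed, 2))
        caller = dataclasses.replace(self.caller, resample=res)
        return dataclasses.replace(
            self, seed=seed, simulation=sim, resample=res, caller=caller
        )


def default_models(n: int = 2) -> list[NaiveDiploidModel]:
    """An ensemble of likelihood models with staggered priors.

    Mimics the multiple-trained-model slots of the original scheme: each
    member differs in its error-rate floor and heterozygous prior, so
    averaging genuinely combines distinct opinions.
    """
    slots = [
        NaiveDiploidModel(0.01, 0.5, "naive"),
        NaiveDiploidModel(0.02, 0.4, "naive:alt-prior"),
        NaiveDiploidModel(0.005, 0.5, "naive:low-floor"),
        NaiveDiploidModel(0.01, 0.3, "naive:hom-lean"),
    ]
    if not 1 <= n <= len(slots):
        raise ValueError(f"n must be between 1 and {len(slots)}")
    return slots[:n]


def run_all(config: PipelineConfig) -> Path:
    """Run every stage, writing artifacts and a run manifest to outdir."""
    config = config.with_seed(config.seed)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        ds = simulate_dataset(config.simulation, out)
        contigs = {ds.reference.name: len(ds.reference)}

        stage = "qc"
        report, _profile = qc_report(
            ds.reads, ds.regions,
            min_mapq=config.resample.min_mapq, primary_only=True,
        )
        report.to_json(out / "qc_report.json")

        stage = "call"
        models = default_models(config.n_models)
        records = call_targets(
            ds.reads, ds.reference, ds.regions, models, config.caller
        )
        echo = (
            f"##capcall_config=seed:{config.seed},max_depth:"
            f"{config.resample.max_depth},max_partitions:"
            f"{config.resample.max_partitions},base_q_cutoff:"
            f"{config.resample.base_q_cutoff},min_mapq:"
            f"{config.resample.min_mapq},models:"
            f"{'+'.join(m.identifier for m in models)}"
        )
        write_vcf(records, out / "calls.vcf", contigs,
                  extra_header_lines=[echo])

        stage = "benchmark"
        result = compare(
            ds.truth.records,
            read_vcf(out / "calls.vcf"),
            confident_regions=ds.regions,
            target_regions=ds.regions,
            ref=ds.reference,
        )
        result.to_json(out / "benchmark.json")
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"simulate": config.simulation.seed,
                        "resample": config.resample.seed},
        "simulation": dataclasses.asdict(config.simulation),
        "resample": dataclasses.asdict(config.resample),
        "caller": {
            "min_alt_fraction": config.caller.min_alt_fraction,
            "min_alt_reads": config.caller.min_alt_reads,
            "qual_floor": config.caller.qual_floor,
            "models": [m.identifier for m in default_models(config.n_models)],
        },
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
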