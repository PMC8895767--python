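"""Simulate a small target-capture nanopore-like dataset.

Generates a reference, a capture panel (BED), two haplotypes with planted
SNVs and indels, and error-bearing aligned reads, then writes all
artifacts to ./example_run and prints a summary.
"""

from pathlib import Path

from capcall import SimulationConfig, simulate_dataset

config = SimulationConfig(
    ref_length=50_000,   # 50 kb reference
    n_regions=40,        # 40 capture targets, ~164 bp each
    mean_depth=80,       # mean target depth before capture bias
    n_snvs=25,           # exact planted variant counts
    n_indels=8,
    seed=7,
)

outdir = Path("example_run")
dataset = simulate_dataset(config, outdir)

print(f"reference: {dataset.reference.name}, {len(dataset.reference):,} bp")
print(f"targets:   {len(dataset.regions)} regions, "
      f"{sum(len(r) for r in dataset.regions):,} bp total")
print(f"reads:     {len(dataset.reads):,}")
print(f"truth:     {len(dataset.truth)} variants "
      f"({sum(1 for v in dataset.truth.records if not v.is_indel)} SNVs, "
      f"{sum(1 for v in dataset.truth.records if v.is_indel)} indels)")
print("\nfirst five truth records:")
for rec in dataset.truth.records[:5]:
    gt = "/".join(map(str, rec.genotype))
    print(f"  {rec.chrom}:{rec.pos} {rec.ref}>{','.join(rec.alts)} GT={gt}")
print(f"\nartifacts written to {outdir}/:",
      ", ".join(sorted(p.name for p in outdir.iterdir())))
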