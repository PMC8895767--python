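"""Coverage and read-quality QC for a capture run.

Simulates a run in memory, then computes the panel QC report: mean
on-target depth of coverage, threshold exceedance, uniformity, read N50
and quality, plus per-site coverage of annotated positions with flanks.
"""

from capcall import SimulationConfig, simulate_dataset
from capcall.qc import qc_report, site_coverage, uncovered_regions

dataset = simulate_dataset(SimulationConfig(
    ref_length=50_000, n_regions=40, mean_depth=80,
    n_snvs=25, n_indels=8, seed=7,
))

report, profile = qc_report(
    dataset.reads, dataset.regions,
    thresholds=(30, 60, 100), min_mapq=60, primary_only=True,
)

print(f"mean on-target DoC: {report.mean_on_target_doc:.1f}x")
for t, pct in report.pct_at_thresholds.items():
    print(f"  bases >= {t}x: {pct:.1f}%")
print(f"uniformity (>= 0.2x mean): {report.uniformity:.1f}%")
print(f"on-target rate: {report.on_target_rate:.1f}%")
print(f"read N50: {report.n50} bp, mean length "
      f"{report.mean_read_length:.0f} bp")
print(f"mean read quality: Q{report.mean_read_q:.1f} "
      f"({report.pct_reads_ge_q10:.1f}% of reads >= Q10)")

# coverage of specific annotated sites with +-10 bp flanks
sites = [(r.chrom, r.pos) for r in dataset.truth.records[:10]]
sc = site_coverage(profile, sites, flank=10, threshold=30)
print(f"\n{len(sites)} annotated sites (+-10 bp): "
      f"{100 * sc.fraction:.1f}% of {sc.n_positions} positions >= 30x")

dropped = uncovered_regions(dataset.reads, dataset.regions)
print(f"target regions with zero overlapping reads: {len(dropped)}")
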