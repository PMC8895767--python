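# capcall

Ensemble variant calling and QC for uneven-depth long-read
target-enrichment (capture) sequencing, with by-position depth-capped
resampling and a built-in capture simulator.

## The problem

Target-enrichment (capture) panels sequenced on long-read platforms
produce coverage that is extremely uneven: hybridization and PCR
efficiency vary per region (often modelled as a log-normal multiplier),
so one exon may sit at 500× while its neighbour barely reaches 30×.
Globally downsampling such data to tame the deep columns starves the
shallow ones; calling at full depth makes deep columns both slow and
statistically mismatched to callers tuned for ~100×.

`capcall` implements a per-position alternative:

1. **By-position depth-capped resampling** — every pileup column at or
   below 100× passes through untouched. Deeper columns are split into up
   to 5 partitions of exactly 100 observations each (quality-filtered at
   Q5, quality-preferentially retained, seeded shuffle, short last
   partition refilled without replacement).
2. **Ensemble calling** — each (partition × model) produces four task
   distributions: a 21-class genotype (`gt21`), zygosity
   (hom-ref/hom-alt/het-alt/het-multi), and two indel-length bins. The
   ensemble averages the probabilities element-wise across all
   partitions and models, then a single decision step turns the averaged
   distributions into a VCF record (with a `TASK_CONFLICT` filter flag
   when the tasks disagree).
3. **Panel QC** — mean on-target depth of coverage, threshold
   exceedance, 0.2×-mean uniformity, flanked site coverage, read N50 /
   quality stats, zero-coverage region detection.
4. **Benchmarking** — vt-style normalization (left-align, trim),
   multi-allelic decomposition, genotype-aware exact matching, SNP/INDEL
   strata.
5. **Simulator** — a capture-data generator (log-normal capture bias,
   ~1 kb reads, configurable substitution/indel error, planted diploid
   truth variants) so every stage is testable without real sequencing
   data.

All randomness is seeded and reproducible: same config ⇒ byte-identical
SAM/VCF/JSON artifacts.

## Worked example

```python
from capcall import SimulationConfig, simulate_dataset
from capcall.benchmark import compare
from capcall.ensemble import call_targets
from capcall.pipeline import default_models

dataset = simulate_dataset(SimulationConfig(
    ref_length=50_000, n_regions=40, mean_depth=80,
    n_snvs=25, n_indels=8, seed=7,
))

records = call_targets(dataset.reads, dataset.reference, dataset.regions,
                       models=default_models(2))
result = compare(dataset.truth.records, records,
                 confident_regions=dataset.regions,
                 target_regions=dataset.regions, ref=dataset.reference)
```

Running this (it is `examples/04_call_and_benchmark.py`) prints:

```
33 variants called; first five:
  chr1:1220 A>ACTGCG GT=0/1 QUAL=99.0 PASS
  chr1:1570 C>CCACACCCCTT GT=1/1 QUAL=96.7 PASS
  chr1:1997 A>C GT=1/1 QUAL=99.0 PASS
  chr1:6458 G>T GT=1/1 QUAL=99.0 PASS
  chr1:6555 T>C GT=0/1 QUAL=99.0 PASS
SNP      TP= 25 FP=  0 FN=  0  precision=1.000 recall=1.000 F1=1.000
INDEL    TP=  8 FP=  0 FN=  0  precision=1.000 recall=1.000 F1=1.000
overall  TP= 33 FP=  0 FN=  0  precision=1.000 recall=1.000 F1=1.000
```

The QC view of the same dataset (`examples/02_coverage_qc.py`):

```
mean on-target DoC: 126.1x
  bases >= 30x: 97.3%
  bases >= 60x: 84.6%
  bases >= 100x: 60.6%
uniformity (>= 0.2x mean): 97.3%
read N50: 1034 bp, mean length 997 bp
mean read quality: Q10.6 (57.4% of reads >= Q10)
```

More narrative scripts live in `examples/`: simulation
(`01_simulate_dataset.py`), QC (`02_coverage_qc.py`), resampling one
deep column (`03_resample_deep_column.py`), calling + benchmarking
(`04_call_and_benchmark.py`), and plugging a custom probability model
into the ensemble (`05_custom_model.py`).

## Command line

A thin CLI wraps the library:

```bash
capcall simulate  --seed 3 --out run/ --ref-length 200000 --n-regions 300
capcall qc        --bam run/reads.sam --bed run/targets.bed \
                  --ref run/reference.fasta --out qc.json
capcall resample  --bam run/reads.sam --bed run/targets.bed \
                  --ref run/reference.fasta --out partitions.tsv
capcall call      --bam run/reads.sam --ref run/reference.fasta \
                  --bed run/targets.bed --models 2 --out calls.vcf
capcall benchmark --truth run/truth.vcf --calls calls.vcf \
                  --bed run/targets.bed --ref run/reference.fasta \
                  --out bench.json
capcall run-all   --seed 3 --out run/        # all of the above
```

Exit codes: 0 success, 2 usage error, 1 stage failure. A flat
`key=value` config file can be passed with `--config`.

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/                       # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script simulates the standard fixture (200 kb reference,
300 regions, 300 SNVs + 50 indels at 120× with 5%/2% errors), runs QC,
calling and benchmarking, plus resampling-concordance and
partition-conservation experiments, and writes every headline quantity
as `{"name": {"value": ..., "n": ...}}`. All randomness derives from
`--seed`; ~1 minute on one CPU.

## Layout

- `src/capcall/io.py` — BED/FASTA/FASTQ/SAM/VCF readers and writers,
  core record types
- `src/capcall/simulate.py` — capture-data simulator with planted truth
- `src/capcall/qc.py` — coverage and read QC
- `src/capcall/resample.py` — pileup assembly and by-position
  depth-capped partitioning
- `src/capcall/ensemble.py` — probability models, averaging, decision
  logic, the caller
- `src/capcall/benchmark.py` — normalization and truth comparison
- `src/capcall/pipeline.py`, `src/capcall/cli.py` — orchestration and
  the `capcall` command
- `docs/methods.md` — model, assumptions and numerical choices
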