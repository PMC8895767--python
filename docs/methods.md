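# Methods

This note documents the statistical model, the algorithmic contracts and
the numerical choices behind `capcall`. It states what the code
computes; empirical performance claims are confined to what the test
suite and `scripts/acceptance.py` actually measure.

## Data model

- Genomic intervals are 0-based half-open (`GenomicRegion`); variant
  records are 1-based (`VariantRecord`), following BED and VCF
  conventions respectively.
- Alignments carry explicit CIGARs over the ops M/I/D/S. `M` denotes
  alignment consumption of both read and reference (match or mismatch);
  hard clips are dropped on input, `=`/`X` are normalized to `M`.
- A pileup column at one reference position holds one `Observation` per
  covering read: a base, an insertion (attached to the *anchor*, the
  last consumed base before the inserted sequence), or a deletion.
  Deletion observations appear at **every** deleted base and carry the
  full event length; `event_start` is true only at the first deleted
  base. The quality of an insertion observation is the minimum over the
  inserted bases; a deletion inherits the Phred of the preceding aligned
  base.

## By-position depth-capped resampling

Columns with depth d ≤ `max_depth` (default 100) pass through as a
single partition, untouched — the base-quality filter is *not* applied
at low depth, so no evidence is lost where coverage is scarce. For
d > `max_depth`:

1. observations with quality < `base_q_cutoff` (Q5) are dropped, giving
   a pool of size d′;
2. if d′ still exceeds the cap, n = min(`max_partitions`, ⌈d′/cap⌉)
   partitions are formed; when d′ > n·cap, the n·cap highest-quality
   observations are retained (ties broken by ascending read id, for
   determinism);
3. the retained pool is shuffled by a per-column seeded generator and
   chunked into n partitions of exactly `cap`;
4. a short final chunk is refilled by seeded sampling *without
   replacement* from pool observations not already in it, so an
   observation can appear at most twice overall and at most once per
   partition.

Distinct-read conservation: the union of the partitions contains exactly
min(d′, n·cap) distinct reads. The per-column generator is seeded with
(global seed, CRC32(chrom), position), making every column reproducible
independently of iteration order.

Alignment admission follows the panel convention: primary alignments
with MAPQ ≥ 60 only.

## Task distributions and the ensemble

Each (partition × model) produces four distributions
(`TaskProbabilities`):

- **gt21** — 21 unordered diploid genotype classes over the four bases
  plus insertion (`I`) and deletion (`D`) pseudo-alleles;
- **zygosity** — hom-ref, hom-alt, het-alt (one reference allele),
  het-multi (two distinct non-reference alleles);
- **len1/len2** — 33 length-change bins each ({≤−16, −15…−1, 0, +1…+15,
  ≥+16}); len1 is the smaller of the two allele length changes.

The ensemble is the element-wise arithmetic mean of all outputs.
Numerically, the addends of each element are sorted before summation and
the mean is computed as `base + mean(deviations from the smallest
addend)`; this makes the average *exactly* invariant to input order and
*exactly* idempotent on identical inputs, at a cost of at most ~1 ulp
versus a plain mean.

### The naive diploid likelihood model

The bundled model is a classical genotype likelihood, not a trained
network. Its allele universe is the four bases plus every indel allele
observed in the partition (including all four bases keeps the hom-ref
posterior non-degenerate and analytically checkable). For genotype
g = {a₁, a₂}, each observation contributes
½·p(obs|a₁) + ½·p(obs|a₂), with p(obs|a) = 1 − ε on a match and ε/3
otherwise, where ε = min(0.75, max(10^(−q/10), `error_rate_prior`)).
The floor (default 0.01) guards against overconfident basecalls; the
0.75 ceiling keeps likelihoods proper. A prior places `het_prior`
(default 0.5) total mass uniformly over heterozygous genotypes and the
rest uniformly over homozygous ones. Posteriors are normalized with
log-sum-exp and marginalized onto the four tasks. `default_models(n)`
provides up to four such models with staggered priors so averaging
combines genuinely different opinions.

With n clean Q20 reference observations the hom-ref zygosity posterior
has the closed form

  P(hom-ref) = π_hom·(1−ε)ⁿ / [π_hom·(1−ε)ⁿ + 3·π_het·((1−ε)/2 + ε/6)ⁿ
               + 3·(π_hom + π_het)·(ε/3)ⁿ]

with π_hom = 0.5/4, π_het = 0.5/6, ε = 0.01 — acceptance criterion 4
verifies the implementation against this to 1e−9.

## Decision logic

Averaged distributions are turned into at most one record per column:

1. zygosity argmax hom-ref ⇒ no variant;
2. otherwise the gt21 argmax fixes the allele-symbol pair (zygosity wins
   on variant-vs-not, gt21 on allele identity);
3. `I`/`D` symbols are realized as the most frequent observed
   insertion/deletion of the length indicated by the len1/len2 argmaxes
   (falling back to the most frequent of any length, flagged
   `TASK_CONFLICT`);
4. if the top class yields no realizable alternate allele, the next-best
   class that does is used (flagged);
5. genotype from zygosity: hom-alt → 1/1, het-alt → 0/1, het-multi →
   1/2, downgraded with a flag when fewer distinct alternates exist;
6. QUAL = −10·log₁₀(1 − min consulted argmax probability), capped at 99;
   the length tasks are consulted only when an indel allele is involved.

Candidate columns are pre-selected by a cheap array scan (≥ 4
non-reference observations and ≥ 12.5% non-reference fraction), so the
full pileup/model machinery runs only where a variant is plausible.

Deletion records are anchored one base to the left (standard VCF
anchoring). Because interior bases of a deletion also carry
observations, a deletion allele is emitted only at columns where at
least `min_alt_reads` deletion events *of the realized length start*
(the `event_start` flag); this yields exactly one record per event.

## Simulator scope

The generator emulates capture sequencing well enough to exercise every
downstream stage, and no further:

- reference: i.i.d. bases at a configurable GC fraction;
- panel: Gamma-distributed region lengths (shape 4, mean 164 bp,
  minimum 50 bp) packed uniformly at random without overlap;
- truth: SNVs and 1–10 bp indels planted at ≥ 12 bp spacing inside
  regions, het with probability `het_fraction`, het variants assigned to
  a random haplotype; counts either Poisson(rate × covered bases) or
  exact (`n_snvs`/`n_indels`);
- reads: per-region depth = `mean_depth` × LogNormal(0, σ) capture-bias
  multiplier; read count Poisson, fragment midpoints uniform over the
  region extended by half a read length per side, lengths
  Normal(1000, 200) truncated at 50; reads are emitted **pre-aligned**
  at their true positions — there is no alignment step, and mapping
  error is out of scope;
- errors: substitutions then 1 bp indels, i.i.d. per base at the
  configured rates; quality strings are drawn independently of the
  planted errors (mean read Phred ~ Normal(mean, 3) truncated at ≥ 3,
  per-base jitter sd 2, clipped to [3, 40]), i.e. qualities are
  *uncalibrated*, as with real basecallers, except that the likelihood
  floor absorbs the mismatch.

Not modelled: reference context effects (homopolymer error bias),
chimeras, strand effects, mapping ambiguity, structural variants.

## Benchmarking

Both truth and calls are decomposed into bi-allelic records, normalized
(shared-suffix truncation with left extension, then shared-prefix
trimming — the standard vt-normalize algorithm, which also left-aligns
indels), filtered to the confident ∩ target regions, and matched exactly
on (chrom, pos, ref, alt, unordered genotype). Strata: a record is
INDEL if any allele length differs from the REF length, else SNP.
Zero-denominator metrics are reported as 0 with an explicit flag.

## Determinism

Every stochastic component takes a `numpy.random.default_rng` seed
sequence derived from one global seed: simulation stages use
`[seed, stage]`, resampling uses `[seed, crc32(chrom), pos]`, and the
pipeline derives per-stage seeds as `(seed·1000003 + stage·7919) mod
2³¹`. Identical configurations therefore reproduce byte-identical
artifacts (the run manifest's timestamp aside).

## Limitations

- The bundled probability models are likelihood heuristics, not trained
  classifiers; ensemble benefits shown on simulated data say nothing
  about real-data accuracy.
- Qualities being uncalibrated in simulation means QUAL values are
  rank-informative, not calibrated phred-scaled error probabilities.
- One record per column: overlapping events at one position beyond a
  diploid pair (or nested indels) are reduced to at most two alternates.
- The benchmark is exact-match; partial-credit schemes (distance-based
  matching of near-miss indels) are out of scope.
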