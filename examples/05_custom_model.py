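"""Plug a custom probability model into the ensemble.

Any callable with an ``identifier`` that maps (partition, ref_base) to
TaskProbabilities can join the ensemble.  Here a crude frequency-counting
model is averaged with the default likelihood model; the ensemble simply
averages all (partition x model) outputs before deciding.
"""

import numpy as np

from capcall import SimulationConfig, simulate_dataset
from capcall.ensemble import (
    GT21_INDEX,
    N_LENGTH_BINS,
    TaskProbabilities,
    ZYGOSITY_CLASSES,
    call_targets,
    gt21_class,
    length_to_bin,
)
from capcall.pipeline import default_models


class FrequencyModel:
    """Allele-frequency heuristic: top two alleles define the genotype."""

    identifier = "frequency"

    def __call__(self, partition, ref_base):
        counts = {}
        for o in partition:
            sym = o.allele if o.kind == "base" else ("I" if o.kind == "ins" else "D")
            counts[sym] = counts.get(sym, 0) + 1
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
        a1 = ranked[0]
        a2 = a1 if len(ranked) < 2 or counts[ranked[1]] / len(partition) < 0.25 else ranked[1]

        gt21 = np.full(21, 0.01 / 20)
        gt21[GT21_INDEX[gt21_class(a1, a2)]] = 0.99
        zyg = np.full(4, 0.01 / 3)
        if a1 == a2:
            zyg[0 if a1 == ref_base else 1] = 0.99
        else:
            zyg[2 if ref_base in (a1, a2) else 3] = 0.99
        len1 = np.full(N_LENGTH_BINS, 0.01 / (N_LENGTH_BINS - 1))
        len2 = len1.copy()
        len1[length_to_bin(0)] = 0.99
        len2[length_to_bin(0)] = 0.99
        return TaskProbabilities(gt21, zyg, len1, len2)


dataset = simulate_dataset(SimulationConfig(
    ref_length=30_000, n_regions=25, mean_depth=80,
    n_snvs=15, n_indels=0, seed=19,
))

ensemble = [default_models(1)[0], FrequencyModel()]
records = call_targets(dataset.reads, dataset.reference, dataset.regions,
                       models=ensemble)
truth_keys = {(r.pos, r.alts) for r in dataset.truth.records}
hits = sum(1 for r in records if (r.pos, r.alts) in truth_keys)
print(f"ensemble of {[m.identifier for m in ensemble]}")
print(f"called {len(records)} variants, {hits} match planted truth "
      f"of {len(dataset.truth)}")
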