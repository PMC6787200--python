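"""GC composition of nucleolar vs speckle interchromosomal hubs.

Synthesizes a genome, assigns 100 kb bins to the two hub types with a
5-GC-point speckle-vs-nucleolar shift (the kind of contrast seen in
split-pool interaction data), and tests the difference with Student's
t-test.
"""

import numpy as np

from tadgc import SyntheticConfig, hub_gc_comparison, synthesize_genome, windowed_gc
from tadgc.synth import synthesize_hub_labels

config = SyntheticConfig(n_chroms=4, n_tads=200, seed=7)
genome, _ = synthesize_genome(config)

gc_track = windowed_gc(genome, resolution=100_000)
hubs, gamma = synthesize_hub_labels(gc_track, hub_gc_shift=5.0, rng=np.random.default_rng(7))

comp = hub_gc_comparison(hubs, gc_track, test="student")

print(comp.summaries[["min", "q1", "median", "q3", "max", "mean", "n"]].round(2))
print(
    f"\nspeckle - nucleolar mean GC = {comp.mean_difference:.2f} points, "
    f"t = {comp.t_statistic:.1f}, p = {comp.p_value:.2e}"
)
print(
    "\nSpeckle-hub bins are GC-richer than nucleolar-hub bins: sequence"
    "\ncomposition tracks which nuclear body a region aggregates around."
)
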