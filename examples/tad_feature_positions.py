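"""Where genes and regulatory elements sit inside TADs, and who expresses them.

Synthesizes TADs with class-dependent feature placement, indexes each
fully contained feature on the 0-1 TAD scale, summarizes border vs
centre occupancy for valley-class TADs, and stratifies genes into
housekeeping / tissue-specific classes with the Tau index.
"""

import numpy as np

from tadgc import (
    GenomicInterval,
    SyntheticConfig,
    positional_density,
    relative_positions,
    stratify_genes,
    synthesize_genome,
)
from tadgc.synth import synthesize_features_and_expression

config = SyntheticConfig(n_chroms=2, n_tads=80, seed=7)
genome, tads = synthesize_genome(config)
feature_sets, expression, gene_truth = synthesize_features_and_expression(
    tads, config, np.random.default_rng(7)
)

tad_list = [
    (r.tad_id, GenomicInterval(r.chrom, r.start, r.end))
    for r in tads.itertuples(index=False)
]
res = relative_positions(tad_list, feature_sets["gene"])
print(
    f"genes: {res.n_assigned} assigned, {res.n_boundary_dropped} dropped for "
    f"crossing a TAD border, {res.n_outside} outside all TADs"
)

valley_ids = set(tads.loc[tads["true_class"].isin(["C", "C-"]), "tad_id"])
valley = res.records[res.records["tad_id"].isin(valley_ids)]
dens = positional_density(valley["rel_pos"])
border = valley["band"].eq("border").mean()
print(f"valley-class TADs: {border:.0%} of genes in the border bands (0-0.2, 0.8-1)")
if dens.marker_75 is not None:
    print(f"kernel density at the 75% position: {dens.marker_75:.2f}")

classes = stratify_genes(expression)
print("\nexpression classes:", classes["expression_class"].value_counts().to_dict())
print(classes.head(3).round(3).to_string(index=False))
print(
    "\nTau = 0 means uniform expression across the 27 tissues (housekeeping,"
    "\nTau < 0.3); Tau = 1 means single-tissue expression (tissue-specific,"
    "\nTau > 0.8). Valley-class TADs concentrate genes at their GC-rich borders."
)
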