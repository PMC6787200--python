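# tadgc

Sequence-composition analysis of chromatin architecture, for genomicists
studying how DNA base composition shapes topologically associating
domains (TADs), chromatin loops and interchromosomal nuclear hubs.

Mammalian interphase chromatin is a mosaic of GC-rich and GC-poor
domains, and interchromosomal contacts are strongly composition-biased:
GC-rich regions aggregate around nuclear speckles, GC-poor regions
around the nucleolus and lamina. `tadgc` implements the quantitative
toolkit behind that observation:

- **Windowed GC% tracks** over a genome at fixed resolution, with
  N/ambiguity masking, and **isochore-family** binning of TADs by mean
  GC (L1 < 37 ≤ L2 < 41 ≤ H1 < 46 ≤ H2 < 53 ≤ H3, in GC%).
- **Six-class GC-gradient classification of TADs/loops.** Each interval
  is split into 100 near-equal bins; in each half (bins 1–50 and
  51–100) the Pearson correlation *r* between bin GC% and bin index
  measures the gradient. Thresholding each *r* at ±0.4 yields signs
  (−, 0, +) per half and the sign pair maps to the classes
  **A** (monotone), **B** (bell), **C** (valley), **B⁻**/**C⁻** (half
  bell / half valley) and **D** (flat or uncorrelated). Classes are
  orientation-invariant: reversing a profile maps (r₁, r₂) → (−r₂, −r₁).
- **PCA verification**: column-centered, unscaled PCA of the N×100 GC
  matrix. F1 carries the compositional level (|corr(F1, mean GC)| ≈ 1);
  bell-like {B, B⁻} and valley-like {C, C⁻} classes separate in the
  (F2, F3) plane, quantified by a silhouette coefficient and a
  nearest-centroid accuracy.
- **Boundary-perturbation robustness**: re-classify every TAD after
  growing or shrinking it by 50 kb at both ends; 6×6 class transition
  matrices with per-class stay rates.
- **ICP**, the interchromosomal contact probability of a bin
  *i*: ICP_i = Σ_{j: chrom(j)≠chrom(i)} C_ij / Σ_j C_ij, computed from a
  symmetric binned contact matrix; GC↔ICP correlation and the linear
  model in both directions.
- **Hub composition**: GC% of nucleolar- vs speckle-assigned bins with
  Student's (or Welch's) t-test.
- **Intra-TAD feature distributions**: relative position index on
  [0, 1] for fully contained genes, super-enhancers, CTCF sites and
  sub-TADs; boundary-corrected kernel densities; per-100 kb densities
  by isochore family; sub-structure enrichment between classes (Welch
  t-test); and **Tau** tissue-specificity stratification,
  Tau = Σᵢ(1 − xᵢ/max x)/(N−1) on log2(TPM+1), with housekeeping
  (Tau < 0.3) vs tissue-specific (Tau > 0.8) contrasts per TAD class
  (Wilcoxon rank-sum).
- A **synthetic-data generator** that emulates all of the above with
  known ground truth (controllable gradient shapes, GC↔contact
  coupling, hub GC shift, positional biases, Tau structure), so the
  whole pipeline is validated end-to-end.

## Worked example

`examples/classify_tads.py` synthesizes 60 TADs with known gradient
classes, recomputes their profiles from sequence and classifies them:

```
class counts: {'A': 9, 'B': 10, 'C': 10, 'B-': 10, 'C-': 11, 'D': 10}
proportions by isochore family (rows sum to 1):
        A     B     C    B-    C-     D
all  0.15  0.17  0.17  0.17  0.18  0.17
...
ground-truth recovery: 98.3%
```

The generator drew ten TADs per class; the classifier recovers the
generating class for 59/60 of them from sequence alone (one monotone
TAD whose noisy half fell under the |r| = 0.4 cut is read as a half
shape). Other examples cover the ICP–GC correlation and linear model
(`icp_correlation.py`, r ≈ 0.61 at a 0.62 coupling target), hub
composition (`hub_composition.py`, a 5.0-point speckle−nucleolar GC gap
at p ≈ 2×10⁻¹⁰), PCA verification (`pca_verification.py`,
|corr(F1, mean GC)| = 1.0000, centroid accuracy 100%) and intra-TAD
feature positions with Tau stratification (`tad_feature_positions.py`).

A command-line interface wraps the same library:

```bash
tadgc synthesize --seed 7 --outdir data/
tadgc classify --fasta data/genome.fa --tads data/tads.bed --out classes.tsv
tadgc demo --seed 7 --outdir demo_run/   # synthesize + analyze + recovery report
```

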