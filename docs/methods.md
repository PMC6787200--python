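# Methods

## Coordinates and input formats

All coordinates are 0-based half-open (BED convention), enforced at the
reader boundary (`tadgc.io`); 1-based input is converted with an
explicit `one_based=True` flag and nothing downstream re-interprets
coordinates. Sequences come from multi-record FASTA; TADs, hubs and
feature tracks from BED3/4/6; contact matrices from sparse triplet TSV
(`binA binB count` with global bin indices, or
`chromA posA chromB posB count`); expression from a gene × tissue TPM
TSV. Contact matrices are symmetrized at read time (entries supplied in
both triangles are summed) and stored sparsely with a chromosome-offset
global bin index; they are densified only per operation.

## GC content and masking

GC% of a stretch of sequence is 100·(G+C)/(A+C+G+T). N and IUPAC
ambiguity codes are excluded from the denominator; a window or profile
bin whose non-ACGT fraction exceeds `mask_threshold` (default 0.5) is
masked (NaN). Soft-masked lowercase bases count as their base identity:
the analysis consumes only composition, and discarding repeat-masked
sequence would discard real nucleotides. Windowed tracks tile each
chromosome; a trailing partial window is kept when it covers at least
10% of the resolution, otherwise masked. The analysis-side default
resolution is 1 Mb (hub and sliding-window scale); synthetic runs use
finer grids because the toy genomes are ~100× smaller than a mammalian
genome (see below).

## TAD profiles and isochore families

A TAD of length L is split into `n_bins` (default 100) near-equal bins;
bin lengths differ by at most 1 bp and the remainder goes to the
leftmost bins — any fixed rule works, this one is testable, and
orientation equivalence is handled in the classifier rather than the
binning. A TAD shorter than `n_bins` bp is an error advising a smaller
`n_bins`. The TAD's mean GC is the mean over unmasked bins, and its
isochore family is a fixed cut-point lookup: L1 < 37 ≤ L2 < 41 ≤ H1 <
46 ≤ H2 < 53 ≤ H3 (GC%), half-open so a value on a cut belongs to the
GC-richer family, and clamped outside the nominal 33–59 range (the
classical isochore families span that range; TAD means occasionally
fall outside it and are clamped rather than dropped). De novo isochore
segmentation is out of scope — families reduce to these cut-points
applied to TAD means.

## Gradient classification

The profile is split into halves (bins 1–50, 51–100). In each half the
Pearson correlation r between bin GC% and bin index is the gradient
measure — the correlation coefficient itself, sign-interpreted as
gradient direction. (A bp-scaled regression slope would not support a
fixed ±0.4 threshold; the correlation does.) Each r is mapped to a sign
s ∈ {−, 0, +} using a single flat threshold, default 0.4, applied
symmetrically to all classes; the threshold is stated in the source
analysis only for the flat class, and using one universal cut is the
unique completion that makes the six classes an exhaustive, mutually
exclusive partition of (r₁, r₂) space:

| (s₁, s₂) | class |
|---|---|
| (0, 0) | D (flat/uncorrelated) |
| (+, +), (−, −) | A (monotone) |
| (+, −) | B (bell) |
| (−, +) | C (valley) |
| (+, 0), (0, −) | B⁻ (half bell, high interior plateau) |
| (−, 0), (0, +) | C⁻ (half valley, low interior plateau) |

Reversing a profile maps (r₁, r₂) → (−r₂, −r₁), so every class is fixed
under orientation reversal by construction.

Numerical conventions: a zero-variance half has r defined as 0 (a
constant half is the definitional flat case). A half whose GC values
have standard deviation ≤ 0.1 points is also treated as constant: a
sequence bin of ≥ 500 bp can deviate from any GC target by at most
0.1 points through integer base counts, so this guard keeps
quantization jitter on essentially-constant sequence from registering
as a spurious (scale-free) correlation. Masked bins are dropped
pairwise within their half; a half with fewer than 3 unmasked bins
leaves the TAD unclassified, reported separately with its reason.

Boundary perturbation re-sizes each TAD by `delta` (default 50 kb) at
both ends — expanded intervals are clipped to chromosome bounds, and a
TAD must be longer than 2·delta + n_bins to shrink, otherwise it is
counted in an `excluded` column — then recomputes the profile from
sequence and reclassifies. Transition matrices have original classes as
rows, so row sums equal original class counts.

Sub-structure enrichment compares per-TAD sub-TAD densities (counts of
fully contained sub-TADs per 100 kb) between two classes with Welch's
unequal-variance t-test; the t-test variant is unstated in the source
analysis and Welch is the safe default. A zero-density reference class
yields an undefined (NaN) ratio rather than infinity.

## PCA verification

PCA of the N × 100 GC matrix is computed by SVD with columns (bins)
centered and **not** scaled. Scaling bin columns to unit variance would
erase the between-TAD GC-level signal that makes F1 track mean GC;
"raw" here means unscaled. Both centering and scaling are exposed as
flags (an entirely uncentered variant is available). Masked bins are
imputed with their row mean; a fully masked row must be excluded
upstream. Components are deterministic up to sign; the convention
orients each loading vector so its largest-magnitude element is
positive, and the F1–meanGC correlation is reported as an absolute
value so the convention cannot affect it. Separation of {B, B⁻} vs
{C, C⁻} is quantified on the (F2, F3) scores by the silhouette
coefficient of the two super-groups and the accuracy of a
nearest-super-group-centroid rule — a visual cluster separation needs a
number for testing, and these two are the simplest pair (one internal,
one decision-rule).

## ICP and hubs

ICP of bin i is the sum of its interchromosomal contact counts divided
by the sum of all its contact counts. Self-bin (diagonal) counts are
included in the intra-chromosomal part of the denominator — the literal
reading of "inter- and intra-chromosomal contact frequencies" — with a
flag to exclude them. Raw counts are used; no ICE/KR balancing, since
ICP is a per-bin ratio and balancing would cancel from numerator and
denominator only approximately. Bins with zero total contacts are
undefined (NaN). The hub comparison uses Student's pooled-variance
t-test by default to match the published test, with Welch available.
The GC↔ICP linear model is ordinary least squares fitted in both
directions (ICP~GC and GC~ICP) and reported separately; OLS is
direction-dependent and the reverse slope is not the reciprocal of the
forward slope unless |r| = 1.

## Intra-TAD feature distributions and Tau

A feature belongs to a TAD only if fully contained in it; features
overlapping a TAD but crossing its border are dropped (and counted), as
are features outside all TADs — the containment rule used for the
published density profiles. Its relative position is
(midpoint − TAD start)/TAD length ∈ [0, 1]; the midpoint anchor is
symmetric under orientation, unlike a start anchor. With nested or
overlapping TAD calls the smallest containing TAD wins (ties:
leftmost) — a deterministic rule needed only for nested inputs. Strand
is ignored throughout; no operation here is strand-aware. Positions
0–0.2 and 0.8–1.0 are reported as a border band and 0.3–0.7 as centre,
as an auxiliary column only.

Positional densities combine a 20-bin histogram with a Gaussian KDE
(Silverman bandwidth) corrected for the bounded support by reflection
at 0 and 1, so the estimate integrates to 1 ± 0.01 on [0, 1]; the
density at the 0.75 position is reported as a border-shift marker.
Fewer than 10 records yield the histogram only.

Tau is computed on x = log2(TPM + 1): Tau = Σᵢ(1 − xᵢ/max x)/(N − 1).
The log transform is the established practice for Tau on RNA-seq
(heavy-tailed TPM would otherwise let one tissue dominate the
normalization); `transform="raw"` is available. Genes with Tau < 0.3
are housekeeping, Tau > 0.8 tissue-specific, boundary values
intermediate (strict inequalities). An all-zero row is undefined and
the gene excluded with a logged reason. Per-gene mean TPM is the
arithmetic mean over tissues and log10 is taken per gene, then
summarized per group — the per-gene-then-summarize order is our
documented choice. Family density tables divide counts of contained
features by the family's total TAD length in 100 kb units.

## Synthetic data generator

The generator defines the validation conditions; its defaults are the
standard suite: 600 TADs (100 per class) distributed round-robin over 6
chromosomes, TAD lengths uniform on 60–140 kb with 2–8 kb background
gaps, mean GC per TAD uniform on 33–59% (the isochore range), gradient
amplitude 5 GC points, per-bin noise sd 1.0 GC points, seed 7. Class
shapes: A is a linear ramp whose endpoint difference equals the
amplitude (random sign); B/C are symmetric triangles (valley = negated
bell) spanning the amplitude; B⁻/C⁻ ramp over one random half and hold
a high/low plateau over the other; D is constant. All targets have mean
exactly the TAD's mean GC.

Sequence is built per profile bin with an **exact** G+C count:
n_GC = round(L_bin·(target + N(0, noise_sd))/100), with the noised
target clamped to [5, 95]%, G/C and A/T split uniformly at random.
This makes `bin_noise_sd` the realized per-bin noise irrespective of
bin length — per-base Bernoulli sampling would add binomial noise of
50/√L_bin GC points, confounding the noise parameter with TAD size.
The sequence model is otherwise independent per base (no dinucleotide
structure): the analysis consumes only windowed GC%, so higher-order
realism would add nothing testable. Gaps are background sequence at
40% GC, also exact-count. Everything derives from one seeded generator,
so all outputs are bit-reproducible.

Contacts: per-bin interchromosomal propensity w_i = logistic(β·z_i)
with z the standardized bin GC. Interchromosomal expected counts are
proportional to w_i·w_j, intra-chromosomal counts are a uniform
per-chromosome background (diagonal included), scaled so each bin
expects `contacts_per_bin` (default 2000) total with `inter_fraction`
(default 0.35) interchromosomal; counts are Poisson and symmetrized. β
is calibrated by bisection on [0, 0.8] against simulations from a fixed
internal seed until the realized ICP–GC Pearson r is within 0.02 of
`icp_gc_coupling` (default 0.62, the strength seen in real
tethered-capture data); above β ≈ 0.8 the propensities saturate and the
achievable correlation declines, so the search stays in the monotone
regime. A coupling of 0 sets β = 0 exactly.

Hubs: bins at `hub_resolution` are labelled speckle with probability
logistic(γ·(GC − median)); γ is bisected until the realized
speckle-minus-nucleolar mean GC difference is within 0.1 of
`hub_gc_shift` (default 5 GC points); an unreachable shift is an error,
a shift of 0 is a fair coin. Masked bins are `unassigned`.

Features: per-TAD counts are Poisson with per-100 kb rates graded
geometrically across isochore families (genes 0.6→3.0, CTCF 2→9,
super-enhancers 0.3→1.8 from L1 to H3), emulating the observed
GC-graded densities. Valley-class TADs place features border-biased
(Beta(0.5, 0.5) on the relative position); bell-class TADs place
super-enhancers centre-biased (Beta(4, 4)); everything else is uniform.
Symmetric Betas are the simplest family matching the observed U- and
bell-shaped densities. Sub-TAD rates per class encode the observed
bell-vs-valley enrichment (B 1.464, B⁻ 1.436 vs 0.4 elsewhere, i.e.
3.66× and 3.59×). Genes draw a true expression class (housekeeping
probability per TAD class, higher in bell classes; tissue-specific 0.3)
and expression rows are constructed to land in the corresponding Tau
band: near-uniform lognormal rows (housekeeping), one dominant tissue
(tissue-specific), or 8–14 expressed tissues (intermediate), over 27
tissues.

Scaling: the suite totals ~64 Mb of sequence, so hub and contact grids
default to 100 kb and 125 kb bins (≈ 640 and ≈ 500 bins genome-wide),
preserving the bin-count regime of 1 Mb analysis on a real genome. The
TAD length distribution is uniform within a configurable range; real
per-class length distributions are unknown and no realism is claimed.

### What passing tests do and do not show

The generator realizes exactly the structure the analysis assumes:
additive Gaussian bin noise, clean TAD boundaries, no assembly gaps
inside TADs, no repeat/centromere structure (satellite-driven ICP
spikes are not modelled), one class per TAD and no nested TAD
hierarchy beyond an optional sub-TAD track. Recovery and calibration
results therefore validate the implementation — that the statistics
measure what they claim under known truth — not the biological claims
on real genomes, which require real Hi-C/SPRITE/TCC data.

## Validation design

Core statistics are pinned to independent oracles: windowed GC against
naive per-window letter counting (exact), half correlations against a
from-scratch covariance formula (1e-12), ICP against a brute-force
double loop on small multi-chromosome matrices (exact), PCA against
scikit-learn's implementation (cross-check only), Tau against analytic
limits (uniform → 0, one-hot → 1) and a hand-computed four-tissue
example. Invariants are property-tested: orientation equivalence and
affine invariance of classification, containment accounting
conservation, transition-matrix count conservation, KDE normalization,
null calibration of the hub t-test (uniform p-values under shift 0).

## Known limitations

- Real-data headline values (hub correlation r = 0.82, ICP–GC r = 0.62,
  human class frequencies, the 3.66× mouse sub-TAD enrichment) require
  the original datasets and are emulated, not reproduced; the
  operations that would compute them on real inputs are implemented.
- Chromatin sub-compartment calling (A1/A2/B1–B4) is not computed;
  precomputed labels can be carried as an extra BED column only.
- The A-class is intrinsically the hardest to recover: its ramp spans
  the amplitude over the full profile, so each half carries half the
  signal, and at amplitude/noise = 5 its per-half |r| sits closest to
  the 0.4 threshold. Suite recovery (~99% overall) is dominated by
  occasional A → B⁻/C⁻ calls.
- Binary formats (BAM, .cool/.hic, bigWig) are out of scope; inputs are
  plain text.
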