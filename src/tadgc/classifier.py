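"""Six-class intra-TAD GC-gradient classifier.

A TAD's 100-bin GC profile is split into halves (bins 1-50, 51-100).
Within each half the Pearson correlation r between bin GC% and bin
index measures the direction of the GC gradient. Thresholding each r at
``flat_threshold`` (default 0.4) gives a sign s in {-, 0, +} per half,
and the sign pair maps onto six shape classes:

=============  =======================================
(s1, s2)       class
=============  =======================================
(0, 0)         D   (flat or uncorrelated)
(+, +), (-,-)  A   (monotone increasing or decreasing)
(+, -)         B   (bell / peak)
(-, +)         C   (valley)
(+, 0), (0,-)  B-  (half bell: high interior plateau)
(-, 0), (0,+)  C-  (half valley: low interior plateau)
=============  =======================================

Reversing a profile maps (r1, r2) -> (-r2, -r1), so every class is
orientation-invariant by construction (5' and 3' gradients equivalent).
A zero-variance half has r defined as 0; to keep quantization jitter on
essentially-constant sequence from registering as a gradient, a half
whose GC values vary by less than ``FLAT_SD_EPS`` (0.1 GC points, the
quantization bound for bins of >= 500 bp) is also treated as constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import FAMILIES, TadProfile, tad_gc_profile
from .intervals import FeatureSet, GenomicInterval

__all__ = [
    "CLASSES",
    "FLAT_SD_EPS",
    "ClassifierConfig",
    "PerturbationConfig",
    "ClassificationResult",
    "EnrichmentResult",
    "InsufficientBinsError",
    "half_correlations",
    "classify",
    "classify_profile",
    "classify_all",
    "class_frequencies",
    "perturb_and_reclassify",
    "substructure_enrichment",
]

#: Gradient classes in canonical order.
CLASSES = ("A", "B", "C", "B-", "C-", "D")

#: GC-percentage-point standard deviation below which a half-profile is
#: considered constant. Guards against base-count quantization: a bin of
#: >= 500 bp can deviate from its GC target by at most 0.1 points, so
#: essentially-constant sequence never registers as a gradient.
FLAT_SD_EPS = 0.1


class InsufficientBinsError(ValueError):
    """Too few unmasked bins in a half-profile to estimate a gradient."""


@dataclass(frozen=True)
class ClassifierConfig:
    flat_threshold: float = 0.4
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.flat_threshold < 1.0):
            raise ValueError("flat_threshold must be in (0, 1)")
        if self.n_bins % 2:
            raise ValueError("n_bins must be even")


@dataclass(frozen=True)
class PerturbationConfig:
    delta: int = 50_000
    modes: tuple[str, ...] = ("expand", "shrink")

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        for m in self.modes:
            if m not in ("expand", "shrink"):
                raise ValueError(f"unknown perturbation mode {m!r}")


def _half_r(values: np.ndarray, min_bins: int = 3) -> float:
    ok = ~np.isnan(values)
    if ok.sum() < min_bins:
        raise InsufficientBinsError(
            f"only {int(ok.sum())} unmasked bins in half (need >= {min_bins})"
        )
    y = values[ok]
    x = np.nonzero(ok)[0].astype(float)
    if np.std(y) <= FLAT_SD_EPS or np.std(x) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def half_correlations(
    bins: np.ndarray, min_bins: int = 3
) -> tuple[float, float]:
    """Pearson r of (GC%, bin index) in each half of a profile.

    Masked bins are dropped pairwise within their half; a constant half
    yields r = 0. Raises :class:`InsufficientBinsError` when a half has
    fewer than ``min_bins`` unmasked bins.
    """
    bins = np.asarray(bins, dtype=float)
    n = len(bins)
    if n % 2:
        raise ValueError("profile must have an even number of bins")
    half = n // 2
    return _half_r(bins[:half], min_bins), _half_r(bins[half:], min_bins)


def _sign(r: float, threshold: float) -> int:
    if r >= threshold:
        return 1
    if r <= -threshold:
        return -1
    return 0


_CLASS_BY_SIGNS = {
    (0, 0): "D",
    (1, 1): "A",
    (-1, -1): "A",
    (1, -1): "B",
    (-1, 1): "C",
    (1, 0): "B-",
    (0, -1): "B-",
    (-1, 0): "C-",
    (0, 1): "C-",
}


def classify(r1: float, r2: float, config: ClassifierConfig | None = None) -> str:
    """Map a half-correlation pair to one of the six gradient classes."""
    config = config or ClassifierConfig()
    for r in (r1, r2):
        if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of [-1, 1]: {r}")
    return _CLASS_BY_SIGNS[(_sign(r1, config.flat_threshold), _sign(r2, config.flat_threshold))]


def classify_profile(
    bins: np.ndarray, config: ClassifierConfig | None = None
) -> tuple[str, float, float]:
    """Classify a binned GC profile; returns (class, r1, r2)."""
    r1, r2 = half_correlations(np.asarray(bins, dtype=float))
    return classify(r1, r2, config), r1, r2


@dataclass
class ClassificationResult:
    """Per-TAD labels plus stratified class frequencies."""

    per_tad: pd.DataFrame  # tad_id, chrom, start, end, r1, r2, gradient_class, mean_gc, family
    excluded: pd.DataFrame  # tad_id, reason
    counts: pd.DataFrame  # families x classes counts (+ 'all' row)
    proportions: pd.DataFrame  # same shape, rows sum to 1


def classify_all(
    profiles: Sequence[TadProfile], config: ClassifierConfig | None = None
) -> ClassificationResult:
    """Classify every profile and tabulate frequencies by isochore family."""
    config = config or ClassifierConfig()
    rows = []
    excluded = []
    for p in profiles:
        try:
            label, r1, r2 = classify_profile(p.bins, config)
        except InsufficientBinsError as exc:
            excluded.append({"tad_id": p.tad_id, "reason": str(exc)})
            continue
        rows.append(
            {
                "tad_id": p.tad_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "r1": r1,
                "r2": r2,
                "gradient_class": label,
                "mean_gc": p.mean_gc,
                "family": p.family,
            }
        )
    per_tad = pd.DataFrame(
        rows,
        columns=[
            "tad_id", "chrom", "start", "end", "r1", "r2",
            "gradient_class", "mean_gc", "family",
        ],
    )
    counts, props = class_frequencies(per_tad)
    return ClassificationResult(
        per_tad, pd.DataFrame(excluded, columns=["tad_id", "reason"]), counts, props
    )


def class_frequencies(per_tad: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class counts and proportions, overall ('all') and per isochore family."""
    strata = ["all", *FAMILIES]
    counts = pd.DataFrame(0, index=strata, columns=list(CLASSES), dtype=int)
    if len(per_tad):
        overall = per_tad["gradient_class"].value_counts()
        for cls, n in overall.items():
            counts.loc["all", cls] = int(n)
        by_fam = per_tad.groupby("family", observed=True)["gradient_class"].value_counts()
        for (fam, cls), n in by_fam.items():
            if fam in counts.index:
                counts.loc[fam, cls] = int(n)
    totals = counts.sum(axis=1)
    props = counts.div(totals.replace(0, np.nan), axis=0)
    return counts, props


def _perturbed_interval(
    iv: GenomicInterval, mode: str, delta: int, chrom_len: int, n_bins: int
) -> GenomicInterval | None:
    if mode == "expand":
        start = max(0, iv.start - delta)
        end = min(chrom_len, iv.end + delta)
    else:  # shrink
        if iv.length <= 2 * delta + n_bins:
            return None
        start, end = iv.start + delta, iv.end - delta
    if end - start < n_bins:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def perturb_and_reclassify(
    profiles: Sequence[TadProfile],
    genome: Mapping[str, str],
    pconfig: PerturbationConfig | None = None,
    config: ClassifierConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Class transition matrices under boundary perturbation.

    Every TAD is re-sized by ``delta`` bp on both ends (expand and/or
    shrink), its profile recomputed from sequence and reclassified. Each
    returned matrix has original classes as rows and perturbed classes
    (plus an ``excluded`` column for TADs too short to perturb or with
    undefined halves) as columns; row sums equal the original class counts.
    """
    pconfig = pconfig or PerturbationConfig()
    config = config or ClassifierConfig()
    out: dict[str, pd.DataFrame] = {}
    cols = [*CLASSES, "excluded"]
    for mode in pconfig.modes:
        mat = pd.DataFrame(0, index=list(CLASSES), columns=cols, dtype=int)
        for p in profiles:
            try:
                orig, _, _ = classify_profile(p.bins, config)
            except InsufficientBinsError:
                continue
            piv = _perturbed_interval(
                p.interval, mode, pconfig.delta, len(genome[p.interval.chrom]), config.n_bins
            )
            if piv is None:
                mat.loc[orig, "excluded"] += 1
                continue
            try:
                newp = tad_gc_profile(genome, piv, n_bins=config.n_bins, tad_id=p.tad_id)
                new, _, _ = classify_profile(newp.bins, config)
            except (InsufficientBinsError, ValueError):
                mat.loc[orig, "excluded"] += 1
                continue
            mat.loc[orig, new] += 1
        out[mode] = mat
    return out


def stay_rates(transition: pd.DataFrame) -> pd.Series:
    """Per-class fraction of TADs keeping their class after perturbation."""
    totals = transition.sum(axis=1)
    diag = pd.Series(
        [transition.loc[c, c] for c in transition.index], index=transition.index, dtype=float
    )
    return diag / totals.replace(0, np.nan)


@dataclass
class EnrichmentResult:
    """Sub-structure density contrast between two TAD classes."""

    ratio: float  # mean density class_a / mean density class_b (NaN if undefined)
    t_statistic: float
    p_value: float
    mean_density_a: float
    mean_density_b: float
    n_a: int
    n_b: int
    densities: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def substructure_enrichment(
    per_tad: pd.DataFrame,
    sub_tads: FeatureSet,
    class_a: str = "B",
    class_b: str = "C",
) -> EnrichmentResult:
    """Compare per-100 kb sub-TAD density between two gradient classes.

    Sub-TADs are counted only when fully contained in a TAD. The contrast
    is the ratio of mean densities plus a Welch two-sample t-test on the
    per-TAD densities.
    """
    from .features import relative_positions  # shared containment rule

    tads = [
        (row.tad_id, GenomicInterval(row.chrom, int(row.start), int(row.end)))
        for row in per_tad.itertuples(index=False)
    ]
    recs = relative_positions(tads, sub_tads).records
    counts = recs.groupby("tad_id").size() if len(recs) else pd.Series(dtype=int)
    df = per_tad[["tad_id", "gradient_class", "start", "end"]].copy()
    df["n_sub"] = df["tad_id"].map(counts).fillna(0).astype(int)
    df["density_per_100kb"] = df["n_sub"] / ((df["end"] - df["start"]) / 1e5)
    a = df.loc[df["gradient_class"] == class_a, "density_per_100kb"].to_numpy()
    b = df.loc[df["gradient_class"] == class_b, "density_per_100kb"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 TADs per class for a t-test (got {len(a)} {class_a!r}, "
            f"{len(b)} {class_b!r})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = mean_a / mean_b if mean_b > 0 else float("nan")
    return EnrichmentResult(
        ratio, float(t), float(p), mean_a, mean_b, len(a), len(b), df
    )
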