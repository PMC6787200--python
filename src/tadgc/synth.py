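"""Synthetic genome and companion tracks with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* TADs tiling small chromosomes, each with a GC-gradient target profile
  from one of the six shape classes (A monotone, B bell, C valley,
  B- half bell, C- half valley, D flat);
* isochore-level spread of TAD mean GC (uniform on 33-59% by default);
* per-bin GC noise realized exactly: every profile bin's sequence is
  built with a fixed G+C count equal to the (noised, clamped) target,
  so ``bin_noise_sd`` is the realized per-bin noise regardless of bin
  length (no extra binomial sampling noise);
* a contact matrix whose per-bin interchromosomal propensity follows a
  logistic function of GC, with the coupling strength calibrated by
  bisection so the realized ICP-GC Pearson r hits a target;
* hub labels whose speckle-minus-nucleolar mean GC difference is tuned
  to ``hub_gc_shift`` by a logistic assignment rule;
* class-dependent feature placement (border-biased Beta(0.5, 0.5) in
  valley-class TADs, centre-biased Beta(4, 4) super-enhancers in
  bell-class TADs) and family-graded feature rates;
* gene expression rows constructed to land in the housekeeping
  (Tau < 0.3), tissue-specific (Tau > 0.8) or intermediate band.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import GcTrack, assign_family, bin_edges, windowed_gc
from .hubs import ContactMatrix, HubTrack
from .intervals import Feature, FeatureSet, GenomicInterval
from .io import ExpressionTable, write_expression, write_fasta

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "TruthTable",
    "make_gc_target_profile",
    "synthesize_genome",
    "synthesize_contacts",
    "synthesize_hub_labels",
    "synthesize_features_and_expression",
    "synthesize_all",
    "standard_suite",
]

_CLASSES = ("A", "B", "C", "B-", "C-", "D")

_BASES = {  # ASCII codes
    "A": 65, "C": 67, "G": 71, "T": 84,
}


def _equal_mix() -> dict[str, float]:
    return {c: 1.0 / len(_CLASSES) for c in _CLASSES}


def _default_rates(low: float, high: float) -> dict[str, float]:
    # geometric ramp across the five families, GC-poor to GC-rich
    fams = ("L1", "L2", "H1", "H2", "H3")
    vals = np.geomspace(low, high, len(fams))
    return {f: float(v) for f, v in zip(fams, vals)}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults define the standard suite: 600 TADs (100 per class) on six
    chromosomes, mean GC uniform on 33-59%, gradient amplitude 5 GC
    points, per-bin noise sd 1.0 GC points, seed 7. Hub and contact
    resolutions are finer than the 1 Mb used on real genomes because the
    synthetic genome is ~100x smaller; the analysis-side defaults remain
    1 Mb.
    """

    n_chroms: int = 6
    n_tads: int | None = 600  # exact TAD count; None = tile chrom_length
    chrom_length: int | None = None  # used when n_tads is None
    tad_length_range: tuple[int, int] = (60_000, 140_000)
    gap_length_range: tuple[int, int] = (2_000, 8_000)
    class_mix: dict[str, float] = field(default_factory=_equal_mix)
    mean_gc_range: tuple[float, float] = (33.0, 59.0)
    gradient_amplitude: float = 5.0
    bin_noise_sd: float = 1.0
    background_gc: float = 40.0
    n_bins: int = 100
    # hubs / contacts
    hub_gc_shift: float = 5.0
    hub_resolution: int = 100_000
    icp_gc_coupling: float = 0.62
    contact_resolution: int = 125_000
    contacts_per_bin: float = 2_000.0
    inter_fraction: float = 0.35
    # features / expression
    n_tissues: int = 27
    gene_rate_by_family: dict[str, float] = field(
        default_factory=lambda: _default_rates(0.6, 3.0)
    )
    ctcf_rate_by_family: dict[str, float] = field(
        default_factory=lambda: _default_rates(2.0, 9.0)
    )
    se_rate_by_family: dict[str, float] = field(
        default_factory=lambda: _default_rates(0.3, 1.8)
    )
    subtad_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.4, "B": 1.464, "C": 0.4, "B-": 1.436, "C-": 0.4, "D": 0.4,
        }
    )
    hk_prob_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.30, "B": 0.44, "C": 0.22, "B-": 0.40, "C-": 0.25, "D": 0.30,
        }
    )
    ts_prob: float = 0.30
    seed: int = 7

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        for c in self.class_mix:
            if c not in _CLASSES:
                raise ValueError(f"unknown class {c!r} in class_mix")
        lo, hi = self.mean_gc_range
        if not (0.0 < lo <= hi < 100.0):
            raise ValueError("mean_gc_range must lie within (0, 100)")
        if not (0.0 <= self.icp_gc_coupling <= 1.0):
            raise ValueError("icp_gc_coupling must be in [0, 1]")
        if self.n_tads is None and self.chrom_length is None:
            raise ValueError("set n_tads or chrom_length")
        if self.tad_length_range[0] < self.n_bins:
            raise ValueError("minimum TAD length must be >= n_bins")


def make_gc_target_profile(
    true_class: str,
    n_bins: int,
    mean_gc: float,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noiseless per-bin GC% target profile for one shape class.

    The profile spans ``amplitude`` GC points (for class A the endpoint
    difference equals the amplitude) and has mean exactly ``mean_gc``.
    Orientation (sign of the ramp, side of the half-shapes) is drawn
    from ``rng``.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    x = np.arange(n_bins) / (n_bins - 1)
    half = n_bins // 2
    if true_class == "D":
        return np.full(n_bins, float(mean_gc))
    if true_class == "A":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        y = sign * amplitude * (x - 0.5)
    elif true_class in ("B", "C"):
        t = 1.0 - 2.0 * np.abs(x - 0.5)
        t = (t - t.min()) / (t.max() - t.min())
        y = amplitude * (t - t.mean())
        if true_class == "C":
            y = -y
    elif true_class in ("B-", "C-"):
        side = rng.random() < 0.5
        h = np.empty(n_bins)
        if side:  # gradient in the first half, plateau in the second
            h[:half] = np.linspace(0.0, 1.0, half)
            h[half:] = 1.0
        else:  # plateau first, gradient second
            h[:half] = 1.0
            h[half:] = np.linspace(1.0, 0.0, n_bins - half)
        if true_class == "C-":
            h = 1.0 - h  # low interior plateau
        y = amplitude * (h - h.mean())
    else:
        raise ValueError(f"unknown class {true_class!r}")
    return mean_gc + y


def _exact_gc_block(
    length: int, gc_percent: float, rng: np.random.Generator
) -> np.ndarray:
    """Random sequence block (ASCII uint8) with an exact G+C count."""
    n_gc = int(round(length * gc_percent / 100.0))
    n_gc = min(max(n_gc, 0), length)
    out = np.empty(length, dtype=np.uint8)
    strong = np.zeros(length, dtype=bool)
    if 0 < n_gc < length:
        strong[np.argpartition(rng.random(length), n_gc - 1)[:n_gc]] = True
    elif n_gc == length:
        strong[:] = True
    coin = rng.random(length) < 0.5
    out[strong & coin] = _BASES["G"]
    out[strong & ~coin] = _BASES["C"]
    out[~strong & coin] = _BASES["A"]
    out[~strong & ~coin] = _BASES["T"]
    return out


def _tad_sequence(
    length: int,
    target: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence of one TAD; returns (ASCII array, realized per-bin GC%)."""
    edges = bin_edges(length, len(target))
    noised = target + (rng.normal(0.0, noise_sd, len(target)) if noise_sd > 0 else 0.0)
    noised = np.clip(noised, 5.0, 95.0)
    parts = []
    realized = np.empty(len(target))
    for k in range(len(target)):
        blen = int(edges[k + 1] - edges[k])
        block = _exact_gc_block(blen, noised[k], rng)
        parts.append(block)
        realized[k] = 100.0 * np.isin(block, (_BASES["G"], _BASES["C"])).sum() / blen
    return np.concatenate(parts), realized


def _class_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n TADs across classes."""
    raw = {c: n * p for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def synthesize_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the genome and the TAD truth table.

    Returns ``(genome, tads)`` where ``genome`` maps chromosome name to
    sequence and ``tads`` has one row per TAD with its interval, true
    class, true mean GC, realized per-bin profile correlation target and
    isochore family. Classes are drawn exactly per ``class_mix`` (up to
    largest-remainder rounding) and shuffled across positions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.tad_length_range
    glo, ghi = config.gap_length_range

    # decide per-chromosome TAD lengths
    per_chrom_lengths: list[list[int]] = [[] for _ in range(config.n_chroms)]
    if config.n_tads is not None:
        lengths = rng.integers(lo, hi + 1, size=config.n_tads)
        for i, L in enumerate(lengths):
            per_chrom_lengths[i % config.n_chroms].append(int(L))
    else:
        for c in range(config.n_chroms):
            remaining = config.chrom_length - int(rng.integers(glo, ghi + 1))
            while True:
                gap = int(rng.integers(glo, ghi + 1))
                if remaining < lo + gap:
                    break
                L = int(rng.integers(lo, hi + 1))
                L = min(L, remaining - gap)
                per_chrom_lengths[c].append(L)
                remaining -= L + gap
        if not any(per_chrom_lengths):
            raise ValueError("infeasible tiling: no TAD fits chrom_length")

    n_total = sum(len(v) for v in per_chrom_lengths)
    counts = _class_counts(n_total, config.class_mix)
    labels = np.array(
        [c for c, k in counts.items() for _ in range(k)], dtype=object
    )
    rng.shuffle(labels)
    mean_gcs = rng.uniform(*config.mean_gc_range, size=n_total)

    genome: dict[str, str] = {}
    rows = []
    tad_idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        parts: list[np.ndarray] = []
        pos = 0
        gap = int(rng.integers(glo, ghi + 1))
        parts.append(_exact_gc_block(gap, config.background_gc, rng))
        pos += gap
        for L in per_chrom_lengths[c]:
            cls = str(labels[tad_idx])
            mgc = float(mean_gcs[tad_idx])
            target = make_gc_target_profile(
                cls, config.n_bins, mgc, config.gradient_amplitude, rng
            )
            seq, _ = _tad_sequence(L, target, config.bin_noise_sd, rng)
            parts.append(seq)
            rows.append(
                {
                    "tad_id": f"tad_{tad_idx:05d}",
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + L,
                    "true_class": cls,
                    "true_mean_gc": mgc,
                    "true_family": assign_family(mgc),
                }
            )
            pos += L
            tad_idx += 1
            gap = int(rng.integers(glo, ghi + 1))
            parts.append(_exact_gc_block(gap, config.background_gc, rng))
            pos += gap
        genome[chrom] = np.concatenate(parts).tobytes().decode("ascii")
    tads = pd.DataFrame(rows)
    return genome, tads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_contacts(
    z: np.ndarray,
    chrom_of: np.ndarray,
    beta: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson contact counts under the logistic GC-propensity model."""
    n = len(z)
    w = _sigmoid(beta * z)
    same = chrom_of[:, None] == chrom_of[None, :]
    lam = np.outer(w, w)
    lam[same] = 0.0
    inter_sum = lam.sum(axis=1)
    scale = n * config.contacts_per_bin * config.inter_fraction / inter_sum.sum()
    lam *= scale
    # uniform intra-chromosomal background, diagonal included
    for c in np.unique(chrom_of):
        idx = chrom_of == c
        n_c = int(idx.sum())
        lam[np.ix_(idx, idx)] = config.contacts_per_bin * (1.0 - config.inter_fraction) / n_c
    upper = np.triu(rng.poisson(lam))
    return upper + upper.T - np.diag(np.diag(upper))


def _icp_from_dense(counts: np.ndarray, chrom_of: np.ndarray) -> np.ndarray:
    total = counts.sum(axis=1).astype(float)
    same = chrom_of[:, None] == chrom_of[None, :]
    intra = np.where(same, counts, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        icp = (total - intra) / total
    icp[total == 0] = np.nan
    return icp


def synthesize_contacts(
    gc_track: GcTrack,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ContactMatrix, float]:
    """Contact matrix whose ICP-GC correlation hits ``icp_gc_coupling``.

    The logistic coupling strength beta is calibrated by bisection
    against simulations drawn from a fixed internal seed (derived from
    ``config.seed``); the returned matrix is then sampled with ``rng``.
    Returns ``(matrix, beta)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    target = config.icp_gc_coupling
    gc = gc_track.concat()
    ok = ~np.isnan(gc)
    if ok.sum() < 10:
        raise ValueError("too few unmasked bins to synthesize contacts")
    gc_f = np.where(ok, gc, np.nanmean(gc))
    sd = gc_f.std()
    z = (gc_f - gc_f.mean()) / (sd if sd > 0 else 1.0)
    sizes = [len(gc_track.gc[c]) for c in gc_track.chroms]
    chrom_of = np.repeat(np.arange(len(sizes)), sizes)
    cal_seed = (config.seed * 1_000_003 + 17) % (2**31)

    def realized_corr(beta: float) -> float:
        r_cal = np.random.default_rng(cal_seed)
        counts = _simulate_contacts(z, chrom_of, beta, config, r_cal)
        icp = _icp_from_dense(counts, chrom_of)
        m = ok & ~np.isnan(icp)
        return float(np.corrcoef(gc[m], icp[m])[0, 1])

    if target == 0.0:
        beta = 0.0
    else:
        # realized corr rises monotonically with beta up to ~0.8, where the
        # logistic is still in its informative range; beyond that the
        # propensities saturate and the correlation slowly degrades
        b_lo, b_hi = 0.0, 0.8
        if realized_corr(b_hi) < target:
            beta = b_hi
        else:
            beta = 0.5 * (b_lo + b_hi)
            for _ in range(40):
                c = realized_corr(beta)
                if abs(c - target) <= 0.02:
                    break
                if c < target:
                    b_lo = beta
                else:
                    b_hi = beta
                beta = 0.5 * (b_lo + b_hi)
    counts = _simulate_contacts(z, chrom_of, beta, config, rng)
    cm = ContactMatrix.from_dense(
        counts, gc_track.resolution, gc_track.chrom_sizes
    )
    return cm, beta


def synthesize_hub_labels(
    gc_track: GcTrack,
    hub_gc_shift: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[HubTrack, float]:
    """Label bins nucleolar/speckle so the group mean-GC gap hits the target.

    Assignment is probabilistic via a logistic rule on bin GC; its
    steepness gamma is tuned by bisection until the realized
    speckle-minus-nucleolar mean GC difference is within 0.1 of
    ``hub_gc_shift``. Masked bins become 'unassigned'. Returns
    ``(track, gamma)``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    df = gc_track.to_dataframe()
    gc = df["gc"].to_numpy()
    ok = ~np.isnan(gc)
    gcv = gc[ok]
    if len(gcv) < 4:
        raise ValueError("too few unmasked bins for hub assignment")
    u = rng.random(len(gcv))
    m = float(np.median(gcv))

    def labels_for(gamma: float) -> np.ndarray:
        return u < _sigmoid(gamma * (gcv - m))

    def diff_for(lab: np.ndarray) -> float:
        if lab.all() or not lab.any():
            return float("nan")
        return float(gcv[lab].mean() - gcv[~lab].mean())

    if hub_gc_shift == 0.0:
        lab = u < 0.5
        gamma = 0.0
    else:
        g_lo, g_hi = 0.0, 50.0
        max_diff = diff_for(labels_for(g_hi))
        if not np.isfinite(max_diff) or hub_gc_shift > max_diff:
            raise ValueError(
                f"hub_gc_shift={hub_gc_shift} not achievable "
                f"(max {max_diff:.2f} on this GC distribution)"
            )
        gamma = 0.5 * (g_lo + g_hi)
        for _ in range(60):
            d = diff_for(labels_for(gamma))
            if np.isfinite(d) and abs(d - hub_gc_shift) <= 0.1:
                break
            if not np.isfinite(d) or d < hub_gc_shift:
                g_lo = gamma
            else:
                g_hi = gamma
            gamma = 0.5 * (g_lo + g_hi)
        lab = labels_for(gamma)
    labels = np.full(len(df), "unassigned", dtype=object)
    labels[np.nonzero(ok)[0][lab]] = "speckle"
    labels[np.nonzero(ok)[0][~lab]] = "nucleolar"
    bins = df[["chrom", "start", "end"]].copy()
    bins["label"] = labels
    return HubTrack(bins, gc_track.resolution), gamma


# ---------------------------------------------------------------------------
# features and expression


def _place_features(
    tad: pd.Series,
    kind: str,
    count: int,
    length_range: tuple[int, int],
    dist: str,
    rng: np.random.Generator,
    start_index: int,
) -> list[Feature]:
    L = int(tad["end"] - tad["start"])
    feats = []
    for k in range(count):
        flen = int(rng.integers(*length_range)) if length_range[0] < length_range[1] else length_range[0]
        flen = min(flen, L)
        if dist == "border":
            m = rng.beta(0.5, 0.5)
        elif dist == "center":
            m = rng.beta(4.0, 4.0)
        else:
            m = rng.random()
        start = int(tad["start"]) + int(round(m * (L - flen)))
        feats.append(
            Feature(
                GenomicInterval(tad["chrom"], start, start + flen),
                kind,
                f"{kind}_{start_index + k:06d}",
            )
        )
    return feats


def _expression_row(
    tau_class: str, n_tissues: int, rng: np.random.Generator
) -> np.ndarray:
    if tau_class == "housekeeping":
        base = rng.lognormal(3.0, 1.0)
        return base * np.exp(rng.normal(0.0, 0.1, n_tissues))
    if tau_class == "tissue_specific":
        row = np.abs(rng.normal(0.0, 0.05, n_tissues))
        row[rng.integers(n_tissues)] = 50.0 + rng.lognormal(5.0, 1.0)
        return row
    # intermediate: expressed in a subset of tissues
    k = int(rng.integers(8, 15))
    row = rng.uniform(0.01, 0.1, n_tissues)
    idx = rng.choice(n_tissues, size=min(k, n_tissues), replace=False)
    row[idx] = rng.lognormal(3.0, 0.3, len(idx))
    return row


def synthesize_features_and_expression(
    tads: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, FeatureSet], ExpressionTable, pd.DataFrame]:
    """Feature tracks and a Tau-structured expression table.

    Feature counts per TAD are Poisson with family-graded rates (per
    100 kb); placement is border-biased in valley-class TADs and
    centre-biased for super-enhancers in bell-class TADs. Genes carry a
    true expression class used to construct their TPM rows. Returns
    ``(feature_sets, expression, gene_truth)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sets: dict[str, list[Feature]] = {
        "gene": [], "super_enhancer": [], "ctcf": [], "sub_tad": []
    }
    gene_rows = []
    counters = dict.fromkeys(sets, 0)
    for _, tad in tads.iterrows():
        cls = tad["true_class"]
        fam = tad["true_family"]
        L100 = (tad["end"] - tad["start"]) / 1e5
        border = cls in ("C", "C-")
        plans = [
            ("gene", config.gene_rate_by_family[fam], (1_000, 5_001),
             "border" if border else "uniform"),
            ("ctcf", config.ctcf_rate_by_family[fam], (200, 201),
             "border" if border else "uniform"),
            ("super_enhancer", config.se_rate_by_family[fam], (5_000, 15_001),
             "border" if border else ("center" if cls in ("B", "B-") else "uniform")),
            ("sub_tad", config.subtad_rate_by_class[cls],
             (max(100, int(0.05 * (tad["end"] - tad["start"]))),
              max(101, int(0.15 * (tad["end"] - tad["start"])))),
             "uniform"),
        ]
        for kind, rate, lrange, dist in plans:
            count = int(rng.poisson(rate * L100))
            feats = _place_features(tad, kind, count, lrange, dist, rng, counters[kind])
            counters[kind] += count
            sets[kind].extend(feats)
            if kind == "gene":
                for f in feats:
                    p_hk = config.hk_prob_by_class[cls]
                    u = rng.random()
                    if u < p_hk:
                        tc = "housekeeping"
                    elif u < p_hk + config.ts_prob:
                        tc = "tissue_specific"
                    else:
                        tc = "intermediate"
                    gene_rows.append(
                        {
                            "gene_id": f.id,
                            "tad_id": tad["tad_id"],
                            "tad_class": cls,
                            "true_tau_class": tc,
                        }
                    )
    gene_truth = pd.DataFrame(
        gene_rows, columns=["gene_id", "tad_id", "tad_class", "true_tau_class"]
    )
    expr = np.vstack(
        [
            _expression_row(tc, config.n_tissues, rng)
            for tc in gene_truth["true_tau_class"]
        ]
    ) if len(gene_truth) else np.empty((0, config.n_tissues))
    table = ExpressionTable(
        pd.DataFrame(
            expr,
            index=pd.Index(gene_truth["gene_id"], name="gene_id"),
            columns=[f"tissue_{i + 1}" for i in range(config.n_tissues)],
        )
    )
    feature_sets = {k: FeatureSet(v) for k, v in sets.items()}
    return feature_sets, table, gene_truth


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class TruthTable:
    """Ground truth of one synthetic dataset."""

    tads: pd.DataFrame  # tad_id, interval, true_class, true_mean_gc, true_family
    genes: pd.DataFrame  # gene_id, tad_id, tad_class, true_tau_class
    hub_bins: pd.DataFrame  # chrom, start, end, label


@dataclass
class SyntheticDataset:
    """All synthetic inputs plus their ground truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    truth: TruthTable
    feature_sets: dict[str, FeatureSet]
    expression: ExpressionTable
    hub_track: HubTrack
    contacts: ContactMatrix
    contact_gc: GcTrack
    hub_gc: GcTrack
    icp_beta: float
    hub_gamma: float

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every track as plain text (FASTA/BED/TSV); returns paths."""
        from .io import BedRecord, write_bed

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["fasta"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["fasta"])
        paths["tads"] = outdir / "tads.bed"
        write_bed(
            [
                BedRecord(
                    GenomicInterval(r.chrom, int(r.start), int(r.end)), (r.tad_id,)
                )
                for r in self.truth.tads.itertuples(index=False)
            ],
            paths["tads"],
        )
        for kind, fs in self.feature_sets.items():
            paths[kind] = outdir / f"{kind}.bed"
            write_bed(
                [BedRecord(f.interval, (f.id,)) for f in fs], paths[kind]
            )
        paths["expression"] = outdir / "expression.tsv"
        write_expression(self.expression, paths["expression"])
        paths["hubs"] = outdir / "hubs.bed"
        write_bed(self.hub_track.to_bed_records(), paths["hubs"])
        paths["contacts"] = outdir / "contacts.tsv"
        self.contacts.write_triplets(paths["contacts"])
        paths["truth_tads"] = outdir / "truth_tads.tsv"
        self.truth.tads.to_csv(paths["truth_tads"], sep="\t", index=False)
        paths["truth_genes"] = outdir / "truth_genes.tsv"
        self.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        return paths


def synthesize_all(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset: genome, TADs, hubs, contacts, features."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    genome, tads = synthesize_genome(config, rng)
    hub_gc = windowed_gc(genome, config.hub_resolution)
    hub_track, gamma = synthesize_hub_labels(hub_gc, config.hub_gc_shift, rng)
    contact_gc = windowed_gc(genome, config.contact_resolution)
    contacts, beta = synthesize_contacts(contact_gc, config, rng)
    feature_sets, expression, gene_truth = synthesize_features_and_expression(
        tads, config, rng
    )
    truth = TruthTable(tads, gene_truth, hub_track.bins.copy())
    return SyntheticDataset(
        config, genome, truth, feature_sets, expression,
        hub_track, contacts, contact_gc, hub_gc, beta, gamma,
    )


def standard_suite(
    seed: int = 7, **overrides
) -> tuple[dict[str, str], pd.DataFrame]:
    """Genome + TAD truth of the standard suite (600 TADs, 100 per class).

    Mean GC uniform on 33-59%, amplitude 5 GC points, per-bin noise sd
    1.0 GC points. ``overrides`` replace config fields.
    """
    config = replace(SyntheticConfig(), seed=seed, **overrides)
    return synthesize_genome(config)
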