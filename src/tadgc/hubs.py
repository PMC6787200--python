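"""Interchromosomal hubs and the ICP statistic.

The interchromosomal contact probability (ICP) of a genomic bin is the
sum of its interchromosomal contact counts divided by the sum of all
its (inter- plus intra-chromosomal) contact counts; it measures the
propensity of a region to contact other chromosomes. Self-bin
(diagonal) counts are included in the intra-chromosomal denominator by
default, the literal reading of the definition; a flag excludes them.
Raw counts are used throughout -- ICP is a per-bin ratio and no matrix
balancing is applied.

This module also compares GC% between nucleolar and speckle hub bins
(Student's t-test, matching the published analysis; Welch available)
and fits the linear GC <-> contact model in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .composition import GcTrack
from .intervals import GenomicInterval

__all__ = [
    "HUB_LABELS",
    "ContactMatrix",
    "IcpTrack",
    "HubTrack",
    "HubComparison",
    "LinearContactModel",
    "compute_icp",
    "hub_gc_comparison",
    "icp_gc_correlation",
    "linear_contact_model",
    "coprofile",
]

HUB_LABELS = ("nucleolar", "speckle", "unassigned")


class ContactMatrix:
    """Symmetric binned genome-wide contact counts.

    Bins are indexed globally with chromosome offsets:
    ``ceil(size / bin_size)`` bins per chromosome, concatenated in the
    order of ``chrom_sizes``. Counts are stored sparsely (CSR, full
    symmetric form) and densified only per-operation.
    """

    def __init__(
        self,
        counts: sparse.spmatrix,
        bin_size: int,
        chrom_sizes: Mapping[str, int],
    ) -> None:
        self.bin_size = int(bin_size)
        self.chrom_sizes = dict(chrom_sizes)
        self.chroms = list(self.chrom_sizes)
        self.bins_per_chrom = {
            c: -(-s // self.bin_size) for c, s in self.chrom_sizes.items()
        }
        offsets = np.cumsum([0, *self.bins_per_chrom.values()])
        self.offsets = {c: int(o) for c, o in zip(self.chroms, offsets[:-1])}
        self.n_bins = int(offsets[-1])
        self.chrom_of_bin = np.repeat(
            np.arange(len(self.chroms)), list(self.bins_per_chrom.values())
        )
        counts = sparse.csr_matrix(counts)
        if counts.shape != (self.n_bins, self.n_bins):
            raise ValueError(
                f"counts shape {counts.shape} does not match {self.n_bins} bins"
            )
        if counts.data.size and counts.data.min() < 0:
            raise ValueError("negative contact counts")
        self.counts = counts

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls, bin_size: int, chrom_sizes: Mapping[str, int]) -> "ContactMatrix":
        n = sum(-(-s // bin_size) for s in chrom_sizes.values())
        return cls(sparse.csr_matrix((n, n)), bin_size, chrom_sizes)

    def with_triplets(
        self, rows: np.ndarray, cols: np.ndarray, vals: np.ndarray
    ) -> "ContactMatrix":
        """New matrix from triplets; both-triangle duplicates are summed."""
        i = np.minimum(rows, cols)
        j = np.maximum(rows, cols)
        upper = sparse.coo_matrix(
            (vals, (i, j)), shape=(self.n_bins, self.n_bins)
        ).tocsr()
        diag = sparse.diags(upper.diagonal())
        full = upper + upper.T - diag
        return ContactMatrix(full, self.bin_size, self.chrom_sizes)

    @classmethod
    def from_dense(
        cls, dense: np.ndarray, bin_size: int, chrom_sizes: Mapping[str, int]
    ) -> "ContactMatrix":
        return cls(sparse.csr_matrix(dense), bin_size, chrom_sizes)

    # -- indexing ----------------------------------------------------------

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(
                f"position {pos} outside {chrom} (size {self.chrom_sizes[chrom]})"
            )
        return self.offsets[chrom] + pos // self.bin_size

    def bin_location(self, i: int) -> tuple[str, int]:
        chrom = self.chroms[self.chrom_of_bin[i]]
        return chrom, (i - self.offsets[chrom]) * self.bin_size

    def chrom_slice(self, chrom: str) -> slice:
        o = self.offsets[chrom]
        return slice(o, o + self.bins_per_chrom[chrom])

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def is_symmetric(self, tol: float = 0.0) -> bool:
        diff = self.counts - self.counts.T
        return diff.nnz == 0 or np.abs(diff.data).max() <= tol

    def write_triplets(self, path: str | Path) -> None:
        """Write the upper triangle (incl. diagonal) as 'binA binB count' TSV."""
        coo = sparse.triu(self.counts).tocoo()
        with open(path, "w") as fh:
            fh.write("# binA\tbinB\tcount\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                v = int(v) if float(v).is_integer() else v
                fh.write(f"{i}\t{j}\t{v}\n")


@dataclass
class IcpTrack:
    """Per-bin ICP aligned with a ContactMatrix bin index.

    ``values[i]`` is in [0, 1], or NaN where the bin has zero total
    contacts (undefined).
    """

    values: np.ndarray
    bin_size: int
    chrom_sizes: dict[str, int]

    def per_chrom(self) -> dict[str, np.ndarray]:
        out = {}
        o = 0
        for c, s in self.chrom_sizes.items():
            n = -(-s // self.bin_size)
            out[c] = self.values[o : o + n]
            o += n
        return out

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom, vals in self.per_chrom().items():
            starts = np.arange(len(vals)) * self.bin_size
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "icp": vals}))
        return pd.concat(frames, ignore_index=True)

    def to_bedgraph(self, path: str | Path) -> None:
        df = self.to_dataframe().dropna(subset=["icp"])
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                end = min(row.start + self.bin_size, self.chrom_sizes[row.chrom])
                fh.write(f"{row.chrom}\t{row.start}\t{end}\t{row.icp:.6f}\n")


def compute_icp(cm: ContactMatrix, include_diagonal: bool = True) -> IcpTrack:
    """ICP per bin: interchromosomal counts over total counts.

    ``include_diagonal=False`` drops self-bin counts from the denominator.
    Raises on an asymmetric matrix (symmetrize at read time only).
    """
    if not cm.is_symmetric(tol=1e-9):
        raise ValueError("contact matrix is not symmetric")
    total = np.asarray(cm.counts.sum(axis=1)).ravel().astype(float)
    intra = np.empty_like(total)
    for chrom in cm.chroms:
        sl = cm.chrom_slice(chrom)
        block = cm.counts[sl, sl]
        intra[sl] = np.asarray(block.sum(axis=1)).ravel()
    if not include_diagonal:
        d = cm.counts.diagonal()
        total = total - d
        intra = intra - d
    inter = total - intra
    with np.errstate(invalid="ignore", divide="ignore"):
        icp = inter / total
    icp[total == 0] = np.nan
    return IcpTrack(icp, cm.bin_size, dict(cm.chrom_sizes))


@dataclass
class HubTrack:
    """Fixed-resolution bins labelled nucleolar / speckle / unassigned."""

    bins: pd.DataFrame  # chrom, start, end, label
    resolution: int

    def __post_init__(self) -> None:
        bad = set(self.bins["label"]) - set(HUB_LABELS)
        if bad:
            raise ValueError(f"unknown hub labels: {sorted(bad)}")

    @classmethod
    def from_bed_records(cls, records, resolution: int) -> "HubTrack":
        rows = []
        for rec in records:
            if rec.label is None:
                raise ValueError("hub BED needs a label column (column 4)")
            rows.append(
                {
                    "chrom": rec.interval.chrom,
                    "start": rec.interval.start,
                    "end": rec.interval.end,
                    "label": rec.label,
                }
            )
        return cls(pd.DataFrame(rows), resolution)

    def to_bed_records(self):
        from .io import BedRecord  # local import avoids a module cycle

        return [
            BedRecord(
                GenomicInterval(r.chrom, int(r.start), int(r.end)), (r.label,)
            )
            for r in self.bins.itertuples(index=False)
        ]


@dataclass
class HubComparison:
    """GC% contrast between speckle and nucleolar hub bins."""

    summaries: pd.DataFrame  # per-label boxplot five-number summary + mean, n
    t_statistic: float
    p_value: float
    mean_difference: float  # speckle mean GC - nucleolar mean GC
    test: str

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries.to_dict(orient="index"),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "test": self.test,
        }


def _five_number(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "n": int(len(x)),
    }


def _hub_gc_groups(
    hub_track: HubTrack, gc_track: GcTrack
) -> dict[str, np.ndarray]:
    if hub_track.resolution != gc_track.resolution:
        raise ValueError(
            f"hub resolution {hub_track.resolution} != GC track resolution "
            f"{gc_track.resolution}"
        )
    groups: dict[str, list[float]] = {lab: [] for lab in HUB_LABELS}
    for row in hub_track.bins.itertuples(index=False):
        vals = gc_track.gc.get(row.chrom)
        if vals is None:
            continue
        w = int(row.start) // gc_track.resolution
        if w < len(vals) and not np.isnan(vals[w]):
            groups[row.label].append(float(vals[w]))
    return {k: np.array(v) for k, v in groups.items()}


def hub_gc_comparison(
    hub_track: HubTrack, gc_track: GcTrack, test: str = "student"
) -> HubComparison:
    """Compare GC% of speckle vs nucleolar bins.

    ``test`` is ``student`` (pooled variance, the default) or ``welch``.
    Unassigned bins are summarized but excluded from the test.
    """
    groups = _hub_gc_groups(hub_track, gc_track)
    spk, nuc = groups["speckle"], groups["nucleolar"]
    if len(spk) == 0 or len(nuc) == 0:
        raise ValueError("both speckle and nucleolar groups must be non-empty")
    if len(spk) < 2 or len(nuc) < 2 or (np.std(spk) == 0 and np.std(nuc) == 0):
        raise ValueError("t-test undefined: need >= 2 values and variation per group")
    t, p = stats.ttest_ind(spk, nuc, equal_var=(test == "student"))
    summaries = pd.DataFrame(
        {lab: _five_number(v) for lab, v in groups.items() if len(v)}
    ).T
    return HubComparison(
        summaries, float(t), float(p), float(spk.mean() - nuc.mean()), test
    )


@dataclass
class IcpGcCorrelation:
    r: float
    p_value: float
    n: int
    table: pd.DataFrame  # chrom, start, gc, icp (paired, unmasked)


def _paired_table(gc_track: GcTrack, icp_track: IcpTrack) -> pd.DataFrame:
    if gc_track.resolution != icp_track.bin_size:
        raise ValueError("GC track and ICP track resolutions differ")
    icp_by_chrom = icp_track.per_chrom()
    frames = []
    for chrom in gc_track.chroms:
        if chrom not in icp_by_chrom:
            continue
        gc = gc_track.gc[chrom]
        icp = icp_by_chrom[chrom]
        n = min(len(gc), len(icp))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n) * gc_track.resolution,
                    "gc": gc[:n],
                    "icp": icp[:n],
                }
            )
        )
    if not frames:
        raise ValueError("no shared chromosomes between tracks")
    return pd.concat(frames, ignore_index=True)


def icp_gc_correlation(icp_track: IcpTrack, gc_track: GcTrack) -> IcpGcCorrelation:
    """Genome-wide Pearson correlation between per-bin ICP and GC%.

    Masked GC windows and undefined ICP bins are dropped pairwise.
    """
    table = _paired_table(gc_track, icp_track).dropna(subset=["gc", "icp"])
    if len(table) < 3:
        raise ValueError(f"only {len(table)} paired bins; need >= 3")
    if np.std(table["icp"]) == 0 or np.std(table["gc"]) == 0:
        raise ValueError("correlation undefined: a track is constant")
    r, p = stats.pearsonr(table["gc"], table["icp"])
    return IcpGcCorrelation(float(r), float(p), len(table), table)


@dataclass
class OlsFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    residual_sd: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class LinearContactModel:
    """OLS fits of ICP ~ GC and GC ~ ICP (reported separately: OLS is
    direction-dependent, the reverse slope is not the reciprocal unless
    |r| = 1)."""

    icp_on_gc: OlsFit
    gc_on_icp: OlsFit
    n: int

    def predict_icp(self, gc: np.ndarray) -> np.ndarray:
        return self.icp_on_gc.predict(gc)

    def predict_gc(self, icp: np.ndarray) -> np.ndarray:
        return self.gc_on_icp.predict(icp)


def _ols(x: np.ndarray, y: np.ndarray) -> OlsFit:
    if np.std(x) == 0:
        raise ValueError("zero predictor variance")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return OlsFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
        float(res.stderr),
        float(np.std(resid, ddof=2)) if len(x) > 2 else float("nan"),
    )


def linear_contact_model(
    gc_values: Sequence[float], icp_values: Sequence[float]
) -> LinearContactModel:
    """Fit the linear GC <-> contact-intensity model in both directions."""
    gc = np.asarray(gc_values, dtype=float)
    icp = np.asarray(icp_values, dtype=float)
    ok = ~(np.isnan(gc) | np.isnan(icp))
    gc, icp = gc[ok], icp[ok]
    if len(gc) < 3:
        raise ValueError("need >= 3 paired points")
    return LinearContactModel(_ols(gc, icp), _ols(icp, gc), len(gc))


def coprofile(gc_track: GcTrack, icp_track: IcpTrack, chrom: str) -> pd.DataFrame:
    """Aligned per-window (start, GC%, ICP) table for one chromosome.

    Masked windows are emitted as NaN (e.g. assembly gaps), preserving
    the window grid for plotting.
    """
    if chrom not in gc_track.chroms:
        raise KeyError(f"chromosome {chrom!r} not in GC track")
    icp_by_chrom = icp_track.per_chrom()
    if chrom not in icp_by_chrom:
        raise KeyError(f"chromosome {chrom!r} not in ICP track")
    table = _paired_table(gc_track, icp_track)
    return table[table["chrom"] == chrom].reset_index(drop=True)[
        ["start", "gc", "icp"]
    ]
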