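"""Windowed GC% tracks, binned TAD GC profiles and isochore families.

GC content is the fraction of G+C among unambiguous bases (A/C/G/T);
N and other IUPAC ambiguity codes are excluded from the denominator, and
a window or bin whose non-ACGT fraction exceeds ``mask_threshold`` is
masked (NaN). Soft-masked (lowercase) bases count as their base identity.

Isochore families reduce the classical L1/L2/H1/H2/H3 compositional
segments to fixed GC% cut-points applied to a TAD's mean GC:
L1 < 37 <= L2 < 41 <= H1 < 46 <= H2 < 53 <= H3, clamped outside the
nominal 33-59% range. Cut-points belong to the upper (GC-richer) family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "FAMILIES",
    "FAMILY_CUTS",
    "DEFAULT_MASK_THRESHOLD",
    "GcTrack",
    "TadProfile",
    "gc_content",
    "windowed_gc",
    "tad_gc_profile",
    "assign_family",
    "bin_edges",
    "profile_matrix",
]

#: Isochore families, GC-poorest to GC-richest.
FAMILIES = ("L1", "L2", "H1", "H2", "H3")

#: Upper GC% cut of each family except the last (half-open on the left).
FAMILY_CUTS = (37.0, 41.0, 46.0, 53.0)

DEFAULT_MASK_THRESHOLD = 0.5

# byte codes for vectorized base counting (upper and lower case)
_GC_BYTES = np.frombuffer(b"GCgc", dtype=np.uint8)
_AT_BYTES = np.frombuffer(b"ATat", dtype=np.uint8)


def _seq_to_bytes(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


def _gc_at_masks(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gc = np.isin(b, _GC_BYTES)
    at = np.isin(b, _AT_BYTES)
    return gc, at


def gc_content(sequence: str, mask_threshold: float = DEFAULT_MASK_THRESHOLD) -> float:
    """GC% of a sequence, or NaN if masked.

    Returns ``100 * (G+C) / (A+C+G+T)``. The result is NaN for an empty
    sequence or when the non-ACGT fraction exceeds ``mask_threshold``.
    """
    if not sequence:
        return float("nan")
    b = _seq_to_bytes(sequence)
    gc, at = _gc_at_masks(b)
    n_gc = int(gc.sum())
    n_acgt = n_gc + int(at.sum())
    if n_acgt == 0 or (len(b) - n_acgt) / len(b) > mask_threshold:
        return float("nan")
    return 100.0 * n_gc / n_acgt


@dataclass
class GcTrack:
    """Per-window GC% over a genome at fixed resolution.

    ``gc[chrom]`` holds one value per tiling window (NaN = masked);
    ``n_fraction[chrom]`` the non-ACGT fraction per window.
    """

    resolution: int
    gc: dict[str, np.ndarray]
    n_fraction: dict[str, np.ndarray]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.gc)

    def values(self, chrom: str) -> np.ndarray:
        return self.gc[chrom]

    def n_windows(self, chrom: str) -> int:
        return len(self.gc[chrom])

    def concat(self, chrom_order: list[str] | None = None) -> np.ndarray:
        order = chrom_order or self.chroms
        return np.concatenate([self.gc[c] for c in order])

    def window_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom), dtype=int) * self.resolution

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom in self.chroms:
            starts = self.window_starts(chrom)
            size = self.chrom_sizes.get(chrom, starts[-1] + self.resolution if len(starts) else 0)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": np.minimum(starts + self.resolution, size),
                        "gc": self.gc[chrom],
                        "n_fraction": self.n_fraction[chrom],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_bedgraph(self, path: str | Path) -> None:
        """Write unmasked windows as bedGraph (chrom, start, end, GC%)."""
        df = self.to_dataframe().dropna(subset=["gc"])
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gc:.4f}\n")


def windowed_gc(
    genome: Mapping[str, str],
    resolution: int,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> GcTrack:
    """Tile each chromosome with non-overlapping windows and compute GC%.

    The trailing partial window is kept when it covers at least 10% of
    ``resolution``, otherwise masked. Window count is
    ``ceil(length / resolution)`` either way.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    gc_out: dict[str, np.ndarray] = {}
    nf_out: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for chrom, seq in genome.items():
        length = len(seq)
        sizes[chrom] = length
        n_win = -(-length // resolution)
        b = _seq_to_bytes(seq)
        gc_mask, at_mask = _gc_at_masks(b)
        edges = np.arange(n_win, dtype=np.intp) * resolution
        gc_counts = np.add.reduceat(gc_mask, edges).astype(float)
        at_counts = np.add.reduceat(at_mask, edges).astype(float)
        win_len = np.full(n_win, resolution, dtype=float)
        if length % resolution:
            win_len[-1] = length % resolution
        acgt = gc_counts + at_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = 100.0 * gc_counts / acgt
            nf = (win_len - acgt) / win_len
        gc[acgt == 0] = np.nan
        gc[nf > mask_threshold] = np.nan
        if length % resolution and (length % resolution) < 0.1 * resolution:
            gc[-1] = np.nan
        gc_out[chrom] = gc
        nf_out[chrom] = nf
    return GcTrack(resolution, gc_out, nf_out, sizes)


def assign_family(mean_gc: float) -> str | None:
    """Isochore family of a mean GC%, clamped below 33 (L1) and above 59 (H3).

    Half-open lookup: a cut-point belongs to the GC-richer family, so
    41.0 -> H1. Masked (NaN) input returns None (unassigned).
    """
    if mean_gc is None or np.isnan(mean_gc):
        return None
    if not (0.0 <= mean_gc <= 100.0):
        raise ValueError(f"mean_gc out of range: {mean_gc}")
    for cut, fam in zip(FAMILY_CUTS, FAMILIES):
        if mean_gc < cut:
            return fam
    return FAMILIES[-1]


def bin_edges(length: int, n_bins: int) -> np.ndarray:
    """Offsets splitting ``length`` into ``n_bins`` near-equal bins.

    Bin lengths differ by at most 1 bp; the remainder goes to the
    leftmost bins. Returns ``n_bins + 1`` offsets starting at 0.
    """
    base, rem = divmod(length, n_bins)
    idx = np.arange(n_bins + 1, dtype=np.intp)
    return idx * base + np.minimum(idx, rem)


@dataclass
class TadProfile:
    """A TAD/loop interval with its binned GC profile.

    ``bins`` holds ``n_bins`` GC% values (NaN = masked bin); ``mean_gc``
    is the mean over unmasked bins and ``family`` the isochore family of
    that mean.
    """

    interval: GenomicInterval
    bins: np.ndarray
    mean_gc: float
    family: str | None
    tad_id: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def tad_gc_profile(
    genome: Mapping[str, str],
    interval: GenomicInterval,
    n_bins: int = 100,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    tad_id: str = "",
) -> TadProfile:
    """Split a TAD into ``n_bins`` near-equal bins and compute per-bin GC%."""
    length = interval.length
    if length < n_bins:
        raise ValueError(
            f"TAD {tad_id or interval} is {length} bp, shorter than n_bins={n_bins}; "
            "use a smaller n_bins"
        )
    seq = genome[interval.chrom][interval.start : interval.end]
    b = _seq_to_bytes(seq)
    gc_mask, at_mask = _gc_at_masks(b)
    edges = bin_edges(length, n_bins)
    starts = edges[:-1]
    lens = np.diff(edges).astype(float)
    gc_counts = np.add.reduceat(gc_mask, starts).astype(float)
    at_counts = np.add.reduceat(at_mask, starts).astype(float)
    acgt = gc_counts + at_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = 100.0 * gc_counts / acgt
        nf = (lens - acgt) / lens
    gc[acgt == 0] = np.nan
    gc[nf > mask_threshold] = np.nan
    mean_gc = float(np.nanmean(gc)) if np.any(~np.isnan(gc)) else float("nan")
    return TadProfile(interval, gc, mean_gc, assign_family(mean_gc), tad_id)


def profile_matrix(
    profiles: list[TadProfile],
) -> tuple[list[str], np.ndarray, np.ndarray, list[str | None]]:
    """Stack profiles into the N x n_bins GC matrix.

    Returns (tad ids, matrix, mean GC vector, families).
    """
    if not profiles:
        raise ValueError("no profiles given")
    ids = [p.tad_id for p in profiles]
    mat = np.vstack([p.bins for p in profiles])
    mean_gc = np.array([p.mean_gc for p in profiles])
    fams = [p.family for p in profiles]
    return ids, mat, mean_gc, fams
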