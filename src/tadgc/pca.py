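"""Unsupervised verification of gradient classes by PCA.

PCA of the N x 100 TAD GC matrix separates compositional level from
shape: the first component (F1) tracks mean GC almost perfectly, while
bell-like ({B, B-}) and valley-like ({C, C-}) shapes separate in the
(F2, F3) plane. Columns (bins) are centered but not scaled by default:
scaling bin columns to unit variance would erase the GC-level signal
that F1 carries. Both choices are exposed as flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.metrics import silhouette_score

__all__ = [
    "PcaResult",
    "SeparationReport",
    "fit_pca",
    "f1_gc_correlation",
    "cluster_separation",
]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of F1..Fk.

    Component signs follow a fixed convention: each loading vector is
    oriented so that its largest-magnitude element is positive.
    """

    scores: np.ndarray  # (N, k)
    loadings: np.ndarray  # (n_bins, k)
    explained_variance_fraction: np.ndarray  # (k,)
    centered: bool
    scaled: bool

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def component(self, i: int) -> np.ndarray:
        """Scores of component Fi (1-based, F1 = first)."""
        return self.scores[:, i - 1]

    def scores_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        cols = [f"F{i + 1}" for i in range(self.k)]
        df = pd.DataFrame(self.scores, columns=cols)
        if ids is not None:
            df.insert(0, "tad_id", ids)
        return df


def fit_pca(
    gc_matrix: np.ndarray,
    k: int = 3,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA of the N x n_bins GC matrix via SVD.

    Masked bins (NaN) are imputed with their row mean; a fully masked
    row is an error (exclude such TADs upstream). Deterministic up to
    the documented sign convention.
    """
    X = np.array(gc_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("gc_matrix must be 2-D")
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(N, n_bins)={min(n, m)}")
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1, keepdims=True)
        if np.isnan(row_means).any():
            raise ValueError("fully masked profile row; exclude it before PCA")
        X = np.where(np.isnan(X), row_means, X)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    evf = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    # sign convention: largest-|loading| element of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(scores, loadings, evf, center, scale)


def f1_gc_correlation(result: PcaResult, mean_gc: np.ndarray) -> float:
    """|Pearson r| between F1 scores and per-TAD mean GC%.

    Returns NaN (undefined) when either vector has zero variance.
    """
    f1 = result.component(1)
    mean_gc = np.asarray(mean_gc, dtype=float)
    if len(f1) != len(mean_gc):
        raise ValueError("length mismatch between scores and mean GC vector")
    if np.std(f1) == 0 or np.std(mean_gc) == 0:
        return float("nan")
    return abs(float(stats.pearsonr(f1, mean_gc)[0]))


@dataclass
class SeparationReport:
    """Separation of the bell-like vs valley-like super-groups in (F2, F3)."""

    class_centroids: dict[str, tuple[float, float]]
    group_centroids: dict[str, tuple[float, float]]
    silhouette: float
    centroid_accuracy: float
    n_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "class_centroids": {k: list(v) for k, v in self.class_centroids.items()},
            "group_centroids": {k: list(v) for k, v in self.group_centroids.items()},
            "silhouette": self.silhouette,
            "centroid_accuracy": self.centroid_accuracy,
            "n_per_group": self.n_per_group,
        }


def cluster_separation(
    result: PcaResult,
    labels: list[str] | np.ndarray,
    groups: tuple[tuple[str, ...], tuple[str, ...]] = (("B", "B-"), ("C", "C-")),
) -> SeparationReport:
    """Quantify super-group separation in the (F2, F3) plane.

    TADs whose class is in neither super-group are ignored. Reports
    per-class and per-group centroids, the silhouette coefficient of the
    two super-groups, and the accuracy of a nearest-group-centroid rule.
    """
    if result.k < 3:
        raise ValueError("need at least 3 components (F2, F3) for separation")
    labels = np.asarray(labels, dtype=object)
    pts = result.scores[:, 1:3]
    name = {c: "+".join(g) for g in groups for c in g}
    mask = np.array([lab in name for lab in labels])
    if not mask.any():
        raise ValueError("no TADs in either super-group")
    pts_used = pts[mask]
    labs_used = labels[mask]
    group_of = np.array([name[lab] for lab in labs_used], dtype=object)
    group_names = ["+".join(g) for g in groups]
    for g in group_names:
        if not np.any(group_of == g):
            raise ValueError(f"super-group {g!r} is empty")
    class_centroids = {
        c: tuple(pts_used[labs_used == c].mean(axis=0))
        for c in np.unique(labs_used)
    }
    group_centroids = {
        g: tuple(pts_used[group_of == g].mean(axis=0)) for g in group_names
    }
    cents = np.array([group_centroids[g] for g in group_names])
    d = np.linalg.norm(pts_used[:, None, :] - cents[None, :, :], axis=2)
    assigned = np.array(group_names, dtype=object)[np.argmin(d, axis=1)]
    accuracy = float(np.mean(assigned == group_of))
    sil = float(silhouette_score(pts_used, group_of.astype(str)))
    return SeparationReport(
        {str(k): (float(v[0]), float(v[1])) for k, v in class_centroids.items()},
        {k: (float(v[0]), float(v[1])) for k, v in group_centroids.items()},
        sil,
        accuracy,
        {g: int(np.sum(group_of == g)) for g in group_names},
    )
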