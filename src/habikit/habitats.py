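"""Habitat subregion delineation by K-means on dual-phase voxel intensities.

Every in-mask voxel contributes a 2-vector (arterial HU, venous HU).  The
voxels of one tumor are clustered with K-means for k = 2..10, the
Calinski-Harabasz (CH) score selects k, and cluster labels are renumbered so
subregion 1 is the most enhancing (largest mean arterial + venous HU),
giving a cross-patient correspondence by enhancement rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .preprocessing import DualPhaseCase

__all__ = [
    "VoxelFeatureMatrix",
    "ClusteringResult",
    "HabitatLabelMap",
    "build_voxel_vectors",
    "kmeans",
    "calinski_harabasz",
    "select_k",
    "select_k_cohort",
    "order_subregions",
    "compute_habitats",
]

DEFAULT_K_RANGE = range(2, 11)


@dataclass
class VoxelFeatureMatrix:
    """Rows = in-mask voxels, columns = (arterial HU, venous HU)."""

    matrix: np.ndarray              # (n_voxels, 2)
    coords: tuple[np.ndarray, ...]  # z, y, x index arrays into the grid
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def scatter(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Place one value per voxel back onto the 3-D grid."""
        out = np.full(self.shape, fill, dtype=np.asarray(values).dtype)
        out[self.coords] = values
        return out


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray      # 1..k per voxel
    centroids: np.ndarray   # (k, 2) HU
    ch_score: float
    inertia: float
    seed: int


@dataclass
class HabitatLabelMap:
    """3-D integer volume: 0 outside the mask, 1..k inside, 1 = most enhancing."""

    volume: np.ndarray
    k: int
    ordering: str = "enhancement_desc"

    def region_mask(self, label: int) -> np.ndarray:
        return self.volume == label


def build_voxel_vectors(case: DualPhaseCase) -> VoxelFeatureMatrix:
    """One row per mask voxel; column order (arterial, venous)."""
    coords = np.nonzero(case.mask)
    if coords[0].size == 0:
        raise ValueError("empty mask")
    mat = np.column_stack([case.arterial[coords], case.venous[coords]]).astype(float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite intensities in mask")
    return VoxelFeatureMatrix(matrix=mat, coords=coords, shape=tuple(case.mask.shape))


def kmeans(
    matrix: np.ndarray | VoxelFeatureMatrix,
    k: int,
    seed: int = 42,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Lloyd's K-means with k-means++ seeding, best of ``n_init`` restarts."""
    X = matrix.matrix if isinstance(matrix, VoxelFeatureMatrix) else np.asarray(matrix, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} voxels < k={k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(int) + 1
    return ClusteringResult(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_.copy(),
        ch_score=calinski_harabasz(X, labels),
        inertia=float(km.inertia_),
        seed=seed,
    )


def calinski_harabasz(matrix: np.ndarray | VoxelFeatureMatrix, labels: np.ndarray) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] with B/W the between/within cluster SSE.

    Perfect separation (W = 0) returns ``inf``; identical cluster means
    (B = 0) return 0.
    """
    X = matrix.matrix if isinstance(matrix, VoxelFeatureMatrix) else np.asarray(matrix, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = uniq.size, X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for u in uniq:
        sub = X[labels == u]
        c = sub.mean(axis=0)
        between += sub.shape[0] * float(((c - grand) ** 2).sum())
        within += float(((sub - c) ** 2).sum())
    if within == 0.0:
        return float("inf") if between > 0 else 0.0
    return (between / (k - 1)) / (within / (n - k))


def select_k(
    matrix: np.ndarray | VoxelFeatureMatrix,
    k_range=DEFAULT_K_RANGE,
    seed: int = 42,
    n_init: int = 10,
) -> tuple[int, dict[int, ClusteringResult]]:
    """Run K-means over ``k_range`` and pick the CH-maximizing k (ties -> smallest)."""
    results: dict[int, ClusteringResult] = {}
    best_k, best_score = None, -np.inf
    for k in k_range:
        res = kmeans(matrix, k, seed=seed, n_init=n_init)
        results[k] = res
        if res.ch_score > best_score:
            best_k, best_score = k, res.ch_score
    assert best_k is not None
    return best_k, results


def select_k_cohort(
    matrices, k_range=DEFAULT_K_RANGE, seed: int = 42, n_init: int = 10
) -> tuple[int, dict]:
    """Cohort-level k: argmax of the mean per-case CH score at each k.

    Returns (best_k, {"mean_ch": {k: score}, "per_case_best_k": [...]}), so a
    single cluster count can be fixed for a whole cohort while the per-case
    argmaxes remain logged.  Infinite per-case scores (perfect separation)
    are excluded from the mean but recorded.
    """
    ks = list(k_range)
    scores = {k: [] for k in ks}
    per_case_best = []
    for matrix in matrices:
        best_k, results = select_k(matrix, k_range=ks, seed=seed, n_init=n_init)
        per_case_best.append(best_k)
        for k, res in results.items():
            scores[k].append(res.ch_score)
    mean_ch = {
        k: float(np.mean([s for s in v if np.isfinite(s)]) if any(np.isfinite(v)) else np.inf)
        for k, v in scores.items()
    }
    best = max(ks, key=lambda k: (mean_ch[k], -k))
    return best, {"mean_ch": mean_ch, "per_case_best_k": per_case_best}


def order_subregions(result: ClusteringResult, matrix: VoxelFeatureMatrix) -> HabitatLabelMap:
    """Renumber clusters so label 1 has the largest mean arterial + venous HU.

    Ties break by arterial mean, then by cluster size (larger first).
    """
    X = matrix.matrix
    stats = []
    for lbl in range(1, result.k + 1):
        sel = result.labels == lbl
        sums = X[sel].sum(axis=0) / max(sel.sum(), 1)
        stats.append((-(sums[0] + sums[1]), -sums[0], -int(sel.sum()), lbl))
    order = [lbl for *_, lbl in sorted(stats)]
    remap = np.empty(result.k + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    new_labels = remap[result.labels]
    return HabitatLabelMap(volume=matrix.scatter(new_labels, fill=0), k=result.k)


def compute_habitats(
    case: DualPhaseCase,
    k: int | None = None,
    k_range=DEFAULT_K_RANGE,
    seed: int = 42,
    n_init: int = 10,
) -> tuple[HabitatLabelMap, dict[int, ClusteringResult]]:
    """Cluster one case into habitats; fixed ``k`` or CH-selected over ``k_range``."""
    vfm = build_voxel_vectors(case)
    if k is not None:
        res = kmeans(vfm, k, seed=seed, n_init=n_init)
        return order_subregions(res, vfm), {k: res}
    best_k, results = select_k(vfm, k_range=k_range, seed=seed, n_init=n_init)
    return order_subregions(results[best_k], vfm), results
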