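"""Tree-island detection by hierarchical clustering.

Trees that share similar topologies form discrete clusters ("islands") in
the landscape. This module cuts an agglomerative dendrogram -- built with
single, complete, UPGMA (average) or Ward linkage -- at exactly k groups.
The default clustering basis is the retained MDS coordinates (clustering on
the projected distances); clustering directly on the raw distance matrix is
available as well. Ward linkage uses scipy's implementation on condensed
distances (the ward.D2-style criterion operating on Euclidean distances),
which is coherent with the Euclidean embedding.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .distances import DistanceMatrix
from .landscape import LandscapeEmbedding

__all__ = [
    "LINKAGES",
    "IslandPartition",
    "find_islands",
    "cut_heights",
    "silhouette_profile",
    "IslandFinder",
]

#: exposed linkage name -> scipy method name
LINKAGES = {
    "single": "single",
    "complete": "complete",
    "upgma": "average",
    "ward": "ward",
}


@dataclass
class IslandPartition:
    """Cluster labels (1..k) over a tree collection."""

    labels: np.ndarray
    k: int
    linkage: str
    basis: str  # "raw_distances" or "mds_coordinates"
    n_axes_used: int | None = None

    def members(self, island_id: int) -> np.ndarray:
        """Indices of the trees assigned to *island_id*."""
        return np.flatnonzero(self.labels == island_id)

    def to_tsv(self, path, tree_names) -> None:
        df = pd.DataFrame({"tree": tree_names, "island": self.labels})
        df.to_csv(path, sep="\t", index=False)


def _condensed_input(x):
    """Condensed distances + basis tag from matrix/embedding/array input."""
    if isinstance(x, DistanceMatrix):
        return squareform(x.values, checks=False), "raw_distances", None
    if isinstance(x, LandscapeEmbedding):
        return pdist(x.coordinates), "mds_coordinates", x.n_axes_retained
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:  # already condensed
        return a, "raw_distances", None
    if a.ndim != 2:
        raise ValueError("input must be a matrix, embedding or coordinate array")
    if a.shape[0] == a.shape[1] and np.allclose(a, a.T, rtol=0, atol=1e-12) \
            and np.all(np.diag(a) == 0):
        return squareform(a, checks=False), "raw_distances", None
    return pdist(a), "mds_coordinates", a.shape[1]


def _linkage_matrix(x, linkage: str):
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(LINKAGES)}")
    cond, basis, n_axes = _condensed_input(x)
    Z = hierarchy.linkage(cond, method=LINKAGES[linkage])
    return Z, basis, n_axes


def find_islands(x, k: int, linkage: str = "ward") -> IslandPartition:
    """Cut the dendrogram of *x* into exactly *k* islands.

    Parameters
    ----------
    x : DistanceMatrix, LandscapeEmbedding or ndarray
        An embedding clusters on Euclidean distances over its retained
        axes; a square symmetric array is treated as precomputed distances,
        any other 2-D array as coordinates.
    k : int
        Number of islands, ``1 <= k <= n_trees``.
    linkage : {"single", "complete", "upgma", "ward"}

    Returns
    -------
    IslandPartition
        Labels 1..k, numbered by first appearance in tree order, so the
        result is deterministic and invariant to label permutations of the
        underlying clustering routine.
    """
    Z, basis, n_axes = _linkage_matrix(x, linkage)
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return IslandPartition(labels, k, linkage, basis, n_axes)


def cut_heights(x, linkage: str = "ward") -> np.ndarray:
    """The n_trees - 1 agglomeration heights of the dendrogram of *x*.

    Nondecreasing for single/complete/UPGMA/Ward on metric input; a large
    jump before the final merges signals well-separated islands.
    """
    Z, _, _ = _linkage_matrix(x, linkage)
    return Z[:, 2].copy()


def silhouette_profile(x, k_values, linkage: str = "ward") -> dict[int, float]:
    """Silhouette score for each candidate k (a helper for choosing k by
    inspection; never applied automatically)."""
    cond, _, _ = _condensed_input(x)
    D = squareform(cond)
    out = {}
    for k in k_values:
        if not 2 <= k <= D.shape[0] - 1:
            continue
        part = find_islands(x, k, linkage)
        out[k] = float(silhouette_score(D, part.labels, metric="precomputed"))
    return out


class IslandFinder:
    """Sklearn-style agglomerative island detector.

    Parameters
    ----------
    n_clusters : int, default 2
    linkage : {"single", "complete", "upgma", "ward"}, default "ward"

    Attributes (after :meth:`fit`)
    ------------------------------
    partition_ : IslandPartition
    labels_ : ndarray of int (1..k)
    heights_ : ndarray
        The agglomeration (merge) heights.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "ward"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "linkage": self.linkage}

    def set_params(self, **params) -> "IslandFinder":
        for k, v in params.items():
            if k not in ("n_clusters", "linkage"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "IslandFinder":
        self.partition_ = find_islands(X, self.n_clusters, self.linkage)
        self.labels_ = self.partition_.labels
        self.heights_ = cut_heights(X, self.linkage)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.labels_
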