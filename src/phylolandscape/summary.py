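"""Geometric median trees: one representative tree per island.

For each island the Kendall-Colijn vectors of its member trees are
averaged, and the median tree(s) are the member(s) whose vector is closest
(Euclidean) to that mean. Because the median is an argmin over the sample
-- the mean vector itself is never converted back to a tree -- the
representative is always an actual tree from the collection, avoiding the
implausible negative branch lengths that averaged consensus trees can
produce. Ties (e.g. duplicated topologies at lambda = 0) are all reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .islands import IslandPartition
from .metrics import collection_vectors
from .trees import TreeCollection, write_trees

__all__ = ["MedianResult", "median_trees", "summarise_islands"]


@dataclass
class MedianResult:
    """Median tree(s) of one island.

    Indices are positions in the full collection; ``distances_to_mean``
    is aligned with ``member_indices``.
    """

    island_id: int
    member_indices: np.ndarray
    median_indices: list[int]
    mean_vector: np.ndarray
    distances_to_mean: np.ndarray


def _labels_array(partition, n: int) -> np.ndarray:
    if isinstance(partition, IslandPartition):
        labels = partition.labels
    else:
        labels = np.asarray(partition, dtype=int)
    if labels.shape != (n,):
        raise ValueError("partition labels do not match the collection size")
    return labels


def median_trees(coll: TreeCollection, partition, lam: float = 0.0) -> list[MedianResult]:
    """Geometric median tree(s) of every island.

    Parameters
    ----------
    coll : TreeCollection
    partition : IslandPartition or integer array of labels
    lam : float in [0, 1]
        Kendall-Colijn blend weight; lam > 0 requires branch lengths.

    Returns
    -------
    list of MedianResult, one per island in increasing island id. All
    member trees attaining the minimal distance to the island's mean
    vector are reported as medians.
    """
    labels = _labels_array(partition, len(coll))
    X, _ = collection_vectors(coll, "kc", lam)
    results = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        mu = X[idx].mean(axis=0)
        d = np.linalg.norm(X[idx] - mu, axis=1)
        med = [int(i) for i in idx[d == d.min()]]
        results.append(MedianResult(int(g), idx, med, mu, d))
    return results


def summarise_islands(coll: TreeCollection, partition, lam: float = 0.0,
                      newick_path=None, tsv_path=None) -> list[MedianResult]:
    """Compute per-island medians and optionally write them out.

    ``newick_path`` receives one median tree per island (the lowest tree
    index on ties), one per line in island order -- every output tree is a
    verbatim member of the input collection. ``tsv_path`` receives the
    per-tree distance to its island's mean vector, with the median flag.
    """
    results = median_trees(coll, partition, lam)
    if newick_path is not None:
        medians = [r.median_indices[0] for r in results]
        names = [f"island_{r.island_id}_median" for r in results]
        write_trees(TreeCollection([coll.trees[i] for i in medians], names),
                    newick_path)
    if tsv_path is not None:
        rows = []
        for r in results:
            for pos, i in enumerate(r.member_indices):
                rows.append({
                    "tree": coll.names[i],
                    "island": r.island_id,
                    "distance_to_mean": r.distances_to_mean[pos],
                    "is_median": int(i in r.median_indices),
                })
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False,
                                  float_format="%.10g")
    return results
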