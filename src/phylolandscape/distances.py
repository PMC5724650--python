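"""Pairwise tree-distance matrices for a collection.

For the vector metrics the distance between two trees is the Euclidean (or,
for ``path_l1``, the L1) norm of the difference of their feature vectors;
the whole matrix is computed in one vectorized ``pdist`` call over the
stacked feature matrix. Robinson-Foulds distances are the symmetric
difference of non-trivial split sets, computed as the L1 distance between
0/1 split-indicator rows over the union of splits -- entrywise identical to
the per-pair set computation but vectorized.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

import dendropy

from .metrics import METRICS, collection_vectors, split_set
from .trees import LabelMismatchError, TreeCollection, tip_labels

__all__ = ["DistanceMatrix", "distance_matrix", "rf_distance"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative tree-distance matrix, tagged with its metric."""

    values: np.ndarray
    tree_names: list[str]
    metric: str
    lam: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.tree_names):
            raise ValueError("tree_names length does not match matrix size")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distance matrix must be nonnegative")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def condensed(self) -> np.ndarray:
        """Upper-triangle (scipy condensed) form."""
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        """Square TSV with tree names as header row and column."""
        df = pd.DataFrame(self.values, index=self.tree_names, columns=self.tree_names)
        df.to_csv(path, sep="\t", float_format="%.10g", index_label="tree")

    def to_phylip(self, path) -> None:
        """PHYLIP square distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for name, row in zip(self.tree_names, self.values):
                fh.write(name + "  " + "  ".join(f"{x:.10g}" for x in row) + "\n")


def distance_matrix(coll: TreeCollection, metric: str = "kc",
                    lam: float = 0.0) -> DistanceMatrix:
    """Pairwise distances between all trees in *coll* under *metric*.

    Parameters
    ----------
    coll : TreeCollection
    metric : one of ``kc, path, path_l1, branch_score, abouheif, sum_dd, rf``
    lam : float in [0, 1]
        Kendall-Colijn blend weight (ignored by other metrics).

    Raises
    ------
    PreconditionError
        With the offending tree index, when a tree violates the metric's
        requirements (unrooted root for kc, missing branch lengths for
        lam > 0 or branch_score).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X, _ = collection_vectors(coll, metric, lam)
    if metric in ("path_l1", "rf"):
        cond = pdist(X, "cityblock")
    else:
        cond = pdist(X, "euclidean")
    values = squareform(cond)
    return DistanceMatrix(values, list(coll.names), metric,
                          lam if metric == "kc" else None)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: |splits(t1) symdiff splits(t2)|.

    Counts non-trivial bipartitions of the unrooted split sets (trivial
    single-tip splits excluded); this is the raw symmetric difference, not
    halved or normalized. Both trees must share the same tip-label set.
    """
    l1 = sorted(tip_labels(t1))
    l2 = sorted(tip_labels(t2))
    if l1 != l2:
        diff = sorted(set(l1) ^ set(l2))
        raise LabelMismatchError(
            f"trees have different tip-label sets; symmetric difference: {diff}"
        )
    return len(split_set(t1, l1) ^ split_set(t2, l1))
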