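"""Per-tree feature vectors for the supported tree metrics.

Every metric here (except the split-based ones) maps a rooted labelled tree
to a fixed-length real vector indexed by unordered tip pairs in a canonical
order -- lexicographically sorted labels, pair (i, j) with label_i < label_j,
ordered as ``itertools.combinations(sorted_labels, 2)``. Distances between
trees are then plain (L2 or L1) norms of vector differences, which is what
makes the whole landscape construction possible.

Metrics
-------
kc
    Kendall-Colijn lambda-blend. For each tip pair (i, j), the topological
    entry m_ij is the number of edges from the root down to MRCA(i, j) and
    the length entry M_ij is the sum of branch lengths on that path; the
    vector ends with n per-tip slots equal to 1 in m and to the tip's
    pendant branch length in M. The returned vector is
    v_lambda = (1 - lambda) * m + lambda * M, so lambda = 0 is purely
    topological and lambda = 1 purely length-based.
path
    Steel-Penny path difference: entry (i, j) is the number of edges on the
    tip-to-tip path in the tree as given (the root node counts as a node on
    paths crossing it). Distances use L2 (``path``) or L1 (``path_l1``,
    the Williams-Clifford variant).
abouheif / sum_dd
    Product (resp. sum) over the internal nodes on the path between tips i
    and j -- the nodes strictly between each tip and the MRCA, plus the MRCA
    itself -- of each node's number of direct descendants (child count).
branch_score
    Kuhner-Felsenstein: a sparse map from each bipartition (split) of the
    tip set to its branch length; the two root edges of a rooted tree induce
    the same split and their lengths are summed (the unrooted convention).
    Distance is the L2 norm over the union of splits, absent splits
    contributing length 0.
rf (split sets)
    Non-trivial splits only, used for the Robinson-Foulds symmetric
    difference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import dendropy

from .trees import (
    MissingBranchLengthsError,
    PreconditionError,
    TreeCollection,
    UnrootedTreeError,
    check_rooted,
    has_branch_lengths,
    tip_labels,
)

__all__ = [
    "TreeVector",
    "SplitVector",
    "VECTOR_METRICS",
    "METRICS",
    "kc_vector",
    "path_vector",
    "abouheif_vector",
    "sum_dd_vector",
    "branch_score_vector",
    "split_set",
    "split_lengths",
    "pair_names",
    "collection_vectors",
    "TreeVectorizer",
]

#: metrics whose feature vector is indexed by tip pairs (plus tip slots for kc)
VECTOR_METRICS = ("kc", "path", "path_l1", "abouheif", "sum_dd")
#: all metric identifiers accepted by :func:`phylolandscape.distance_matrix`
METRICS = VECTOR_METRICS + ("branch_score", "rf")


@dataclass
class TreeVector:
    """The feature vector of one tree under one metric."""

    metric: str
    entries: np.ndarray
    feature_names: list[str]
    n_tips: int
    lam: float | None = None


@dataclass
class SplitVector:
    """Sparse split -> branch length map (branch-score feature 'vector').

    Splits are encoded as bitmasks over the canonical (sorted) label order,
    canonicalized to the side *not* containing the first label, so split
    identity is independent of which side of the bipartition is named.
    """

    splits: dict[int, float]
    labels: list[str]
    metric: str = "branch_score"


def pair_names(labels: list[str]) -> list[str]:
    return [f"{a}|{b}" for a, b in combinations(labels, 2)]


def _pair_pos(i: int, j: int, n: int) -> int:
    # condensed index for i < j, matching combinations(range(n), 2)
    return n * i - i * (i + 1) // 2 + (j - i - 1)


def _resolve_labels(tree: dendropy.Tree, labels) -> list[str]:
    tl = sorted(tip_labels(tree))
    if labels is None:
        return tl
    labels = list(labels)
    if sorted(labels) != tl:
        raise PreconditionError(
            "tree tip labels do not match the requested canonical label set"
        )
    return labels


class _TreeIndex:
    """One-pass annotations of a tree against a canonical label order."""

    def __init__(self, tree: dendropy.Tree, labels: list[str]):
        self.labels = labels
        n = len(labels)
        self.n = n
        pos = {lab: i for i, lab in enumerate(labels)}
        depth_e: dict = {}
        depth_l: dict = {}
        dd: dict = {}
        leaf = [None] * n
        pendant = np.zeros(n)
        for nd in tree.preorder_node_iter():
            par = nd.parent_node
            if par is None:
                depth_e[nd] = 0
                depth_l[nd] = 0.0
            else:
                depth_e[nd] = depth_e[par] + 1
                depth_l[nd] = depth_l[par] + (nd.edge.length or 0.0)
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                i = pos[lab]
                leaf[i] = nd
                pendant[i] = nd.edge.length or 0.0
            else:
                dd[nd] = nd.num_child_nodes()
        self.depth_e = depth_e
        self.depth_l = depth_l
        self.dd = dd
        self.leaf = leaf
        self.pendant = pendant

        # MRCA per tip pair: at each internal node, cross pairs of the child
        # subtree tip sets have that node as their MRCA. O(n^2) overall.
        mrca = [None] * (n * (n - 1) // 2)
        tipsets: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                tipsets[nd] = [pos[lab]]
            else:
                childsets = [tipsets.pop(c) for c in nd.child_nodes()]
                for x in range(len(childsets)):
                    for y in range(x + 1, len(childsets)):
                        for a in childsets[x]:
                            for b in childsets[y]:
                                i, j = (a, b) if a < b else (b, a)
                                mrca[_pair_pos(i, j, n)] = nd
                merged = []
                for s in childsets:
                    merged.extend(s)
                tipsets[nd] = merged
        self.mrca = mrca

    def ancestors(self, i: int):
        """Ancestor nodes of tip i, from its parent up to the root."""
        out = []
        nd = self.leaf[i].parent_node
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out


def kc_vector(tree: dendropy.Tree, lam: float = 0.0, labels=None) -> TreeVector:
    """Kendall-Colijn lambda-blended vector of a rooted tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Must have a bifurcating root (the root-to-MRCA path count is
        undefined under a basal polytomy). Non-root multifurcations are
        accepted: MRCA depths remain well defined.
    lam : float in [0, 1]
        Blend weight: 0 = topology only, 1 = branch lengths only.
        lam > 0 requires branch lengths on every edge.
    labels : list of str, optional
        Canonical tip order; defaults to the tree's sorted labels.

    Returns
    -------
    TreeVector
        n(n-1)/2 pair entries in canonical pair order followed by n per-tip
        slots in canonical label order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if not check_rooted(tree):
        raise UnrootedTreeError(
            "Kendall-Colijn vector requires a rooted tree with a bifurcating "
            f"root; found a root with {len(tree.seed_node.child_nodes())} children"
        )
    lengths = has_branch_lengths(tree)
    if lam > 0 and not lengths:
        raise MissingBranchLengthsError(
            "lambda > 0 requires branch lengths on every edge"
        )
    labels = _resolve_labels(tree, labels)
    ix = _TreeIndex(tree, labels)
    n = ix.n
    npairs = n * (n - 1) // 2
    m = np.empty(npairs)
    M = np.empty(npairs)
    for p, nd in enumerate(ix.mrca):
        m[p] = ix.depth_e[nd]
        M[p] = ix.depth_l[nd]
    mfull = np.concatenate([m, np.ones(n)])
    Mfull = np.concatenate([M, ix.pendant])
    entries = (1.0 - lam) * mfull + lam * Mfull
    return TreeVector("kc", entries, pair_names(labels) + list(labels), n, lam)


def path_vector(tree: dendropy.Tree, labels=None) -> TreeVector:
    """Topological path-difference vector: edge counts between tip pairs."""
    labels = _resolve_labels(tree, labels)
    ix = _TreeIndex(tree, labels)
    n = ix.n
    entries = np.empty(n * (n - 1) // 2)
    p = 0
    for i, j in combinations(range(n), 2):
        v = ix.mrca[p]
        entries[p] = (
            ix.depth_e[ix.leaf[i]] + ix.depth_e[ix.leaf[j]] - 2 * ix.depth_e[v]
        )
        p += 1
    return TreeVector("path", entries, pair_names(labels), n)


def _dd_path_values(ix: _TreeIndex, i: int, j: int, p: int) -> list[int]:
    """Child counts of the internal nodes on the tip i -- tip j path."""
    v = ix.mrca[p]
    vals = [ix.dd[v]]
    for nd in ix.ancestors(i):
        if nd is v:
            break
        vals.append(ix.dd[nd])
    for nd in ix.ancestors(j):
        if nd is v:
            break
        vals.append(ix.dd[nd])
    return vals


def abouheif_vector(tree: dendropy.Tree, labels=None) -> TreeVector:
    """Abouheif dissimilarity vector: product of direct-descendant counts
    over the internal nodes (MRCA included) on each tip-to-tip path."""
    labels = _resolve_labels(tree, labels)
    ix = _TreeIndex(tree, labels)
    n = ix.n
    entries = np.empty(n * (n - 1) // 2)
    p = 0
    for i, j in combinations(range(n), 2):
        entries[p] = math.prod(_dd_path_values(ix, i, j, p))
        p += 1
    return TreeVector("abouheif", entries, pair_names(labels), n)


def sum_dd_vector(tree: dendropy.Tree, labels=None) -> TreeVector:
    """Sum-of-direct-descendants vector: as Abouheif but summing the child
    counts along the path instead of multiplying them."""
    labels = _resolve_labels(tree, labels)
    ix = _TreeIndex(tree, labels)
    n = ix.n
    entries = np.empty(n * (n - 1) // 2)
    p = 0
    for i, j in combinations(range(n), 2):
        entries[p] = sum(_dd_path_values(ix, i, j, p))
        p += 1
    return TreeVector("sum_dd", entries, pair_names(labels), n)


# ---------------------------------------------------------------------------
# splits


def _split_length_map(tree: dendropy.Tree, labels: list[str]) -> dict[int, float]:
    """Canonical split bitmask -> summed branch length, unrooted convention.

    Each non-root edge contributes the bipartition induced by removing it.
    The mask of the subtree side is canonicalized to the side not containing
    labels[0] (bit 0 cleared); the two edges below a bifurcating root induce
    the same split and their lengths add up.
    """
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    full = (1 << n) - 1
    masks: dict = {}
    out: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            masks[nd] = 1 << pos[lab]
        else:
            m = 0
            for c in nd.child_nodes():
                m |= masks[c]
            masks[nd] = m
        if nd.parent_node is None:
            continue
        mask = masks[nd]
        if mask == full:
            continue
        canon = mask if not (mask & 1) else mask ^ full
        out[canon] = out.get(canon, 0.0) + (nd.edge.length or 0.0)
    return out


def split_lengths(tree: dendropy.Tree, labels=None) -> dict[int, float]:
    """All splits (trivial pendant splits included) with branch lengths."""
    labels = _resolve_labels(tree, labels)
    return _split_length_map(tree, labels)


def split_set(tree: dendropy.Tree, labels=None) -> set[int]:
    """Non-trivial splits of the (implicitly unrooted) tree as canonical masks."""
    labels = _resolve_labels(tree, labels)
    n = len(labels)
    return {
        s
        for s in _split_length_map(tree, labels)
        if s.bit_count() not in (1, n - 1)
    }


def branch_score_vector(tree: dendropy.Tree, labels=None) -> SplitVector:
    """Kuhner-Felsenstein sparse split -> length vector.

    Requires branch lengths; the branch-score distance between two trees is
    the L2 norm of the difference over the union of their splits, with
    length 0 for splits absent from a tree.
    """
    if not has_branch_lengths(tree):
        raise MissingBranchLengthsError(
            "branch-score vector requires branch lengths on every edge"
        )
    labels = _resolve_labels(tree, labels)
    return SplitVector(_split_length_map(tree, labels), list(labels))


def split_feature_name(mask: int, labels: list[str]) -> str:
    side = [labels[i] for i in range(len(labels)) if mask >> i & 1]
    return ",".join(side)


# ---------------------------------------------------------------------------
# collection-level stacking


def collection_vectors(coll: TreeCollection, metric: str, lam: float = 0.0):
    """Stack the feature vectors of every tree in a collection.

    Parameters
    ----------
    coll : TreeCollection
    metric : one of :data:`METRICS`
        ``path_l1`` shares the ``path`` vector (the norms differ, not the
        features). For ``branch_score`` and ``rf`` the columns are the union
        of splits observed in the collection (absent splits are 0), which
        yields distances identical to per-pair union computations.
    lam : float
        Kendall-Colijn blend weight (ignored by other metrics).

    Returns
    -------
    (X, feature_names) : (ndarray of shape (n_trees, n_features), list of str)
    """
    labels = coll.labels
    base = "path" if metric == "path_l1" else metric
    if base in VECTOR_METRICS:
        fn = {
            "kc": lambda t: kc_vector(t, lam, labels),
            "path": lambda t: path_vector(t, labels),
            "abouheif": lambda t: abouheif_vector(t, labels),
            "sum_dd": lambda t: sum_dd_vector(t, labels),
        }[base]
        rows = []
        names = None
        for i, tree in enumerate(coll.trees):
            try:
                tv = fn(tree)
            except PreconditionError as exc:
                raise type(exc)(f"tree {i} ({coll.names[i]}): {exc}") from None
            rows.append(tv.entries)
            names = tv.feature_names
        return np.vstack(rows), names
    if base == "branch_score":
        maps = []
        for i, tree in enumerate(coll.trees):
            try:
                maps.append(branch_score_vector(tree, labels).splits)
            except PreconditionError as exc:
                raise type(exc)(f"tree {i} ({coll.names[i]}): {exc}") from None
        union = sorted(set().union(*maps))
        col = {s: k for k, s in enumerate(union)}
        X = np.zeros((len(coll), len(union)))
        for r, mp in enumerate(maps):
            for s, ln in mp.items():
                X[r, col[s]] = ln
        return X, [split_feature_name(s, labels) for s in union]
    if base == "rf":
        sets = [split_set(tree, labels) for tree in coll.trees]
        union = sorted(set().union(*sets))
        col = {s: k for k, s in enumerate(union)}
        X = np.zeros((len(coll), len(union)))
        for r, ss in enumerate(sets):
            for s in ss:
                X[r, col[s]] = 1.0
        return X, [split_feature_name(s, labels) for s in union]
    raise ValueError(f"unknown metric: {metric!r}")


class TreeVectorizer:
    """Map a tree collection to its metric feature matrix (sklearn-style).

    Parameters
    ----------
    metric : str, default "kc"
        One of :data:`METRICS`.
    lam : float, default 0.0
        Kendall-Colijn blend weight.

    Attributes
    ----------
    labels_ : list of str
        Canonical tip order learned in :meth:`fit`.
    feature_names_ : list of str
        Column names of the transformed matrix. For split-based metrics
        the basis is the union of splits of the *fitted* collection, so
        transforming a different collection requires its splits to be a
        subset of the fitted union.
    """

    def __init__(self, metric: str = "kc", lam: float = 0.0):
        self.metric = metric
        self.lam = lam

    # minimal BaseEstimator protocol (kept dependency-light)
    def get_params(self, deep: bool = True) -> dict:
        return {"metric": self.metric, "lam": self.lam}

    def set_params(self, **params) -> "TreeVectorizer":
        for k, v in params.items():
            if k not in ("metric", "lam"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, coll: TreeCollection, y=None) -> "TreeVectorizer":
        X, names = collection_vectors(coll, self.metric, self.lam)
        self.labels_ = list(coll.labels)
        self.feature_names_ = names
        self._fitted_X = X
        self._fitted_names = coll.names
        return self

    def transform(self, coll: TreeCollection) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("TreeVectorizer is not fitted")
        X, names = collection_vectors(coll, self.metric, self.lam)
        if names == self.feature_names_:
            return X
        if self.metric in ("branch_score", "rf"):
            col = {nm: k for k, nm in enumerate(self.feature_names_)}
            out = np.zeros((X.shape[0], len(self.feature_names_)))
            for j, nm in enumerate(names):
                if nm not in col:
                    raise PreconditionError(
                        f"collection contains a split absent from the fitted "
                        f"basis: {nm}"
                    )
                out[:, col[nm]] = X[:, j]
            return out
        raise PreconditionError("collection labels differ from the fitted labels")

    def fit_transform(self, coll: TreeCollection, y=None) -> np.ndarray:
        self.fit(coll)
        return self._fitted_X
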