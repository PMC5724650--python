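"""Synthetic tree collections with known island structure.

Stands in for the tree sets a real analysis would consume (bootstrap
replicates, Bayesian posterior samples, trees from competing inference
methods): each "island" is a cloud of nearest-neighbour-interchange (NNI)
perturbations of a distinct base topology, so the generating partition is
known exactly and every pipeline stage can be validated end to end.

All randomness flows from a single numpy Generator; identical spec + seed
reproduces the identical collection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import dendropy

from .distances import rf_distance
from .trees import TreeCollection

__all__ = ["IslandSpec", "random_tree", "nni_perturb", "make_islands"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class IslandSpec:
    """Parameters of an island-structured synthetic collection.

    Defaults mirror the benchmark used throughout the test suite: 4 islands
    of 50 trees on 20 tips, members 2 NNI moves from their base topology,
    branch lengths i.i.d. exponential with rate 1 (mean 1, in arbitrary
    substitution-like units).
    """

    n_tips: int = 20
    n_islands: int = 4
    trees_per_island: int = 50
    nni_moves_per_tree: int = 2
    branch_length_rate: float = 1.0
    seed: int = 0
    min_rf_separation: int = 4

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_islands < 1 or self.trees_per_island < 1:
            raise ValueError("island counts must be positive")
        if self.nni_moves_per_tree < 0:
            raise ValueError("nni_moves_per_tree must be >= 0")
        if self.branch_length_rate <= 0:
            raise ValueError("branch_length_rate must be > 0")


def random_tree(n_tips: int, seed=None, branch_length_rate: float = 1.0,
                taxon_namespace=None) -> dendropy.Tree:
    """Random rooted binary tree by uniform sequential pair-joining.

    Starts from ``n_tips`` leaves labelled ``t1 .. tn`` and repeatedly
    joins two subtrees picked uniformly at random under a new parent until
    one root remains, so the root always has out-degree 2. Branch lengths
    are i.i.d. exponential with the given rate.

    Parameters
    ----------
    n_tips : int >= 2
    seed : int, numpy Generator or None
    branch_length_rate : float
        Rate of the exponential law (mean length = 1 / rate).
    taxon_namespace : dendropy.TaxonNamespace, optional
        Shared namespace for building collections.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    rng = _rng(seed)
    scale = 1.0 / branch_length_rate
    tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    pool = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(f"t{i + 1}")
        pool.append(nd)
    while len(pool) > 1:
        a = pool.pop(int(rng.integers(len(pool))))
        b = pool.pop(int(rng.integers(len(pool))))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(scale))
        b.edge.length = float(rng.exponential(scale))
        pool.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = pool[0]
    tree.is_rooted = True
    return tree


def nni_perturb(tree: dendropy.Tree, moves: int, seed=None,
                branch_length_rate: float = 1.0) -> dendropy.Tree:
    """Apply random nearest-neighbour-interchange moves to a binary tree.

    Moves act on the internal edges of the tree viewed as *unrooted* (the
    two edges below the root count as the single edge joining the root's
    children), so every move replaces exactly one non-trivial split: a
    single move always yields Robinson-Foulds distance 2 from the input.
    The lengths of the edges touched by a move are redrawn from the
    exponential law. The input tree is not modified; trees with fewer than
    4 tips have no internal edge and are returned as (a copy of) given.
    """
    if moves < 0:
        raise ValueError("moves must be >= 0")
    rng = _rng(seed)
    scale = 1.0 / branch_length_rate
    out = tree.clone(depth=1)
    root = out.seed_node
    for _ in range(moves):
        # candidate internal edges of the unrooted tree: (u, v) with both
        # endpoints internal and u not the root, plus the merged root edge
        # when both root children are internal
        candidates = [
            ("deep", nd)
            for nd in out.preorder_node_iter()
            if nd.parent_node is not None and nd.parent_node is not root
            and not nd.is_leaf()
        ]
        rc = root.child_nodes()
        if len(rc) == 2 and not rc[0].is_leaf() and not rc[1].is_leaf():
            candidates.append(("root", None))
        if not candidates:
            break
        kind, v = candidates[int(rng.integers(len(candidates)))]
        if kind == "deep":
            u = v.parent_node
            siblings = [c for c in u.child_nodes() if c is not v]
            w = siblings[int(rng.integers(len(siblings)))]
            children = v.child_nodes()
            c = children[int(rng.integers(len(children)))]
            u.remove_child(w)
            v.remove_child(c)
            u.add_child(c)
            v.add_child(w)
            touched = (w, c, v)
        else:  # exchange across the merged edge between the root's children
            v1, v2 = root.child_nodes()
            c = v1.child_nodes()[int(rng.integers(v1.num_child_nodes()))]
            d = v2.child_nodes()[int(rng.integers(v2.num_child_nodes()))]
            v1.remove_child(c)
            v2.remove_child(d)
            v1.add_child(d)
            v2.add_child(c)
            touched = (c, d, v1, v2)
        for nd in touched:
            nd.edge.length = float(rng.exponential(scale))
    return out


def make_islands(spec: IslandSpec):
    """Generate an island-structured collection with known ground truth.

    Base topologies are drawn until pairwise RF >= ``spec.min_rf_separation``
    (at most 1000 draws, then an error -- tiny tip counts cannot host many
    well-separated islands). Island members are independent NNI
    perturbations of their base tree; the bases themselves are not included.

    Returns
    -------
    (TreeCollection, ndarray)
        Trees named ``island<g>_tree<j>`` plus the generating island label
        (1..n_islands) per tree.
    """
    rng = _rng(spec.seed)
    tns = dendropy.TaxonNamespace()
    bases: list[dendropy.Tree] = []
    attempts = 0
    while len(bases) < spec.n_islands:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                f"could not draw {spec.n_islands} base trees with pairwise "
                f"RF >= {spec.min_rf_separation} on {spec.n_tips} tips "
                f"after 1000 attempts"
            )
        cand = random_tree(spec.n_tips, rng, spec.branch_length_rate, tns)
        if all(rf_distance(cand, b) >= spec.min_rf_separation for b in bases):
            bases.append(cand)
    trees, names, labels = [], [], []
    for g, base in enumerate(bases, start=1):
        for j in range(spec.trees_per_island):
            trees.append(
                nni_perturb(base, spec.nni_moves_per_tree, rng,
                            spec.branch_length_rate)
            )
            names.append(f"island{g}_tree{j + 1}")
            labels.append(g)
    return TreeCollection(trees, names), np.asarray(labels, dtype=int)
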