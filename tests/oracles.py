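"""Independent brute-force oracles used to validate the implementation.

Deliberately naive: graph flood-fills (networkx) for splits and paths,
ancestor-set intersection for MRCAs. None of these share code with the
package's own traversals.
"""
from __future__ import annotations

import math

import networkx as nx


def leaf_by_label(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label if leaf.taxon is not None else leaf.label] = leaf
    return out


def tree_graph(tree) -> nx.Graph:
    g = nx.Graph()
    for nd in tree.preorder_node_iter():
        g.add_node(id(nd))
        if nd.parent_node is not None:
            g.add_edge(id(nd.parent_node), id(nd), length=nd.edge.length or 0.0)
    return g


def ancestor_chain(nd):
    """Node plus its ancestors, leaf-to-root order."""
    out = []
    while nd is not None:
        out.append(nd)
        nd = nd.parent_node
    return out


def oracle_mrca(tree, label_a, label_b):
    """MRCA via pairwise ancestor-set intersection."""
    leaves = leaf_by_label(tree)
    chain_a = ancestor_chain(leaves[label_a])
    ids_b = {id(x) for x in ancestor_chain(leaves[label_b])}
    for nd in chain_a:
        if id(nd) in ids_b:
            return nd
    raise AssertionError("no common ancestor (not a tree?)")


def oracle_kc_pair(tree, label_a, label_b):
    """(edge count, length sum) of the root -> MRCA(a, b) path.

    The length is accumulated from the root downward so float addition
    order matches a root-down depth recursion.
    """
    mrca = oracle_mrca(tree, label_a, label_b)
    path_up = ancestor_chain(mrca)  # mrca..root
    path_down = list(reversed(path_up))[1:]  # exclude root; root-down order
    total = 0.0
    for nd in path_down:
        total += nd.edge.length or 0.0
    return len(path_down), total


def oracle_path_edges(tree, label_a, label_b):
    """Edge count between two tips by BFS on the tree graph."""
    leaves = leaf_by_label(tree)
    return nx.shortest_path_length(
        tree_graph(tree), id(leaves[label_a]), id(leaves[label_b])
    )


def oracle_dd_path(tree, label_a, label_b, op: str):
    """Product/sum of direct-descendant counts over the internal nodes on
    the tip-to-tip path (endpoints excluded), via a graph shortest path."""
    leaves = leaf_by_label(tree)
    nodes = {id(nd): nd for nd in tree.preorder_node_iter()}
    path = nx.shortest_path(
        tree_graph(tree), id(leaves[label_a]), id(leaves[label_b])
    )
    dds = [nodes[i].num_child_nodes() for i in path[1:-1]]
    return math.prod(dds) if op == "prod" else sum(dds)


def _canonical_side(side: frozenset, labels) -> frozenset:
    first = sorted(labels)[0]
    if first in side:
        return frozenset(labels) - side
    return side


def oracle_splits(tree, include_trivial=False):
    """Splits by edge removal + flood fill; canonical side excludes the
    lexicographically first label. Returns split -> summed branch length."""
    labels = {l.taxon.label if l.taxon is not None else l.label
              for l in tree.leaf_node_iter()}
    leaves = {id(nd): (nd.taxon.label if nd.taxon is not None else nd.label)
              for nd in tree.leaf_node_iter()}
    g = tree_graph(tree)
    out: dict[frozenset, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        h = g.copy()
        h.remove_edge(id(nd.parent_node), id(nd))
        comp = nx.node_connected_component(h, id(nd))
        side = frozenset(leaves[i] for i in comp if i in leaves)
        if not side or side == labels:
            continue
        if not include_trivial and len(side) in (1, len(labels) - 1):
            continue
        canon = _canonical_side(side, labels)
        out[canon] = out.get(canon, 0.0) + (nd.edge.length or 0.0)
    return out


def oracle_rf(t1, t2) -> int:
    return len(set(oracle_splits(t1)) ^ set(oracle_splits(t2)))


def oracle_branch_score(t1, t2) -> float:
    m1 = oracle_splits(t1, include_trivial=True)
    m2 = oracle_splits(t2, include_trivial=True)
    total = 0.0
    for s in set(m1) | set(m2):
        total += (m1.get(s, 0.0) - m2.get(s, 0.0)) ** 2
    return math.sqrt(total)


def mask_to_side(mask: int, labels) -> frozenset:
    return frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)


def topology_signature(tree):
    """Canonical labelled-rooted-topology fingerprint (ignores lengths)."""

    def sig(nd):
        if nd.is_leaf():
            return ("leaf", nd.taxon.label if nd.taxon is not None else nd.label)
        return ("node", tuple(sorted(sig(c) for c in nd.child_nodes())))

    return sig(tree.seed_node)


def scale_lengths(tree, factor: float):
    """Return a copy with every branch length multiplied by *factor*."""
    out = tree.clone(depth=1)
    for nd in out.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is not None:
            nd.edge.length = nd.edge.length * factor
    return out
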