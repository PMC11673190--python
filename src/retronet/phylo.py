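"""Distance-based phylogenetics: neighbor joining, rooting, clade tests.

Neighbor joining (Saitou–Nei) exactly recovers additive distance matrices
and serves here as the reproducible taxonomy baseline: a tree is built from
the same distance matrix as the similarity network, rooted (midpoint by
default, or on a named outgroup), and cut at a branch-length threshold to
yield a partition comparable to network clusterings.

Trees are :class:`skbio.TreeNode` objects; tie-breaks in the Q-matrix
minimization are lexicographic on the smallest leaf name of each subtree,
so output is deterministic.  Negative NJ branch lengths are clamped to zero
and the clamp count is stored on ``tree.n_clamped``.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix
from .ssn import Partition

__all__ = ["nj_tree", "root_tree", "is_monophyletic", "taxonomy_from_tree"]


def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining on a distance matrix.

    Requires n >= 3; returns an unrooted tree (trifurcating root) whose leaf
    set equals the matrix identifiers.
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.any(~np.isfinite(m.values)):
        raise ValueError("distance matrix contains undefined entries")
    D = m.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in m.ids]
    # smallest leaf name per subtree, for deterministic tie-breaking
    keys: list[str] = list(m.ids)
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        rest = [x for x in range(k) if x not in (i, j)]
        newD = np.zeros((k - 1, k - 1))
        for a, x in enumerate(rest):
            for b, y in enumerate(rest):
                newD[a, b] = D[x, y]
            newD[a, k - 2] = newD[k - 2, a] = 0.5 * (D[x, i] + D[x, j] - D[i, j])
        D = newD
        new_nodes = [nodes[x] for x in rest] + [parent]
        new_keys = [keys[x] for x in rest] + [min(keys[i], keys[j])]
        nodes, keys = new_nodes, new_keys

    # join the last three around an unrooted (trifurcating) root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = clamp(length)
    root = TreeNode(children=list(nodes))
    root.n_clamped = n_clamped
    return root


def root_tree(tree: TreeNode, root: str = "midpoint") -> TreeNode:
    """Root a tree at its midpoint or on a named outgroup leaf."""
    if root == "midpoint":
        return tree.root_at_midpoint()
    if tree.find(root) is None:  # pragma: no cover - find raises on miss
        raise KeyError(root)
    return tree.root_by_outgroup([root])


def is_monophyletic(tree: TreeNode, leafset, root: str = "midpoint") -> bool:
    """True iff ``leafset`` is exactly the leaf set of a clade after rooting."""
    leafset = set(leafset)
    names = {t.name for t in tree.tips()}
    unknown = leafset - names
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not leafset:
        raise ValueError("leafset must be non-empty")
    if leafset == names:
        return True
    if len(leafset) == 1:
        return True
    rooted = root_tree(tree, root)
    lca = rooted.lca(sorted(leafset))
    return {t.name for t in lca.tips()} == leafset


def taxonomy_from_tree(tree: TreeNode, cut: float, root: str = "midpoint") -> Partition:
    """Cut branches longer than ``cut``; connected leaf groups become clusters.

    The explicit, reproducible surrogate for reading taxonomy off a tree:
    long branches separate groups, short ones keep leaves together.
    """
    if cut <= 0:
        raise ValueError("cut must be positive")
    rooted = root_tree(tree, root)
    component: dict[int, int] = {}
    next_comp = 0
    assignment: dict[str, int] = {}
    for node in rooted.preorder():
        if node.is_root():
            component[id(node)] = next_comp
            next_comp += 1
        else:
            length = node.length or 0.0
            if length > cut:
                component[id(node)] = next_comp
                next_comp += 1
            else:
                component[id(node)] = component[id(node.parent)]
        if node.is_tip():
            assignment[node.name] = component[id(node)]
    return Partition(assignment, method="tree-cut")
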