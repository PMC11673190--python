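"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration, pair
counting, path sums on explicitly constructed trees — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


def set_partitions(items):
    """Yield all set partitions of ``items`` (lists of lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_from_adjacency(A: np.ndarray, communities) -> float:
    """Newman–Girvan modularity from an adjacency matrix, direct formula."""
    k = A.sum(axis=1)
    m2 = k.sum()
    B = A - np.outer(k, k) / m2
    return float(sum(B[np.ix_(c, c)].sum() for c in communities) / m2)


def brute_force_best_modularity(A: np.ndarray) -> float:
    """Exhaustive maximum modularity over all set partitions of the nodes."""
    n = A.shape[0]
    best = -np.inf
    for part in set_partitions(range(n)):
        q = modularity_from_adjacency(A, part)
        if q > best:
            best = q
    return best


def rand_index_by_pairs(a, b) -> float:
    """Unadjusted Rand index by explicit enumeration of all item pairs."""
    n = len(a)
    assert n == len(b) and n >= 2
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random unrooted binary tree with uniform(0.1, 1.0) branch lengths.

    Built by attaching each new leaf to a uniformly chosen existing edge —
    independent of any reconstruction code.
    """
    names = [f"L{i}" for i in range(n_leaves)]
    tips = [TreeNode(name=nm, length=float(rng.uniform(0.1, 1.0))) for nm in names[:3]]
    root = TreeNode(children=tips)
    for nm in names[3:]:
        edges = [nd for nd in root.traverse() if not nd.is_root()]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        parent.remove(target)
        half = target.length / 2.0
        target.length = half
        new_leaf = TreeNode(name=nm, length=float(rng.uniform(0.1, 1.0)))
        joint = TreeNode(children=[target, new_leaf], length=half)
        parent.append(joint)
    return root


def additive_matrix(tree: TreeNode):
    """Leaf-to-leaf path-sum distances of a tree (ids, square array)."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)
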