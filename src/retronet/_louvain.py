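"""Greedy modularity optimization (Louvain) with randomized restarts.

Two-phase scheme: local moving (each node greedily joins the neighboring
community with the best modularity gain, visiting nodes in a seeded random
order, until no move improves) followed by aggregation of communities into
super-nodes, repeated until the graph stops shrinking.  Because greedy
optimization of modularity is NP-hard and stalls in local optima, each
restart begins from a different seeded initial assignment (the first from
singletons, the classical start), and a final local-moving pass on the
original graph guarantees the returned partition admits no improving
single-node move.  The best-modularity restart wins, so results are
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

Adjacency = list[dict[int, float]]


def _local_moving(
    adj: Adjacency,
    k: np.ndarray,
    m2: float,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> bool:
    """Greedy single-node moves until none improves modularity.

    Returns True when at least one move was made.  ``adj`` excludes
    self-loops; ``k`` is the (weighted) degree including them, so the
    modularity gain of moving u from community a to b is
    2/m2 * [(w_ub - w_ua) - k_u (K_b - K_a + k_u)/m2], with self-loop terms
    cancelling.
    """
    n = len(adj)
    K = np.zeros(int(labels.max()) + n + 2)
    for u in range(n):
        K[labels[u]] += k[u]
    moved_any = False
    next_free = int(labels.max()) + 1
    improved = True
    while improved:
        improved = False
        for u in rng.permutation(n):
            cu = int(labels[u])
            w_to: dict[int, float] = {}
            for v, w in adj[u].items():
                lv = int(labels[v])
                w_to[lv] = w_to.get(lv, 0.0) + w
            base = w_to.get(cu, 0.0) - k[u] * (K[cu] - k[u]) / m2
            best_gain, best_c = 1e-12, cu
            for c, w in w_to.items():
                if c == cu:
                    continue
                gain = (w - k[u] * K[c] / m2) - base
                if gain > best_gain:
                    best_gain, best_c = gain, c
            # moving u out into a fresh singleton can also help
            lone_gain = -base
            if lone_gain > best_gain and K[cu] > k[u]:
                best_gain, best_c = lone_gain, next_free
            if best_c != cu:
                if best_c == next_free:
                    next_free += 1
                    if next_free >= K.size:
                        K = np.concatenate([K, np.zeros(K.size)])
                K[cu] -= k[u]
                K[best_c] += k[u]
                labels[u] = best_c
                improved = moved_any = True
    return moved_any


def _compact(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq = {c: i for i, c in enumerate(dict.fromkeys(int(x) for x in labels))}
    return np.array([uniq[int(x)] for x in labels]), len(uniq)


def _aggregate(
    adj: Adjacency, self_w: np.ndarray, labels: np.ndarray, n_comm: int
) -> tuple[Adjacency, np.ndarray]:
    new_adj: Adjacency = [dict() for _ in range(n_comm)]
    new_self = np.zeros(n_comm)
    for u in range(len(adj)):
        cu = int(labels[u])
        new_self[cu] += self_w[u]
        for v, w in adj[u].items():
            cv = int(labels[v])
            if cv == cu:
                if u < v:
                    new_self[cu] += w
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, new_self


def louvain_labels(
    adj: Adjacency,
    seed: int = 0,
    n_restarts: int = 16,
) -> tuple[np.ndarray, float]:
    """Run restarted Louvain on an adjacency list; returns (labels, modularity)."""
    n = len(adj)
    k0 = np.array([sum(a.values()) for a in adj])
    m2 = float(k0.sum())
    if m2 == 0:
        raise ValueError("graph has no edges")

    def score(labels: np.ndarray) -> float:
        K = np.zeros(int(labels.max()) + 1)
        intra = np.zeros(int(labels.max()) + 1)
        for u in range(n):
            K[labels[u]] += k0[u]
            for v, w in adj[u].items():
                if labels[v] == labels[u] and u < v:
                    intra[labels[u]] += w
        return float(np.sum(intra / (m2 / 2.0)) - np.sum((K / m2) ** 2))

    rng = np.random.default_rng(seed)
    best_labels, best_q = None, -np.inf
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = np.arange(n)  # classical start: every node its own community
        else:
            init = rng.integers(0, int(rng.integers(2, n + 1)), size=n)
        # multi-level: local moving + aggregation until the graph stops shrinking
        node_comm = np.arange(n)  # original node -> current level-graph node
        level_adj = [dict(a) for a in adj]
        level_self = np.zeros(n)
        level_k = k0.copy()
        agg_labels, _ = _compact(init)  # level-0 graph nodes are the originals
        while True:
            _local_moving(level_adj, level_k, m2, agg_labels, rng)
            agg_labels, n_comm = _compact(agg_labels)
            node_comm = agg_labels[node_comm]
            if n_comm == len(level_adj):
                break
            level_adj, level_self = _aggregate(level_adj, level_self, agg_labels, n_comm)
            level_k = np.array([sum(a.values()) for a in level_adj]) + 2.0 * level_self
            agg_labels = np.arange(n_comm)
        # final refinement on the original graph: no single-node move improves
        final = node_comm.copy()
        _local_moving([dict(a) for a in adj], k0, m2, final, rng)
        final, _ = _compact(final)
        q = score(final)
        if q > best_q + 1e-13:
            best_q, best_labels = q, final
    return best_labels, best_q
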