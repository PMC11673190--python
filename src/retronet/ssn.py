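"""Sequence similarity networks, clustering and partition agreement.

The network has one node per sequence and an edge for every pair whose
similarity weight w = 1/d reaches the threshold tau (default 0.666, i.e.
distances above 1.5 are pruned).  Two clustering schemes operate on it:

* MC — modularity-based community detection (Louvain local moving with
  aggregation, randomized restarts, best modularity kept);
* CC — connected components of the thresholded graph.

Agreement with a reference taxonomy is scored by the Rand index, in both its
unadjusted and chance-corrected (Hubert–Arabie adjusted) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score, rand_score

from .distances import DistanceMatrix
from .exceptions import ModularityUndefinedError, PartitionMismatchError

__all__ = [
    "Partition",
    "build_ssn",
    "connected_components",
    "modularity",
    "louvain_cluster",
    "rand_index",
    "cluster_report",
    "SSNClustering",
]


@dataclass
class Partition:
    """Mapping of identifiers to integer cluster labels.

    Labels are canonical: clusters numbered 1..k by decreasing size, ties
    broken by the lexicographically smallest member identifier.  ``quality``
    carries the modularity value for MC partitions, else None.
    """

    assignment: dict[str, int]
    method: str = "unknown"
    quality: float | None = None

    def __post_init__(self) -> None:
        self.assignment = canonical_labels(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for ident, lab in self.assignment.items():
            out.setdefault(lab, []).append(ident)
        return {k: sorted(v) for k, v in out.items()}

    @classmethod
    def from_labels(cls, labels: dict[str, str], method: str = "taxonomy") -> "Partition":
        uniq = {g: i for i, g in enumerate(sorted(set(labels.values())))}
        return cls({k: uniq[v] for k, v in labels.items()}, method=method)


def canonical_labels(assignment: dict[str, object]) -> dict[str, int]:
    """Renumber clusters by decreasing size, ties by smallest member id."""
    members: dict[object, list[str]] = {}
    for ident, lab in assignment.items():
        members.setdefault(lab, []).append(ident)
    order = sorted(members, key=lambda lab: (-len(members[lab]), min(members[lab])))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {ident: remap[lab] for ident, lab in assignment.items()}


def build_ssn(m: DistanceMatrix, tau: float = 0.666, w_cap: float = 1000.0) -> nx.Graph:
    """Threshold a distance matrix into a similarity network.

    Edge weight is 1/d, capped at ``w_cap`` for near-identical pairs
    (d < 1/w_cap); an edge is retained iff its weight is >= ``tau``.  Pairs
    with undefined distance get no edge.  All nodes are retained, isolated
    or not.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if w_cap <= 0:
        raise ValueError("w_cap must be positive")
    g = nx.Graph(tau=tau, w_cap=w_cap, model=m.model)
    g.add_nodes_from(m.ids)
    n = len(m.ids)
    vals = m.values
    for i in range(n):
        for j in range(i + 1, n):
            d = vals[i, j]
            if not np.isfinite(d):
                continue
            w = w_cap if d < 1.0 / w_cap else 1.0 / d
            if w >= tau:
                g.add_edge(m.ids[i], m.ids[j], weight=float(w), distance=float(d))
    return g


def connected_components(g: nx.Graph) -> Partition:
    """Partition by maximal connected subgraphs; isolated nodes are singletons."""
    assignment: dict[str, int] = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for ident in comp:
            assignment[ident] = k
    return Partition(assignment, method="CC")


def modularity(g: nx.Graph, p: Partition, weighted: bool = True) -> float:
    """Newman–Girvan modularity of a partition, resolution 1.

    M = sum_c [ l_c/m - (d_c/(2m))^2 ] with l_c the intra-community edge
    weight (edge count if unweighted), d_c the community degree sum and m
    the total edge weight.
    """
    missing = set(g.nodes) - set(p.assignment)
    if missing:
        raise PartitionMismatchError(f"partition misses nodes: {sorted(missing)[:5]}")
    m2 = 0.0  # 2m
    intra: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        m2 += 2.0 * w
        cu, cv = p.assignment[u], p.assignment[v]
        deg[cu] = deg.get(cu, 0.0) + w
        deg[cv] = deg.get(cv, 0.0) + w
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    if m2 == 0.0:
        raise ModularityUndefinedError("modularity undefined on an edgeless graph")
    m = m2 / 2.0
    return float(
        sum(intra.get(c, 0.0) / m - (deg.get(c, 0.0) / m2) ** 2 for c in set(deg) | set(intra))
    )


def louvain_cluster(
    g: nx.Graph,
    seed: int = 0,
    weighted: bool = True,
    n_restarts: int = 16,
) -> Partition:
    """Greedy modularity optimization (Louvain), deterministic for a seed.

    Two-phase local moving + aggregation, node visit order shuffled by the
    seed, with ``n_restarts`` randomized restarts (the first from the
    classical all-singletons start) and a final node-level pass so that no
    single-node move can improve the returned partition.  The best-modularity
    restart wins.  Resolution is fixed at 1.
    """
    if g.number_of_edges() == 0:
        raise ModularityUndefinedError("modularity clustering needs at least one edge")
    from ._louvain import louvain_labels

    nodes = sorted(g.nodes)
    index = {ident: i for i, ident in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v, data in g.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        adj[index[u]][index[v]] = w
        adj[index[v]][index[u]] = w
    labels, _ = louvain_labels(adj, seed=int(seed), n_restarts=n_restarts)
    part = Partition({ident: int(labels[index[ident]]) for ident in nodes}, method="MC")
    part.quality = modularity(g, part, weighted=weighted)
    return part


def _check_same_ids(p1: Partition, p2: Partition) -> list[str]:
    ids1, ids2 = set(p1.assignment), set(p2.assignment)
    if ids1 != ids2:
        offenders = sorted(ids1 ^ ids2)
        raise PartitionMismatchError(
            f"partitions cover different identifiers; offenders: {offenders[:10]}"
        )
    return sorted(ids1)


def rand_index(p1: Partition, p2: Partition, adjusted: bool = True) -> float:
    """Rand index between two partitions over the same identifiers.

    ``adjusted=False`` gives the plain pairwise-agreement fraction;
    ``adjusted=True`` the Hubert–Arabie chance-corrected form.  Identifier
    mismatch is an error (no silent intersection).
    """
    ids = _check_same_ids(p1, p2)
    if len(ids) < 2:
        raise PartitionMismatchError("Rand index undefined for fewer than 2 items")
    a = [p1.assignment[i] for i in ids]
    b = [p2.assignment[i] for i in ids]
    return float(adjusted_rand_score(a, b) if adjusted else rand_score(a, b))


def cluster_report(
    g: nx.Graph,
    partitions: list[Partition],
    taxonomy: dict[str, str],
    weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score partitions against a taxonomy.

    Returns ``(report, contingency)``: one report row per partition with
    cluster count, modularity (MC only) and both Rand variants versus the
    taxonomy; and a cluster x taxonomy-group contingency table for the first
    partition.  Nodes missing from the taxonomy are an error — silent drops
    would bias the agreement scores.
    """
    unlabeled = set(g.nodes) - set(taxonomy)
    if unlabeled:
        raise PartitionMismatchError(
            f"taxonomy misses node(s): {sorted(unlabeled)[:10]}"
        )
    ref = Partition.from_labels({n: taxonomy[n] for n in g.nodes}, method="taxonomy")
    rows = []
    for part in partitions:
        rows.append(
            {
                "method": part.method,
                "n_clusters": part.n_clusters,
                "modularity": (
                    round(part.quality, 6) if part.quality is not None else np.nan
                ),
                "rand_unadjusted": round(rand_index(part, ref, adjusted=False), 6),
                "rand_adjusted": round(rand_index(part, ref, adjusted=True), 6),
            }
        )
    report = pd.DataFrame(rows)
    first = partitions[0]
    cont = pd.crosstab(
        pd.Series(first.assignment, name="cluster"),
        pd.Series({n: taxonomy[n] for n in first.assignment}, name="group"),
    )
    return report, cont


class SSNClustering(ClusterMixin, BaseEstimator):
    """Similarity-network clustering as a scikit-learn estimator.

    Takes a precomputed pairwise distance matrix (square array or
    :class:`DistanceMatrix`), thresholds it into a similarity network with
    edge weight 1/d, and clusters by modularity (``method='mc'``) or
    connected components (``method='cc'``).

    Parameters
    ----------
    tau : float
        Minimum edge weight retained (1/d >= tau).
    method : {'mc', 'cc'}
        Modularity (Louvain) or connected-component clustering.
    weighted : bool
        Whether modularity uses edge weights.
    w_cap : float
        Weight cap for near-zero distances.
    n_restarts : int
        Louvain restarts; the best-modularity run wins.
    random_state : int
        Seed for the Louvain node order.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Canonical cluster labels.
    partition_ : Partition
    graph_ : networkx.Graph
    modularity_ : float or None
    n_clusters_ : int
    """

    def __init__(
        self,
        tau: float = 0.666,
        method: str = "mc",
        weighted: bool = True,
        w_cap: float = 1000.0,
        n_restarts: int = 8,
        random_state: int = 0,
    ):
        self.tau = tau
        self.method = method
        self.weighted = weighted
        self.w_cap = w_cap
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, DistanceMatrix):
            dm = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("X must be a square precomputed distance matrix")
            dm = DistanceMatrix(
                ids=[str(i) for i in range(X.shape[0])], values=X, model="precomputed"
            )
        if self.method not in ("mc", "cc"):
            raise ValueError("method must be 'mc' or 'cc'")
        self.graph_ = build_ssn(dm, tau=self.tau, w_cap=self.w_cap)
        if self.method == "cc":
            self.partition_ = connected_components(self.graph_)
            self.modularity_ = None
        else:
            self.partition_ = louvain_cluster(
                self.graph_,
                seed=self.random_state,
                weighted=self.weighted,
                n_restarts=self.n_restarts,
            )
            self.modularity_ = self.partition_.quality
        self.labels_ = np.array([self.partition_.assignment[i] for i in dm.ids])
        self.n_clusters_ = self.partition_.n_clusters
        return self
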