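"""Connection-cluster classification of brain-network nodes.

The unit of analysis is the *connection cluster*: a node together with all
edges incident to it.  Each node i of an N-node weighted network is encoded
as the vector of its N-1 connectivity strengths, and the vectors are
agglomeratively clustered under Euclidean distance: starting from N
singletons, the closest pair of clusters is merged until one remains,
recording the full dendrogram.  Cutting the dendrogram at Z clusters and
ranking the surviving clusters by how soon they are absorbed into the
remaining merges yields *merge-order classes* 1..Z: the later a cluster is
absorbed, the more it differs from the rest of the network, and the higher
(more "active") its class.  Z defaults to 4.

Determinism: among equal-distance candidate pairs the lexicographically
smallest (i, j) cluster-id pair is merged, and when two cut clusters are
absorbed at the same step (they merge with each other) the one containing
the lower canonical node index takes the lower class.

A Louvain community-detection comparator over the same weighted graph is
included, with its modularity Q reported alongside the partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .connectivity import ConnectivityMatrix

__all__ = [
    "Merge",
    "Dendrogram",
    "ClassAssignment",
    "node_vectors",
    "connection_cluster_distances",
    "agglomerate",
    "agglomerate_distances",
    "cut",
    "assign_classes",
    "class_trajectory",
    "louvain_communities",
    "ConnectionClusterClassifier",
]

LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``left`` and ``right`` -> ``new``."""

    step: int
    left: int
    right: int
    new: int
    distance: float


@dataclass(frozen=True)
class Dendrogram:
    """Full merge history over N leaves.

    Leaf clusters carry ids 1..N (canonical node order); the cluster created
    at step s carries id N+s, so ids run up to 2N-1.
    """

    n_leaves: int
    merges: tuple[Merge, ...]
    leaf_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over N leaves has exactly N-1 merges")
        seen: set[int] = set()
        for m in self.merges:
            for cid in (m.left, m.right):
                if cid in seen:
                    raise ValueError(f"cluster {cid} merged twice")
                seen.add(cid)

    def members(self, upto: int | None = None) -> dict[int, frozenset[int]]:
        """Leaf sets of the clusters alive after the first ``upto`` merges."""
        alive = {i: frozenset([i]) for i in range(1, self.n_leaves + 1)}
        for m in self.merges[: upto if upto is not None else len(self.merges)]:
            alive[m.new] = alive.pop(m.left) | alive.pop(m.right)
        return alive


@dataclass(frozen=True)
class ClassAssignment:
    """Node -> merge-order class (1..Z) for one network."""

    labels: Mapping[int, int]  # leaf id (1..N) -> class
    n_classes: int
    leaf_labels: tuple[str, ...] | None = None

    def as_array(self) -> np.ndarray:
        n = len(self.labels)
        return np.asarray([self.labels[i] for i in range(1, n + 1)], dtype=int)

    def by_channel(self) -> dict[str, int]:
        if self.leaf_labels is None:
            raise ValueError("no channel labels attached")
        return {self.leaf_labels[i - 1]: c for i, c in self.labels.items()}


def node_vectors(F: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Node-attribute matrix: row i holds F(i, j) for all j != i.

    Attribute order follows the canonical node order with self omitted, so
    the result has shape (N, N-1).
    """
    v = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, dtype=float)
    n = v.shape[0]
    if v.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    out = np.empty((n, n - 1))
    for i in range(n):
        out[i] = np.delete(v[i], i)
    return out


def connection_cluster_distances(F: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Euclidean distance between connection clusters, aligned by node.

    The M = N-1 attributes of nodes i and j are paired by the node they
    point to: the N-2 entries toward common third nodes are differenced,
    and the mutual pair (F_ij, F_ji) aligns with itself, contributing zero
    by symmetry.  This pairing makes the distance independent of node
    numbering, which a positional pairing of the self-deleted rows is not.
    """
    v = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, dtype=float)
    n = v.shape[0]
    if v.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k != i and k != j]
            d = float(np.linalg.norm(v[i, keep] - v[j, keep]))
            D[i, j] = D[j, i] = d
    return D


def agglomerate_distances(D: np.ndarray, linkage: str = "single",
                          leaf_labels: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative clustering from a precomputed node-distance matrix.

    Cluster-level distances are lifted from the node distances by the
    chosen linkage (Lance–Williams updates); ties break toward the
    lexicographically smallest (i, j) id pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    base = np.asarray(D, dtype=float)
    n = base.shape[0]
    if n == 0:
        raise ValueError("no nodes given")
    if n < 2:
        raise ValueError("need at least two nodes")
    if base.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if leaf_labels is not None and len(leaf_labels) != n:
        raise ValueError("one label per node required")

    dist: dict[tuple[int, int], float] = {
        (i + 1, j + 1): float(base[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(1, n + 1)}
    merges: list[Merge] = []
    for step in range(1, n):
        (a, b) = min(dist, key=lambda p: (dist[p], p))
        d = dist[(a, b)]
        new = n + step
        for k in list(size):
            if k in (a, b):
                continue
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            dist[(k, new)] = _linkage_update(linkage, d_ak, d_bk,
                                             size[a], size[b])
        del dist[(a, b)]
        size[new] = size.pop(a) + size.pop(b)
        merges.append(Merge(step, a, b, new, d))
    return Dendrogram(n, tuple(merges),
                      tuple(leaf_labels) if leaf_labels is not None else None)


def _linkage_update(linkage: str, d_ak: float, d_bk: float,
                    na: int, nb: int) -> float:
    if linkage == "single":
        return min(d_ak, d_bk)
    if linkage == "complete":
        return max(d_ak, d_bk)
    # average: unweighted mean over member pairs (UPGMA)
    return (na * d_ak + nb * d_bk) / (na + nb)


def agglomerate(vectors, linkage: str = "single",
                leaf_labels: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative clustering of node vectors under Euclidean distance.

    At each step the pair of clusters at minimal distance is merged, the
    Euclidean inter-node distance being lifted to clusters by the chosen
    linkage (Lance–Williams updates).  Ties are broken toward the
    lexicographically smallest (i, j) id pair, which makes the merge
    sequence fully deterministic.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("no node vectors given")
    diff = X[:, None, :] - X[None, :, :]
    base = np.sqrt(np.sum(diff ** 2, axis=-1))
    return agglomerate_distances(base, linkage, leaf_labels)


def cut(dend: Dendrogram, Z: int) -> dict[int, tuple[int, ...]]:
    """Partition obtained by undoing the last Z-1 merges.

    Returns surviving cluster id -> sorted tuple of leaf ids.
    """
    if not 1 <= Z <= dend.n_leaves:
        raise ValueError(f"Z={Z} outside 1..{dend.n_leaves}")
    alive = dend.members(upto=dend.n_leaves - Z)
    return {cid: tuple(sorted(s)) for cid, s in sorted(alive.items())}


def assign_classes(dend: Dendrogram, Z: int) -> ClassAssignment:
    """Merge-order classes 1..Z for the Z-cluster cut.

    Each cut cluster is ranked by the step at which it is first absorbed
    into a merge above the cut; the earliest-absorbed cluster becomes
    Class 1 and the latest Class Z.  Two clusters absorbed at the same step
    (merging with each other) are ordered by their lowest node index.
    """
    partition = cut(dend, Z)
    absorbed: dict[int, int] = {}
    for m in dend.merges[dend.n_leaves - Z:]:
        for cid in (m.left, m.right):
            if cid in partition:
                absorbed[cid] = m.step
    if Z == 1:
        absorbed = {next(iter(partition)): 0}
    order = sorted(partition, key=lambda cid: (absorbed[cid], min(partition[cid])))
    labels: dict[int, int] = {}
    for rank, cid in enumerate(order, start=1):
        for leaf in partition[cid]:
            labels[leaf] = rank
    return ClassAssignment(labels, Z, dend.leaf_labels)


def class_trajectory(assignments: Sequence[ClassAssignment]) -> np.ndarray:
    """Stack per-segment class labels into an (N x K) integer matrix.

    Row order is the canonical node order; column k holds segment k+1.
    All assignments must share the node set.
    """
    if not assignments:
        raise ValueError("no assignments given")
    node_sets = {frozenset(a.labels) for a in assignments}
    if len(node_sets) != 1:
        raise ValueError("assignments cover different node sets")
    return np.column_stack([a.as_array() for a in assignments])


def louvain_communities(F: ConnectivityMatrix | np.ndarray,
                        seed: int = 0) -> tuple[dict[int, int], float]:
    """Louvain community detection on the weighted connectivity graph.

    Greedy two-phase modularity optimisation (each node moves to the
    neighbouring community of largest modularity increment, then the graph
    is aggregated).  Returns node (1..N) -> community id and the weighted
    modularity Q of the partition; the node sweep order is randomised by
    ``seed``, so results are reproducible per seed.  An edgeless network is
    a single community with Q = 0.
    """
    v = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, dtype=float)
    n = v.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(1, n + 1))
    for i in range(n):
        for j in range(i + 1, n):
            if v[i, j] > 0.0:
                G.add_edge(i + 1, j + 1, weight=float(v[i, j]))
    if G.number_of_edges() == 0:
        return {i: 0 for i in range(1, n + 1)}, 0.0
    parts = nx.community.louvain_communities(G, weight="weight", seed=seed)
    parts = sorted((sorted(p) for p in parts), key=lambda p: p[0])
    mapping = {node: cid for cid, p in enumerate(parts) for node in p}
    q = nx.community.modularity(G, [set(p) for p in parts], weight="weight")
    return mapping, float(q)


def modularity_brute(values: np.ndarray, communities: Mapping[int, int]) -> float:
    """Direct evaluation of weighted modularity Q for a given partition.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j), summed over
    all ordered pairs including i=j (A_ii = 0 here).
    """
    A = np.asarray(values, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = float(A.sum())
    if two_m == 0.0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if communities[i + 1] == communities[j + 1]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


class ConnectionClusterClassifier(ClusterMixin, BaseEstimator):
    """Merge-order classification of connection clusters.

    Fits on a square symmetric connectivity matrix with zero diagonal:
    nodes are compared through their connectivity profiles (entries paired
    by the node they point to, see :func:`connection_cluster_distances`),
    agglomeratively clustered, and labelled 1..``n_classes`` by merge
    order (class ``n_classes`` = most distinct / most active).

    Parameters
    ----------
    n_classes : int
        Number of clusters Z left by the dendrogram cut (default 4).
    linkage : {"single", "complete", "average"}
        How Euclidean inter-node distance is lifted to clusters.

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Merge-order class of each node, in 1..n_classes.
    dendrogram_ : Dendrogram
        Full merge history.
    assignment_ : ClassAssignment
    """

    def __init__(self, n_classes: int = 4, linkage: str = "single"):
        self.n_classes = n_classes
        self.linkage = linkage

    def fit(self, X, y=None):
        F = X.values if isinstance(X, ConnectivityMatrix) else np.asarray(X, dtype=float)
        labels = X.labels if isinstance(X, ConnectivityMatrix) else None
        n = F.shape[0]
        if F.ndim != 2 or F.shape != (n, n):
            raise ValueError("X must be a square connectivity matrix")
        if not np.allclose(F, F.T):
            raise ValueError("X must be symmetric")
        D = connection_cluster_distances(F)
        self.dendrogram_ = agglomerate_distances(D, self.linkage,
                                                 leaf_labels=labels)
        self.assignment_ = assign_classes(self.dendrogram_, self.n_classes)
        self.labels_ = self.assignment_.as_array()
        self.n_features_in_ = n
        return self
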