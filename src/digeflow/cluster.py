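"""k-means and complete-linkage hierarchical clustering with automated
k-selection, plus partition-concordance statistics.

Two clusterings of the same items are compared by an integral similarity S:
for each cluster of the partition with more clusters, take the best-matching
set coefficient (Simpson = overlap over the smaller set, or Jaccard =
overlap over the union) against the clusters of the other partition, sum the
terms, and divide by the larger cluster count.  S is 1 for identical
partitions in both modes; in Simpson mode S is also 1 whenever every cluster
of the finer partition nests inside a cluster of the coarser one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class Partition:
    """Cluster labels (1..k) over a fixed item set; every cluster non-empty."""

    item_ids: list[str]
    labels: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.item_ids) != self.labels.size:
            raise ValueError("labels and item_ids differ in length")
        present = sorted(set(self.labels.tolist()))
        if not self.k:
            self.k = len(present)
        if present != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be 1..k with no empty cluster, got {present}")

    def clusters(self) -> list[set]:
        return [
            {i for i, l in zip(self.item_ids, self.labels) if l == c}
            for c in range(1, self.k + 1)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "cluster": self.labels})


@dataclass
class ConcordanceScore:
    S: float
    mode: str
    per_cluster_terms: list[float] = field(default_factory=list)


def kmeans_cluster(X: np.ndarray, k: int, seed: int, item_ids=None) -> Partition:
    """Lloyd's algorithm with k-means++ initialization and 10 restarts; the
    solution with the lowest within-cluster sum of squares is kept."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of items {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    item_ids = list(item_ids) if item_ids is not None else [str(i) for i in range(X.shape[0])]
    return Partition(item_ids=item_ids, labels=_relabel(labels))


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, l in enumerate(labels):
        mapping.setdefault(int(l), len(mapping) + 1)
        out[i] = mapping[int(l)]
    return out


def wss_curve(X: np.ndarray, k_max: int, seed: int = 0) -> np.ndarray:
    """Within-cluster sum of squares for k = 1..k_max."""
    X = np.asarray(X, dtype=float)
    wss = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        km.fit(X)
        wss.append(km.inertia_)
    return np.asarray(wss)


def select_k_elbow(X: np.ndarray, k_max: int, seed: int = 0) -> tuple[int, np.ndarray]:
    """Automated elbow criterion: the k maximizing the discrete second
    difference WSS(k-1) - 2 WSS(k) + WSS(k+1) over the WSS curve.  The curve
    is returned alongside so a human can override the choice."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        import warnings

        warnings.warn("fewer than 4 items: elbow selection defaults to k=2")
        return 2, wss_curve(X, min(k_max, n), seed)
    if k_max < 3:
        raise ValueError("k_max must be >= 3 for the elbow criterion")
    k_max = min(k_max, n)
    wss = wss_curve(X, k_max, seed)
    second = wss[:-2] - 2 * wss[1:-1] + wss[2:]  # index i -> k = i + 2
    k = int(np.argmax(second)) + 2
    return k, wss


def hier_cluster(D: np.ndarray, k: int, item_ids=None) -> Partition:
    """Agglomerative complete-linkage clustering of a distance matrix, cut to
    k clusters."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be symmetric with a zero diagonal")
    if k > D.shape[0]:
        raise ValueError("k exceeds the number of items")
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    item_ids = list(item_ids) if item_ids is not None else [str(i) for i in range(D.shape[0])]
    return Partition(item_ids=item_ids, labels=_relabel(labels))


def complete_linkage_tree(D: np.ndarray) -> np.ndarray:
    """The scipy linkage matrix, for dendrogram/newick export."""
    D = np.asarray(D, dtype=float)
    return linkage(squareform(D, checks=False), method="complete")


def linkage_to_newick(Z: np.ndarray, item_ids: list[str]) -> str:
    """Serialize a linkage matrix as a newick string with branch lengths."""
    n = len(item_ids)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: item_ids[i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + idx
        nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node] = h
    return nodes[n + len(Z) - 1] + ";"


def select_k_silhouette(D: np.ndarray, k_range=None, item_ids=None) -> tuple[int, dict[int, float]]:
    """Choose k maximizing the mean silhouette width over complete-linkage
    cuts; ties resolve to the smallest k."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items for silhouette selection")
    if k_range is None:
        k_range = range(2, min(8, n - 1) + 1)
    scores: dict[int, float] = {}
    for k in k_range:
        part = hier_cluster(D, k, item_ids)
        scores[k] = float(silhouette_score(D, part.labels, metric="precomputed"))
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


def set_coefficient(A: set, B: set, mode: str = "simpson") -> float:
    """Simpson = |A∩B| / min(|A|,|B|); Jaccard = |A∩B| / |A∪B|."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("set coefficients are undefined for empty sets")
    inter = len(A & B)
    if mode == "simpson":
        return inter / min(len(A), len(B))
    if mode == "jaccard":
        return inter / len(A | B)
    raise ValueError(f"unknown mode {mode!r}")


def partition_concordance(P: Partition, Q: Partition, mode: str = "simpson") -> ConcordanceScore:
    """Integral similarity between two partitions of the same items.

    The partition with more clusters (ties favor P) is traversed; each of
    its clusters contributes its best set coefficient against the clusters
    of the other partition, and the sum is divided by max(|P|, |Q|).
    """
    if set(P.item_ids) != set(Q.item_ids):
        diff = sorted(set(P.item_ids) ^ set(Q.item_ids))
        raise ValueError(f"partitions cover different items: {diff}")
    cp, cq = P.clusters(), Q.clusters()
    larger, other = (cp, cq) if len(cp) >= len(cq) else (cq, cp)
    terms = [max(set_coefficient(c, d, mode) for d in other) for c in larger]
    S = sum(terms) / max(len(cp), len(cq))
    return ConcordanceScore(S=float(S), mode=mode, per_cluster_terms=terms)


def concordance_matrix(partitions: dict[str, Partition], mode: str = "simpson") -> pd.DataFrame:
    """Pairwise concordance among named partitions, as a square frame."""
    names = list(partitions)
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            s = partition_concordance(partitions[a], partitions[b], mode).S
            M.loc[a, b] = M.loc[b, a] = s
    return M
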