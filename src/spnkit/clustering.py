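"""t-invariant clustering: Pearson similarity, UPGMA, and cluster validity.

Invariant coefficient vectors are compared by sample Pearson correlation
``r``; the clustering distance is ``1 - r`` (range [0, 2]).  Agglomeration
uses UPGMA (unweighted arithmetic-mean linkage) with a deterministic
tie-break, and cluster counts are assessed with the Calinski–Harabasz index
(higher is better) and a Mean Split Silhouette (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "pearson_similarity",
    "similarity_to_distance",
    "upgma",
    "Dendrogram",
    "Clustering",
    "cut",
    "ch_index",
    "mss_index",
    "select_clustering",
]


def pearson_similarity(vectors: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise sample Pearson correlations.

    Rows of ``vectors`` are observations (e.g. invariant coefficient
    vectors).  A zero-variance (constant) vector is defined to have
    correlation 0 with everything (distance 1), keeping the matrix total;
    the diagonal is always 1.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 vectors of length >= 2")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    zero = norms == 0
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def similarity_to_distance(R: np.ndarray) -> np.ndarray:
    """Distance ``1 - r`` with an exactly-zero diagonal."""
    D = 1.0 - np.asarray(R, dtype=float)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree over ``n_leaves`` items.

    ``merges[i] = (left, right, height, size)`` in scipy linkage numbering:
    leaves are 0..n-1, the i-th merge creates node ``n + i``.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]

    def linkage(self) -> np.ndarray:
        """The merge list as a scipy-style (n-1) x 4 linkage array."""
        return np.array([list(m) for m in self.merges], dtype=float)

    def newick(self, labels: Sequence[str] | None = None) -> str:
        """Newick serialisation with branch lengths from merge heights."""
        if labels is None:
            labels = [str(i) for i in range(self.n_leaves)]
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: str(labels[i]) for i in range(self.n_leaves)}
        for i, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + i
            la, lb = h - height[a], h - height[b]
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return text[root] + ";"


def upgma(distances: np.ndarray) -> Dendrogram:
    """UPGMA agglomeration of a symmetric nonnegative distance matrix.

    Ties on the minimum inter-cluster distance are broken by merging the
    lexicographically smallest (node-id) pair, so the result is fully
    deterministic.  Merge heights are non-decreasing (UPGMA is reducible).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 1:
        raise ValueError("empty distance matrix")
    if np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ValueError("distances must be nonnegative with a zero diagonal")

    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # node -> leaves
    dist: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(n), 2):
        dist[(i, j)] = D[i, j]

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        la, lb = active.pop(a), active.pop(b)
        merged = la + lb
        for c in active:
            ca = dist.pop((min(a, c), max(a, c)))
            cb = dist.pop((min(b, c), max(b, c)))
            # unweighted mean over all leaf pairs
            dist[(c, next_id)] = (len(la) * ca + len(lb) * cb) / len(merged)
        dist.pop((a, b))
        merges.append((a, b, h, len(merged)))
        active[next_id] = merged
        next_id += 1
    return Dendrogram(n, tuple(merges))


@dataclass(frozen=True)
class Clustering:
    """Flat partition of items 0..n-1 into clusters 1..k."""

    assignment: tuple[int, ...]
    k: int
    scores: dict = field(default_factory=dict, compare=False)

    def members(self, cluster: int) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.assignment) if c == cluster)

    def sizes(self) -> tuple[int, ...]:
        """Cluster cardinalities, largest first."""
        counts = [0] * self.k
        for c in self.assignment:
            counts[c - 1] += 1
        return tuple(sorted(counts, reverse=True))


def cut(tree: Dendrogram, k: int) -> Clustering:
    """The partition obtained by undoing the last ``k - 1`` merges.

    Cluster ids 1..k are assigned in order of each cluster's smallest leaf.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # apply the first n-k merges
    for i, (a, b, _h, _s) in enumerate(tree.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node

    roots: dict[int, int] = {}
    assignment = [0] * n
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[leaf] = roots[r]
    return Clustering(tuple(assignment), k)


def ch_index(data: np.ndarray, clustering: Clustering) -> float:
    """Calinski–Harabasz variance-ratio criterion.

    ``(between-cluster dispersion / (k-1)) / (within-cluster dispersion /
    (N-k))``; larger means better-separated clusters.  Degenerate zero
    within-dispersion returns ``inf``.
    """
    X = np.asarray(data, dtype=float)
    N, k = X.shape[0], clustering.k
    if not 2 <= k < N:
        raise ValueError(f"C-H index requires 2 <= k < N (k={k}, N={N})")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in range(1, k + 1):
        idx = list(clustering.members(c))
        centre = X[idx].mean(axis=0)
        between += len(idx) * float(((centre - grand) ** 2).sum())
        within += float(((X[idx] - centre) ** 2).sum())
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (N - k))


def _two_medoid_split(D: np.ndarray, idx: list[int]) -> list[int]:
    """Deterministic 2-medoid partition of ``idx`` on distance matrix ``D``.

    Chooses the medoid pair minimising total distance to the nearer medoid
    (ties: lexicographically smallest pair); points tie-break to the first
    medoid.  Returns a 0/1 label per member of ``idx``.
    """
    best = None
    for a, b in combinations(range(len(idx)), 2):
        cost = sum(
            min(D[idx[i], idx[a]], D[idx[i], idx[b]]) for i in range(len(idx))
        )
        if best is None or cost < best[0]:
            best = (cost, a, b)
    _, a, b = best
    return [0 if D[idx[i], idx[a]] <= D[idx[i], idx[b]] else 1 for i in range(len(idx))]


def _silhouette(D: np.ndarray, idx: list[int], labels: list[int]) -> float:
    """Mean silhouette of points ``idx`` under a binary split, via distances."""
    groups = {g: [idx[i] for i in range(len(idx)) if labels[i] == g] for g in (0, 1)}
    vals = []
    for i, lab in zip(idx, labels):
        own = [j for j in groups[lab] if j != i]
        other = groups[1 - lab]
        if not own or not other:
            vals.append(0.0)
            continue
        a = float(np.mean([D[i, j] for j in own]))
        b = float(np.mean([D[i, j] for j in other]))
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def mss_index(distances: np.ndarray, clustering: Clustering) -> float:
    """Mean Split Silhouette: homogeneity of clusters under re-splitting.

    Each cluster is split into two by deterministic 2-medoid partitioning of
    its own distance submatrix; the cluster's split silhouette is the mean
    silhouette of its points under that split.  MSS is the mean over
    clusters — *low* values mean clusters resist further splitting, i.e.
    are internally homogeneous.  Clusters of fewer than three points
    contribute 0 (no meaningful split exists).
    """
    D = np.asarray(distances, dtype=float)
    per_cluster = []
    for c in range(1, clustering.k + 1):
        idx = list(clustering.members(c))
        if len(idx) < 3:
            per_cluster.append(0.0)
            continue
        labels = _two_medoid_split(D, idx)
        if len(set(labels)) < 2:
            per_cluster.append(0.0)
            continue
        per_cluster.append(_silhouette(D, idx, labels))
    return float(np.mean(per_cluster))


def select_clustering(vectors: np.ndarray, k_range: Sequence[int]) -> tuple[pd.DataFrame, Clustering]:
    """Evaluate UPGMA cuts over ``k_range``; recommend the best-C-H cut.

    Returns ``(table, recommended)`` where the table has one row per k with
    columns ``algorithm, k, ch, mss``.
    """
    ks = sorted(set(int(k) for k in k_range))
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    R = pearson_similarity(X)
    D = similarity_to_distance(R)
    tree = upgma(D)
    rows = []
    best: tuple[float, int, Clustering] | None = None
    for k in ks:
        cl = cut(tree, k)
        ch = ch_index(X, cl)
        mss = mss_index(D, cl)
        cl = Clustering(cl.assignment, cl.k, {"ch": ch, "mss": mss})
        rows.append({"algorithm": "upgma-pearson", "k": k, "ch": ch, "mss": mss})
        if best is None or ch > best[0]:
            best = (ch, k, cl)
    return pd.DataFrame(rows), best[2]
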