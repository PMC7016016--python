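"""Building blocks for agglomerative hierarchical clustering.

Provides the pieces both clustering models are assembled from: generalized
Minkowski distances (including fractional orders ``0 < p < 1``, which yield
valid dissimilarities but not metrics), Ward and weighted-average (WPGMA)
linkage, inconsistency coefficients of dendrogram links, and three rules for
cutting a dendrogram into a flat partition (by inconsistency, by cluster
count, by height).

Dendrograms use the scipy linkage-matrix encoding: for ``n`` leaves
(ids ``0..n-1``) the ``k``-th row of the linkage matrix merges two existing
nodes into new node ``n + k`` at the recorded height.  Partitions are integer
label vectors, renumbered ``1..K`` by order of first sample occurrence so
that partitions from different models are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "minkowski_distance",
    "pairwise_distances",
    "agglomerate",
    "inconsistency",
    "max_subtree_inconsistency",
    "cut_by_inconsistency",
    "cut_by_count",
    "cut_by_height",
    "canonical_labels",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over ``n`` leaves.

    Parameters
    ----------
    linkage_matrix
        ``(n-1, 4)`` array in scipy convention: columns are left child id,
        right child id, merge height, and cluster size.  Leaves are
        ``0..n-1``; the ``k``-th merge creates internal node ``n + k``.
    """

    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != 4 or Z.shape[0] < 1:
            raise ValueError("linkage matrix must be (n-1, 4) with n >= 2")
        if np.any(Z[:, 2] < 0):
            raise ValueError("merge heights must be non-negative")
        object.__setattr__(self, "linkage_matrix", Z)

    @property
    def n_leaves(self) -> int:
        return self.linkage_matrix.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def minkowski_distance(x, y, p: float) -> float:
    """Generalized Minkowski dissimilarity ``(sum_j |x_j - y_j|^p)^(1/p)``.

    Equals the Euclidean distance at ``p = 2`` and the Manhattan distance at
    ``p = 1``.  Fractional orders ``0 < p < 1`` are allowed; they emphasize
    the largest coordinate-wise differences less and may violate the
    triangle inequality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("inputs must be finite")
    if not p > 0:
        raise ValueError("Minkowski order p must be > 0")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


def pairwise_distances(table, p: float = 2.0) -> np.ndarray:
    """All-pairs Minkowski distances of the rows of ``table``.

    Parameters
    ----------
    table
        ``(n_samples, n_features)`` array or DataFrame; no missing values.
    p
        Minkowski order, ``p > 0``.

    Returns
    -------
    Condensed distance vector of length ``n (n-1) / 2`` in scipy order.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("table must be 2-D with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("table contains missing or non-finite values")
    if not p > 0:
        raise ValueError("Minkowski order p must be > 0")
    # broadcast rather than scipy.pdist: one code path for all p > 0,
    # including fractional orders; fine at the panel sizes targeted here
    diff = np.abs(X[:, None, :] - X[None, :, :]) ** p
    full = diff.sum(axis=-1) ** (1.0 / p)
    np.fill_diagonal(full, 0.0)
    return squareform(full, checks=False)


_METHODS = {"ward": "ward", "weighted_average": "weighted"}


def agglomerate(d: np.ndarray, method: str = "ward") -> Dendrogram:
    """Build the agglomerative merge tree from a condensed distance vector.

    ``ward`` merges the pair minimizing the increase in within-cluster sum
    of squares (heights follow the usual convention where a singleton pair
    merges at its Euclidean distance; the input should be Euclidean for the
    criterion to be meaningful, which is not enforced).  ``weighted_average``
    is WPGMA: after merging ``i`` and ``j``, ``d(ij, k) = (d(i,k) + d(j,k)) / 2``.

    Both methods are reducible, so heights should be non-decreasing in merge
    order; a violation (possible only on pathological input) raises a
    warning, not an error.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("need a condensed distance vector over >= 2 items")
    Z = hierarchy.linkage(d, method=_METHODS[method])
    h = Z[:, 2]
    if np.any(np.diff(h) < -1e-12 * max(1.0, float(h.max()))):
        warnings.warn(
            f"{method} linkage produced non-monotone merge heights",
            RuntimeWarning,
            stacklevel=2,
        )
    return Dendrogram(Z)


def inconsistency(dend: Dendrogram, dep: int = 2) -> np.ndarray:
    """Inconsistency coefficient of every merge at depth ``dep``.

    For merge ``k`` let ``S`` be the heights of merge ``k`` and of all
    internal merges reachable within ``dep`` levels below it (the merge
    itself is level 1; leaves contribute no height).  The coefficient is
    ``(h_k - mean(S)) / sd(S)`` with the sample standard deviation, and 0
    when ``S`` has a single element or zero spread.  Large values mark
    merges that join well-separated subtrees.
    """
    if dep < 1:
        raise ValueError("dep must be >= 1")
    Z = dend.linkage_matrix
    n = dend.n_leaves
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    h = Z[:, 2]
    coefs = np.zeros(n - 1)
    for k in range(n - 1):
        heights = []
        stack = [(k, 1)]
        while stack:
            node, lvl = stack.pop()
            heights.append(h[node])
            if lvl < dep:
                for child in (left[node], right[node]):
                    if child >= n:
                        stack.append((child - n, lvl + 1))
        if len(heights) > 1:
            arr = np.asarray(heights)
            sd = arr.std(ddof=1)
            if sd > 0:
                coefs[k] = (h[k] - arr.mean()) / sd
    return coefs


def max_subtree_inconsistency(dend: Dendrogram, dep: int = 2) -> np.ndarray:
    """Per merge, the maximum inconsistency coefficient over its subtree.

    Monotone non-decreasing from leaves to root, which makes the set of
    "consistent" merges (max below a cutoff) downward closed — the property
    :func:`cut_by_inconsistency` relies on.
    """
    coefs = inconsistency(dend, dep)
    Z = dend.linkage_matrix
    n = dend.n_leaves
    out = coefs.copy()
    for k in range(n - 1):
        for child in (int(Z[k, 0]), int(Z[k, 1])):
            if child >= n:
                m = out[child - n]
                if m > out[k]:
                    out[k] = m
    return out


def canonical_labels(labels) -> np.ndarray:
    """Renumber arbitrary labels to ``1..K`` by order of first occurrence."""
    out = np.empty(len(labels), dtype=np.int64)
    seen: dict = {}
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen) + 1)
    return out


def _components(dend: Dendrogram, keep: np.ndarray) -> np.ndarray:
    """Flat partition from the forest obtained by keeping a subset of merges.

    A kept merge connects its two child nodes; labels are the connected
    components restricted to the leaves, canonicalized.
    """
    n = dend.n_leaves
    Z = dend.linkage_matrix
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for k in range(n - 1):
        if keep[k]:
            node = n + k
            for child in (int(Z[k, 0]), int(Z[k, 1])):
                ra, rb = find(node), find(child)
                if ra != rb:
                    parent[rb] = ra
    return canonical_labels([find(i) for i in range(n)])


def cut_by_inconsistency(dend: Dendrogram, dep: int, cut: float) -> np.ndarray:
    """Cluster leaves under the highest merges that are consistent throughout.

    A merge survives when its own inconsistency coefficient and those of all
    its descendant merges are strictly below ``cut``; each leaf joins the
    highest surviving ancestor, leaves with no surviving ancestor become
    singletons.  Labels are ``1..K`` by first occurrence.
    """
    if not cut > 0:
        raise ValueError("cut must be > 0")
    maxi = max_subtree_inconsistency(dend, dep)
    return _components(dend, maxi < cut)


def cut_by_count(dend: Dendrogram, k: int) -> np.ndarray:
    """Partition into exactly ``k`` clusters by undoing the last ``k-1`` merges."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    keep = np.zeros(n - 1, dtype=bool)
    keep[: n - k] = True
    return _components(dend, keep)


def cut_by_height(dend: Dendrogram, h: float) -> np.ndarray:
    """Partition by removing every merge with height strictly above ``h``."""
    if h < 0:
        raise ValueError("h must be >= 0")
    return _components(dend, dend.heights <= h)
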