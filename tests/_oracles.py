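"""Independent brute-force oracles used to validate the library.

Each oracle re-derives a quantity from first principles (greedy search over
raw coordinates, explicit pair counting, double loops) without touching the
code paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_ward(X: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration straight from raw coordinates.

    At every step merges the pair of clusters minimizing the increase in
    within-cluster sum of squares; the recorded height is ``sqrt(2 dSS)``,
    the convention under which a singleton pair merges at its Euclidean
    distance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    rows = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            A, B = X[clusters[a]], X[clusters[b]]
            na, nb = len(A), len(B)
            gap = A.mean(axis=0) - B.mean(axis=0)
            delta = na * nb / (na + nb) * float(gap @ gap)
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        rows.append([a, b, np.sqrt(2 * delta), len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.asarray(rows)


def oracle_wpgma(D: np.ndarray) -> np.ndarray:
    """Greedy WPGMA agglomeration on a full square distance matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    dist = {(i, j): D[i, j] for i, j in combinations(range(n), 2)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    rows = []
    while len(sizes) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        rows.append([a, b, h, sizes[a] + sizes[b]])
        others = [k for k in sizes if k not in (a, b)]
        for k in others:
            da = dist.pop(tuple(sorted((a, k))))
            db = dist.pop(tuple(sorted((b, k))))
            dist[(k, next_id)] = (da + db) / 2
        dist.pop((a, b))
        sizes[next_id] = sizes.pop(a) + sizes.pop(b)
        next_id += 1
    return np.asarray(rows)


def oracle_ari(a, b) -> float:
    """ARI by explicit pair counting over all C(n, 2) item pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    together_a = together_b = together_both = 0
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    total = n * (n - 1) // 2
    expected = together_a * together_b / total
    maximum = (together_a + together_b) / 2
    if maximum == expected:
        return 1.0  # both partitions trivial
    return (together_both - expected) / (maximum - expected)


def oracle_consensus(label_sets: list[np.ndarray]) -> np.ndarray:
    """Consensus dissimilarity by a double loop over pairs and models."""
    n = label_sets[0].size
    D = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            together = sum(lab[s] == lab[t] for lab in label_sets)
            D[s, t] = 1 - together / len(label_sets)
    return D


def oracle_inconsistency(Z: np.ndarray, dep: int) -> np.ndarray:
    """Inconsistency coefficients by recursive height collection."""
    n = Z.shape[0] + 1

    def collect(k: int, levels: int) -> list[float]:
        out = [Z[k, 2]]
        if levels > 1:
            for child in (int(Z[k, 0]), int(Z[k, 1])):
                if child >= n:
                    out.extend(collect(child - n, levels - 1))
        return out

    coefs = np.zeros(n - 1)
    for k in range(n - 1):
        hs = np.asarray(collect(k, dep))
        if hs.size > 1 and hs.std(ddof=1) > 0:
            coefs[k] = (Z[k, 2] - hs.mean()) / hs.std(ddof=1)
    return coefs
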