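"""The two full clustering models.

``conventional_model`` is the widely used recipe: Euclidean distances,
Ward's linkage, cut to a fixed number of clusters.

``consensus_model`` sweeps a grid of base models — Minkowski order ``p``
from 0.1 to 2.0 in steps of 0.1, weighted-average (WPGMA) linkage, and
inconsistency-coefficient clustering over depths 2–6 and cutoffs 1.0–3.0 in
steps of 0.1 (2100 base models by default).  Base models that collapse to a
single cluster are discarded.  The retained partitions are combined into a
consensus dissimilarity, ``1 - (fraction of retained models in which two
samples share a cluster)``: 0 for samples that always co-cluster, 1 for
samples that never do.  The final partition is read off a WPGMA tree of
the consensus dissimilarities, cut by default in the widest gap between
successive merge heights (low cutoffs in the grid always fragment part of
the retained models, so a fixed majority cut at 0.5 is brittle; the gap
cut separates the co-clustering core from the between-cluster plateau).
A fixed cut height may be given instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import NamedTuple, Sequence

import numpy as np

from .hca_core import (
    Dendrogram,
    _components,
    agglomerate,
    canonical_labels,
    cut_by_count,
    cut_by_height,
    max_subtree_inconsistency,
    pairwise_distances,
)
from scipy.spatial.distance import squareform

__all__ = [
    "GridConfig",
    "BaseModelSpec",
    "BaseModelResult",
    "ConsensusMatrix",
    "ConsensusResult",
    "NoRetainedModelsError",
    "enumerate_grid",
    "run_base_models",
    "consensus_matrix",
    "consensus_partition",
    "consensus_model",
    "conventional_model",
]


def _tenths(lo: int, hi: int) -> tuple[float, ...]:
    # ranges built from integer tenths so the grid has exactly the printed
    # number of values, with no floating-point accumulation dropouts
    return tuple(i / 10 for i in range(lo, hi + 1))


@dataclass(frozen=True)
class GridConfig:
    """Base-model grid: Minkowski orders x depths x inconsistency cutoffs."""

    p_values: tuple[float, ...] = field(default_factory=lambda: _tenths(1, 20))
    depths: tuple[int, ...] = field(default_factory=lambda: tuple(range(2, 7)))
    cutoffs: tuple[float, ...] = field(default_factory=lambda: _tenths(10, 30))

    def __post_init__(self) -> None:
        if not (self.p_values and self.depths and self.cutoffs):
            raise ValueError("grid ranges must be non-empty")
        if any(p <= 0 for p in self.p_values):
            raise ValueError("all p values must be > 0")
        if any(d < 1 for d in self.depths):
            raise ValueError("all depths must be >= 1")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("all cutoffs must be > 0")

    @property
    def size(self) -> int:
        return len(self.p_values) * len(self.depths) * len(self.cutoffs)


class BaseModelSpec(NamedTuple):
    p: float
    dep: int
    cut: float


@dataclass(frozen=True)
class BaseModelResult:
    """One base model's partition; retained iff it found >= 2 clusters."""

    spec: BaseModelSpec
    labels: np.ndarray
    n_clusters: int

    @property
    def retained(self) -> bool:
        return self.n_clusters >= 2


class NoRetainedModelsError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConsensusMatrix:
    """Symmetric co-clustering dissimilarity in [0, 1], zero diagonal."""

    distances: np.ndarray
    model_count: int

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("consensus matrix must be square")
        if self.model_count < 1:
            raise ValueError("model_count must be >= 1")
        if not np.allclose(D, D.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("consensus matrix diagonal must be zero")
        if D.min() < 0 or D.max() > 1:
            raise ValueError("consensus entries must lie in [0, 1]")
        object.__setattr__(self, "distances", D)

    @property
    def n(self) -> int:
        return self.distances.shape[0]


@dataclass(frozen=True)
class ConsensusResult:
    labels: np.ndarray
    matrix: ConsensusMatrix
    n_retained: int
    n_models: int


def enumerate_grid(cfg: GridConfig | None = None) -> list[BaseModelSpec]:
    """All base-model specs, p outermost, then depth, then cutoff."""
    cfg = cfg or GridConfig()
    return [
        BaseModelSpec(p, dep, cut)
        for p, dep, cut in product(cfg.p_values, cfg.depths, cfg.cutoffs)
    ]


def run_base_models(table, cfg: GridConfig | None = None) -> list[BaseModelResult]:
    """Fit every base model on a cleaned (log-scale) marker table.

    Distance matrices are computed once per Minkowski order and subtree
    inconsistency maxima once per (p, depth), then reused across the cutoff
    sweep.  Raises :class:`NoRetainedModelsError` when every grid cell
    collapses to a single cluster (featureless data); widen the cutoff grid
    or inspect the input in that case.
    """
    cfg = cfg or GridConfig()
    X = np.asarray(table, dtype=float)
    results: list[BaseModelResult] = []
    any_retained = False
    for p in cfg.p_values:
        d = pairwise_distances(X, p)
        dend = agglomerate(d, "weighted_average")
        for dep in cfg.depths:
            maxi = max_subtree_inconsistency(dend, dep)
            for cut in cfg.cutoffs:
                labels = _components(dend, maxi < cut)
                k = int(labels.max())
                results.append(BaseModelResult(BaseModelSpec(p, dep, cut), labels, k))
                any_retained = any_retained or k >= 2
    if not any_retained:
        raise NoRetainedModelsError(
            "every base model produced a single cluster; the data show no "
            "separable structure at these settings — widen the cutoff grid "
            "or check the input table"
        )
    return results


def consensus_matrix(results: Sequence[BaseModelResult]) -> ConsensusMatrix:
    """Co-clustering dissimilarity over the retained base models.

    Entry ``(s, t)`` is one minus the fraction of retained models in which
    ``s`` and ``t`` carry the same cluster label.
    """
    retained = [r for r in results if r.retained]
    if not retained:
        raise NoRetainedModelsError("no retained base models to combine")
    n = retained[0].labels.shape[0]
    # identical partitions are common across the grid: count multiplicity
    # once per distinct label vector before forming co-membership matrices
    unique: dict[bytes, list] = {}
    for r in retained:
        key = r.labels.tobytes()
        if key in unique:
            unique[key][1] += 1
        else:
            unique[key] = [r.labels, 1]
    co = np.zeros((n, n))
    for labels, count in unique.values():
        co += count * (labels[:, None] == labels[None, :])
    D = 1.0 - co / len(retained)
    np.fill_diagonal(D, 0.0)
    np.clip(D, 0.0, 1.0, out=D)
    return ConsensusMatrix(D, model_count=len(retained))


def consensus_partition(
    cm: ConsensusMatrix, height: float | str = "gap"
) -> np.ndarray:
    """Final partition: WPGMA over consensus distances, then cut.

    With ``height="gap"`` (default) the tree is cut in the widest gap
    between successive merge heights — the longest stretch of consensus
    scale that no merge crosses; if all merges sit at the same height the
    result is a single cluster.  A numeric ``height`` cuts at that fixed
    consensus dissimilarity instead (0.5 = majority co-clustering).
    """
    if cm.n == 1:
        return np.array([1], dtype=np.int64)
    condensed = squareform(cm.distances, checks=False)
    dend = agglomerate(condensed, "weighted_average")
    if height == "gap":
        h = dend.heights
        gaps = np.diff(np.concatenate([[0.0], h]))
        if gaps.max() <= 1e-12:
            return np.ones(cm.n, dtype=np.int64)
        # widest gap; ties resolved toward the highest cut (fewest clusters)
        i = len(gaps) - 1 - int(np.argmax(gaps[::-1]))
        threshold = (h[i] + (h[i - 1] if i > 0 else 0.0)) / 2
        return cut_by_height(dend, threshold)
    return cut_by_height(dend, float(height))


def consensus_model(
    table, cfg: GridConfig | None = None, height: float | str = "gap"
) -> ConsensusResult:
    """Run the full consensus pipeline: grid sweep, filter, combine, cut."""
    cfg = cfg or GridConfig()
    results = run_base_models(table, cfg)
    cm = consensus_matrix(results)
    labels = consensus_partition(cm, height)
    return ConsensusResult(
        labels=labels, matrix=cm, n_retained=cm.model_count, n_models=len(results)
    )


def _auto_k(dend: Dendrogram, k_max: int = 10) -> int:
    """Pick a cluster count by the largest relative gap in merge heights."""
    h = dend.heights
    n = dend.n_leaves
    best_k, best_gap = 2, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        lower = h[n - k - 1]
        upper = h[n - k]
        gap = (upper - lower) / lower if lower > 0 else np.inf
        if gap > best_gap:
            best_gap, best_k = gap, k
    return best_k


def conventional_model(table, k: int | None = None) -> np.ndarray:
    """Euclidean distances + Ward's linkage, cut to ``k`` clusters.

    When ``k`` is omitted it is chosen as the ``2 <= k <= 10`` maximizing
    the relative gap between successive merge heights.
    """
    X = np.asarray(table, dtype=float)
    d = pairwise_distances(X, 2.0)
    dend = agglomerate(d, "ward")
    if k is None:
        k = _auto_k(dend)
    return cut_by_count(dend, k)
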