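"""Benchmark machinery: adjusted Rand index, scenario runner, model comparison.

A benchmark run draws each trial of a :class:`~plasmahca.synthetic_data.Scenario`,
fits one of the two clustering models, and scores the result against the
known group labels with the Hubert–Arabie adjusted Rand index (ARI): 1 for
a perfect match, 0 in expectation for random assignment, negative for
worse-than-chance.  Two models are compared by a two-sided pooled-variance
t-test on their per-trial ARIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .consensus_hca import (
    GridConfig,
    NoRetainedModelsError,
    consensus_model,
    conventional_model,
)
from .synthetic_data import Scenario

__all__ = [
    "ARIResult",
    "ModelComparison",
    "adjusted_rand_index",
    "run_scenario",
    "compare_models",
]


@dataclass(frozen=True)
class ARIResult:
    """Per-trial ARI values (NaN = degenerate trial), their mean and SEM."""

    model: str
    values: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def mean(self) -> float:
        return float(self.valid.mean())

    @property
    def sem(self) -> float:
        v = self.valid
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")


@dataclass(frozen=True)
class ModelComparison:
    model_a: str
    model_b: str
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p value must be in [0, 1]")


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie ARI between two partitions of the same items.

    Computed from the contingency table as ``(Index - Expected) /
    (Max - Expected)``; invariant to label permutation, at most 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def run_scenario(
    scenario: Scenario,
    model: str = "conventional",
    grid: GridConfig | None = None,
    consensus_height: float | str = "gap",
) -> ARIResult:
    """Score one model over all trials of a scenario.

    The conventional model is cut to the true group count; the consensus
    model runs its full default grid.  A trial in which every consensus
    base model collapses to one cluster is recorded as NaN with a warning
    and excluded from the mean.
    """
    if model not in ("conventional", "consensus"):
        raise ValueError("model must be 'conventional' or 'consensus'")
    values = np.empty(scenario.n_trials)
    for t in range(scenario.n_trials):
        table, truth = scenario.generate_trial(t)
        if model == "conventional":
            labels = conventional_model(table, k=scenario.n_groups)
        else:
            try:
                labels = consensus_model(table, grid, consensus_height).labels
            except NoRetainedModelsError:
                warnings.warn(
                    f"trial {t}: no retained base models; ARI recorded as missing",
                    RuntimeWarning,
                    stacklevel=2,
                )
                values[t] = np.nan
                continue
        values[t] = adjusted_rand_index(truth, labels)
    return ARIResult(model=model, values=values)


def compare_models(a: ARIResult, b: ARIResult) -> ModelComparison:
    """Two-sided pooled-variance t-test on the per-trial ARIs."""
    xa, xb = a.valid, b.valid
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need at least 2 valid trials per model")
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        # degenerate: no spread in either sample
        t = 0.0 if xa.mean() == xb.mean() else float("inf")
        p = 1.0 if xa.mean() == xb.mean() else 0.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return ModelComparison(
        model_a=a.model, model_b=b.model, t_statistic=float(t), p_value=float(p)
    )
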