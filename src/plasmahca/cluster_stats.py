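"""Per-marker characterization of clusters.

Once a clustering model has split the cohort, each marker is compared
across clusters to find which proteins drive the separation.  The test
choice mirrors common biostatistics practice: a Levene variance gate
(centered on the mean) decides between the equal-variance and
unequal-variance branch.

Two clusters
    homogeneous variances -> pooled two-sample t; heterogeneous ->
    Welch–Satterthwaite t.

Three or more clusters
    homogeneous -> one-way ANOVA, post hoc Tukey HSD when significant;
    heterogeneous -> Welch's ANOVA, post hoc Dunnett T3 when significant.

Tests run on log-transformed values; descriptive means +/- SEM are
reported on the original pg/mL scale.  No multiplicity correction is
applied across markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "MarkerComparison",
    "levene_test",
    "two_group_compare",
    "multi_group_compare",
    "dunnett_t3",
    "marker_report",
]

_SMM_DRAWS = 100_000
_SMM_SEED = 20_201_120  # fixed: Dunnett T3 p-values are deterministic


@dataclass(frozen=True)
class MarkerComparison:
    """Result of comparing one marker across clusters."""

    marker: str
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    test: str  # pooled-t | satterthwaite-t | anova+tukey | welch+dunnett-t3
    statistic: float
    p_value: float
    levene_p: float
    posthoc: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p value must be in [0, 1]")
        if any(s < 0 for s in self.group_sems):
            raise ValueError("SEMs must be >= 0")


def _check_groups(groups, min_groups: int) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    return gs


def levene_test(groups) -> tuple[float, float]:
    """Levene's test centered on the mean: ANOVA F on |x - group mean|."""
    gs = _check_groups(groups, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.levene(*gs, center="mean")
    if np.isnan(stat):  # all deviations identical
        stat, p = 0.0, 1.0
    return float(stat), float(p)


def two_group_compare(x, y, alpha: float = 0.05, marker: str = "") -> MarkerComparison:
    """Two-cluster location test with a Levene variance gate.

    Heterogeneous variances (Levene p < alpha) use the Welch–Satterthwaite
    t-test; otherwise the pooled-variance t-test.  Two-sided p.
    """
    gs = _check_groups([x, y], 2)
    _, lev_p = levene_test(gs)
    equal_var = lev_p >= alpha
    t, p = stats.ttest_ind(gs[0], gs[1], equal_var=equal_var)
    if np.isnan(t):  # identical constant groups
        t, p = 0.0, 1.0
    return MarkerComparison(
        marker=marker,
        group_means=tuple(float(g.mean()) for g in gs),
        group_sems=tuple(float(stats.sem(g)) for g in gs),
        test="pooled-t" if equal_var else "satterthwaite-t",
        statistic=float(t),
        p_value=float(p),
        levene_p=lev_p,
    )


def _smm_sf(q: float, n_means: int, df: float, rng: np.random.Generator) -> float:
    """Monte-Carlo survival function of the studentized maximum modulus.

    SMM(m, nu) = max of m independent |N(0,1)| draws divided by
    sqrt(chi2_nu / nu).  No closed form exists; quantiles are estimated
    from a fixed-seed sample so results are deterministic.
    """
    z = np.abs(rng.standard_normal((_SMM_DRAWS, n_means))).max(axis=1)
    s = np.sqrt(rng.chisquare(df, _SMM_DRAWS) / df)
    return float(np.mean(z / s > q))


def dunnett_t3(groups, seed: int = _SMM_SEED) -> dict[tuple[int, int], float]:
    """Dunnett T3 all-pairs comparisons for heterogeneous variances.

    Each pair uses a Welch-type statistic
    ``|m_i - m_j| / sqrt(s_i^2/n_i + s_j^2/n_j)`` with Satterthwaite
    degrees of freedom, referred to the studentized maximum modulus
    distribution with m = number of pairs.  The Sidak-corrected Welch-t
    p-value is an upper bound on each T3 p-value (checked in tests).
    """
    gs = _check_groups(groups, 2)
    m = len(gs) * (len(gs) - 1) // 2
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(gs)), 2):
        vi, vj = gs[i].var(ddof=1), gs[j].var(ddof=1)
        ni, nj = gs[i].size, gs[j].size
        se2 = vi / ni + vj / nj
        if se2 == 0:
            out[(i, j)] = 1.0 if gs[i].mean() == gs[j].mean() else 0.0
            continue
        t = abs(gs[i].mean() - gs[j].mean()) / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        out[(i, j)] = _smm_sf(t, m, df, rng)
    return out


def multi_group_compare(groups, alpha: float = 0.05, marker: str = "") -> MarkerComparison:
    """Omnibus comparison of three or more clusters with post hoc pairs.

    Levene gate: homogeneous -> one-way ANOVA (+ Tukey HSD when the
    omnibus is significant); heterogeneous -> Welch's ANOVA (+ Dunnett T3
    when significant).
    """
    gs = _check_groups(groups, 3)
    _, lev_p = levene_test(gs)
    homogeneous = lev_p >= alpha
    if homogeneous:
        f, p = stats.f_oneway(*gs)
        if np.isnan(f):  # identical constant groups
            f, p = 0.0, 1.0
        test = "anova"
        posthoc: dict[tuple[int, int], float] = {}
        if p < alpha:
            res = stats.tukey_hsd(*gs)
            posthoc = {
                (i, j): float(res.pvalue[i, j])
                for i, j in combinations(range(len(gs)), 2)
            }
            test = "anova+tukey"
    else:
        res = anova_oneway(gs, use_var="unequal", welch_correction=True)
        f, p = float(res.statistic), float(res.pvalue)
        test = "welch"
        posthoc = {}
        if p < alpha:
            posthoc = dunnett_t3(gs)
            test = "welch+dunnett-t3"
    return MarkerComparison(
        marker=marker,
        group_means=tuple(float(g.mean()) for g in gs),
        group_sems=tuple(float(stats.sem(g)) for g in gs),
        test=test,
        statistic=float(f),
        p_value=float(p),
        levene_p=lev_p,
        posthoc=posthoc,
    )


def marker_report(
    raw_table: pd.DataFrame,
    log_table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
) -> list[MarkerComparison]:
    """Compare every marker across clusters.

    Tests use the log-transformed values; the reported means +/- SEM come
    from the raw pg/mL table, matching how panel results are usually
    presented.  Markers where any cluster has fewer than 2 samples are
    skipped with a warning entry (NaN statistic).
    """
    labels = np.asarray(labels)
    if not (len(labels) == raw_table.shape[0] == log_table.shape[0]):
        raise ValueError("tables and labels must cover the same samples")
    if not (raw_table.index.equals(log_table.index)):
        raise ValueError("raw and log tables must be aligned")
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("need at least 2 clusters to compare")
    report: list[MarkerComparison] = []
    for marker in raw_table.columns:
        log_groups = [log_table.loc[labels == k, marker].to_numpy() for k in ks]
        raw_groups = [raw_table.loc[labels == k, marker].to_numpy() for k in ks]
        means = tuple(float(g.mean()) for g in raw_groups)
        sems = tuple(
            float(stats.sem(g)) if g.size > 1 else 0.0 for g in raw_groups
        )
        if any(g.size < 2 for g in log_groups):
            import warnings

            warnings.warn(
                f"marker {marker!r}: a cluster has < 2 samples; test skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            report.append(
                MarkerComparison(
                    marker=str(marker),
                    group_means=means,
                    group_sems=sems,
                    test="skipped",
                    statistic=float("nan"),
                    p_value=1.0,
                    levene_p=float("nan"),
                )
            )
            continue
        if ks.size == 2:
            cmp = two_group_compare(*log_groups, alpha=alpha, marker=str(marker))
        else:
            cmp = multi_group_compare(log_groups, alpha=alpha, marker=str(marker))
        # swap in raw-scale descriptive statistics
        report.append(
            MarkerComparison(
                marker=cmp.marker,
                group_means=means,
                group_sems=sems,
                test=cmp.test,
                statistic=cmp.statistic,
                p_value=cmp.p_value,
                levene_p=cmp.levene_p,
                posthoc=cmp.posthoc,
            )
        )
    return report
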