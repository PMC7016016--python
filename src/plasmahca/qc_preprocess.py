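"""Plate-level QC for duplicate-well multiplex immunoassay data.

Raw electrochemiluminescence panels arrive as duplicate wells per sample
per marker, spread over several plates that each carry three pooled
control samples (run twice, in duplicate — four wells per control per
marker).  The pipeline turns this into the cleaned table the clustering
models consume:

1. drop markers whose duplicate-well CV is >= ``cv_cutoff`` in at least
   ``sample_frac_cutoff`` of samples (imprecise assays);
2. drop markers whose pooled-control CV, averaged over the three controls,
   exceeds ``cv_cutoff`` (irreproducible assays);
3. collapse duplicates to their mean, divide each plate by its
   control-derived scaling factor (inter-plate batch correction);
4. log-transform so all markers share an order of magnitude;
5. iteratively apply Grubbs' two-sided outlier test per marker and drop
   any sample flagged in one or more markers.

Everything is deterministic: the same input always yields the same
:class:`QCReport`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateDataset",
    "QCThresholds",
    "QCReport",
    "GrubbsResult",
    "duplicate_cv",
    "sample_duplicate_cvs",
    "filter_markers_by_sample_cv",
    "filter_markers_by_control_cv",
    "working_table",
    "compute_plate_scaling",
    "apply_plate_scaling",
    "log_transform",
    "grubbs_test",
    "grubbs_outliers",
    "exclude_outlier_samples",
    "run_qc",
]

_COLUMNS = (
    "sample_id",
    "plate_id",
    "marker",
    "replicate",
    "value",
    "is_control",
    "control_id",
    "run",
)


@dataclass(frozen=True)
class PlateDataset:
    """Long-format plate data: duplicate sample wells plus pooled controls.

    ``data`` columns: sample_id, plate_id, marker, replicate (1/2), value,
    is_control, control_id (controls only), run (controls only, 1/2).
    Every sample sits on exactly one plate; every plate carries the same
    set of pooled controls for every marker.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"plate data missing columns: {sorted(missing)}")
        plates_per_sample = (
            df.loc[~df["is_control"]].groupby("sample_id")["plate_id"].nunique()
        )
        if (plates_per_sample > 1).any():
            bad = plates_per_sample[plates_per_sample > 1].index.tolist()
            raise ValueError(f"samples on more than one plate: {bad}")

    @property
    def markers(self) -> list[str]:
        return sorted(self.data["marker"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data.loc[~self.data["is_control"], "sample_id"].unique())

    @property
    def plates(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    def sample_rows(self) -> pd.DataFrame:
        return self.data.loc[~self.data["is_control"]]

    def control_rows(self) -> pd.DataFrame:
        return self.data.loc[self.data["is_control"]]


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for the QC pipeline (defaults follow standard MSD practice)."""

    cv_cutoff: float = 0.25
    sample_frac_cutoff: float = 0.20
    grubbs_alpha: float = 0.05
    log_base: float = 10.0

    def __post_init__(self) -> None:
        for name in ("cv_cutoff", "sample_frac_cutoff", "grubbs_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not self.log_base > 1:
            raise ValueError("log_base must be > 1")


@dataclass(frozen=True)
class GrubbsResult:
    """One Grubbs step: statistic, two-sided critical value, flagged index."""

    G: float
    critical: float
    outlier_index: int | None

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("G must be >= 0")


@dataclass
class QCReport:
    """Everything the QC pipeline decided, plus the retained clean table."""

    dropped_markers: dict[str, str]
    scaling_factors: pd.DataFrame  # plates x markers
    excluded_samples: dict[str, list[str]]  # sample -> offending markers
    table: pd.DataFrame  # retained samples x markers, log scale
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    notes: str = "sample working value = mean of the two duplicate wells"

    def to_dict(self) -> dict:
        return {
            "dropped_markers": self.dropped_markers,
            "scaling_factors": {
                p: self.scaling_factors.loc[p].to_dict()
                for p in self.scaling_factors.index
            },
            "excluded_samples": self.excluded_samples,
            "n_retained_samples": int(self.table.shape[0]),
            "retained_markers": list(self.table.columns),
            "thresholds": {
                "cv_cutoff": self.thresholds.cv_cutoff,
                "sample_frac_cutoff": self.thresholds.sample_frac_cutoff,
                "grubbs_alpha": self.thresholds.grubbs_alpha,
                "log_base": self.thresholds.log_base,
            },
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def duplicate_cv(a: float, b: float) -> float:
    """CV of a duplicate pair: sample sd of {a, b} over their mean."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("duplicate values must be finite")
    mean = (a + b) / 2
    if mean == 0:
        raise ValueError("duplicate mean is zero; CV undefined")
    sd = abs(a - b) / math.sqrt(2)  # sample sd of two values
    return sd / mean


def sample_duplicate_cvs(dataset: PlateDataset) -> pd.DataFrame:
    """Per-sample, per-marker duplicate CV (samples x markers)."""
    rows = dataset.sample_rows()
    wide = rows.pivot_table(
        index="sample_id", columns="marker", values="value", aggfunc=list
    )

    def _cv(pair):
        if not isinstance(pair, list) or len(pair) != 2:
            raise ValueError("every sample needs exactly two duplicate wells")
        return duplicate_cv(pair[0], pair[1])

    return wide.map(_cv)


def filter_markers_by_sample_cv(
    dataset: PlateDataset, thr: QCThresholds = QCThresholds()
) -> tuple[list[str], list[str]]:
    """Split markers by the duplicate-CV rule.

    A marker is dropped when the fraction of samples whose duplicate CV is
    at or above ``cv_cutoff`` reaches ``sample_frac_cutoff`` (both bounds
    inclusive).
    """
    cvs = sample_duplicate_cvs(dataset)
    if cvs.isna().any().any():
        bad = cvs.columns[cvs.isna().any()].tolist()
        raise ValueError(f"markers with missing duplicate pairs: {bad}")
    flagged_frac = (cvs >= thr.cv_cutoff).mean(axis=0)
    dropped = flagged_frac[flagged_frac >= thr.sample_frac_cutoff].index.tolist()
    kept = [m for m in cvs.columns if m not in dropped]
    return kept, dropped


def _control_cvs(dataset: PlateDataset) -> pd.DataFrame:
    """CV of each pooled control's four wells, per (plate, control, marker)."""
    ctrl = dataset.control_rows()
    if ctrl.empty:
        raise ValueError("dataset has no pooled controls")
    grouped = ctrl.groupby(["plate_id", "control_id", "marker"])["value"]
    stats_df = grouped.agg(["mean", "std", "count"]).reset_index()
    if (stats_df["count"] < 2).any():
        raise ValueError("each pooled control needs repeated measurements")
    stats_df["cv"] = stats_df["std"] / stats_df["mean"]
    return stats_df


def filter_markers_by_control_cv(
    dataset: PlateDataset, thr: QCThresholds = QCThresholds()
) -> tuple[list[str], list[str]]:
    """Split markers by the pooled-control reproducibility rule.

    Per marker, the CV of each control's repeated wells is averaged over
    the controls (and plates); the marker is dropped when that average is
    strictly greater than ``cv_cutoff``.
    """
    cv = _control_cvs(dataset)
    n_controls = cv.groupby(["plate_id", "marker"])["control_id"].nunique()
    if n_controls.nunique() > 1:
        raise ValueError("unequal pooled-control counts across plates/markers")
    avg = cv.groupby("marker")["cv"].mean()
    dropped = avg[avg > thr.cv_cutoff].index.tolist()
    kept = [m for m in avg.index if m not in dropped]
    return kept, dropped


def working_table(
    dataset: PlateDataset, markers: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse duplicates to their mean; return (table, sample -> plate)."""
    rows = dataset.sample_rows()
    if markers is not None:
        rows = rows.loc[rows["marker"].isin(markers)]
    table = rows.pivot_table(
        index="sample_id", columns="marker", values="value", aggfunc="mean"
    )
    plate_of = rows.groupby("sample_id")["plate_id"].first()
    return table, plate_of.loc[table.index]


def compute_plate_scaling(
    dataset: PlateDataset,
    markers: list[str] | None = None,
    grand_mean: str = "per_control",
) -> pd.DataFrame:
    """Per-plate, per-marker scaling factor from the pooled controls.

    Each control's plate value (mean of its four wells) is divided by that
    control's grand mean across plates (``grand_mean='per_control'``; with
    ``'pooled'`` a single per-marker grand mean is used) and the ratios are
    averaged over the three controls.  Dividing a plate's values by this
    factor equalizes control levels across plates.
    """
    if grand_mean not in ("per_control", "pooled"):
        raise ValueError("grand_mean must be 'per_control' or 'pooled'")
    ctrl = dataset.control_rows()
    if markers is not None:
        ctrl = ctrl.loc[ctrl["marker"].isin(markers)]
    if (ctrl["value"] <= 0).any():
        raise ValueError("pooled-control values must be positive")
    per_plate = (
        ctrl.groupby(["plate_id", "control_id", "marker"])["value"]
        .mean()
        .rename("control_value")
        .reset_index()
    )
    grand_cols = ["marker"] if grand_mean == "pooled" else ["marker", "control_id"]
    grand = per_plate.groupby(grand_cols)["control_value"].mean().rename("grand")
    merged = per_plate.join(grand, on=grand_cols)
    if (merged["grand"] == 0).any():
        raise ValueError("zero grand control mean")
    merged["ratio"] = merged["control_value"] / merged["grand"]
    factors = merged.pivot_table(
        index="plate_id", columns="marker", values="ratio", aggfunc="mean"
    )
    return factors


def apply_plate_scaling(
    table: pd.DataFrame, plate_of: pd.Series, factors: pd.DataFrame
) -> pd.DataFrame:
    """Divide every value by its plate's scaling factor for that marker."""
    missing_plates = set(plate_of.unique()) - set(factors.index)
    if missing_plates:
        raise ValueError(f"no scaling factors for plates: {sorted(missing_plates)}")
    missing_markers = set(table.columns) - set(factors.columns)
    if missing_markers:
        raise ValueError(f"no scaling factors for markers: {sorted(missing_markers)}")
    per_sample = factors.loc[plate_of.loc[table.index], table.columns]
    per_sample.index = table.index
    return table / per_sample


def log_transform(table: pd.DataFrame, base: float = 10.0) -> pd.DataFrame:
    """Elementwise logarithm; every value must be strictly positive."""
    if not base > 1:
        raise ValueError("log base must be > 1")
    values = table.to_numpy(dtype=float)
    if np.any(values <= 0):
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive value for sample {table.index[i]!r}, "
            f"marker {table.columns[j]!r}: cannot log-transform"
        )
    return pd.DataFrame(
        np.log(values) / np.log(base), index=table.index, columns=table.columns
    )


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """One two-sided Grubbs step on a vector.

    ``G = max_i |x_i - mean| / sd`` (sample sd) against the critical value
    ``((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the upper
    ``alpha/(2n)`` Student-t quantile at ``n - 2`` degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs test undefined for zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = dev[idx] / sd
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    critical = ((n - 1) / math.sqrt(n)) * math.sqrt(t**2 / (n - 2 + t**2))
    return GrubbsResult(
        G=float(G), critical=float(critical), outlier_index=idx if G > critical else None
    )


def grubbs_outliers(values, alpha: float = 0.05) -> list[int]:
    """Iterative Grubbs: re-test after each removal until nothing is flagged.

    Returns indices into the original vector, in order of removal.  The
    initial vector must satisfy the test's preconditions; iteration stops
    quietly if removals shrink the remainder below n = 3 or to zero spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if x.std(ddof=1) == 0:
        raise ValueError("Grubbs test undefined for zero variance")
    alive = list(range(x.size))
    flagged: list[int] = []
    while len(alive) >= 3 and np.std(x[alive], ddof=1) > 0:
        res = grubbs_test(x[alive], alpha)
        if res.outlier_index is None:
            break
        flagged.append(alive.pop(res.outlier_index))
    return flagged


def exclude_outlier_samples(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Drop every sample flagged by iterative Grubbs in one or more markers.

    Runs per marker column of the (log-scale) table; returns the reduced
    table and a mapping of excluded sample -> offending markers.
    """
    excluded: dict[str, list[str]] = {}
    for marker in table.columns:
        for i in grubbs_outliers(table[marker].to_numpy(), alpha):
            sid = str(table.index[i])
            excluded.setdefault(sid, []).append(str(marker))
    kept = table.drop(index=list(excluded))
    return kept, excluded


def run_qc(dataset: PlateDataset, thr: QCThresholds = QCThresholds()) -> QCReport:
    """Full deterministic QC pipeline; see module docstring for the order."""
    _, dropped_sample_cv = filter_markers_by_sample_cv(dataset, thr)
    _, dropped_control_cv = filter_markers_by_control_cv(dataset, thr)
    dropped: dict[str, str] = {m: "intra-CV" for m in dropped_sample_cv}
    for m in dropped_control_cv:
        dropped[m] = "control-CV" if m not in dropped else "intra-CV;control-CV"
    kept_markers = [m for m in dataset.markers if m not in dropped]
    if not kept_markers:
        raise ValueError("all markers failed QC")
    table, plate_of = working_table(dataset, kept_markers)
    factors = compute_plate_scaling(dataset, kept_markers)
    scaled = apply_plate_scaling(table, plate_of, factors)
    logged = log_transform(scaled, thr.log_base)
    clean, excluded = exclude_outlier_samples(logged, thr.grubbs_alpha)
    return QCReport(
        dropped_markers=dropped,
        scaling_factors=factors,
        excluded_samples=excluded,
        table=clean,
        thresholds=thr,
    )
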