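"""Seeded simulation scenarios and a plate-structured raw-assay emulator.

The multivariate-normal scenarios reproduce the benchmark design used to
compare the two clustering models: every scenario draws 11 variables and
100 samples per group, is run over 35 trials, and trial ``t`` is seeded
with ``base_seed + t`` so every number in a benchmark is a pure function of
the scenario and its base seed.

Preset families
---------------
``distant`` / ``close`` control mean separation (8 vs 1.5 within-group
standard deviations per affected variable); ``uniform`` / ``variable``
control whether groups share one covariance scale or have group-specific
scales; ``predicted_*`` are heavily overlapping groups (separation 0.5)
with compound-symmetric (non-diagonal) covariance, emulating the diffuse
structure expected of a real plasma-biomarker cohort.  Distant-family
groups differ in every variable; close-family groups share means on the
first six variables and differ with opposite signs on the remaining five.
For ``variable`` covariances, separation is measured in units of the
largest group standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PRESETS",
    "Scenario",
    "sample_mvn",
    "make_scenario",
    "bhattacharyya_distance",
    "emulate_plate_data",
]

N_VARIABLES = 11
N_PER_GROUP = 100
N_TRIALS = 35

PRESETS = (
    "two_distant_uniform",
    "two_distant_variable",
    "three_distant_uniform",
    "three_distant_variable",
    "two_close_uniform",
    "two_close_variable",
    "three_close_uniform",
    "three_close_variable",
    "predicted_two",
    "predicted_three",
)

_DEFAULT_SEPARATION = {"distant": 8.0, "close": 1.5, "predicted": 0.5}
# group-specific sd scales for the 'variable' covariance family
_VARIABLE_SCALES = {2: (1.0, 2.0), 3: (1.0, 2.0, 1.5)}


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation: group MVN parameters, sizes, seeds."""

    name: str
    means: np.ndarray  # (k, n_vars)
    covariances: np.ndarray  # (k, n_vars, n_vars)
    group_sizes: tuple[int, ...]
    n_trials: int = N_TRIALS
    base_seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        if means.ndim != 2 or covs.shape != (*means.shape, means.shape[1]):
            raise ValueError("means must be (k, d) and covariances (k, d, d)")
        if len(self.group_sizes) != means.shape[0]:
            raise ValueError("one group size per group required")
        for S in covs:
            if not np.allclose(S, S.T):
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ValueError("covariances must be positive semi-definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)

    @property
    def n_groups(self) -> int:
        return self.means.shape[0]

    def trial_seed(self, trial: int) -> int:
        return self.base_seed + trial

    def generate_trial(self, trial: int) -> tuple[pd.DataFrame, np.ndarray]:
        """Draw one trial: a samples x variables table plus true labels."""
        if not 0 <= trial < self.n_trials:
            raise ValueError(f"trial must be in [0, {self.n_trials})")
        rng = np.random.default_rng(self.trial_seed(trial))
        blocks, labels = [], []
        for g, (mu, S, n) in enumerate(
            zip(self.means, self.covariances, self.group_sizes), start=1
        ):
            blocks.append(
                rng.multivariate_normal(mu, S, size=n, check_valid="raise", method="svd")
            )
            labels.extend([g] * n)
        X = np.vstack(blocks)
        table = pd.DataFrame(
            X,
            index=[f"S{i:04d}" for i in range(X.shape[0])],
            columns=[f"V{j + 1:02d}" for j in range(X.shape[1])],
        )
        return table, np.asarray(labels, dtype=np.int64)


def sample_mvn(mu, sigma, n: int, seed: int) -> np.ndarray:
    """``n`` seeded draws from a multivariate normal (PSD sigma required)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mu, sigma, size=n, check_valid="raise", method="svd")


def _parse_preset(preset: str) -> tuple[int, str, str]:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    if preset.startswith("predicted"):
        k = 2 if preset.endswith("two") else 3
        return k, "predicted", "uniform"
    count, family, cov = preset.split("_")
    return {"two": 2, "three": 3}[count], family, cov


def make_scenario(
    preset: str,
    separation: float | None = None,
    seed: int = 0,
    n_per_group: int = N_PER_GROUP,
    n_trials: int = N_TRIALS,
) -> Scenario:
    """Build one of the named benchmark scenarios.

    ``separation`` overrides the family default (8 for distant, 1.5 for
    close, 0.5 for predicted), in units of the largest within-group sd.
    """
    k, family, cov = _parse_preset(preset)
    if separation is None:
        separation = _DEFAULT_SEPARATION[family]
    if separation < 0:
        raise ValueError("separation must be >= 0")

    scales = np.ones(k) if cov == "uniform" else np.asarray(_VARIABLE_SCALES[k])
    step = separation * scales.max()
    offsets = (np.arange(k) - (k - 1) / 2) * step

    means = np.zeros((k, N_VARIABLES))
    if family == "close":
        # groups agree on the first six variables and take offsets of
        # opposite signs on the remaining five
        means[:, 6:] = offsets[:, None]
    else:
        means[:, :] = offsets[:, None]

    if family == "predicted":
        # overlapping groups with correlated markers: compound symmetry,
        # unit variances, rho = 0.5
        base = 0.5 * np.eye(N_VARIABLES) + 0.5 * np.ones((N_VARIABLES, N_VARIABLES))
        covs = np.stack([base] * k)
    else:
        covs = np.stack([s**2 * np.eye(N_VARIABLES) for s in scales])

    return Scenario(
        name=preset,
        means=means,
        covariances=covs,
        group_sizes=(n_per_group,) * k,
        n_trials=n_trials,
        base_seed=seed,
    )


def bhattacharyya_distance(mu1, sigma1, mu2, sigma2) -> float:
    """Bhattacharyya distance between two Gaussians (0 = identical)."""
    mu1, mu2 = np.asarray(mu1, float), np.asarray(mu2, float)
    S1, S2 = np.asarray(sigma1, float), np.asarray(sigma2, float)
    S = (S1 + S2) / 2
    dm = mu1 - mu2
    term1 = 0.125 * dm @ np.linalg.solve(S, dm)
    _, logdet = np.linalg.slogdet(S)
    _, logdet1 = np.linalg.slogdet(S1)
    _, logdet2 = np.linalg.slogdet(S2)
    return float(term1 + 0.5 * (logdet - 0.5 * (logdet1 + logdet2)))


def emulate_plate_data(
    table: pd.DataFrame,
    n_plates: int = 3,
    plate_bias_sd: float = 0.0,
    duplicate_cv: float = 0.0,
    seed: int = 0,
    cv_overrides: dict | None = None,
    n_controls: int = 3,
):
    """Turn a clean concentration table into plate-structured duplicate data.

    Samples are assigned to ``n_plates`` plates in contiguous blocks.  Every
    value on plate ``q`` is multiplied by a per-plate, per-marker lognormal
    bias ``exp(N(0, plate_bias_sd^2))`` — the batch effect the plate-scaling
    step is meant to remove — then split into two duplicate wells
    ``v (1 +/- cv / sqrt(2))`` (random sign) so the duplicate-pair CV equals
    ``cv`` exactly.  Each plate also carries ``n_controls`` pooled controls
    per marker, the same aliquot on every plate (true value = geometric mean
    of the marker column), measured as two duplicate-well runs each.

    ``cv_overrides`` maps ``marker -> (cv, fraction_of_samples)`` to inject
    elevated duplicate scatter into a seeded random subset of samples for
    that marker (for exercising the marker-level CV filters).

    Returns a :class:`plasmahca.qc_preprocess.PlateDataset`.
    """
    from .qc_preprocess import PlateDataset

    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if plate_bias_sd < 0 or duplicate_cv < 0:
        raise ValueError("noise parameters must be >= 0")
    values = table.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("raw concentrations must be positive")
    rng = np.random.default_rng(seed)
    samples = list(table.index.astype(str))
    markers = list(table.columns.astype(str))
    n = len(samples)

    bounds = np.linspace(0, n, n_plates + 1).astype(int)
    plate_of = np.empty(n, dtype=int)
    for q in range(n_plates):
        plate_of[bounds[q] : bounds[q + 1]] = q

    bias = (
        np.exp(rng.normal(0.0, plate_bias_sd, size=(n_plates, len(markers))))
        if plate_bias_sd > 0
        else np.ones((n_plates, len(markers)))
    )

    cv = np.full((n, len(markers)), float(duplicate_cv))
    for m, (over_cv, frac) in (cv_overrides or {}).items():
        j = markers.index(m)
        n_hit = int(round(frac * n))
        hit = rng.choice(n, size=n_hit, replace=False)
        cv[hit, j] = over_cv

    rows = []
    sign = rng.choice([-1.0, 1.0], size=(n, len(markers)))
    for i, sid in enumerate(samples):
        q = plate_of[i]
        for j, m in enumerate(markers):
            v = values[i, j] * bias[q, j]
            delta = sign[i, j] * cv[i, j] / np.sqrt(2)
            for rep, well in ((1, v * (1 + delta)), (2, v * (1 - delta))):
                rows.append(
                    (sid, f"P{q + 1}", m, rep, well, False, None, None)
                )

    ctrl_true = np.exp(np.log(values).mean(axis=0))  # geometric mean per marker
    ctrl_sign = rng.choice(
        [-1.0, 1.0], size=(n_plates, n_controls, 2, len(markers))
    )
    for q in range(n_plates):
        for c in range(n_controls):
            for run in (1, 2):
                for j, m in enumerate(markers):
                    v = ctrl_true[j] * bias[q, j]
                    delta = (
                        ctrl_sign[q, c, run - 1, j] * duplicate_cv / np.sqrt(2)
                    )
                    for rep, well in ((1, v * (1 + delta)), (2, v * (1 - delta))):
                        rows.append(
                            (
                                f"CTRL{c + 1}_run{run}",
                                f"P{q + 1}",
                                m,
                                rep,
                                well,
                                True,
                                f"C{c + 1}",
                                run,
                            )
                        )

    data = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "plate_id",
            "marker",
            "replicate",
            "value",
            "is_control",
            "control_id",
            "run",
        ],
    )
    return PlateDataset(data)
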