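"""Plate QC: CV filters, plate scaling, log transform, Grubbs exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmahca.qc_preprocess import (
    PlateDataset,
    QCThresholds,
    apply_plate_scaling,
    compute_plate_scaling,
    duplicate_cv,
    exclude_outlier_samples,
    filter_markers_by_control_cv,
    filter_markers_by_sample_cv,
    grubbs_outliers,
    grubbs_test,
    log_transform,
    run_qc,
    working_table,
)
from plasmahca.synthetic_data import emulate_plate_data


def _dataset(sample_wells, control_value=10.0, markers=("A",), n_plates=1):
    """Small PlateDataset: sample_wells[sample][marker] = (w1, w2)."""
    rows = []
    sids = sorted(sample_wells)
    for idx, sid in enumerate(sids):
        plate = f"P{idx * n_plates // len(sids) + 1}"
        for m in markers:
            w1, w2 = sample_wells[sid][m]
            rows.append((sid, plate, m, 1, w1, False, None, None))
            rows.append((sid, plate, m, 2, w2, False, None, None))
    for q in range(n_plates):
        for c in range(3):
            for run in (1, 2):
                for m in markers:
                    v = control_value
                    rows.append(
                        (f"CTRL{c}_r{run}", f"P{q + 1}", m, 1, v, True, f"C{c + 1}", run)
                    )
                    rows.append(
                        (f"CTRL{c}_r{run}", f"P{q + 1}", m, 2, v, True, f"C{c + 1}", run)
                    )
    return PlateDataset(
        pd.DataFrame(
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
    )


def _pair_with_cv(mean, cv):
    delta = cv / np.sqrt(2)
    return (mean * (1 + delta), mean * (1 - delta))


class TestDuplicateCV:
    def test_equal_duplicates_zero(self):
        assert duplicate_cv(10, 10) == 0.0

    def test_hand_value(self):
        # sd of {8, 12} is sqrt(8), mean 10
        assert duplicate_cv(8, 12) == pytest.approx(np.sqrt(8) / 10)

    def test_zero_mean_error(self):
        with pytest.raises(ValueError):
            duplicate_cv(0, 0)

    def test_constructed_cv_exact(self):
        a, b = _pair_with_cv(50.0, 0.3)
        assert duplicate_cv(a, b) == pytest.approx(0.3)


class TestSampleCVFilter:
    @pytest.mark.parametrize(
        "n_flagged, dropped",
        [(21, True), (20, True), (19, False)],  # 20% boundary is inclusive
    )
    def test_20_percent_boundary(self, n_flagged, dropped):
        wells = {}
        for i in range(100):
            cv = 0.30 if i < n_flagged else 0.05
            wells[f"S{i:03d}"] = {"A": _pair_with_cv(10.0, cv)}
        _, removed = filter_markers_by_sample_cv(_dataset(wells))
        assert (["A"] == removed) is dropped

    def test_flag_threshold_is_inclusive(self):
        # a duplicate CV exactly at the cutoff counts as flagged: run the
        # filter with the cutoff set to the measured CV itself
        from plasmahca.qc_preprocess import sample_duplicate_cvs

        wells = {f"S{i}": {"A": _pair_with_cv(10.0, 0.25)} for i in range(5)}
        ds = _dataset(wells)
        measured = float(sample_duplicate_cvs(ds)["A"].iloc[0])
        thr = QCThresholds(cv_cutoff=measured)
        _, removed = filter_markers_by_sample_cv(ds, thr)
        assert removed == ["A"]


class TestControlCVFilter:
    def _with_control_cvs(self, cvs):
        rows = []
        wells = {"S0": {"A": (10.0, 10.0)}}
        ds = _dataset(wells)
        df = ds.data.copy()
        ctrl = df["is_control"]
        for cid, cv in zip(("C1", "C2", "C3"), cvs):
            mask = ctrl & (df["control_id"] == cid)
            values = df.loc[mask, "value"].to_numpy()
            # four wells v(1 +/- d) x2 have CV = 2 d / sqrt(3)
            delta = cv * np.sqrt(3) / 2 * np.tile([1.0, -1.0], len(values) // 2)
            df.loc[mask, "value"] = values * (1 + delta)
        return PlateDataset(df)

    def test_average_above_cutoff_dropped(self):
        ds = self._with_control_cvs([0.30, 0.30, 0.30])
        _, removed = filter_markers_by_control_cv(ds)
        assert removed == ["A"]

    def test_boundary_is_strict(self):
        # a marker whose average control CV sits exactly at the cutoff
        # survives: the rule is 'strictly greater than'
        from plasmahca.qc_preprocess import _control_cvs

        ds = self._with_control_cvs([0.25, 0.25, 0.25])
        measured_avg = float(_control_cvs(ds).groupby("marker")["cv"].mean()["A"])
        thr = QCThresholds(cv_cutoff=measured_avg)
        kept, removed = filter_markers_by_control_cv(ds, thr)
        assert kept == ["A"] and removed == []

    def test_perfect_replication_kept(self):
        ds = self._with_control_cvs([0.0, 0.0, 0.0])
        kept, _ = filter_markers_by_control_cv(ds)
        assert kept == ["A"]


class TestPlateScaling:
    def _two_plate_ds(self, control_values):
        """control_values[plate] = scalar applied to all three controls."""
        rows = []
        for q, cval in enumerate(control_values):
            sid = f"S{q}"
            rows.append((sid, f"P{q + 1}", "A", 1, 50.0, False, None, None))
            rows.append((sid, f"P{q + 1}", "A", 2, 50.0, False, None, None))
            for c in range(3):
                for run in (1, 2):
                    for rep in (1, 2):
                        rows.append(
                            (f"CT{c}_{run}", f"P{q + 1}", "A", rep, cval, True, f"C{c + 1}", run)
                        )
        return PlateDataset(
            pd.DataFrame(rows, columns=list(_dataset({"S0": {"A": (1, 1)}}).data.columns))
        )

    def test_identity_factor(self):
        ds = self._two_plate_ds([10.0, 10.0])
        factors = compute_plate_scaling(ds)
        np.testing.assert_allclose(factors.to_numpy(), 1.0)

    def test_uniform_doubling(self):
        ds = self._two_plate_ds([20.0, 10.0])
        factors = compute_plate_scaling(ds)
        # grand mean 15 -> plate factors 20/15 and 10/15
        np.testing.assert_allclose(
            sorted(factors["A"]), [10 / 15, 20 / 15]
        )

    def test_symmetric_offsets_cancel(self):
        # plate controls (12, 8, 10) against grand mean 10 -> factor 1
        rows = []
        rows.append(("S0", "P1", "A", 1, 50.0, False, None, None))
        rows.append(("S0", "P1", "A", 2, 50.0, False, None, None))
        for c, v in enumerate((12.0, 8.0, 10.0)):
            for run in (1, 2):
                for rep in (1, 2):
                    rows.append((f"CT{c}", "P1", "A", rep, v, True, f"C{c + 1}", run))
        ds = PlateDataset(
            pd.DataFrame(rows, columns=list(_dataset({"S0": {"A": (1, 1)}}).data.columns))
        )
        factors = compute_plate_scaling(ds, grand_mean="pooled")
        assert factors.loc["P1", "A"] == pytest.approx(1.0)

    def test_apply_scaling_values(self):
        table = pd.DataFrame({"A": [50.0]}, index=["S0"])
        plate_of = pd.Series({"S0": "P1"})
        factors = pd.DataFrame({"A": [2.0]}, index=["P1"])
        out = apply_plate_scaling(table, plate_of, factors)
        assert out.loc["S0", "A"] == 25.0
        factors_one = pd.DataFrame({"A": [1.0]}, index=["P1"])
        assert apply_plate_scaling(table, plate_of, factors_one).loc["S0", "A"] == 50.0

    def test_missing_factor_errors(self):
        table = pd.DataFrame({"A": [50.0]}, index=["S0"])
        plate_of = pd.Series({"S0": "P9"})
        factors = pd.DataFrame({"A": [2.0]}, index=["P1"])
        with pytest.raises(ValueError, match="P9"):
            apply_plate_scaling(table, plate_of, factors)

    def test_scaled_controls_equalize_across_plates(self, raw_concentrations):
        ds = emulate_plate_data(
            raw_concentrations, n_plates=3, plate_bias_sd=0.25, seed=7
        )
        factors = compute_plate_scaling(ds)
        ctrl = ds.control_rows().copy()
        ctrl["factor"] = [
            factors.loc[p, m] for p, m in zip(ctrl["plate_id"], ctrl["marker"])
        ]
        ctrl["scaled"] = ctrl["value"] / ctrl["factor"]
        per_plate = ctrl.groupby(["marker", "plate_id"])["scaled"].mean().unstack()
        spread = per_plate.max(axis=1) - per_plate.min(axis=1)
        np.testing.assert_allclose(spread.to_numpy(), 0.0, atol=1e-9 * per_plate.to_numpy().max())


class TestLogTransform:
    def test_known_values(self):
        table = pd.DataFrame({"A": [100.0, 1.0]}, index=["s", "t"])
        out = log_transform(table, 10.0)
        assert out["A"].tolist() == pytest.approx([2.0, 0.0])

    def test_nonpositive_names_offender(self):
        table = pd.DataFrame({"A": [1.0], "B": [-1.0]}, index=["s1"])
        with pytest.raises(ValueError, match=r"s1.*B"):
            log_transform(table)


class TestGrubbs:
    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            grubbs_test([5, 5, 5, 5])
        with pytest.raises(ValueError):
            grubbs_test([1, 2])

    def test_hand_case_flags_extreme(self):
        res = grubbs_test([1, 2, 3, 100], alpha=0.05)
        assert res.G == pytest.approx(1.4998, abs=1e-4)
        # critical value from the t-quantile formula, recomputed directly
        t = stats.t.ppf(1 - 0.05 / 8, 2)
        expected_crit = (3 / 2) * np.sqrt(t**2 / (2 + t**2))
        assert res.critical == pytest.approx(expected_crit)
        assert res.critical == pytest.approx(1.481, abs=2e-3)
        assert res.outlier_index == 3

    def test_standard_normal_rarely_flags(self):
        rng = np.random.default_rng(3)
        flagged = sum(
            bool(grubbs_outliers(rng.standard_normal(50), alpha=0.05))
            for _ in range(200)
        )
        # false-positive rate is roughly alpha
        assert flagged / 200 == pytest.approx(0.05, abs=0.05)

    def test_iterative_removal(self):
        x = np.concatenate([np.zeros(20) + np.linspace(-1, 1, 20), [40.0, 45.0]])
        out = grubbs_outliers(x, alpha=0.05)
        assert set(out) == {20, 21}


class TestExcludeOutliers:
    def _table(self, rng, n=30):
        return pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"S{i:03d}" for i in range(n)],
            columns=["A", "B", "C"],
        )

    def test_clean_table_unchanged(self, rng):
        table = self._table(rng)
        out, excluded = exclude_outlier_samples(table)
        if not excluded:  # seeded: no outliers in this draw
            pd.testing.assert_frame_equal(out, table)

    def test_planted_outlier_removed(self, rng):
        table = self._table(rng)
        table.loc["S005", "B"] = 10.0 * table["B"].std() + table["B"].mean()
        out, excluded = exclude_outlier_samples(table)
        assert "S005" in excluded
        assert "B" in excluded["S005"]
        assert "S005" not in out.index

    def test_idempotent_on_own_output(self, rng):
        table = self._table(rng)
        table.loc["S005", "B"] = 10.0 * table["B"].std()
        once, _ = exclude_outlier_samples(table)
        twice, again = exclude_outlier_samples(once)
        assert not again
        pd.testing.assert_frame_equal(once, twice)

    def test_output_strict_subset(self, rng):
        table = self._table(rng)
        table.loc["S000", "A"] = 50.0
        out, _ = exclude_outlier_samples(table)
        assert set(out.index) < set(table.index)


class TestPipeline:
    def test_noise_free_round_trip(self, raw_concentrations):
        ds = emulate_plate_data(raw_concentrations, n_plates=2, seed=0)
        report = run_qc(ds)
        assert not report.dropped_markers
        recovered = 10.0**report.table
        kept = raw_concentrations.loc[report.table.index, report.table.columns]
        np.testing.assert_allclose(recovered.to_numpy(), kept.to_numpy(), rtol=1e-9)

    def test_plate_bias_removed(self, raw_concentrations):
        biased = emulate_plate_data(
            raw_concentrations, n_plates=3, plate_bias_sd=0.2, seed=11
        )
        report = run_qc(biased)
        recovered = 10.0**report.table
        kept = raw_concentrations.loc[report.table.index, report.table.columns]
        # scaling removes the per-plate bias up to one constant per marker
        # (the cross-plate mean bias), so recovered / true must be constant
        # within each marker column
        ratio = recovered.to_numpy() / kept.to_numpy()
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[0], ratio.shape), rtol=1e-9
        )

    def test_high_cv_marker_dropped(self, raw_concentrations):
        ds = emulate_plate_data(
            raw_concentrations,
            n_plates=2,
            seed=5,
            cv_overrides={"VEGF": (0.4, 0.25)},
        )
        report = run_qc(ds)
        assert report.dropped_markers.get("VEGF") == "intra-CV"
        assert "VEGF" not in report.table.columns

    def test_report_is_deterministic(self, raw_concentrations):
        ds = emulate_plate_data(raw_concentrations, n_plates=2, plate_bias_sd=0.1, seed=3)
        r1, r2 = run_qc(ds), run_qc(ds)
        assert r1.to_dict() == r2.to_dict()
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_report_consistency_invariant(self, raw_concentrations):
        ds = emulate_plate_data(raw_concentrations, n_plates=2, seed=9)
        report = run_qc(ds)
        assert not set(report.excluded_samples) & set(report.table.index)
        assert not set(report.dropped_markers) & set(report.table.columns)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            QCThresholds(cv_cutoff=0.0)
        with pytest.raises(ValueError):
            QCThresholds(log_base=1.0)
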