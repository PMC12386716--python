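import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrmref.config import PipelineConfig
from mrmref.io_formats import Panel, PanelEntry
from mrmref.pipeline import run_quantify
from mrmref.quantify import (
    BatchVerdict,
    CalibrationCurve,
    QuantificationError,
    back_calculate,
    evaluate_batch,
    fit_batch_curves,
    fit_calibration_curve,
    filter_quantifiable,
    gate_standards,
    quantify_samples,
)
from mrmref.simulate import SimConfig, simulate_experiment


def normal_equations_oracle(x, y, w):
    """Brute-force 2x2 weighted normal equations."""
    A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    b = np.array([(w * y).sum(), (w * x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


class TestCurveFit:
    def test_exact_line(self):
        pts = [(x, 0.02 * x) for x in (1.0, 5.0, 25.0, 125.0)]
        c = fit_calibration_curve(pts)
        assert np.isclose(c.slope, 0.02) and np.isclose(c.intercept, 0.0)
        assert np.isclose(c.r2, 1.0)

    def test_matches_normal_equations_oracle(self):
        pts = [(1.0, 0.021), (10.0, 0.20), (100.0, 2.2)]
        c = fit_calibration_curve(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope, intercept = normal_equations_oracle(x, y, 1.0 / x**2)
        assert np.isclose(c.slope, slope, rtol=1e-12)
        assert np.isclose(c.intercept, intercept, rtol=1e-12)

    def test_two_levels_unfittable(self):
        c = fit_calibration_curve([(1.0, 0.1), (1.0, 0.11), (10.0, 1.0)])
        assert not c.fittable

    def test_zero_slope_back_calc_raises(self):
        c = CalibrationCurve("p", "b", slope=0.0, intercept=0.1, r2=1.0)
        with pytest.raises(QuantificationError, match="zero slope"):
            back_calculate(c, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        slope=st.floats(0.001, 10),
        intercept=st.floats(-0.5, 0.5),
        x=st.floats(0.01, 1e4),
    )
    def test_back_calculate_inverts_predict(self, slope, intercept, x):
        c = CalibrationCurve("p", "b", slope=slope, intercept=intercept, r2=1.0)
        assert np.isclose(back_calculate(c, c.predict(x)), x, rtol=1e-9)


class TestGating:
    def _curve(self):
        # identity curve: ratio == concentration
        return CalibrationCurve("p", "b", slope=1.0, intercept=0.0, r2=1.0)

    def test_accuracy_boundary(self, default_config):
        c = gate_standards(
            self._curve(),
            {"A": (10.0, [12.1, 12.1]), "B": (10.0, [11.9, 11.9])},
            default_config,
        )
        acc = {rec.level: rec for rec in c.levels}
        assert np.isclose(acc["A"].accuracy_dev, 0.21)
        assert not acc["A"].passed
        assert np.isclose(acc["B"].accuracy_dev, 0.19)
        assert acc["B"].passed

    def test_precision_included(self, default_config):
        c = gate_standards(
            self._curve(), {"A": (10.0, [8.0, 14.0])}, default_config
        )
        rec = c.levels[0]
        assert rec.precision_cv > 0.20 and not rec.passed

    def test_min_standards_rule(self, default_config):
        good = (10.0, [10.0, 10.0])
        bad = (10.0, [15.0, 15.0])
        levels4 = {"A": good, "B": good, "C": good, "D": good,
                   "E": bad, "F": bad, "G": bad}
        assert not gate_standards(self._curve(), levels4, default_config).curve_pass
        levels5 = dict(levels4, E=good)
        assert gate_standards(self._curve(), levels5, default_config).curve_pass


class TestBatchVerdict:
    def _setup(self, n_qc_pass, n_qc, n_curves=1, n_curve_pass=1):
        entry = PanelEntry(
            "P1", "P1_pep", {lv: 4.0**i for i, lv in enumerate("ABCDEFG")},
            sis_conc=1.0, qc_concs={"QCA": 10.0},
        )
        panel = Panel([entry])
        curves = {}
        for i in range(n_curves):
            pep = f"P{i + 1}_pep"
            c = CalibrationCurve(pep, "B1", 1.0, 0.0, 1.0)
            c.curve_pass = i < n_curve_pass
            curves[(pep, "B1")] = c
        ratios = [10.0] * n_qc_pass + [15.0] * (n_qc - n_qc_pass)
        rows = pd.DataFrame(
            {
                "sample_id": [f"B1_QCA_r{i}" for i in range(n_qc)],
                "role": "qc:QCA",
                "batch": "B1",
                "replicate": range(n_qc),
                "peptide": "P1_pep",
                "ratio": ratios,
            }
        )
        return curves, rows, panel

    def test_qc_below_66_invalid(self, default_config):
        curves, rows, panel = self._setup(6, 10)
        v = evaluate_batch("B1", curves, rows, panel, default_config)
        assert np.isclose(v.qc_pass_frac_observed, 0.60) and not v.valid

    def test_qc_70_and_curves_95_valid(self, default_config):
        curves, rows, panel = self._setup(7, 10, n_curves=100, n_curve_pass=95)
        v = evaluate_batch("B1", curves, rows, panel, default_config)
        assert v.valid

    def test_curves_89_invalid(self, default_config):
        curves, rows, panel = self._setup(7, 10, n_curves=100, n_curve_pass=89)
        v = evaluate_batch("B1", curves, rows, panel, default_config)
        assert np.isclose(v.curve_pass_frac_observed, 0.89) and not v.valid

    def test_no_qc_errors(self, default_config):
        curves, rows, panel = self._setup(6, 10)
        with pytest.raises(QuantificationError, match="no QC"):
            evaluate_batch("B1", curves, rows.iloc[:0], panel, default_config)


class TestQuantifySamples:
    def _table(self, single_entry_panel, cohort_rows):
        std = []
        entry = single_entry_panel["P1_pep"]
        for lv, conc in entry.level_concs.items():
            for rep in (1, 2):
                std.append(
                    (f"B1_std{lv}_r{rep}", f"standard:{lv}", "B1", rep, "P1_pep",
                     conc / entry.sis_conc)
                )
        qc = [(f"B1_QCA_r{r}", "qc:QCA", "B1", r, "P1_pep", 3.0) for r in (1, 2, 3)]
        rows = std + qc + cohort_rows
        return pd.DataFrame(
            rows,
            columns=["sample_id", "role", "batch", "replicate", "peptide", "ratio"],
        )

    def test_duplicates_averaged_and_clamping(self, single_entry_panel, default_config):
        cohort = [
            ("S1", "cohort", "B1", 1, "P1_pep", 4.0),
            ("S1", "cohort", "B1", 2, "P1_pep", 6.0),
            ("S2", "cohort", "B1", 1, "P1_pep", 0.5),  # 0.5 * LLOQ
            ("S2", "cohort", "B1", 2, "P1_pep", 0.5),
            ("S3", "cohort", "B1", 1, "P1_pep", np.nan),
            ("S3", "cohort", "B1", 2, "P1_pep", np.nan),
        ]
        table = self._table(single_entry_panel, cohort)
        curves = fit_batch_curves(table, single_entry_panel, default_config)
        q = quantify_samples(table, curves, single_entry_panel, default_config)
        assert np.isclose(q.conc.loc["S1", "P1"], 5.0)
        assert q.flags.loc["S1", "P1"] == "measured"
        assert np.isclose(q.conc.loc["S2", "P1"], 1.0)  # clamped to LLOQ
        assert q.flags.loc["S2", "P1"] == "clamped_LLOQ"
        assert q.flags.loc["S3", "P1"] == "missing"
        assert np.isnan(q.conc.loc["S3", "P1"])

    def test_flag_conservation(self, small_experiment, default_config):
        q = run_quantify(
            small_experiment.peak_table, small_experiment.panel, default_config
        ).quant
        counts = q.flags.stack().value_counts()
        assert counts.sum() == q.conc.size


class TestFilter:
    def test_majority_clamped_excluded(self, single_entry_panel, default_config):
        curve = CalibrationCurve("P1_pep", "B1", 1.0, 0.0, 0.999)
        curves = {("P1_pep", "B1"): curve}
        verdict = BatchVerdict("B1", 1.0, 1.0, 3, 1, True)
        from mrmref.quantify import QuantMatrix

        n = 10
        flags = pd.DataFrame(
            {"P1": ["clamped_LLOQ"] * 6 + ["measured"] * 4},
            index=[f"S{i}" for i in range(n)],
        )
        conc = pd.DataFrame({"P1": np.ones(n)}, index=flags.index)
        q = QuantMatrix(conc, flags, {"B1": verdict}, {})
        retained, report = filter_quantifiable(q, curves, single_entry_panel, default_config)
        assert retained == [] and "60%" in report[0]["reasons"][0]

    def test_half_clamped_retained(self, single_entry_panel, default_config):
        from mrmref.quantify import QuantMatrix

        curve = CalibrationCurve("P1_pep", "B1", 1.0, 0.0, 0.999)
        flags = pd.DataFrame(
            {"P1": ["clamped_LLOQ"] * 5 + ["measured"] * 5},
            index=[f"S{i}" for i in range(10)],
        )
        conc = pd.DataFrame({"P1": np.ones(10)}, index=flags.index)
        q = QuantMatrix(conc, flags, {"B1": BatchVerdict("B1", 1, 1, 3, 1, True)}, {})
        retained, _ = filter_quantifiable(
            q, {("P1_pep", "B1"): curve}, single_entry_panel, default_config
        )
        assert retained == ["P1"]

    def test_low_r2_excluded(self, single_entry_panel, default_config):
        from mrmref.quantify import QuantMatrix

        curve = CalibrationCurve("P1_pep", "B1", 1.0, 0.0, 0.989)
        flags = pd.DataFrame({"P1": ["measured"] * 4}, index=list("abcd"))
        conc = pd.DataFrame({"P1": np.ones(4)}, index=flags.index)
        q = QuantMatrix(conc, flags, {"B1": BatchVerdict("B1", 1, 1, 3, 1, True)}, {})
        retained, report = filter_quantifiable(
            q, {("P1_pep", "B1"): curve}, single_entry_panel, default_config
        )
        assert retained == [] and "R^2" in report[0]["reasons"][0]

    def test_designed_detectability_recovered(self):
        """24 engineered below-LLOQ proteins leave 115 of 139 quantified."""
        exp = simulate_experiment(SimConfig(seed=1))
        res = run_quantify(exp.peak_table, exp.panel, PipelineConfig())
        assert len(res.retained) == 115
        excluded = {r["protein_id"] for r in res.exclusions}
        assert excluded == {name for name, _ in exp.config.dropout}


def test_noise_monotonicity_of_passing_levels():
    """More technical noise never increases passing calibration levels
    (in expectation; paired seeds, three noise grades)."""
    totals = []
    for cv in (0.02, 0.10, 0.25):
        n_pass = 0
        for seed in (1, 2, 3):
            cfg = SimConfig(
                n_samples=4, n_proteins=15, seed=seed, tech_cv=cv,
                standard_cv=cv, dropout=(), noisy_proteins=(),
            )
            exp = simulate_experiment(cfg)
            curves = fit_batch_curves(exp.peak_table, exp.panel, PipelineConfig())
            n_pass += sum(
                sum(rec.passed for rec in c.levels) for c in curves.values()
            )
        totals.append(n_pass)
    assert totals[0] >= totals[1] >= totals[2]
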