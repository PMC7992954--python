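"""4PL dose-response, ΔΔCt quantification, and hypothesis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fructolyze.assays import (
    cellmeans_anova_lsd,
    compare_two_groups,
    copy_number_ratio,
    delta_ct_fold_change,
    fit_4pl,
    four_pl,
    normalize_viability,
    sensitivity_ratio,
)
from fructolyze.errors import InsufficientDataError, ValidationError
from fructolyze.synthetic import generate_ct_table, generate_dose_response

CONCS = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 200.0])


class TestFourPL:
    def test_exact_model_data_recovered(self):
        tbl = generate_dose_response(0.0, 1.0, 5.0, 1.0, CONCS, 0, seed=0)
        c = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
        assert c.converged
        assert c.bottom == pytest.approx(0.0, abs=1e-6)
        assert c.top == pytest.approx(1.0, abs=1e-6)
        assert c.ic50_mm == pytest.approx(5.0, rel=1e-6)
        assert c.hill == pytest.approx(1.0, rel=1e-6)
        assert c.residual_ss < 1e-10

    def test_fitted_curve_midpoint_identity(self):
        tbl = generate_dose_response(0.1, 0.9, 3.0, 1.7, CONCS, 0.02, 3, seed=4)
        c = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
        assert c.predict(c.ic50_mm) == pytest.approx((c.top + c.bottom) / 2, abs=1e-9)

    def test_noisy_recovery_monte_carlo(self):
        errs = []
        for i in range(50):
            tbl = generate_dose_response(0.0, 1.0, 5.0, 1.0, CONCS, 0.05, 3, seed=i)
            c = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
            errs.append(abs(c.ic50_mm - 5.0) / 5.0)
        assert np.median(errs) <= 0.10

    def test_flat_data_rejected(self):
        with pytest.raises(ValidationError):
            fit_4pl(CONCS, np.full(CONCS.size, 0.8))

    def test_too_few_doses_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_4pl(np.array([0, 1, 2, 4.0]), np.array([1, 0.8, 0.5, 0.2]))

    def test_normalization_anchors_zero_drug_to_one(self):
        tbl = generate_dose_response(0.0, 5e4, 5.0, 1.0, CONCS, 0, seed=0)
        v = normalize_viability(tbl.viability.to_numpy(), tbl.concentration_mm.to_numpy())
        assert v[tbl.concentration_mm.to_numpy() == 0][0] == pytest.approx(1.0)


class TestSensitivityRatio:
    def test_identical_curves_ratio_one(self):
        tbl = generate_dose_response(0.0, 1.0, 5.0, 1.0, CONCS, 0, seed=0)
        c = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
        assert sensitivity_ratio(c, c) == pytest.approx(1.0)

    def test_programmed_ratio_ten(self):
        g = generate_dose_response(0.0, 1.0, 20.0, 1.0, CONCS, 0, seed=0)
        f = generate_dose_response(0.0, 1.0, 2.0, 1.0, CONCS, 0, seed=0)
        cg = fit_4pl(g.concentration_mm.to_numpy(), g.viability.to_numpy())
        cf = fit_4pl(f.concentration_mm.to_numpy(), f.viability.to_numpy())
        assert sensitivity_ratio(cg, cf) == pytest.approx(10.0, rel=1e-5)

    def test_unconverged_propagates_nan(self):
        tbl = generate_dose_response(0.0, 1.0, 5.0, 1.0, CONCS, 0, seed=0)
        good = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
        bad = fit_4pl(tbl.concentration_mm.to_numpy(), tbl.viability.to_numpy())
        bad.converged = False
        assert np.isnan(sensitivity_ratio(good, bad))


class TestDeltaCt:
    def test_equal_delta_ct_fold_one(self):
        tbl = generate_ct_table({"G": 1.0}, noise_sd=0)
        out = delta_ct_fold_change(tbl, "parental")
        assert (out.fold_change == pytest.approx(1.0)) is not False
        np.testing.assert_allclose(out.fold_change, 1.0)

    def test_ddct_minus_one_doubles(self):
        tbl = generate_ct_table({"G": 2.0}, noise_sd=0)
        out = delta_ct_fold_change(tbl, "parental")
        row = out[out.group == "trained"].iloc[0]
        assert row.ddct == pytest.approx(-1.0)
        assert row.fold_change == pytest.approx(2.0)

    @pytest.mark.parametrize("fold", [0.1, 1.0, 30.0, 200.0])
    def test_zero_noise_inversion(self, fold):
        tbl = generate_ct_table({"G": fold}, noise_sd=0)
        out = delta_ct_fold_change(tbl, "parental")
        got = out[out.group == "trained"].fold_change.iloc[0]
        assert got == pytest.approx(fold, rel=1e-12)

    def test_missing_control_gene_rejected(self):
        tbl = generate_ct_table({"G": 2.0}, noise_sd=0)
        tbl = tbl[~tbl.is_control]
        with pytest.raises(ValidationError):
            delta_ct_fold_change(tbl, "parental")

    def test_high_ct_flagged_low_confidence(self):
        tbl = generate_ct_table({"G": 2.0}, control_ct=32.0, noise_sd=0)
        out = delta_ct_fold_change(tbl, "parental")
        assert out.low_confidence.all()


class TestCopyNumber:
    @staticmethod
    def _gdna(target_shift):
        rows = []
        for sample, shift in [("cal", 0.0), ("test", target_shift)]:
            rows.append({"sample": sample, "gene": "B2M", "ct": 22.0})
            rows.append({"sample": sample, "gene": "SLC2A5", "ct": 24.0 + shift})
        return pd.DataFrame(rows)

    def test_identical_cts_ratio_one(self):
        out = copy_number_ratio(self._gdna(0.0), "B2M", "cal")
        np.testing.assert_allclose(out.copy_ratio, 1.0)

    def test_one_ct_earlier_doubles(self):
        out = copy_number_ratio(self._gdna(-1.0), "B2M", "cal")
        assert out[out["sample"] == "test"].copy_ratio.iloc[0] == pytest.approx(2.0)

    def test_programmed_four_copies_vs_diploid(self):
        # 4 copies vs 2 = ratio 2 = target Ct earlier by 1 cycle
        out = copy_number_ratio(self._gdna(-np.log2(2.0)), "B2M", "cal")
        assert out[out["sample"] == "test"].copy_ratio.iloc[0] == pytest.approx(2.0)

    def test_missing_calibrator_rejected(self):
        with pytest.raises(ValidationError):
            copy_number_ratio(self._gdna(0.0), "B2M", "absent")


class TestTwoGroupTest:
    def test_identical_groups(self):
        r = compare_two_groups(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # hand-computed pooled t on {1,2,3} vs {4,5,6}
        r = compare_two_groups(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.p_value == pytest.approx(0.0214, abs=2e-3)

    def test_degenerate_zero_variance(self):
        same = compare_two_groups(np.array([2.0, 2]), np.array([2.0, 2]))
        assert same.p_value == 1.0 and same.degenerate
        diff = compare_two_groups(np.array([2.0, 2]), np.array([3.0, 3]))
        assert diff.p_value == 0.0 and diff.degenerate

    def test_welch_flag_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 3, 12)
        r = compare_two_groups(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


def _balanced_2x2(shift=0.0, noise=0.25, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in ("glc", "fru"):
        for b in ("parental", "trained"):
            mu = 1.0 + (shift if (a, b) == ("fru", "trained") else 0.0)
            for v in mu + rng.normal(0, noise, 4):
                rows.append({"sugar": a, "line": b, "y": v})
    return pd.DataFrame(rows)


class TestAnovaLsd:
    def test_all_cells_identical_all_p_one(self):
        rows = [
            {"sugar": a, "line": b, "y": 1.0}
            for a in ("glc", "fru") for b in ("p", "t") for _ in range(3)
        ]
        res = cellmeans_anova_lsd(pd.DataFrame(rows), "sugar", "line", "y")
        assert (res.comparisons.p == 1.0).all()

    def test_shifted_cell_most_significant(self):
        res = cellmeans_anova_lsd(_balanced_2x2(shift=3.0), "sugar", "line", "y")
        comp = res.comparisons
        involving = comp[
            comp.apply(lambda r: ("fru", "trained") in (r.cell_a, r.cell_b), axis=1)
        ]
        others = comp[
            comp.apply(lambda r: ("fru", "trained") not in (r.cell_a, r.cell_b), axis=1)
        ]
        assert involving.p.max() < others.p.min()

    def test_lsd_equals_pooled_df_t_test(self):
        # algebraic identity: LSD p == t test using ANOVA residual MS and df
        df = _balanced_2x2(shift=1.0, seed=3)
        res = cellmeans_anova_lsd(df, "sugar", "line", "y")
        row = res.comparisons.iloc[0]
        ca, cb = row.cell_a, row.cell_b
        va = df[(df.sugar == ca[0]) & (df.line == ca[1])].y.to_numpy()
        vb = df[(df.sugar == cb[0]) & (df.line == cb[1])].y.to_numpy()
        t = (va.mean() - vb.mean()) / np.sqrt(res.mse * (1 / va.size + 1 / vb.size))
        p = 2 * stats.t.sf(abs(t), res.residual_df)
        assert row.t == pytest.approx(t) and row.p == pytest.approx(p)

    def test_residual_ms_matches_statsmodels(self):
        # independent oracle: OLS two-way ANOVA residual mean square
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _balanced_2x2(shift=1.5, seed=5)
        fit = smf.ols("y ~ C(sugar) * C(line)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        mse_ref = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
        res = cellmeans_anova_lsd(df, "sugar", "line", "y")
        assert res.mse == pytest.approx(mse_ref, rel=1e-10)
        assert res.residual_df == int(table.loc["Residual", "df"])

    def test_empty_cell_rejected(self):
        df = _balanced_2x2()
        df = df[~((df.sugar == "fru") & (df.line == "trained"))]
        with pytest.raises(ValidationError):
            cellmeans_anova_lsd(df, "sugar", "line", "y")
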