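"""Feature assembly, OLS models, LOOCV, ANOVA/ANCOVA, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from numpy.testing import assert_allclose
from scipy import stats as sp_stats

import alphafield as af
from alphafield.errors import AnalysisError, InputError


def random_table(rng, n=18, planted=True):
    t = af.simulate_feature_table(n, seed=rng.integers(2**31))
    return t if planted else t.assign(
        dd_alpha_amp=rng.normal(0, 0.3, n)
    )


def feature_row(i, **overrides):
    base = dict(subject_id=f"s{i}", dd_alpha_amp=0.1 * i, dd_connectivity=0.01 * i,
                dd_sleepiness=0.05 * i, mismatch=0.1, efield_alphabold=0.12,
                efield_strong=0.27)
    base.update(overrides)
    return af.SubjectFeatures(**base)


class TestAssembleFeatures:
    def test_rows_carry_stage_outputs_unchanged(self):
        rows = [feature_row(i) for i in range(4)]
        table, excl = af.assemble_features(rows)
        assert len(table) == 4 and excl.empty
        assert table.loc["s2", "dd_alpha_amp"] == pytest.approx(0.2)

    def test_empty_input_gives_empty_table(self):
        table, excl = af.assemble_features([])
        assert table.empty and excl.empty

    def test_exclusions_listed_with_reason(self):
        """22 subjects entering, 4 dropped for a flat alpha spectrum."""
        rows = [feature_row(i) for i in range(18)]
        excluded = {f"x{i}": "non-identifiable alpha peak" for i in range(4)}
        table, excl = af.assemble_features(rows, excluded)
        assert len(table) == 18
        assert len(excl) == 4
        assert set(excl["reason"]) == {"non-identifiable alpha peak"}

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            af.assemble_features([feature_row(1), feature_row(1)])

    def test_nonfinite_feature_rejected(self):
        with pytest.raises(InputError):
            feature_row(1, dd_alpha_amp=np.nan)


class TestFitLinearModel:
    def test_exact_linear_response_perfect_fit(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, (2, 12))
        table = pd.DataFrame({"y": 1.0 + 2 * x1 - 3 * x2, "x1": x1, "x2": x2})
        fit = af.fit_linear_model(table, "y", ["x1", "x2"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.loocv_rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.params["x1"] == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self, rng):
        table = random_table(rng)
        preds = ["dd_sleepiness", "mismatch", "efield_alphabold"]
        fit = af.fit_linear_model(table, "dd_alpha_amp", preds)
        X = np.column_stack([np.ones(len(table))] + [table[p] for p in preds])
        y = table["dd_alpha_amp"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = (resid**2).sum() / (len(y) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        for i, name in enumerate(["const", *preds]):
            assert_allclose(fit.params[name], beta[i], rtol=1e-10)
            assert_allclose(fit.bse[name], se[i], rtol=1e-10)
        assert_allclose(fit.rmse, np.sqrt((resid**2).mean()), rtol=1e-10)

    def test_planted_coefficients_recovered_on_average(self):
        coefs = []
        for seed in range(60):
            t = af.simulate_feature_table(18, seed=seed)
            fit = af.fit_linear_model(t, "dd_alpha_amp",
                                      ["dd_sleepiness", "efield_alphabold"])
            coefs.append([fit.params["dd_sleepiness"], fit.params["efield_alphabold"],
                          fit.params["const"]])
        mean = np.mean(coefs, axis=0)
        sem = np.std(coefs, axis=0, ddof=1) / np.sqrt(len(coefs))
        for m, s, planted in zip(mean, sem, (0.9, 11.7, -1.5)):
            assert abs(m - planted) < 3 * s + 0.02 * abs(planted)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.05, max_value=50.0))
    def test_scale_equivariance(self, c):
        t = af.simulate_feature_table(18, seed=11)
        base = af.fit_linear_model(t, "dd_alpha_amp",
                                   ["dd_sleepiness", "efield_alphabold"])
        scaled_t = t.assign(efield_alphabold=c * t["efield_alphabold"])
        scaled = af.fit_linear_model(scaled_t, "dd_alpha_amp",
                                     ["dd_sleepiness", "efield_alphabold"])
        assert scaled.params["efield_alphabold"] == pytest.approx(
            base.params["efield_alphabold"] / c)
        assert scaled.r2 == pytest.approx(base.r2)
        assert scaled.rmse == pytest.approx(base.rmse)
        assert scaled.pvalues["efield_alphabold"] == pytest.approx(
            base.pvalues["efield_alphabold"])

    def test_collinear_predictors_rejected(self, rng):
        t = random_table(rng)
        t = t.assign(dup=2 * t["efield_alphabold"])
        with pytest.raises(AnalysisError, match="collinear"):
            af.fit_linear_model(t, "dd_alpha_amp", ["efield_alphabold", "dup"])

    def test_too_few_rows_rejected(self, rng):
        t = random_table(rng).iloc[:3]
        with pytest.raises(AnalysisError):
            af.fit_linear_model(t, "dd_alpha_amp",
                                ["dd_sleepiness", "mismatch", "efield_alphabold"])


class TestLoocv:
    def test_matches_explicit_refit_oracle(self, rng):
        t = random_table(rng)
        preds = ["dd_sleepiness", "efield_alphabold"]
        got = af.loocv_rmse(t, "dd_alpha_amp", preds)
        errs = []
        for i in range(len(t)):
            train = t.drop(t.index[i])
            X = np.column_stack([np.ones(len(train))] + [train[p] for p in preds])
            y = train["dd_alpha_amp"].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            xi = np.r_[1.0, [t[p].iloc[i] for p in preds]]
            errs.append(t["dd_alpha_amp"].iloc[i] - xi @ beta)
        assert_allclose(got, np.sqrt(np.mean(np.square(errs))), rtol=1e-10)

    def test_zero_on_noiseless_planar_data(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(0, 1, (2, 10))
        t = pd.DataFrame({"y": 2 + x1 - x2, "x1": x1, "x2": x2})
        assert af.loocv_rmse(t, "y", ["x1", "x2"]) == pytest.approx(0.0, abs=1e-10)

    def test_loocv_agrees_with_fit_linear_model_field(self, rng):
        t = random_table(rng)
        preds = ["dd_sleepiness", "efield_alphabold"]
        fit = af.fit_linear_model(t, "dd_alpha_amp", preds)
        assert fit.loocv_rmse == pytest.approx(af.loocv_rmse(t, "dd_alpha_amp", preds))


class TestRmAnova2x2:
    @staticmethod
    def _cell_means_oracle(Y):
        """Brute-force sums-of-squares via explicit loops."""
        n = Y.shape[0]
        grand = Y.mean()
        ss = {}
        ss_run = sum(4 * n / 2 * (Y[:, r, :].mean() - grand) ** 2 for r in range(2))
        ss_sess = sum(4 * n / 2 * (Y[:, :, s].mean() - grand) ** 2 for s in range(2))
        ss_int = 0.0
        for r in range(2):
            for s in range(2):
                ss_int += n * (Y[:, r, s].mean() - Y[:, r, :].mean()
                               - Y[:, :, s].mean() + grand) ** 2
        ss_run_err = 0.0
        for i in range(n):
            for r in range(2):
                ss_run_err += 2 * (Y[i, r, :].mean() - Y[i].mean()
                                   - Y[:, r, :].mean() + grand) ** 2
        ss_sess_err = 0.0
        for i in range(n):
            for s in range(2):
                ss_sess_err += 2 * (Y[i, :, s].mean() - Y[i].mean()
                                    - Y[:, :, s].mean() + grand) ** 2
        ss_int_err = 0.0
        for i in range(n):
            for r in range(2):
                for s in range(2):
                    pred = (Y[i].mean() + Y[:, r, :].mean() + Y[:, :, s].mean()
                            - 2 * grand
                            + (Y[i, r, :].mean() - Y[i].mean() - Y[:, r, :].mean() + grand)
                            + (Y[i, :, s].mean() - Y[i].mean() - Y[:, :, s].mean() + grand)
                            + (Y[:, r, s].mean() - Y[:, r, :].mean()
                               - Y[:, :, s].mean() + grand))
                    ss_int_err += (Y[i, r, s] - pred) ** 2
        f_run = (ss_run / 1) / (ss_run_err / (n - 1))
        f_sess = (ss_sess / 1) / (ss_sess_err / (n - 1))
        f_int = (ss_int / 1) / (ss_int_err / (n - 1))
        return f_run, f_sess, f_int

    def test_textbook_example_matches_sums_of_squares_oracle(self):
        Y = np.array([
            [[3.0, 5.0], [6.0, 4.0]],
            [[2.0, 4.0], [5.0, 6.0]],
            [[5.0, 3.0], [7.0, 5.0]],
            [[4.0, 4.0], [8.0, 7.0]],
        ])
        res = af.rm_anova_2x2(Y)
        f_run, f_sess, f_int = self._cell_means_oracle(Y)
        assert_allclose(res.f["run"], f_run, rtol=1e-10)
        assert_allclose(res.f["session"], f_sess, rtol=1e-10)
        assert_allclose(res.f["run x session"], f_int, rtol=1e-10)
        assert res.dof == (1, 3)

    def test_f_run_equals_squared_paired_t(self, rng):
        Y = rng.normal(0, 1, (10, 2, 2))
        res = af.rm_anova_2x2(Y)
        d = Y[:, 1, :].mean(axis=1) - Y[:, 0, :].mean(axis=1)
        tval = sp_stats.ttest_1samp(d, 0).statistic
        assert_allclose(res.f["run"], tval**2, rtol=1e-8)
        d_int = (Y[:, 1, 0] - Y[:, 0, 0]) - (Y[:, 1, 1] - Y[:, 0, 1])
        t_int = sp_stats.ttest_1samp(d_int, 0).statistic
        assert_allclose(res.f["run x session"], t_int**2, rtol=1e-8)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        Y = rng.normal(0, 1, (12, 2, 2))
        frame = pd.DataFrame(
            [
                {"subject": i, "run": r, "session": s, "y": Y[i, r, s]}
                for i in range(12) for r in range(2) for s in range(2)
            ]
        )
        pg = pingouin.rm_anova(data=frame, dv="y", within=["run", "session"],
                               subject="subject", detailed=True)
        res = af.rm_anova_2x2(Y)
        pg = pg.set_index("Source")
        assert_allclose(res.f["run"], pg.loc["run", "F"], rtol=1e-8)
        assert_allclose(res.f["session"], pg.loc["session", "F"], rtol=1e-8)
        assert_allclose(res.f["run x session"], pg.loc["run * session", "F"], rtol=1e-8)
        assert_allclose(res.p["run"], pg.loc["run", "p_unc"], rtol=1e-8)

    def test_no_variation_guarded_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no variation"):
            res = af.rm_anova_2x2(np.ones((4, 2, 2)))
        assert all(v == 0.0 for v in res.f.values())

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 2, 2))
        Y[0, 0, 0] = np.nan
        with pytest.raises(InputError):
            af.rm_anova_2x2(Y)


class TestAncova:
    def test_matches_dummy_ols_oracle(self, rng):
        n = 15
        deltas = rng.normal(0, 1, (n, 2))
        cov = rng.normal(0, 1, (n, 2))
        F, p, dof = af.ancova_group(deltas, cov)
        y = np.r_[deltas[:, 0], deltas[:, 1]]
        X = np.column_stack([
            np.ones(2 * n), np.r_[np.ones(n), np.zeros(n)], np.r_[cov[:, 0], cov[:, 1]]
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = (resid**2).sum() / (2 * n - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert_allclose(F, (beta[1] / se) ** 2, rtol=1e-10)
        assert dof == (1, 2 * n - 3)

    def test_identical_conditions_give_zero_f(self, rng):
        d = rng.normal(0, 1, 10)
        cov = rng.normal(0, 1, (10, 2))
        F, p, _ = af.ancova_group(np.column_stack([d, d]), cov)
        assert F == pytest.approx(0.0, abs=1e-8)

    def test_null_f_is_small_on_average(self):
        fs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            fs.append(af.ancova_group(r.normal(0, 1, (12, 2)), r.normal(0, 1, (12, 2)))[0])
        # mean of F(1, m) is m/(m-2) ~ 1.1 under the null
        assert np.mean(fs) < 2.5

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(AnalysisError):
            af.ancova_group(rng.normal(0, 1, (8, 2)), np.ones((8, 2)))


class TestResidualizeThenCorrelate:
    def test_orthogonal_covariate_approximates_plain_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 2000)
        y = 0.5 * x + rng.normal(0, 1, 2000)
        cov = rng.normal(0, 1, 2000)
        plain = sp_stats.pearsonr(y, x).statistic
        part = af.residualize_then_correlate(y, x, cov)
        assert part == pytest.approx(plain, abs=0.02)

    def test_matches_two_step_brute_force(self, rng):
        y, x, cov = rng.normal(0, 1, (3, 20))
        got = af.residualize_then_correlate(y, x, cov)
        X = np.column_stack([np.ones(20), cov])
        ry = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        oracle = np.corrcoef(ry, x)[0, 1]
        assert abs(got - oracle) <= 1e-12

    def test_correlation_increases_when_covariate_masks_signal(self):
        """Partialling out a shared nuisance strengthens the dose-response
        correlation, as in the published before/after comparison."""
        rng = np.random.default_rng(5)
        stronger = 0
        for _ in range(50):
            efield = rng.normal(0.12, 0.03, 18)
            sleep = rng.normal(0, 0.45, 18)
            y = -1.5 + 0.9 * sleep + 11.7 * efield + rng.normal(0, 0.3, 18)
            before = sp_stats.pearsonr(y, efield).statistic
            after = af.residualize_then_correlate(y, efield, sleep)
            stronger += after > before
        assert stronger > 40

    def test_constant_input_rejected(self):
        with pytest.raises(AnalysisError):
            af.residualize_then_correlate(np.ones(10), np.arange(10.0), np.arange(10.0))


class TestBonferroni:
    def test_family_of_four_threshold(self):
        calls, threshold = af.bonferroni([0.001, 0.02, 0.012, 0.8])
        assert threshold == pytest.approx(0.0125)
        assert calls.tolist() == [True, False, True, False]

    def test_single_test_keeps_alpha(self):
        _, threshold = af.bonferroni([0.04], m=1)
        assert threshold == pytest.approx(0.05)

    def test_borderline_p_depends_on_family_size(self):
        assert not af.bonferroni([0.013], m=4)[0][0]
        assert af.bonferroni([0.013], m=3)[0][0]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InputError):
            af.bonferroni([1.2])
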