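"""QC rules, factorial models, count models, partial correlations."""

import numpy as np
import pandas as pd
import pytest

from netrai.group_inference import (
    apply_qc_filters,
    dispersion_test,
    factorial_glm,
    linear_check_regression,
    log10_plus_one,
    negbin_regression,
    partial_correlation,
    two_sample_t,
)
from netrai.synthetic import simulate_unaware_counts


def _cohort(rng, n_per_cell=25, hiv_shift=0.0, outcome_sd=1.0):
    n = 4 * n_per_cell
    hiv = np.repeat([1, 1, 0, 0], n_per_cell)
    cb = np.tile(np.repeat([1, 0], n_per_cell), 2)
    return pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "hiv": hiv,
            "cb": cb,
            "age": rng.normal(35, 10, n),
            "sex": rng.integers(0, 2, n),
            "mean_fd": rng.gamma(2.0, 0.05, n),
            "nic": rng.integers(0, 2, n),
            "y": rng.normal(0, outcome_sd, n) + hiv_shift * hiv,
        }
    )


class TestQCFilters:
    def test_go_error_violator_excluded_with_reason(self, rng):
        df = _cohort(rng, 4)
        df["go_error_rate"] = 0.1
        df.loc[3, "go_error_rate"] = 0.6
        df["unaware_errors"] = rng.poisson(5, len(df))
        kept, log = apply_qc_filters(df)
        assert len(kept) == len(df) - 1
        assert df.loc[3, "subject"] not in set(kept.subject)
        assert "go_error_rate" in log.iloc[0]["reason"]

    def test_clean_cohort_unchanged(self, rng):
        df = _cohort(rng, 4)
        df["go_error_rate"] = 0.05
        df["unaware_errors"] = rng.poisson(5, len(df))
        kept, log = apply_qc_filters(df)
        assert len(kept) == len(df) and log.empty

    def test_extreme_count_outlier_removed_under_z3_rule(self, rng):
        df = _cohort(rng, 25)
        df["go_error_rate"] = 0.05
        counts = rng.poisson(5, len(df)).astype(float)
        counts[10] = counts.mean() + 6 * max(counts.std(), 1.0) * 3  # far out
        df["unaware_errors"] = counts
        kept, log = apply_qc_filters(df)
        assert len(log) == 1
        assert "outlier" in log.iloc[0]["reason"]
        assert df.loc[10, "subject"] not in set(kept.subject)


class TestFactorialGLM:
    def test_balanced_design_matches_textbook_anova(self, rng):
        # without covariates, Type-III on a balanced 2x2 equals classic ANOVA
        df = _cohort(rng, 10)
        res = factorial_glm(df, "y", covariates=())
        y = df["y"].to_numpy()
        a = df["hiv"].to_numpy()
        b = df["cb"].to_numpy()
        cell = {(i, j): y[(a == i) & (b == j)] for i in (0, 1) for j in (0, 1)}
        nc = 10
        grand = y.mean()
        mean_a = {i: y[a == i].mean() for i in (0, 1)}
        mean_b = {j: y[b == j].mean() for j in (0, 1)}
        ss_a = 2 * nc * sum((mean_a[i] - grand) ** 2 for i in (0, 1))
        ss_b = 2 * nc * sum((mean_b[j] - grand) ** 2 for j in (0, 1))
        ss_ab = nc * sum(
            (cell[(i, j)].mean() - mean_a[i] - mean_b[j] + grand) ** 2
            for i in (0, 1)
            for j in (0, 1)
        )
        ss_err = sum(((cell[k] - cell[k].mean()) ** 2).sum() for k in cell)
        ms_err = ss_err / (len(y) - 4)
        assert res.term("HIV")["F"] == pytest.approx(ss_a / ms_err, abs=1e-10)
        assert res.term("CB")["F"] == pytest.approx(ss_b / ms_err, abs=1e-10)
        assert res.term("HIV:CB")["F"] == pytest.approx(ss_ab / ms_err, abs=1e-10)
        assert res.term("HIV")["eta_p2"] == pytest.approx(ss_a / (ss_a + ss_err))

    def test_null_type_one_error_near_nominal(self, rng):
        rej = sum(
            factorial_glm(_cohort(rng), "y").term("HIV")["p"] < 0.05
            for _ in range(500)
        )
        assert 0.03 <= rej / 500 <= 0.07

    def test_power_for_unit_shift(self, rng):
        hits = sum(
            factorial_glm(_cohort(rng, hiv_shift=1.0), "y").term("HIV")["p"] < 0.05
            for _ in range(100)
        )
        assert hits / 100 > 0.9

    def test_missing_cell_rejected(self, rng):
        df = _cohort(rng, 4)
        df = df[~((df.hiv == 1) & (df.cb == 1))]
        with pytest.raises(ValueError, match="cell"):
            factorial_glm(df, "y")


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        t, df, p = two_sample_t(a, a.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_df_structure(self, rng):
        t, df, p = two_sample_t(rng.normal(0, 1, 26), rng.normal(0, 1, 17))
        assert df == 41

    def test_matches_brute_force_formula(self, rng):
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.5, 1.3, 9)
        t, df, p = two_sample_t(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestTransform:
    @pytest.mark.parametrize("x, expect", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_reference_points(self, x, expect):
        assert log10_plus_one(x) == pytest.approx(expect, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log10_plus_one(-1)


class TestDispersionTest:
    def test_null_calibration_on_poisson_counts(self, rng):
        rej = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(5000)
            y = rng.poisson(np.exp(1.5 + 0.2 * x))
            rej += dispersion_test(y, {"x": x}).pvalue < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_power_against_nb_alternative(self, rng):
        rej = 0
        reps = 100
        for _ in range(reps):
            y = simulate_unaware_counts(np.zeros(200), np.log(5.0), 0.0, 1.0, seed=rng)
            rej += dispersion_test(y, {"x": rng.standard_normal(200)}).pvalue < 0.05
        assert rej / reps > 0.9

    def test_equidispersed_constantish_counts_not_flagged(self):
        y = np.full(50, 4)
        y[::2] = 5  # variance well below the mean
        res = dispersion_test(y, {"x": np.zeros(50) + np.arange(50) * 0})
        assert res.statistic <= 0 and res.pvalue >= 0.5


class TestNegBin:
    def test_slope_recovery_and_coverage(self, rng):
        est, cover = [], 0
        reps = 100
        for _ in range(reps):
            z = rng.normal(0.35, 0.15, 85)
            y = simulate_unaware_counts(z, 0.95, 1.7, 0.5, seed=rng)
            c = negbin_regression(y, {"z": z}, run_dispersion_test=False).coef("z")
            est.append(c["coef"])
            cover += c["coef"] - 1.96 * c["se"] <= 1.7 <= c["coef"] + 1.96 * c["se"]
        assert abs(np.mean(est) - 1.7) < 0.15
        assert 0.88 <= cover / reps <= 0.99

    def test_null_slope_ci_coverage(self, rng):
        cover = 0
        reps = 100
        for _ in range(reps):
            z = rng.normal(0.0, 0.5, 85)
            y = simulate_unaware_counts(z, np.log(5.0), 0.0, 0.5, seed=rng)
            c = negbin_regression(y, {"z": z}, run_dispersion_test=False).coef("z")
            cover += abs(c["z"]) < 1.96
        assert cover / reps >= 0.88

    def test_poisson_limit_matches_poisson_glm(self, rng):
        import statsmodels.api as sm

        z = rng.normal(0.0, 0.5, 500)
        y = rng.poisson(np.exp(1.0 + 0.5 * z))
        nb = negbin_regression(y, {"z": z}, run_dispersion_test=False)
        X = sm.add_constant(pd.DataFrame({"z": z}))
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert nb.coef("z")["coef"] == pytest.approx(pois.params["z"], abs=1e-2)
        assert nb.alpha < 0.05

    def test_wald_z_is_coef_over_se(self, rng):
        z = rng.normal(0.3, 0.2, 85)
        y = simulate_unaware_counts(z, 0.95, 1.7, 0.5, seed=rng)
        res = negbin_regression(y, {"z": z})
        c = res.coef("z")
        assert c["z"] == pytest.approx(c["coef"] / c["se"])
        assert res.dispersion_test is not None

    def test_separation_warning(self):
        z = np.arange(20, dtype=float)
        y = np.arange(20)
        with pytest.warns(UserWarning, match="orders the counts"):
            negbin_regression(y, {"z": z}, run_dispersion_test=False)


class TestLinearCheck:
    def test_sign_agreement_with_nb_on_monotone_data(self, rng):
        agree = 0
        reps = 60
        for _ in range(reps):
            z = rng.normal(0.35, 0.2, 85)
            y = simulate_unaware_counts(z, 0.95, 1.7, 0.5, seed=rng)
            nb = negbin_regression(y, {"z": z}, run_dispersion_test=False).coef("z")
            ols = linear_check_regression(y, {"z": z}).loc["z"]
            agree += np.sign(nb["coef"]) == np.sign(ols["coef"])
        assert agree / reps >= 0.95

    def test_exact_recovery_of_linear_noiseless_outcome(self):
        # choose z = log10(x+1) so the transformed outcome is exactly linear
        counts = np.arange(30)
        z = log10_plus_one(counts)
        tab = linear_check_regression(counts, {"z": z})
        assert tab.loc["z", "coef"] == pytest.approx(1.0, abs=1e-10)
        assert tab.loc["const", "coef"] == pytest.approx(0.0, abs=1e-10)


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x = rng.standard_normal(200)
        y = 0.4 * x + rng.standard_normal(200)
        pc = partial_correlation(x, y)
        assert pc.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert pc.df == 198

    def test_control_annihilates_itself(self, rng):
        x = rng.standard_normal(100)
        c = rng.standard_normal(100)
        pc = partial_correlation(x, c, controls=c)
        assert abs(pc.r) < 1e-10

    def test_known_partial_correlation_recovered(self, rng):
        n = 10_000
        c = rng.standard_normal(n)
        u = rng.standard_normal(n)
        v = 0.3 * u + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        pc = partial_correlation(u + 2 * c, v - 1.5 * c, controls=c)
        assert pc.r == pytest.approx(0.3, abs=0.03)
        assert pc.df == n - 3

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(80),
                "y": rng.standard_normal(80),
                "c": rng.standard_normal(80),
            }
        )
        df["y"] += 0.5 * df.c
        df["x"] += 0.3 * df.c
        ours = partial_correlation(df.x, df.y, controls=df[["c"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        pcol = "p_val" if "p_val" in ref.columns else "p-unc"
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            partial_correlation(np.ones(30), np.arange(30.0))


class TestEndToEndInference:
    def test_null_cohorts_keep_nominal_false_positive_rates(self, rng):
        # no group effect, no behaviour link: HIV term, NB slope and partial r
        reps = 300
        hits = np.zeros(3)
        for _ in range(reps):
            df = _cohort(rng)
            n = len(df)
            df["fcc"] = rng.normal(0.35, 0.1, n)
            df["counts"] = simulate_unaware_counts(
                np.zeros(n), np.log(5.0), 0.0, 0.5, seed=rng
            )
            hits[0] += factorial_glm(df, "y").term("HIV")["p"] < 0.05
            nb = negbin_regression(df["counts"], {"fcc": df["fcc"]},
                                   run_dispersion_test=False)
            hits[1] += nb.coef("fcc")["p"] < 0.05
            pc = partial_correlation(
                df["fcc"], rng.standard_normal(n), controls=df[["mean_fd"]].to_numpy()
            )
            hits[2] += pc.p < 0.05
        rates = hits / reps
        assert np.all(rates >= 0.02) and np.all(rates <= 0.08)
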