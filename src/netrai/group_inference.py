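"""Cohort-level statistics for the 2×2 (HIV × CB) design.

Factorial general linear models with sum-to-zero factor coding and Type-III
F tests (partial eta squared per term), pooled-variance follow-up t tests,
overdispersion-tested negative-binomial models of unaware-error counts with
an OLS sensitivity re-analysis on log10(x+1), partial Pearson correlations,
and the cohort QC rules (>50% Go-error exclusion, |z|>3 count-outlier
removal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "GroupModelResult",
    "NBFitResult",
    "DispersionTest",
    "PartialCorrelation",
    "apply_qc_filters",
    "factorial_glm",
    "two_sample_t",
    "log10_plus_one",
    "dispersion_test",
    "negbin_regression",
    "linear_check_regression",
    "partial_correlation",
]

DEFAULT_COVARIATES = ("age", "sex", "mean_fd", "nic")


# ---------------------------------------------------------------------------
# QC


def apply_qc_filters(
    cohort: pd.DataFrame,
    go_error_cap: float = 0.5,
    outlier_z: float | None = 3.0,
    count_col: str = "unaware_errors",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply task-performance and count-outlier exclusions.

    Subjects with Go-error rate above ``go_error_cap`` are removed; among
    the remainder, subjects whose ``count_col`` z-score exceeds
    ``outlier_z`` in magnitude are removed.  Returns (filtered cohort,
    exclusion log with one row per removed subject and its reason).
    """
    exclusions = []
    keep = cohort.copy()
    if "go_error_rate" in keep.columns:
        bad = keep["go_error_rate"] > go_error_cap
        for _, row in keep[bad].iterrows():
            exclusions.append(
                {
                    "subject": row.get("subject", "?"),
                    "reason": f"go_error_rate {row['go_error_rate']:.3f} > {go_error_cap}",
                }
            )
        keep = keep[~bad]
    if outlier_z is not None and count_col in keep.columns and len(keep) > 2:
        x = keep[count_col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd > 0:
            z = (x - x.mean()) / sd
            bad = np.abs(z) > outlier_z
            for row, zi in zip(keep[bad].itertuples(), z[bad]):
                exclusions.append(
                    {
                        "subject": getattr(row, "subject", "?"),
                        "reason": f"{count_col} outlier |z|={abs(zi):.2f} > {outlier_z}",
                    }
                )
            keep = keep[~bad]
    if len(keep) == 0:
        warnings.warn("QC filters removed every subject", stacklevel=2)
    return keep.reset_index(drop=True), pd.DataFrame(
        exclusions, columns=["subject", "reason"]
    )


# ---------------------------------------------------------------------------
# factorial models


@dataclass
class GroupModelResult:
    """Type-III factorial-model summary.

    ``terms`` is indexed by HIV / CB / HIV:CB (plus covariates) with
    columns F, df_num, df_den, p, eta_p2; ``coefficients`` carries the
    estimates and SEs; ``model`` is the fitted statsmodels results object.
    """

    terms: pd.DataFrame
    coefficients: pd.DataFrame
    model: object

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


_TERM_NAMES = {
    "C(hiv, Sum)": "HIV",
    "C(cb, Sum)": "CB",
    "C(hiv, Sum):C(cb, Sum)": "HIV:CB",
}


def factorial_glm(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> GroupModelResult:
    """HIV × CB linear model with covariates and Type-III F tests.

    Factors are sum-to-zero coded, so each main-effect F is tested in the
    presence of the interaction (the convention matching per-factor F
    reporting in unbalanced designs).  Partial eta squared is
    SS_effect / (SS_effect + SS_error) per term.
    """
    for col in ("hiv", "cb", outcome, *covariates):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    counts = cohort.groupby(["hiv", "cb"]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError("need >= 2 subjects in each of the four HIV x CB cells")
    rhs = "C(hiv, Sum) * C(cb, Sum)"
    for cov in covariates:
        rhs += f" + {cov}"
    fit = smf.ols(f"Q('{outcome}') ~ {rhs}", data=cohort).fit()
    anova = sm.stats.anova_lm(fit, typ=3)
    ss_err = float(anova.loc["Residual", "sum_sq"])
    df_den = float(anova.loc["Residual", "df"])
    rows = {}
    for term, row in anova.iterrows():
        if term in ("Intercept", "Residual"):
            continue
        name = _TERM_NAMES.get(term, term)
        ss = float(row["sum_sq"])
        rows[name] = {
            "F": float(row["F"]),
            "df_num": float(row["df"]),
            "df_den": df_den,
            "p": float(row["PR(>F)"]),
            "eta_p2": ss / (ss + ss_err),
        }
    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return GroupModelResult(terms=pd.DataFrame(rows).T, coefficients=coef, model=fit)


def two_sample_t(a, b, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sided two-sample t test; pooled-variance Student t by default.

    Returns (t, df, p); with pooling df = n_a + n_b − 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if pooled and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log10_plus_one(x):
    """log10(x + 1) for nonnegative counts; 0 maps to 0, monotone."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    out = np.log10(x + 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# count models


@dataclass
class DispersionTest:
    """Cameron–Trivedi auxiliary overdispersion test after a Poisson fit."""

    statistic: float
    pvalue: float
    slope: float


def _design(predictors) -> pd.DataFrame:
    X = pd.DataFrame(predictors).astype(float)
    return sm.add_constant(X, has_constant="add")


def dispersion_test(counts, predictors) -> DispersionTest:
    """One-sided test of overdispersion against the Poisson mean model.

    Fits Poisson(log link) means μ̂, then regresses ((y−μ̂)² − y)/μ̂ on μ̂
    without intercept; the slope's t statistic tests Var(y) > E(y).
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    X = _design(predictors)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few observations for the dispersion test")
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = pois.fittedvalues
    aux_y = ((y - mu) ** 2 - y) / mu
    slope_fit = sm.OLS(aux_y, np.asarray(mu)).fit()
    t = float(np.asarray(slope_fit.tvalues)[0])
    p = float(stats.t.sf(t, df=len(y) - 1))
    return DispersionTest(
        statistic=t, pvalue=p, slope=float(np.asarray(slope_fit.params)[0])
    )


@dataclass
class NBFitResult:
    """Negative-binomial (NB2) ML fit summary.

    ``table`` is indexed by predictor with columns coef, se, z, p; ``alpha``
    is the dispersion in Var = μ + α·μ², estimated jointly.
    """

    table: pd.DataFrame
    alpha: float
    llf: float
    converged: bool
    dispersion_test: DispersionTest | None = None

    def coef(self, name: str) -> pd.Series:
        return self.table.loc[name]


def negbin_regression(
    counts,
    predictors,
    run_dispersion_test: bool = True,
) -> NBFitResult:
    """Maximum-likelihood negative-binomial (quadratic variance) regression.

    Log link; Wald z = coef/SE with two-sided p per predictor; dispersion α
    estimated jointly.  A perfect monotone ordering of counts by a single
    predictor triggers a separation warning; nonconvergence raises with the
    optimizer trace embedded.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    X = _design(predictors)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    for col in X.columns:
        if col == "const":
            continue
        order = np.argsort(X[col].to_numpy())
        if np.all(np.diff(y[order]) >= 0) and y[order][0] < y[order][-1]:
            warnings.warn(
                f"predictor {col!r} perfectly orders the counts (possible separation)",
                stacklevel=2,
            )
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200, method="bfgs")
        except Exception:
            fit = None
        if fit is None or not fit.mle_retvals.get("converged", False):
            fit_nm = model.fit(disp=0, maxiter=2000, method="nm")
            fit = fit_nm if fit is None or fit_nm.llf >= fit.llf else fit
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged and not np.all(np.isfinite(fit.bse)):
        raise RuntimeError(
            f"negative-binomial fit did not converge: {fit.mle_retvals}"
        )
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    names = list(X.columns)
    table = pd.DataFrame(
        {"coef": params[: len(names)], "se": bse[: len(names)]}, index=names
    )
    table["z"] = table["coef"] / table["se"]
    table["p"] = 2 * stats.norm.sf(np.abs(table["z"]))
    alpha = float(params[-1])
    disp = dispersion_test(counts, predictors) if run_dispersion_test else None
    return NBFitResult(
        table=table, alpha=alpha, llf=float(fit.llf), converged=converged,
        dispersion_test=disp,
    )


def linear_check_regression(counts, predictors) -> pd.DataFrame:
    """OLS sensitivity re-analysis of the count model on log10(x+1).

    Returns a tidy coefficient table (coef, se, t, p) on the transformed
    outcome with the same predictors as the NB model.
    """
    y = log10_plus_one(np.asarray(counts, dtype=float))
    X = _design(predictors)
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )


# ---------------------------------------------------------------------------
# partial correlation


@dataclass
class PartialCorrelation:
    r: float
    df: int
    p: float


def partial_correlation(x, y, controls=None) -> PartialCorrelation:
    """Pearson correlation of x and y after regressing out controls.

    Residualizes both variables on [1 | controls] by OLS, correlates the
    residuals, and tests with t = r·sqrt(df/(1−r²)) on df = n − 2 − k.
    With no controls this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if controls is None:
        C = np.ones((n, 1))
        k = 0
    else:
        C = np.column_stack([np.ones(n), np.asarray(controls, dtype=float).reshape(n, -1)])
        k = C.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations for {k} controls")
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals: partial correlation undefined")
    # a variable numerically annihilated by its controls carries no signal
    df = n - 2 - k
    if rx.var() < 1e-20 * x.var() or ry.var() < 1e-20 * y.var():
        return PartialCorrelation(r=0.0, df=df, p=1.0)
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return PartialCorrelation(r=r, df=df, p=0.0)
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=df))
    return PartialCorrelation(r=r, df=df, p=p)
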