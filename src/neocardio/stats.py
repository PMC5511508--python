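"""Group comparison and regression layer.

Thin, typed wrappers around scipy/statsmodels for the standard tests
(two-sample t / Mann-Whitney, chi-square, Pearson r, forced-entry OLS)
plus two pieces implemented here: the closed-form minimal detectable
standardized difference for a two-sample design, and a random-intercept
regression estimated by between/within moment decomposition with GLS for
the fixed effects.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "RegressionResult",
    "two_group_test",
    "chi_square",
    "forced_entry_ols",
    "pearson_r",
    "mde_two_sample",
    "random_intercept_fit",
]

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    estimate: float
    n: tuple
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    n: int
    r: float | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    method: str = "ols"


def two_group_test(x, y, method: str = "welch") -> TestResult:
    """Two-sample comparison: 'student', 'welch' or 'mannwhitney'.

    Mann-Whitney uses exact enumeration for small tie-free samples
    (both n <= 20) and the normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if method in ("student", "welch"):
        equal_var = method == "student"
        if equal_var and np.var(x) == 0 and np.var(y) == 0:
            raise ValueError("zero pooled variance")
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        est = float(np.mean(x) - np.mean(y))
        return TestResult(float(res.statistic), float(res.pvalue), est,
                          (len(x), len(y)), method)
    if method == "mannwhitney":
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        mw_method = "exact" if (max(len(x), len(y)) <= 20 and not ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=mw_method)
        est = float(np.median(x) - np.median(y))
        return TestResult(float(res.statistic), float(res.pvalue), est,
                          (len(x), len(y)), f"mannwhitney-{mw_method}")
    raise ValueError(f"unknown method {method!r}")


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 (or larger) count table."""
    t = np.asarray(table)
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a marginal total is zero")
    res = stats.chi2_contingency(t, correction=yates)
    # odds ratio as the estimate for 2x2 tables
    est = float("nan")
    if t.shape == (2, 2) and np.all(t > 0):
        est = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return TestResult(float(res.statistic), float(res.pvalue), est,
                      tuple(int(v) for v in t.sum(axis=1)),
                      "chi2-yates" if yates else "chi2")


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        if others.shape[1] == 0:
            continue
        resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j],
                                                     rcond=None)[0]
        if np.sum(resid ** 2) < 1e-10 * max(np.sum(arr[:, j] ** 2), 1.0):
            bad.append(name)
    return bad


def forced_entry_ols(y, predictors) -> RegressionResult:
    """OLS with all predictors entered simultaneously (forced entry).

    predictors: DataFrame (or dict of arrays).  Raises on rank deficiency,
    naming the collinear columns.
    """
    X = pd.DataFrame(predictors)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X.astype(float), prepend=True)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        bad = _collinear_columns(Xc.drop(columns="const"))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    r = None
    if X.shape[1] == 1:
        r = math.copysign(math.sqrt(fit.rsquared), fit.params.iloc[1])
    return RegressionResult(
        params=dict(fit.params), bse=dict(fit.bse), pvalues=dict(fit.pvalues),
        n=len(y), r=r, method="ols")


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(res.statistic), (len(x),), "pearson")


def mde_two_sample(n1: int, n2: int, alpha: float = 0.05,
                   power: float = 0.80, exact: bool = False) -> float:
    """Minimal detectable standardized difference (SD units).

    Normal approximation: d = (z_{1-alpha/2} + z_power) * sqrt(1/n1 + 1/n2).
    With exact=True the noncentral-t solution is used instead
    (statsmodels power machinery).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if exact:
        from statsmodels.stats.power import TTestIndPower

        return float(TTestIndPower().solve_power(
            effect_size=None, nobs1=n1, ratio=n2 / n1, alpha=alpha,
            power=power, alternative="two-sided"))
    z = stats.norm.ppf
    return float((z(1 - alpha / 2) + z(power)) * math.sqrt(1 / n1 + 1 / n2))


def random_intercept_fit(y, x, subject_ids) -> RegressionResult:
    """Random-intercept linear regression by moment decomposition + GLS.

    Variance components from the between/within decomposition of OLS
    residuals; fixed effects by the random-effects quasi-demeaning GLS
    transform.  With all subjects singletons this falls back to OLS with a
    warning; with zero intercept variance it equals OLS.
    """
    X = pd.DataFrame(x)
    y = np.asarray(y, dtype=float)
    sid = np.asarray(subject_ids)
    ids, inv, counts = np.unique(sid, return_inverse=True, return_counts=True)
    if np.sum(counts >= 2) < 2:
        warnings.warn("fewer than 2 subjects with repeats; falling back to OLS")
        res = forced_entry_ols(y, X)
        res.method = "ols-fallback"
        return res

    ols = forced_entry_ols(y, X)
    Xc = sm.add_constant(X.astype(float), prepend=True).to_numpy()
    beta = np.array([ols.params[k] for k in
                     sm.add_constant(X, prepend=True).columns])
    resid = y - Xc @ beta
    means = np.bincount(inv, resid) / counts
    within = resid - means[inv]
    sigma_e2 = float(np.sum(within ** 2) / max(len(y) - len(ids) - Xc.shape[1], 1))
    between = float(np.var(means, ddof=1))
    sigma_u2 = max(0.0, between - sigma_e2 * float(np.mean(1.0 / counts)))

    # quasi-demeaning GLS transform
    theta = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + counts * sigma_u2))
    ybar = np.bincount(inv, y) / counts
    xbar = np.vstack([np.bincount(inv, Xc[:, j]) / counts
                      for j in range(Xc.shape[1])]).T
    yt = y - theta[inv] * ybar[inv]
    Xt = Xc - theta[inv][:, None] * xbar[inv]
    fit = sm.OLS(yt, Xt).fit()
    names = list(sm.add_constant(X, prepend=True).columns)
    return RegressionResult(
        params=dict(zip(names, fit.params)),
        bse=dict(zip(names, fit.bse)),
        pvalues=dict(zip(names, fit.pvalues)),
        n=len(y),
        variance_components={"intercept_sd": math.sqrt(sigma_u2),
                             "residual_sd": math.sqrt(sigma_e2)},
        method="random-intercept-gls")
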