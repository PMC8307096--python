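"""Classical replication suite: chi-squared, t-tests, Spearman correlation,
hierarchical (two-step) regression with an R^2-change F test, median split,
and one-way ANOVA with Tukey HSD pairwise comparisons.

Thin, contract-checked wrappers over scipy.stats and statsmodels. The
chi-squared test is Pearson's without continuity correction; the t-test
defaults to pooled variances with Welch available by flag; group dummy
coding for the regression is CHR = 0, HC = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "TestResult",
    "HierRegResult",
    "pearson_chi2",
    "two_sample_t",
    "spearman_corr",
    "hierarchical_regression",
    "median_split",
    "anova_tukey",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str
    estimate: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "statistic": self.statistic,
            "df": df,
            "p_value": self.p_value,
            "method": self.method,
            "estimate": self.estimate,
        }


@dataclass(frozen=True)
class HierRegResult:
    """Two-step OLS: step-1 fit, step-2 fit, and the R^2-change F test."""

    step1_r2: float
    step1_adj_r2: float
    step1_f: float
    step1_df: tuple
    step1_p: float
    step2_r2: float
    delta_r2: float
    f_change: float
    f_change_df: tuple
    f_change_p: float
    coefficients: dict = field(default_factory=dict)  # name -> (B, t, p)

    def to_dict(self) -> dict:
        return {
            "step1": {
                "r2": self.step1_r2,
                "adj_r2": self.step1_adj_r2,
                "f": self.step1_f,
                "df": list(self.step1_df),
                "p": self.step1_p,
            },
            "step2": {
                "r2": self.step2_r2,
                "delta_r2": self.delta_r2,
                "f_change": self.f_change,
                "df": list(self.f_change_df),
                "p": self.f_change_p,
            },
            "coefficients": {k: {"B": v[0], "t": v[1], "p": v[2]} for k, v in self.coefficients.items()},
        }


def pearson_chi2(table) -> TestResult:
    """Pearson chi-squared on a 2x2 count table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError("zero margin: expected counts undefined")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(res.statistic), df=1.0, p_value=float(res.pvalue), method="pearson_chi2")


def two_sample_t(a, b, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t-test; pooled variances by default, Welch otherwise.

    ``estimate`` is the mean difference ``mean(a) - mean(b)``.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    av, bv = av[np.isfinite(av)], bv[np.isfinite(bv)]
    if av.size < 2 or bv.size < 2:
        raise DegenerateInputError("each group needs at least 2 observations")
    if av.std(ddof=1) == 0 and bv.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance in both groups: t undefined")
    res = stats.ttest_ind(av, bv, equal_var=pooled)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method="t_pooled" if pooled else "t_welch",
        estimate=float(av.mean() - bv.mean()),
    )


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation (tie-safe midranks), p via the t approximation."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("paired vectors required")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {xv.size}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(xv, yv)
    return TestResult(
        statistic=float(rho), df=float(xv.size - 2), p_value=float(min(max(p, 0.0), 1.0)),
        method="spearman", estimate=float(rho),
    )


def _ols(y, X):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    fit = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DegenerateInputError("rank-deficient design matrix")
    return fit


def hierarchical_regression(y, step1_predictors, step2_predictors, names=None) -> HierRegResult:
    """Two-step OLS with the R^2-change F test between steps.

    ``step1_predictors`` and ``step2_predictors`` are (n, k) matrices (1-D
    vectors accepted); step 2 refits on the concatenation of both blocks.
    ``names`` optionally labels the full-model predictors (after 'const').
    """
    y = np.asarray(y, dtype=float).ravel()
    X1 = np.atleast_2d(np.asarray(step1_predictors, dtype=float))
    X2 = np.atleast_2d(np.asarray(step2_predictors, dtype=float))
    if X1.shape[0] != y.size:
        X1 = X1.T
    if X2.shape[0] != y.size:
        X2 = X2.T
    n = y.size
    k1, k2 = X1.shape[1], X2.shape[1]
    k_tot = k1 + k2
    if n <= k_tot + 1:
        raise ValueError(f"n = {n} must exceed total predictors + 1 = {k_tot + 1}")

    fit1 = _ols(y, X1)
    fit_full = _ols(y, np.column_stack([X1, X2]))

    r2_1, r2_2 = float(fit1.rsquared), float(fit_full.rsquared)
    df_change = (k2, n - k_tot - 1)
    denom = (1.0 - r2_2) / df_change[1]
    f_change = ((r2_2 - r2_1) / k2) / denom if denom > 0 else float("inf")
    p_change = float(stats.f.sf(f_change, *df_change)) if np.isfinite(f_change) else 0.0

    if names is None:
        names = [f"x{i + 1}" for i in range(k_tot)]
    coef_names = ["const"] + list(names)
    coefficients = {
        nm: (float(b), float(t), float(p))
        for nm, b, t, p in zip(coef_names, fit_full.params, fit_full.tvalues, fit_full.pvalues)
    }
    return HierRegResult(
        step1_r2=r2_1,
        step1_adj_r2=float(fit1.rsquared_adj),
        step1_f=float(fit1.fvalue),
        step1_df=(k1, n - k1 - 1),
        step1_p=float(fit1.f_pvalue),
        step2_r2=r2_2,
        delta_r2=r2_2 - r2_1,
        f_change=float(f_change),
        f_change_df=df_change,
        f_change_p=p_change,
        coefficients=coefficients,
    )


def median_split(values) -> np.ndarray:
    """Split at the sample median: strictly above -> 'high', else 'low'.

    Values equal to the median go to the low subgroup, so an odd-length
    vector of distinct values splits ceil(n/2) low / floor(n/2) high.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to split")
    med = float(np.median(v))
    return np.where(v > med, "high", "low")


def anova_tukey(values, labels):
    """One-way ANOVA across k groups plus Tukey HSD pairwise comparisons.

    Returns ``(TestResult, pairs)`` where ``pairs`` is a list of
    ``{"groups": (a, b), "diff": mean_a - mean_b, "p_adj": ...}`` with p
    adjusted via the studentized-range distribution.
    """
    v = np.asarray(values, dtype=float).ravel()
    lab = np.asarray(labels).astype(str).ravel()
    if v.size != lab.size:
        raise ValueError("values and labels must have equal length")
    keep = np.isfinite(v)
    v, lab = v[keep], lab[keep]
    names = sorted(set(lab.tolist()))
    if len(names) < 2:
        raise DegenerateInputError("need at least 2 groups")
    samples = [v[lab == nm] for nm in names]
    for nm, s in zip(names, samples):
        if s.size < 2:
            raise DegenerateInputError(f"group {nm!r} has fewer than 2 observations")
    k = len(names)
    n = v.size
    if all(s.std(ddof=1) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        omnibus = TestResult(statistic=0.0, df=(float(k - 1), float(n - k)), p_value=1.0, method="anova")
        pairs = [
            {"groups": (names[i], names[j]), "diff": 0.0, "p_adj": 1.0}
            for i in range(k) for j in range(i + 1, k)
        ]
        return omnibus, pairs
    f, p = stats.f_oneway(*samples)
    omnibus = TestResult(statistic=float(f), df=(float(k - 1), float(n - k)), p_value=float(p), method="anova")
    hsd = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(
                {
                    "groups": (names[i], names[j]),
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(min(max(hsd.pvalue[i, j], 0.0), 1.0)),
                }
            )
    return omnibus, pairs
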