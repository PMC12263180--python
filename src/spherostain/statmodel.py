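"""Time-course regression and variance-gated two-group comparison.

The statistical conventions used throughout:

* responses over staining time are fit by ordinary least squares (not
  forced through the origin), reporting slope, intercept and R²;
* for the fractional-penetration response, the predicted time to complete
  penetration solves ``intercept + slope·t = 1``;
* two groups are compared with an initial two-sided F-test of variance
  equality at the same alpha; Welch's two-tailed t-test is used when the
  variances differ, otherwise the unpaired Student's t-test.  p < 0.05 is
  reported as significant, with the star convention
  (* p<0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001);
* summaries are mean ± sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RegressionFit:
    slope: float  #: response units per minute
    intercept: float  #: response units
    r_squared: float
    n: int


@dataclass
class ComparisonResult:
    test_used: str  #: "student" or "welch"
    f_statistic: float
    f_p_value: float
    t_statistic: float
    p_value: float
    significant: bool
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n_per_group: tuple[int, int]
    alpha: float
    stars: str


def fit_timecourse(times, responses) -> RegressionFit:
    """Ordinary least squares of response on staining time (minutes)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(responses, dtype=float)
    if t.size != y.size:
        raise ValueError("times and responses must have the same length")
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(t).size < 2:
        raise ValueError("all times identical; regression undefined")
    if np.allclose(y, y[0]):
        # zero total variance: flat fit, R^2 defined as 0
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=t.size)
    res = stats.linregress(t, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=t.size,
    )


def predict_complete_time(fit: RegressionFit) -> float:
    """Staining time (min) at which a fractional-depth fit reaches 1.0."""
    if fit.slope <= 0:
        raise ValueError("non-positive slope: the fit never predicts completion")
    return (1.0 - fit.intercept) / fit.slope


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison with an initial F-test gate on the variances.

    The F statistic is the larger sample variance over the smaller, with a
    two-sided p-value; if variance equality is rejected at ``alpha`` the
    groups are compared with Welch's two-tailed t-test, otherwise with the
    unpaired Student's t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance; comparison degenerate")
    # report the larger variance over the smaller; two-sided p from the
    # standard doubled-tail definition, p = 2*min(P(F<=f), P(F>=f))
    if va == 0.0 or vb == 0.0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = max(va, vb) / min(va, vb)
        dfa, dfb = a.size - 1, b.size - 1
        f_p = min(
            1.0,
            2.0 * float(min(stats.f.cdf(va / vb, dfa, dfb), stats.f.sf(va / vb, dfa, dfb))),
        )
    welch = f_p < alpha
    t_res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(t_res.pvalue)
    return ComparisonResult(
        test_used="welch" if welch else "student",
        f_statistic=float(f_stat),
        f_p_value=f_p,
        t_statistic=float(t_res.statistic),
        p_value=p,
        significant=p < alpha,
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        n_per_group=(int(a.size), int(b.size)),
        alpha=alpha,
        stars=significance_stars(p),
    )


def summarize(values) -> tuple[float, float, int]:
    """Mean, sample SD (0 when n == 1) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd, int(v.size)
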