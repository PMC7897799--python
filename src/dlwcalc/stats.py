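"""Method-comparison statistics.

The validation workflow compares DLW-derived rCO2 against chamber
indirect calorimetry with four standard tools: per-subject percent
deviations, column summaries with one-sample t-tests against zero bias,
Bland-Altman agreement analysis (mean difference +/- 2 SD limits, plus a
count of subjects beyond +/-10% disagreement), and ordinary
least-squares regression of prediction on reference together with the
reduced-major-axis (RMA) slope SD(y)/SD(x), which is symmetric in the
two methods and satisfies rma = ols/r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError


def percent_deviation(test_value, reference_value):
    """100 * (test - reference) / reference. Accepts scalars or arrays."""
    ref = np.asarray(reference_value, dtype=float)
    if np.any(ref <= 0):
        raise DataError("reference values must be positive")
    out = 100.0 * (np.asarray(test_value, dtype=float) - ref) / ref
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DeviationSummary:
    """n, mean, SD (n-1 denominator) of a percent-deviation column and the
    one-sample two-sided t-test of the mean against zero. For a constant
    column SD is 0 and t/p are NaN with ``sd_zero`` set."""

    n: int
    mean: float
    sd: float
    t_statistic: float
    p_value: float
    sd_zero: bool = False


def summarize_deviations(deviations) -> DeviationSummary:
    """Summarize a percent-deviation column; missing entries are excluded
    and ``n`` reports the values actually used."""
    values = np.asarray(deviations, dtype=float)
    values = values[~np.isnan(values)]
    n = int(values.size)
    if n < 2:
        raise DataError(f"need at least 2 non-missing deviations, got {n}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return DeviationSummary(n=n, mean=mean, sd=0.0,
                                t_statistic=float("nan"),
                                p_value=float("nan"), sd_zero=True)
    t_res = sps.ttest_1samp(values, 0.0)
    return DeviationSummary(n=n, mean=mean, sd=sd,
                            t_statistic=float(t_res.statistic),
                            p_value=float(t_res.pvalue))


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]      # mean +/- multiplier * SD
    limit_multiplier: float
    n: int
    n_beyond_10pct: int              # |percent difference| > 10


def bland_altman(test, reference, limit_multiplier: float = 2.0,
                 ) -> BlandAltmanResult:
    """Bland-Altman comparison of paired measurements.

    Differences are test - reference; agreement limits are
    mean +/- ``limit_multiplier`` * SD (2 by convention here, not 1.96);
    the percent band count uses 100*(test-reference)/reference.
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise DataError("test and reference must be 1-D sequences of equal length")
    keep = ~(np.isnan(t) | np.isnan(r))
    t, r = t[keep], r[keep]
    if t.size < 2:
        raise DataError(f"need at least 2 complete pairs, got {t.size}")
    diff = t - r
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pct = percent_deviation(t, r)
    return BlandAltmanResult(
        mean_difference=mean, sd_difference=sd,
        limits=(mean - limit_multiplier * sd, mean + limit_multiplier * sd),
        limit_multiplier=limit_multiplier, n=int(t.size),
        n_beyond_10pct=int((np.abs(pct) > 10.0).sum()))


@dataclass(frozen=True)
class RegressionResult:
    ols_slope: float
    ols_intercept: float
    r_squared: float
    rma_slope: float
    n: int


def ols_with_rma(x, y) -> RegressionResult:
    """OLS regression of prediction ``y`` on reference ``x`` plus the RMA
    slope SD(y)/SD(x) signed by the correlation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DataError("x and y must be 1-D sequences of equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise DataError(f"need at least 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0:
        raise DataError("x has zero variance; regression is undefined")
    fit = sps.linregress(xa, ya)
    rma = float(ya.std(ddof=1) / xa.std(ddof=1))
    rma = math.copysign(rma, fit.rvalue) if fit.rvalue != 0 else rma
    return RegressionResult(ols_slope=float(fit.slope),
                            ols_intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            rma_slope=rma, n=int(xa.size))
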