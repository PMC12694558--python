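"""Method-agreement statistics for paired sensor-vs-reference measurements.

The validation suite compares device-computed gait features against a
reference (e.g. video) on matched subjects: per-pair relative error,
paired Student t for systematic bias, Pearson correlation, the
intraclass correlation ICC(2,1) for absolute agreement, and mean ± SD
with a t-based 95% confidence interval.

ICC(2,1) follows the Shrout–Fleiss two-way random-effects, absolute
agreement, single-measures form computed from the two-way ANOVA mean
squares:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

with MSR the between-subject, MSC the between-rater and MSE the
residual mean square for n subjects × k raters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .series import SignalError


@dataclass
class AgreementStats:
    """Full agreement report for one feature's measured/reference pairs.

    ``re_values`` are per-pair relative errors in %; ``mean``/``sd`` and
    the 95% CI summarize the paired differences (measured − reference),
    i.e. the systematic bias in input units.
    """

    re_values: np.ndarray
    re_mean: float
    re_sd: float
    t_stat: float
    df: int
    p_two_sided: float
    pearson_r: float
    p_r: float
    icc21: float
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float


def relative_error(y, yr):
    """Relative error |y − yr| / yr × 100, in percent (elementwise)."""
    y = np.asarray(y, dtype=float)
    yr = np.asarray(yr, dtype=float)
    if np.any(yr == 0):
        raise SignalError("reference value of 0 makes relative error undefined")
    out = np.abs(y - yr) / yr * 100.0
    return float(out) if out.ndim == 0 else out


def paired_t(a, b):
    """Paired Student t on d = a − b: returns (t, df, two-sided p).

    t = mean(d) / (sd(d)/√n) with the sample (n−1) SD and df = n − 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise SignalError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise SignalError("zero-variance differences: t undefined")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return t, n - 1, p


def pearson(a, b):
    """Pearson product-moment correlation and its two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise SignalError("need two equal-length vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise SignalError("constant input: correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def icc_2_1(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an n-subjects × k-raters matrix with no missing cells.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise SignalError("ratings must be an n>=2 by k>=2 matrix")
    if not np.all(np.isfinite(y)):
        raise SignalError("ratings matrix must be complete")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise SignalError("degenerate ratings matrix: ICC undefined")
    return float((msr - mse) / denom)


def mean_sd_ci(values, confidence: float = 0.95):
    """Sample mean, SD (n−1) and t-based confidence interval.

    Returns ``(mean, sd, (ci_low, ci_high))`` with
    CI = mean ± t_{1−α/2, n−1}·sd/√n.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise SignalError("need at least 2 values")
    n = len(x)
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return m, sd, (m - half, m + half)


def agreement(measured, reference) -> AgreementStats:
    """All agreement statistics for one measured-vs-reference feature."""
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    re = relative_error(measured, reference)
    re_mean, re_sd, _ = mean_sd_ci(re)
    t, df, p = paired_t(measured, reference)
    r, p_r = pearson(measured, reference)
    icc = icc_2_1(np.column_stack([reference, measured]))
    d_mean, d_sd, (lo, hi) = mean_sd_ci(measured - reference)
    return AgreementStats(
        re_values=re,
        re_mean=re_mean,
        re_sd=re_sd,
        t_stat=t,
        df=df,
        p_two_sided=p,
        pearson_r=r,
        p_r=p_r,
        icc21=icc,
        mean=d_mean,
        sd=d_sd,
        ci95_low=lo,
        ci95_high=hi,
    )
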