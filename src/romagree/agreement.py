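"""Reliability and agreement statistics for repeated angle measurements.

Implements the full battery used for method-comparison of goniometry
devices on a two-way crossed design (n subjects x k measurements):

* summary statistics and t-tests (paired, and pooled two-sample from
  summary statistics, which is the form the printed reliability tables
  are internally consistent with);
* Bland-Altman analysis: bias, SD of the paired differences, 1.96-SD
  limits of agreement (LOA), the percentage of differences inside the
  LOA, the standard error of the mean difference and the minimal
  detectable change MDC95 = 1.96*sqrt(2)*SEM;
* intraclass correlation, two-way random-effects absolute-agreement
  forms ICC(2,1) (single measures) and ICC(2,2) (average of k
  measures), with the F-based 95% confidence interval and the
  conventional qualitative grading;
* Lin's concordance correlation coefficient.

A note on SEM: throughout this package SEM is the standard error of the
mean difference, sd(differences)/sqrt(n) -- not the classical
reliability SEM = SD*sqrt(1-ICC).  The MDC95 column is defined from it,
so MDC95/SEM = 1.96*sqrt(2) = 2.77186... exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: MDC95 = MDC_FACTOR * SEM.
MDC_FACTOR = 1.96 * math.sqrt(2.0)

#: Variance below which a series is treated as exactly constant.
_ZERO_VAR = 1e-24

ICC_GRADES = ("poor", "fair", "good", "excellent")


class DegenerateDataError(ValueError):
    """Raised when zero-variance input makes a statistic undefined."""


# ---------------------------------------------------------------------------
# summary statistics and t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Sample mean, sample SD (n-1 divisor) and count."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def summarize(values) -> SummaryStats:
    x = np.asarray(values, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize needs a 1-d sequence with n >= 2")
    return SummaryStats(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def t_test_from_summary(a: SummaryStats, b: SummaryStats) -> TTestResult:
    """Pooled two-sample t-test from summary statistics (equal n).

    t = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2)/n), df = 2n - 2,
    two-sided p.  With equal n this equals the classic pooled-variance
    two-sample statistic.  Zero pooled variance with equal means returns
    t=0, p=1; with unequal means it is undefined and raises.
    """
    if a.n != b.n:
        raise ValueError("summary-form t-test requires equal group sizes")
    n = a.n
    se2 = (a.sd**2 + b.sd**2) / n
    if se2 <= _ZERO_VAR:
        if a.mean == b.mean:
            return TTestResult(0.0, 2 * n - 2, 1.0, degenerate=True)
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = 2 * n - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def paired_t_test(differences) -> TTestResult:
    """One-sample t-test of the paired differences against zero."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    n = d.size
    sd = d.std(ddof=1)
    if sd**2 <= _ZERO_VAR:
        if abs(d.mean()) <= 1e-12:
            return TTestResult(0.0, n - 1, 1.0, degenerate=True)
        # all differences identical and nonzero: the statistic diverges
        return TTestResult(math.inf if d.mean() > 0 else -math.inf, n - 1, 0.0, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), float(n - 1), float(p))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series via their differences.

    ``agreement_pct`` is the percentage of paired differences falling
    inside the limits of agreement (boundary inclusive); by construction
    it is an integer multiple of 100/n.
    """

    bias: float
    sd_d: float
    loa_low: float
    loa_high: float
    agreement_pct: float
    sem: float
    mdc95: float
    n: int
    degenerate: bool = False
    means: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    diffs: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def agreement_pct(differences, loa_low: float, loa_high: float) -> float:
    """Percentage of differences with loa_low <= d <= loa_high."""
    d = np.asarray(differences, float)
    if d.size == 0:
        raise ValueError("agreement_pct needs a non-empty input")
    if loa_low > loa_high:
        raise ValueError("loa_low must not exceed loa_high")
    inside = np.count_nonzero((d >= loa_low) & (d <= loa_high))
    return 100.0 * inside / d.size


def bland_altman(x, y, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman analysis of paired series ``x`` and ``y`` (d = x - y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if x.size < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = x - y
    n = d.size
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    half = loa_multiplier * sd_d
    loa_low, loa_high = bias - half, bias + half
    sem = sd_d / math.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        sd_d=sd_d,
        loa_low=loa_low,
        loa_high=loa_high,
        agreement_pct=agreement_pct(d, loa_low, loa_high),
        sem=sem,
        mdc95=mdc95(sem),
        n=n,
        degenerate=sd_d**2 <= _ZERO_VAR,
        means=(x + y) / 2.0,
        diffs=d,
    )


def mdc95(sem: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96*sqrt(2)*SEM."""
    if sem < 0:
        raise ValueError("sem must be non-negative")
    return MDC_FACTOR * sem


# ---------------------------------------------------------------------------
# two-way ANOVA mean squares and ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Mean squares of the two-way crossed decomposition without replication.

    msr: between-subjects (rows, df n-1); msc: between-measurements
    (columns, df k-1); mse: residual (df (n-1)(k-1)).
    """

    msr: float
    msc: float
    mse: float
    n: int
    k: int


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    form: str  # "single" (2,1) or "average" (2,2)
    grade: str


def anova_two_way(matrix) -> AnovaMeanSquares:
    """Row/column/residual mean squares of an n x k table (no missing cells)."""
    m = np.asarray(matrix, float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-d (subjects x measurements)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("ANOVA needs at least 2 subjects and 2 measurements")
    if not np.isfinite(m).all():
        raise ValueError("matrix must not contain missing cells")
    grand = m.mean()
    ssr = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ssc = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return AnovaMeanSquares(
        msr=ssr / (n - 1),
        msc=ssc / (k - 1),
        mse=sse / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def grade_icc(estimate: float) -> str:
    """Conventional qualitative grade for a reliability ICC.

    < 0.50 poor; [0.50, 0.75) fair; [0.75, 0.90) good; >= 0.90
    excellent.  The 0.75 and 0.90 boundaries are assigned to the higher
    class.
    """
    if not math.isfinite(estimate):
        raise ValueError("estimate must be finite")
    if estimate < 0.50:
        return "poor"
    if estimate < 0.75:
        return "fair"
    if estimate < 0.90:
        return "good"
    return "excellent"


def _icc_single_ci(ms: AnovaMeanSquares, est: float, alpha: float) -> tuple[float, float]:
    # F-based interval for the single-measures absolute-agreement ICC
    # (Shrout & Fleiss construction with Satterthwaite df for the
    # column/error mixture).
    n, k = ms.n, ms.k
    msr, msc, mse = ms.msr, ms.msc, ms.mse
    if mse <= _ZERO_VAR and msc <= _ZERO_VAR:
        # no within-subject noise at all: interval collapses to the estimate
        return est, est
    a = k * est / (n * (1.0 - est)) if est < 1.0 else math.inf
    b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est)) if est < 1.0 else math.inf
    if not math.isfinite(a):
        return est, est
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(lo), float(hi)


def _sb_average(r: float, k: int) -> float:
    # Spearman-Brown step-up from a single-measures coefficient.
    if r >= 1.0:
        return 1.0
    return k * r / (1.0 + (k - 1.0) * r)


def icc(matrix, form: str = "single", alpha: float = 0.05) -> IccResult:
    """Two-way random-effects absolute-agreement intraclass correlation.

    ``form="single"`` is ICC(2,1) -- reliability of one measurement:

        (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    ``form="average"`` is ICC(2,k) -- reliability of the mean of the k
    measurements:

        (MSR - MSE) / (MSR + (MSC - MSE)/n)

    The 95% CI for the single form uses the F-based construction; the
    average-form interval is the Spearman-Brown transform of the
    single-form bounds.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    ms = anova_two_way(matrix)
    n, k = ms.n, ms.k
    if ms.msr <= _ZERO_VAR and ms.msc <= _ZERO_VAR and ms.mse <= _ZERO_VAR:
        raise DegenerateDataError("constant matrix: ICC is undefined")
    denom_single = ms.msr + (k - 1) * ms.mse + k * (ms.msc - ms.mse) / n
    if abs(denom_single) <= _ZERO_VAR:
        raise DegenerateDataError("zero denominator: ICC is undefined")
    est_single = (ms.msr - ms.mse) / denom_single
    lo_s, hi_s = _icc_single_ci(ms, est_single, alpha)
    if form == "single":
        est, lo, hi = est_single, lo_s, hi_s
    else:
        denom_avg = ms.msr + (ms.msc - ms.mse) / n
        if abs(denom_avg) <= _ZERO_VAR:
            raise DegenerateDataError("zero denominator: ICC is undefined")
        est = (ms.msr - ms.mse) / denom_avg
        lo, hi = _sb_average(lo_s, k), _sb_average(hi_s, k)
    lo = min(lo, est)
    hi = max(hi, est)
    return IccResult(float(est), float(lo), float(hi), form, grade_icc(est))


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient
# ---------------------------------------------------------------------------


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with the
    n-1 divisor used consistently for the covariance and both variances
    (the divisor cancels except against the squared mean shift, where
    the sample-variance convention matches the rest of this module).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("lin_ccc needs equal-length 1-d sequences with n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx <= _ZERO_VAR and vy <= _ZERO_VAR:
        raise DegenerateDataError("both series constant: CCC is undefined")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))
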