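"""Test-retest reliability statistics and ICC-based sample-size planning.

The unit of analysis is a ratings matrix: n subjects x k repeated
measurements of one HRV index (the same recordings analyzed twice by one
rater, or once each by two raters). For each index the suite reports

* ICC(2,1): two-way random-effects, absolute-agreement, single-measures
  intraclass correlation, with its exact F-based 95% confidence interval
  and the conventional interpretation bands (<0.40 low, 0.40-0.75
  moderate, 0.75-0.90 substantial, >0.90 excellent);
* SEM = SD x sqrt(1 - ICC), the random measurement error in index
  units (SD pooled over all n*k values), and MDC95 = 1.96 x sqrt(2) x SEM,
  the smallest change exceeding that error with 95% confidence, each
  also as a percentage of the grand mean;
* the mean within-subject coefficient of variation;
* Bland-Altman bias, SD of the paired differences, and 95% limits of
  agreement bias +/- 1.96 x SD.

Sample-size planning for a reliability study uses the
Walter-Eliasziw-Donner approximation for testing ICC >= rho1 against a
minimum acceptable rho0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FLEISS_BANDS = ((0.40, "low"), (0.75, "moderate"), (0.90, "substantial"))

#: Multiplier converting SEM to the 95% minimal detectable change.
MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class RatingsMatrix:
    """n subjects x k repeated measurements of one index."""

    values: np.ndarray
    index_name: str = ""
    comparison: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D (subjects x measurements) array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 measurements")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings must be finite with no missing cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns, error."""
    n, k = values.shape
    grand = values.mean()
    ss_rows = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return float(msr), float(msc), float(mse)


def icc_2_1(
    ratings: RatingsMatrix, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) point estimate with its exact F-based confidence interval.

    Two-way random effects, absolute agreement, single measures:
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)). The interval is
    the F-based two-sided construction for this form. With fewer than 3
    subjects only the point estimate is defined and the CI is (nan, nan).
    """
    v = ratings.values
    n, k = v.shape
    msr, msc, mse = _anova_mean_squares(v)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("degenerate ratings: zero total variance")
    icc = (msr - mse) / denom
    if n < 3:
        return float(icc), (float("nan"), float("nan"))
    if mse == 0:
        # perfect agreement: interval degenerates to the point estimate
        return float(icc), (float(icc), float(icc))
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else float("inf")
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else float("inf")
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v_df = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v_df)
    f2 = stats.f.ppf(1 - alpha / 2, v_df, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return float(icc), (float(lower), float(upper))


def classify_icc(icc: float) -> str:
    """Interpretation bands: <0.40 low, [0.40,0.75) moderate,
    [0.75,0.90] substantial, >0.90 excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "low"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "substantial"
    return "excellent"


def sem(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, SD x sqrt(1 - ICC)."""
    if sd_pooled < 0:
        raise ValueError("SD must be non-negative")
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    return float(sd_pooled * math.sqrt(1.0 - icc))


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence, 1.96 x sqrt(2) x SEM."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return float(MDC_FACTOR * sem_value)


def percent_of_mean(stat: float, ratings: RatingsMatrix) -> float:
    """Express a statistic as a percentage of the grand mean of all cells."""
    grand = float(ratings.values.mean())
    if grand == 0:
        raise ValueError("grand mean is zero")
    return 100.0 * stat / grand


def cv_percent(ratings: RatingsMatrix, aggregate: str = "mean") -> float:
    """Within-subject coefficient of variation, %.

    Per subject: SD of the k measurements / their mean x 100. Aggregated
    across subjects by the arithmetic mean (default) or root mean square
    (``aggregate='rms'``).
    """
    v = ratings.values
    means = v.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("a subject mean of zero makes CV undefined")
    cvs = 100.0 * v.std(axis=1, ddof=1) / means
    if aggregate == "mean":
        return float(cvs.mean())
    if aggregate == "rms":
        return float(np.sqrt(np.mean(cvs**2)))
    raise ValueError("aggregate must be 'mean' or 'rms'")


def bland_altman(ratings: RatingsMatrix) -> tuple[float, float, tuple[float, float]]:
    """Bias, SD of paired differences, and 95% limits of agreement.

    Only defined for k = 2; differences are first minus second
    measurement.
    """
    if ratings.k != 2:
        raise ValueError("Bland-Altman agreement requires exactly 2 measurements")
    d = ratings.values[:, 0] - ratings.values[:, 1]
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return bias, sd_diff, (bias - 1.96 * sd_diff, bias + 1.96 * sd_diff)


@dataclass
class ReliabilityReport:
    """All reliability statistics for one index (one table row)."""

    index_name: str
    comparison: str
    n: int
    icc: float
    ci95: tuple
    icc_class: str
    sem: float
    sem_pct: float
    mdc: float
    mdc_pct: float
    cv_pct: float
    bias: float
    sd_diff: float
    loa: tuple
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "index": self.index_name,
            "comparison": self.comparison,
            "n": self.n,
            "ICC": self.icc,
            "CI95_low": self.ci95[0],
            "CI95_high": self.ci95[1],
            "ICC_class": self.icc_class,
            "SEM": self.sem,
            "SEM_pct": self.sem_pct,
            "MDC": self.mdc,
            "MDC_pct": self.mdc_pct,
            "bias": self.bias,
            "SD_diff": self.sd_diff,
            "CV_pct": self.cv_pct,
            "LoA_low": self.loa[0],
            "LoA_high": self.loa[1],
        }


def reliability_report(ratings: RatingsMatrix) -> ReliabilityReport:
    """Full reliability panel for one ratings matrix (k = 2)."""
    icc, ci = icc_2_1(ratings)
    sd_pooled = float(ratings.values.std(ddof=1))
    sem_value = sem(sd_pooled, icc)
    mdc_value = mdc(sem_value)
    bias, sd_diff, loa = bland_altman(ratings)
    return ReliabilityReport(
        index_name=ratings.index_name,
        comparison=ratings.comparison,
        n=ratings.n,
        icc=icc,
        ci95=ci,
        icc_class=classify_icc(icc),
        sem=sem_value,
        sem_pct=percent_of_mean(sem_value, ratings),
        mdc=mdc_value,
        mdc_pct=percent_of_mean(mdc_value, ratings),
        cv_pct=cv_percent(ratings),
        bias=bias,
        sd_diff=sd_diff,
        loa=loa,
    )


def sample_size_icc(
    rho0: float,
    rho1: float,
    alpha: float = 0.05,
    power: float = 0.80,
    k: int = 2,
    loss_frac: float = 0.0,
) -> int:
    """Walter-Eliasziw-Donner sample size for detecting ICC rho1 vs rho0.

    theta = rho/(1-rho); C0 = (1 + k theta0)/(1 + k theta1);
    n0 = 1 + 2k (z_{1-alpha/2} + z_{1-beta})^2 / ((k-1) ln(C0)^2),
    rounded up, then inflated for the anticipated loss rate and rounded
    up again.
    """
    if not 0 <= rho0 < 1 or not 0 < rho1 < 1:
        raise ValueError("ICC values must lie in [0, 1)")
    if rho1 <= rho0:
        raise ValueError("no detectable difference: rho1 must exceed rho0")
    if k < 2:
        raise ValueError("need at least 2 measurements per subject")
    if not 0 <= loss_frac < 1:
        raise ValueError("loss fraction must lie in [0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    theta0 = rho0 / (1 - rho0)
    theta1 = rho1 / (1 - rho1)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    n0 = 1 + 2 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return math.ceil(math.ceil(n0) / (1 - loss_frac))
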