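"""ICH-style validation statistics and between-method comparison tests.

Covers linearity (OLS with residual SD), accuracy (recovery %), precision
(RSD %), detection/quantitation limits (3.3 sigma/S and 10 sigma/S),
standard-addition extrapolation, and the two summary-statistics tests used
to compare assay methods: the pooled-variance two-sample t test and the
variance-ratio F test, both evaluated against two-tailed/upper 5% critical
values as is conventional in pharmaceutical QC reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares calibration line y = slope*x + intercept."""

    slope: float
    intercept: float
    r: float
    residual_sd: float
    n: int
    intercept_sd: float = float("nan")

    def predict_concentration(self, signal: float) -> float:
        """Invert the calibration: C = (signal - intercept) / slope."""
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (signal - self.intercept) / self.slope


def fit_line(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS line of y on x with Pearson r and n-2 residual SD.

    Requires at least 3 points and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x values are all equal; cannot fit a line")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ssr = float(np.sum((y - fitted) ** 2))
    residual_sd = math.sqrt(ssr / (n - 2))
    # SD of the intercept estimate: s * sqrt(sum x^2 / (n * Sxx))
    intercept_sd = residual_sd * math.sqrt(float(np.sum(x * x)) / (n * sxx))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        residual_sd=residual_sd,
        n=int(n),
        intercept_sd=intercept_sd,
    )


def recovery_percent(found: float, true: float) -> float:
    """Accuracy as 100 * found / true (%); `true` must be positive."""
    if true <= 0:
        raise ValueError("true concentration must be positive")
    return 100.0 * found / true


def precision_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicate determinations."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    return 100.0 * float(arr.std(ddof=1)) / mean


def lod_loq(fit: LinearFit, sigma_source: str = "residual_sd") -> tuple[float, float]:
    """Detection and quantitation limits: 3.3 sigma/|S| and 10 sigma/|S|.

    sigma is the regression residual SD by default, or the SD of the
    intercept estimate with sigma_source="intercept_sd".  The LOQ/LOD ratio
    is 10/3.3 by construction.
    """
    if fit.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    if sigma_source == "residual_sd":
        sigma = fit.residual_sd
    elif sigma_source == "intercept_sd":
        sigma = fit.intercept_sd
        if not np.isfinite(sigma):
            raise ValueError("fit carries no intercept SD")
    else:
        raise ValueError(f"unknown sigma_source {sigma_source!r}")
    lod = 3.3 * sigma / abs(fit.slope)
    loq = 10.0 * sigma / abs(fit.slope)
    return lod, loq


def standard_addition(
    base_response: float, added: Sequence[tuple[float, float]]
) -> float:
    """Estimate the original content from a standard-addition series.

    `added` holds (added concentration, signal) pairs for the spiked
    determinations; the unspiked sample contributes (0, base_response).  The
    estimate is the magnitude of the x-intercept of the regression of signal
    on added concentration, i.e. intercept/slope.
    """
    pts = [(0.0, float(base_response))] + [(float(c), float(s)) for c, s in added]
    if len(pts) < 3:
        raise ValueError("need the base point plus at least 2 addition levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = fit_line(x, y)
    if fit.slope <= 0:
        raise ValueError("standard-addition slope must be positive")
    return fit.intercept / fit.slope


# ---------------------------------------------------------------------------
# Summary-statistics method comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Mean recovery (%), spread and replicate count of one assay series.

    Either `sd` or `variance` may be given; the other is derived.  If both
    are given they must agree.
    """

    mean: float
    n: int
    sd: float | None = None
    variance: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd is None and self.variance is None:
            raise ValueError("give sd or variance")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.variance is not None and self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.sd is None:
            object.__setattr__(self, "sd", math.sqrt(self.variance))
        elif self.variance is None:
            object.__setattr__(self, "variance", self.sd**2)
        elif not math.isclose(self.variance, self.sd**2, rel_tol=0.15, abs_tol=1e-12):
            # generous: printed tables round sd and variance independently
            raise ValueError(
                f"sd {self.sd} and variance {self.variance} are inconsistent"
            )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    t_crit: float
    significant: bool


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_num: int
    df_den: int
    F_crit: float
    significant: bool


def pooled_t(a: SummaryStats, b: SummaryStats, alpha: float = 0.05) -> TTestResult:
    """Pooled-variance two-sample t test from summary statistics.

    sp^2 = ((n1-1)v1 + (n2-1)v2) / (n1+n2-2);
    t = |m1-m2| / (sp * sqrt(1/n1 + 1/n2)), df = n1+n2-2, compared to the
    two-tailed critical value at `alpha`.
    """
    df = a.n + b.n - 2
    if df < 1:
        raise ValueError("n1 + n2 must exceed 2")
    sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / df
    if sp2 == 0:
        raise ValueError("pooled variance is zero")
    t = abs(a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return TTestResult(t=t, df=df, t_crit=t_crit, significant=t > t_crit)


def f_test(a: SummaryStats, b: SummaryStats, alpha: float = 0.05) -> FTestResult:
    """Variance-ratio F test, oriented larger/smaller so F >= 1."""
    if a.variance <= 0 or b.variance <= 0:
        raise ValueError("both variances must be positive")
    if a.variance >= b.variance:
        num, den = a, b
    else:
        num, den = b, a
    F = num.variance / den.variance
    df_num, df_den = num.n - 1, den.n - 1
    F_crit = float(stats.f.ppf(1.0 - alpha, df_num, df_den))
    return FTestResult(
        F=F, df_num=df_num, df_den=df_den, F_crit=F_crit, significant=F > F_crit
    )
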