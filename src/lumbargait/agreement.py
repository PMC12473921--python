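"""Method-comparison statistics for paired per-subject gait parameters.

The battery mirrors standard practice for validating a new measurement
method against a reference:

* a paired location test, parametric (Student t) or non-parametric
  (Wilcoxon signed rank) depending on a Shapiro-Wilk normality test of
  the paired differences;
* Passing-Bablok regression, the nonparametric regression built from the
  shifted median of all pairwise slopes; a 95% confidence interval of the
  slope excluding 1 flags a proportional systematic error, and an
  intercept interval excluding 0 flags a constant systematic error;
* Bland-Altman analysis: bias (mean difference), its 95% confidence
  interval (z-based, bias +/- 1.96 sd / sqrt(n)) and the limits of
  agreement bias +/- 1.96 sd.

The overall verdict declares disagreement exactly when a proportional
systematic error is present; a constant-only error is reported as a flag
but -- when its magnitude is negligible for the use case -- does not by
itself overturn agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Literal

import numpy as np
from scipy import stats

from .errors import EstimationError

__all__ = [
    "PairedTestResult",
    "PBResult",
    "BAResult",
    "AgreementVerdict",
    "paired_test",
    "passing_bablok",
    "bland_altman",
    "ba_from_loa",
    "classify_agreement",
]


@dataclass(frozen=True)
class PairedTestResult:
    test_used: Literal["t_test", "wilcoxon"]
    statistic: float
    p_value: float
    significant: bool
    shapiro_p: float


@dataclass(frozen=True)
class PBResult:
    """Passing-Bablok slope/intercept with confidence intervals."""

    m: float
    q: float
    ci_m: tuple[float, float]
    ci_q: tuple[float, float]
    proportional_error: bool
    constant_error: bool
    n: int


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman bias, bias confidence interval and limits of agreement."""

    bias: float
    ci_bias: tuple[float, float]
    loa: tuple[float, float]
    n: int
    sd: float


@dataclass(frozen=True)
class AgreementVerdict:
    parameter: str
    level: Literal["agreement", "no_agreement"]
    error_type: Literal["none", "constant", "proportional", "both"]


def paired_test(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> PairedTestResult:
    """Normality-gated paired test on the differences a - b.

    Shapiro-Wilk at the same alpha decides the test: a paired t test when
    normality is not rejected, otherwise a Wilcoxon signed-rank test
    (zero differences dropped; normal approximation with continuity
    correction for more than 25 nonzero differences, exact otherwise).
    Two-tailed p values throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise EstimationError("need two equal-length vectors of length >= 3")
    d = a - b
    if np.ptp(d) == 0 and d[0] == 0:
        raise EstimationError("all differences are zero: no paired test defined")
    if np.ptp(d) == 0:
        # constant nonzero difference: Shapiro is undefined; the location
        # shift is unambiguous, report a degenerate t test
        raise EstimationError("differences are all identical: no test defined")
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = stats.ttest_rel(a, b)
        used = "t_test"
    else:
        nonzero = int(np.count_nonzero(d))
        method = "approx" if nonzero > 25 else "auto"
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=True, method=method
        )
        used = "wilcoxon"
    p = float(res.pvalue)
    return PairedTestResult(
        test_used=used,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
        shapiro_p=shapiro_p,
    )


def passing_bablok(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> PBResult:
    """Passing-Bablok regression of y on x.

    The slope is the shifted median of all pairwise slopes
    ``S_ij = (y_j - y_i) / (x_j - x_i)`` for ``i < j``; pairs with
    ``x_i == x_j`` are dropped and slopes exactly equal to -1 are
    excluded.  The shift ``K`` is the number of slopes below -1, which
    makes the estimator invariant to swapping the two methods.  The
    confidence interval uses the rank-based normal approximation with

        C = z_{(1+conf)/2} * sqrt(n (n-1) (2n+5) / 18).

    The intercept is ``median(y - m x)`` and its interval is evaluated at
    the slope interval endpoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EstimationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 10:
        raise EstimationError(f"Passing-Bablok needs n >= 10, got {n}")
    if np.ptp(x) == 0:
        raise EstimationError("x values are all equal")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    valid = dx != 0
    S = dy[valid] / dx[valid]
    S = S[S != -1.0]
    N = len(S)
    if N < 2:
        raise EstimationError("fewer than 2 finite pairwise slopes")
    S = np.sort(S)
    K = int(np.sum(S < -1.0))

    def _shifted_median(s: np.ndarray, k: int) -> float:
        m = len(s)
        if m % 2 == 1:
            return float(s[min((m - 1) // 2 + k, m - 1)])
        lo = min(m // 2 - 1 + k, m - 1)
        hi = min(m // 2 + k, m - 1)
        return float(0.5 * (s[lo] + s[hi]))

    m_hat = _shifted_median(S, K)

    z = stats.norm.ppf((1.0 + conf) / 2.0)
    C = z * sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - C) / 2.0))
    M2 = N - M1 + 1
    lo_idx = int(np.clip(M1 + K - 1, 0, N - 1))
    hi_idx = int(np.clip(M2 + K - 1, 0, N - 1))
    ci_m = (float(S[lo_idx]), float(S[hi_idx]))

    q = float(np.median(y - m_hat * x))
    q_at_hi = float(np.median(y - ci_m[1] * x))
    q_at_lo = float(np.median(y - ci_m[0] * x))
    ci_q = (min(q_at_hi, q_at_lo), max(q_at_hi, q_at_lo))

    return PBResult(
        m=m_hat,
        q=q,
        ci_m=ci_m,
        ci_q=ci_q,
        proportional_error=not (ci_m[0] <= 1.0 <= ci_m[1]),
        constant_error=not (ci_q[0] <= 0.0 <= ci_q[1]),
        n=n,
    )


def bland_altman(a: np.ndarray, b: np.ndarray) -> BAResult:
    """Bland-Altman analysis of the differences a - b.

    bias = mean(d); sd uses the n-1 denominator; limits of agreement are
    bias +/- 1.96 sd and the bias confidence interval is
    bias +/- 1.96 sd / sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EstimationError("need two equal-length vectors of length >= 2")
    d = a - b
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half_loa = 1.96 * sd
    half_ci = 1.96 * sd / sqrt(n)
    return BAResult(
        bias=bias,
        ci_bias=(bias - half_ci, bias + half_ci),
        loa=(bias - half_loa, bias + half_loa),
        n=n,
        sd=sd,
    )


def ba_from_loa(loa_lo: float, loa_hi: float, n: int) -> BAResult:
    """Reconstruct a Bland-Altman result from its limits of agreement.

    The limits determine the analysis completely: the bias is their
    midpoint, sd = (loa_hi - loa_lo) / (2 * 1.96), and the bias interval
    follows as bias +/- 1.96 sd / sqrt(n).  Useful for checking the
    internal consistency of reported agreement tables.
    """
    if loa_hi < loa_lo or n < 2:
        raise EstimationError("invalid limits of agreement")
    bias = 0.5 * (loa_lo + loa_hi)
    sd = (loa_hi - loa_lo) / (2.0 * 1.96)
    half_ci = 1.96 * sd / sqrt(n)
    return BAResult(
        bias=bias,
        ci_bias=(bias - half_ci, bias + half_ci),
        loa=(loa_lo, loa_hi),
        n=n,
        sd=sd,
    )


def classify_agreement(
    pb: PBResult,
    ba: BAResult,
    paired: PairedTestResult | None = None,
    parameter: str = "",
) -> AgreementVerdict:
    """Combine the battery into an agreement verdict.

    A proportional systematic error (slope interval excluding 1) implies
    disagreement.  A constant systematic error is flagged when either the
    Passing-Bablok intercept interval excludes 0 or the Bland-Altman bias
    interval excludes 0; on its own it does not overturn agreement.
    """
    proportional = pb.proportional_error
    ba_constant = not (ba.ci_bias[0] <= 0.0 <= ba.ci_bias[1])
    constant = pb.constant_error or ba_constant
    if proportional and constant:
        error_type = "both"
    elif proportional:
        error_type = "proportional"
    elif constant:
        error_type = "constant"
    else:
        error_type = "none"
    return AgreementVerdict(
        parameter=parameter,
        level="no_agreement" if proportional else "agreement",
        error_type=error_type,
    )
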