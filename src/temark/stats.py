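"""Statistical primitives shared by every analysis stage.

All functions here are pure and seed-free: Poisson presence thresholds for
promoter peak calling, the goodness-of-fit G-test, Pearson/Spearman
correlation with t-distribution p-values, the pooled two-sample t-test, a
Q-Q-correlation normality heuristic, and Bonferroni correction.

The G-test statistic is the log-likelihood ratio

    G = 2 * sum_i o_i * ln(o_i / e_i)

over categories with observed counts ``o`` and expected counts ``e``
(``0 * ln 0 = 0``), referred to a chi-square distribution with
``k - 1`` degrees of freedom.  Correlation p-values use the classical
approximation ``t = c * sqrt((n - 2) / (1 - c^2))`` with ``n - 2`` degrees
of freedom, for both Pearson's r and Spearman's rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GTestResult",
    "CorrelationResult",
    "NormalityResult",
    "bonferroni",
    "poisson_presence_threshold",
    "g_test",
    "correlate",
    "two_sample_t",
    "normality_check",
]


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    t: float
    p: float
    method: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class NormalityResult:
    """Outcome of the Q-Q correlation check.

    ``theoretical`` and ``sample`` are the Q-Q point pairs (standard-normal
    quantiles vs. sorted data) for optional plotting.
    """

    is_normal: bool
    r: float
    theoretical: np.ndarray
    sample: np.ndarray

    def __bool__(self) -> bool:
        return self.is_normal


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test level ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def poisson_presence_threshold(lambda_bg: float, alpha: float, n_tests: int = 1) -> int:
    """Smallest count k with P(X >= k | Poisson(lambda_bg)) < alpha / n_tests.

    Used to convert a promoter tag count into a presence/absence call against
    a genomic background rate; the strict inequality makes the call
    conservative, and Bonferroni correction enters through ``n_tests``.
    """
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    level = bonferroni(alpha, n_tests)
    # P(X >= 0) = 1 >= level always, so k >= 1.
    k = max(1, int(sps.poisson.ppf(1 - level, lambda_bg)))
    while sps.poisson.sf(k - 1, lambda_bg) >= level:
        k += 1
    while k > 1 and sps.poisson.sf(k - 2, lambda_bg) < level:
        k -= 1
    return k


def g_test(observed, expected, rtol: float = 1e-6) -> GTestResult:
    """Goodness-of-fit G-test of observed against expected counts."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1:
        raise ValueError("observed and expected must be 1-D arrays of equal length")
    if len(o) < 2:
        raise ValueError("need at least two categories")
    if np.any(o < 0):
        raise ValueError("observed counts must be non-negative")
    if np.any(e <= 0):
        raise ValueError("expected counts must be strictly positive")
    if abs(o.sum() - e.sum()) > rtol * max(1.0, e.sum()):
        raise ValueError("observed and expected totals differ beyond tolerance")
    nz = o > 0
    G = 2.0 * float(np.sum(o[nz] * np.log(o[nz] / e[nz])))
    G = max(G, 0.0)
    df = len(o) - 1
    p = float(sps.chi2.sf(G, df))
    return GTestResult(G=G, df=df, p=p)


def _corr_t_p(c: float, n: int) -> tuple[float, float]:
    if abs(c) >= 1.0 - 1e-15:
        return float(np.sign(c)) * np.inf, 0.0
    t = c * np.sqrt((n - 2) / (1.0 - c * c))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return float(t), p


def correlate(x, y, method: str = "auto", normality_cutoff: float = 0.99) -> CorrelationResult:
    """Pearson or Spearman correlation with a t-approximation p-value.

    ``method="auto"`` applies :func:`normality_check` to both vectors and
    uses Pearson only when both pass (falling back to Spearman when either
    fails or when n is too small for the check).  Spearman uses average
    ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "auto":
        if n >= 10 and normality_check(x, cutoff=normality_cutoff).is_normal and \
                normality_check(y, cutoff=normality_cutoff).is_normal:
            method = "pearson"
        else:
            method = "spearman"
    if method == "spearman":
        xv = sps.rankdata(x)
        yv = sps.rankdata(y)
    elif method == "pearson":
        xv, yv = x, y
    else:
        raise ValueError(f"unknown method {method!r}")
    c = float(np.corrcoef(xv, yv)[0, 1])
    c = min(1.0, max(-1.0, c))
    if abs(c) > 1.0 - 1e-12:  # snap exact monotone agreement lost to rounding
        c = float(np.sign(c))
    t, p = _corr_t_p(c, n)
    return CorrelationResult(coefficient=c, n=n, t=t, p=p, method=method)


def two_sample_t(a, b) -> tuple[float, float]:
    """Classical pooled-variance (Student's) two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def normality_check(x, cutoff: float = 0.99) -> NormalityResult:
    """Q-Q correlation heuristic standing in for a visual Q-Q plot check.

    Sorted data are paired with standard-normal quantiles at plotting
    positions (i + 0.5)/n; the sample is deemed normal when the Pearson
    correlation of the Q-Q points reaches ``cutoff``.  Invariant under
    affine transforms of the data.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need n >= 10 for the normality check")
    sample = np.sort(x)
    theoretical = sps.norm.ppf((np.arange(n) + 0.5) / n)
    if np.ptp(sample) == 0:
        return NormalityResult(False, 0.0, theoretical, sample)
    r = float(np.corrcoef(theoretical, sample)[0, 1])
    return NormalityResult(bool(r >= cutoff), r, theoretical, sample)
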