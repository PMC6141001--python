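"""Statistical primitives used throughout the pipeline.

Thin, opinionated wrappers around :mod:`scipy.stats` that (a) return a
uniform :class:`TestResult` record, (b) flag degenerate inputs (zero
variance, empty groups) instead of propagating NaNs, and (c) pin down the
exact conventions used: one- vs two-tailed t tests, exact vs asymptotic
Mann-Whitney, and the exact two-sided binomial test against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "unpaired_t",
    "mann_whitney",
    "binomial_vs_half",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (t, U, or k depending on the test).
    p : float
        p value in [0, 1].
    n : int
        Total number of observations used.
    test_name : str
        Identifier of the test performed.
    tails : int
        1 or 2.
    degenerate : bool
        True when the input had zero variance (or another degeneracy) and
        the statistic/p are conventions rather than sampling results.
    """

    statistic: float
    p: float
    n: int
    test_name: str
    tails: int
    degenerate: bool = False


def one_sample_t(
    values, tails: int = 2, direction: str = "less"
) -> TestResult:
    """One-sample t test of ``mean(values) == 0``.

    Parameters
    ----------
    values : array-like
        Sample, n >= 2.
    tails : int
        2 for a two-tailed test, 1 for one-tailed.
    direction : {"less", "greater"}
        Alternative hypothesis direction when ``tails == 1``.

    For a zero-variance sample the result is flagged degenerate: an
    all-zero sample yields t = 0 with p = 0.5 (one-tailed) or 1.0
    (two-tailed); a constant non-zero sample yields an infinite statistic
    with p = 0 or 1 according to the direction of the constant.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatisticsError(f"one-sample t needs n >= 2, got n={x.size}")
    if tails not in (1, 2):
        raise StatisticsError("tails must be 1 or 2")
    name = "one_sample_t"
    if np.ptp(x) == 0.0:
        m = x[0]
        if m == 0.0:
            p = 0.5 if tails == 1 else 1.0
            return TestResult(0.0, p, x.size, name, tails, degenerate=True)
        t = np.inf * np.sign(m)
        if tails == 2:
            p = 0.0
        else:
            want_neg = direction == "less"
            p = 0.0 if (m < 0) == want_neg else 1.0
        return TestResult(float(t), p, x.size, name, tails, degenerate=True)
    if tails == 2:
        res = sps.ttest_1samp(x, 0.0)
    else:
        res = sps.ttest_1samp(x, 0.0, alternative=direction)
    return TestResult(
        float(res.statistic), float(res.pvalue), x.size, name, tails
    )


def paired_t(a, b) -> TestResult:
    """Two-tailed paired t test (equivalent to one-sample t on a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatisticsError("paired samples must have equal length")
    res = one_sample_t(a - b, tails=2)
    return TestResult(
        res.statistic, res.p, a.size, "paired_t", 2, res.degenerate
    )


def unpaired_t(a, b) -> TestResult:
    """Two-tailed unpaired (two-sample, pooled-variance) t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("unpaired t needs n >= 2 per group")
    n = a.size + b.size
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return TestResult(0.0, 1.0, n, "unpaired_t", 2, degenerate=True)
    res = sps.ttest_ind(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), n, "unpaired_t", 2)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when ``min(n_a, n_b) <= 8`` and the pooled
    sample is tie-free; otherwise the normal approximation with average
    ranks, tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticsError("mann_whitney needs non-empty samples")
    n = a.size + b.size
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return TestResult(
            a.size * b.size / 2.0, 1.0, n, "mann_whitney", 2, degenerate=True
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), n, "mann_whitney", 2)


def binomial_vs_half(k: int, n: int) -> TestResult:
    """Exact two-sided binomial test of ``k`` successes in ``n`` vs p = 0.5.

    Two-sided p is the sum of outcome probabilities no larger than that of
    the observed count (the minlike convention).
    """
    if not (0 <= k <= n) or n < 1:
        raise StatisticsError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    res = sps.binomtest(int(k), int(n), p=0.5)
    return TestResult(float(k), float(res.pvalue), int(n), "binomial_vs_half", 2)
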