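"""Order-0/1 distributional rhythm metrics.

All functions accept NaN-masked vectors; NaNs are treated as missing
values and never contribute to a statistic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from speechtiming.series import IniSeries

__all__ = [
    "MetricError",
    "npvi",
    "ks_normality_d",
    "dagostino_pearson",
    "spearman",
]

#: Minimum sample size for the D'Agostino–Pearson omnibus test.
NORMALITY_TEST_MIN_N = 8


class MetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


def npvi(d: IniSeries | np.ndarray) -> float:
    """Normalized pairwise variability index over interval durations.

    100/m · Σ |d_t − d_{t+1}| / (0.5·(d_t + d_{t+1})), summed over the m
    adjacent pairs in which both durations are present (pairs spanning a
    masked interval are dropped, so the denominator counts valid pairs
    rather than n − 1).  Identical durations give 0; strongly
    alternating short/long patterns approach 200 in theory, ~100 in
    practice for speech-like variability.
    """
    x = d.d if isinstance(d, IniSeries) else np.asarray(d, dtype=float)
    if len(x) < 2:
        raise MetricError("nPVI needs at least 2 intervals")
    a, b = x[:-1], x[1:]
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        raise MetricError("nPVI undefined: no adjacent pair of present intervals")
    a, b = a[valid], b[valid]
    terms = np.abs(a - b) / (0.5 * (a + b))
    return float(100.0 * terms.mean())


def ks_normality_d(x: np.ndarray) -> float:
    """Kolmogorov–Smirnov D between the empirical distribution of ``x``
    and a normal distribution with the same mean and standard deviation.

    Both one-sided ECDF limits are evaluated at every sample point.  The
    statistic is used descriptively (no p-value, no small-sample
    correction); sample sd uses ddof=1.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise MetricError(f"KS D needs >= 3 present values, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise MetricError("KS D undefined for zero-variance input")
    xs = np.sort(x)
    cdf = stats.norm.cdf(xs, loc=float(np.mean(x)), scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def dagostino_pearson(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test (K² statistic and
    two-sided p-value), combining skewness and kurtosis z-scores."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < NORMALITY_TEST_MIN_N:
        raise MetricError(
            f"normality test needs >= {NORMALITY_TEST_MIN_N} present values, "
            f"got {len(x)}"
        )
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling
    (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MetricError("x and y must have equal length")
    if len(x) < 3:
        raise MetricError("Spearman correlation needs >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise MetricError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
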