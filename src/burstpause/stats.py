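"""Inferential statistics and the crawling stride-speed metric.

These are thin, convention-pinning wrappers around scipy/statsmodels: tie
handling uses average ranks, rank-sum means the Mann-Whitney U statistic,
signed-rank excludes zero differences, Fisher's test is two-tailed, and
the binomial interval is the exact Clopper-Pearson one. For very small
samples the Spearman p-value is computed by exhaustive permutation.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "spearman",
    "rank_tests",
    "fisher_exact",
    "bonferroni",
    "clopper_pearson",
    "max_stride_speed",
]


def _check_not_constant(v: np.ndarray, name: str) -> None:
    if np.all(v == v[0]):
        raise ValueError(f"{name} is constant; rank correlation undefined")


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling.

    For ``n <= exact_max_n`` the two-sided p-value is computed by
    enumerating all permutations of ``y`` (exact under the null of
    exchangeability); otherwise scipy's large-sample approximation is
    used. Constant input is an error (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    _check_not_constant(x, "x")
    _check_not_constant(y, "y")
    rho, p = sstats.spearmanr(x, y)
    n = x.size
    if n <= exact_max_n:
        rx = sstats.rankdata(x)
        ry = sstats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def rank_tests(x, y, paired: bool = False) -> float:
    """Two-sided rank test p-value.

    Unpaired: Wilcoxon rank-sum (Mann-Whitney U, exact for small tie-free
    samples). Paired: Wilcoxon signed-rank with zero differences excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        return float(sstats.wilcoxon(x, y, zero_method="wilcox").pvalue)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        raise ValueError("all observations tied across both samples")
    return float(sstats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def fisher_exact(table) -> float:
    """Two-tailed Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    return float(sstats.fisher_exact(t, alternative="two-sided")[1])


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def clopper_pearson(
    k: int, n: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Exact binomial proportion and confidence interval, as percentages.

    Returns ``(100*k/n, (lo, hi))`` with the Clopper-Pearson (beta
    quantile) interval at confidence ``1 - alpha``.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must be within [0, n]")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return 100.0 * k / n, (100.0 * float(lo), 100.0 * float(hi))


def max_stride_speed(
    t, xy, event_time: float, window: float = 5.0, smooth: int = 1
) -> tuple[float, float]:
    """Maximum crawling speed before and after an activation event (mm/s).

    Speeds are frame-to-frame displacements over frame intervals; the
    maxima are taken over ``[event - window, event)`` and
    ``(event, event + window]``. ``smooth > 1`` applies a moving average
    over that many speed samples first. The track must cover both windows.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if t.size != xy.shape[0]:
        raise ValueError("one position per timestamp required")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if t[0] > event_time - window + 1e-9 or t[-1] < event_time + window - 1e-9:
        raise ValueError("track does not cover both analysis windows")
    dt = np.diff(t)
    speed = np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        speed = np.convolve(speed, kernel, mode="same")
    mid = 0.5 * (t[:-1] + t[1:])
    pre = speed[(mid >= event_time - window) & (mid < event_time)]
    post = speed[(mid > event_time) & (mid <= event_time + window)]
    pre_max = float(pre.max()) if pre.size else math.nan
    post_max = float(post.max()) if post.size else math.nan
    return pre_max, post_max
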