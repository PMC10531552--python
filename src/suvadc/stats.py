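"""Correlation, regression and paired-test statistics.

All statistics are computed from the defining formulas so tests can check
them against independent brute-force oracles.  The Wilcoxon signed-rank test
drops zero differences (classical convention, not Pratt), uses midranks for
ties, and switches from exact sign-pattern enumeration to a tie- and
continuity-corrected normal approximation above n = 15 effective pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

#: largest effective n for which the exact Wilcoxon null is enumerated (2^n patterns)
WILCOXON_EXACT_N = 15


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx**2))
    sy = np.sqrt(np.sum(dy**2))
    if sx == 0 or sy == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.sum(dx * dy) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def point_biserial(binary, continuous) -> tuple[float, float]:
    """Pearson correlation between a two-level variable (coded 0/1) and a continuous one."""
    b = np.asarray(binary)
    levels = np.unique(b)
    if levels.size != 2:
        raise ValueError(f"binary variable must have exactly 2 levels, got {levels.size}")
    coded = (b == levels[1]).astype(float)  # higher level coded 1
    return pearson(coded, continuous)


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    dx = x - x.mean()
    sxx = float(np.sum(dx**2))
    if sxx == 0:
        raise ValueError("constant x: regression undefined")
    slope = float(np.sum(dx * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return slope, intercept, 1.0
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, intercept, r2


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by full enumeration of all 2^n sign patterns.

    p = P(W+ <= w_lo) + P(W+ >= T - w_lo) under the symmetric null, where
    w_lo = min(W+, W-) and T is the total rank sum.
    """
    n = ranks.size
    total = float(ranks.sum())
    w_lo = min(w_plus, total - w_plus)
    patterns = np.arange(2**n, dtype=np.uint32)
    bits = (patterns[:, None] >> np.arange(n)) & 1  # (2^n, n)
    w_dist = bits @ ranks
    tol = 1e-9
    count = np.sum(w_dist <= w_lo + tol) + np.sum(w_dist >= total - w_lo - tol)
    return min(1.0, float(count) / 2**n)


def _wilcoxon_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    # continuity correction shrinks |diff| by 0.5
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return min(1.0, float(2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(pre, post) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W, two-sided p).

    Zero differences are dropped; W = min(W+, W-).  Exact enumeration for
    effective n <= 15, normal approximation beyond.  All-zero differences
    give W = 0, p = 1 with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    if pre.size < 1:
        raise ValueError("need at least one pair")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if d.size <= WILCOXON_EXACT_N:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        p = _wilcoxon_normal_p(ranks, w_plus)
    return w, p
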