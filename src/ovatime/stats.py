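"""Small-sample statistical tests shared across the pipeline.

The paired t-test and the one-sided exact Wilcoxon signed-rank test are
coded from their closed forms so their small-n behaviour is auditable;
everything else (Welch t, exact binomial, large-sample Spearman) delegates
to scipy.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "paired_t",
    "wilcoxon_signed_rank_less",
    "poisson_upper_tail",
    "fisher_combine",
    "binomial_two_sided",
    "welch_t",
    "spearman",
]


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on differences ``a - b``.

    Returns ``(t, p)``; ``t = mean(d) / (sd(d)/sqrt(n))`` with ``n-1`` df.
    With zero difference variance, t is 0 when the mean difference is 0
    (p = 1) and infinite otherwise (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal-length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if d.mean() == 0.0 else (math.inf * np.sign(d.mean()), 0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(min(p, 1.0))


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (rank sum of positive differences, midranks for tied |d|) and the ranks."""
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def wilcoxon_signed_rank_less(values: Sequence[float], mu: float = 0.0) -> tuple[float, int]:
    """One-sided Wilcoxon signed-rank p for the alternative "shifted below mu".

    Zeros (values exactly equal to ``mu``) are dropped (Wilcoxon's
    zero-handling), so the returned effective n may be smaller than the
    input.  For effective n <= 25 the null distribution of W+ is computed
    exactly, conditional on the observed midranks, via a generating-function
    convolution over doubled ranks — this matches full enumeration of the
    2^n sign assignments even when tied |differences| yield fractional
    midranks.  Above 25 the normal approximation with tie correction and
    continuity correction is used.

    Returns ``(p, effective_n)``; with no non-zero differences, p = 1 and
    effective n = 0.
    """
    diffs = np.asarray(values, dtype=float) - mu
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return 1.0, 0
    w_plus, ranks = _signed_rank_statistic(diffs)
    if n <= 25:
        # Doubling makes midranks integral; count sign assignments by W+.
        doubled = np.rint(2 * ranks).astype(int)
        total = doubled.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        target = int(round(2 * w_plus))
        p = counts[: target + 1].sum() / counts.sum()
        return float(p), n
    mean = n * (n + 1) / 4.0
    # Tie correction for midranks: Var = sum(ranks^2)/4.
    var = float((ranks**2).sum()) / 4.0
    z = (w_plus - mean + 0.5) / math.sqrt(var)
    return float(sps.norm.cdf(z)), n


def poisson_upper_tail(observed: int, mean: float) -> float:
    """P(X >= observed) for X ~ Poisson(mean); 1 when observed is 0."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if observed == 0:
        return 1.0
    return float(sps.poisson.sf(observed - 1, mean))


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's combined probability: -2 Σ ln p ~ χ² with 2k df."""
    ps = [float(p) for p in pvalues]
    if not ps:
        raise ValueError("no p-values to combine")
    if any(not 0.0 < p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * sum(math.log(p) for p in ps)
    return float(sps.chi2.sf(stat, df=2 * len(ps)))


def binomial_two_sided(successes: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p (minimum-likelihood method)."""
    if n <= 0:
        raise ValueError("binomial test undefined for n = 0")
    return float(sps.binomtest(successes, n, p0, alternative="two-sided").pvalue)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each cohort needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-value is exact (full permutation enumeration of rank orderings) for
    n <= 9, else the standard large-sample t approximation from scipy.
    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(_rank_corr(rx, ry))
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs - 1e-12:
                hits += 1
        return rho, hits / total
    return rho, float(sps.spearmanr(x, y).pvalue)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum() / denom)
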