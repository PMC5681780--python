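"""Statistical primitives shared across the pipeline.

The exact binomial test under the balanced null is evaluated in closed form:
with X ~ Binomial(n, 1/2) the probability mass is symmetric and unimodal, so
the two-sided p-value (sum of outcomes no more likely than the observed k)
is ``min(1, 2 * P(X <= min(k, n - k)))``. This vectorises over the hundreds
of thousands of (site, cell) tests of a typical run.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def binom_test_two_sided(k, n):
    """Exact two-sided binomial p-value(s) under the null p=0.5.

    Accepts scalars or arrays; n must be >= 1 everywhere (uncovered sites
    must not be tested).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n < 1):
        raise ValueError("binomial test requires n >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("k must satisfy 0 <= k <= n")
    m = np.minimum(k, n - k)
    p = 2.0 * sps.binom.cdf(m, n, 0.5)
    return np.minimum(p, 1.0) if p.ndim else float(min(p, 1.0))


def binom_test_one_sided(k, n):
    """P(X >= max(k, n-k)) under the null: one-sided toward the majority allele."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n < 1):
        raise ValueError("binomial test requires n >= 1")
    hi = np.maximum(k, n - k)
    p = sps.binom.sf(hi - 1, n, 0.5)
    return p if p.ndim else float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def rank_sum_test(a, b, alternative: str):
    """One- or two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when both samples have <= 25 observations and
    the pooled values are tie-free; otherwise the normal approximation with
    tie correction. No continuity correction is applied, so two identical
    samples give a one-sided p of exactly 0.5.

    Returns (median_a, median_b, U statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= 25 and b.size <= 25 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return float(np.median(a)), float(np.median(b)), float(res.statistic), float(res.pvalue)
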