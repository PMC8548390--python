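"""Independent brute-force reference implementations used only by the tests.

Each function here re-derives a statistic from first principles (closed
forms, exhaustive enumeration, O(n^3) clustering) so the package's
scipy/statsmodels-backed operations can be checked against a second route.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats


def pooled_t_closed_form(a, b):
    """Student two-sample t from the textbook pooled-variance formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_step_up(p_values):
    """Benjamini-Hochberg by direct definition: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail(k, N, K, n) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) by combinatorial enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


def upgma_merge_heights(x):
    """O(n^3) UPGMA on Euclidean distances; returns sorted merge heights.

    Average linkage between clusters is the arithmetic mean of all original
    pairwise leaf distances across the two clusters.
    """
    x = np.asarray(x, float)
    n = x.shape[0]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best[0] - 1e-15:
                    best = (avg, i, j)
        avg, i, j = best
        heights.append(avg)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)
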