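"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they verify: exact test p-values by
exhaustive enumeration of rank assignments, hypergeometric tails by direct
binomial-coefficient summation, relative entropy by an explicit python loop.
"""

import math
from itertools import combinations


def ks_statistic(x_sorted, y_sorted):
    """sup_t |ECDF_x(t) - ECDF_y(t)| by merging the two sorted samples."""
    n, m = len(x_sorted), len(y_sorted)
    values = sorted(set(x_sorted) | set(y_sorted))
    d = 0.0
    for t in values:
        fx = sum(1 for v in x_sorted if v <= t) / n
        fy = sum(1 for v in y_sorted if v <= t) / m
        d = max(d, abs(fx - fy))
    return d


def ks_exact_p_enumeration(x, y):
    """P(D >= observed D) over all equally likely splits of the pooled sample.

    Assumes no ties between (or within) the samples.
    """
    x, y = sorted(x), sorted(y)
    n, m = len(x), len(y)
    d_obs = ks_statistic(x, y)
    pooled = sorted(x + y)
    total = 0
    hits = 0
    for x_positions in combinations(range(n + m), n):
        xs = [pooled[i] for i in x_positions]
        ys = [pooled[i] for i in range(n + m) if i not in set(x_positions)]
        total += 1
        if ks_statistic(xs, ys) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


def mw_exact_p_enumeration(x, y):
    """Exact two-sided Mann-Whitney p: 2 * min tail of the enumerated U law."""
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    counts = {}
    total = 0
    for x_positions in combinations(range(n + m), n):
        xset = set(x_positions)
        u = sum(sum(1 for j in range(i) if j not in xset) for i in x_positions)
        counts[u] = counts.get(u, 0) + 1
        total += 1
    cdf = sum(c for u, c in counts.items() if u <= u_obs) / total
    sf = sum(c for u, c in counts.items() if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


def hypergeom_tail(k, total, annotated, drawn):
    """P(X >= k) for X ~ Hypergeom(total, annotated, drawn), via math.comb."""
    denom = math.comb(total, drawn)
    upper = min(drawn, annotated)
    acc = 0
    for j in range(max(k, max(0, drawn + annotated - total)), upper + 1):
        acc += math.comb(annotated, j) * math.comb(total - annotated, drawn - j)
    return acc / denom


def relative_entropy_loop(p, q):
    """Direct term-by-term summation with the 0 * log 0 = 0 convention."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total
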