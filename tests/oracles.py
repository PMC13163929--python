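"""Independent brute-force oracles used to cross-check the implementations.

Each oracle recomputes a statistic by direct enumeration or a hand-rolled
definition, sharing no code path with the package.
"""

from itertools import combinations, permutations

import numpy as np
from scipy.special import comb
from scipy.stats import hypergeom, rankdata


def ranksum_exact_p(a, b):
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Requires tie-free data.  Enumerates every way the pooled observations
    could split between the groups, computes the U statistic of the first
    group for each, and sums the probability of assignments at least as
    extreme in either tail (the null distribution of U is symmetric).
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    m = n1 * n2
    lo_tail, hi_tail = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if u <= lo_tail + 1e-9 or u >= hi_tail - 1e-9:
            hits += 1
    return hits / total


def bh_stepup(p_values):
    """Hand step-up Benjamini-Hochberg: p(i)*n/i then cumulative minimum."""
    p = list(p_values)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def fisher_twosided_p(k1, n1, k2, n2):
    """Two-sided Fisher p by summing hypergeometric point masses.

    Conditions on the margins: total positives K = k1 + k2 drawn from n1 of
    n1 + n2; every table with P(table) <= P(observed) contributes.
    """
    K = k1 + k2
    N = n1 + n2
    rv = hypergeom(N, K, n1)
    support = range(max(0, K - n2), min(K, n1) + 1)
    p_obs = rv.pmf(k1)
    return float(sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9)))


def kw_h(groups):
    """Kruskal-Wallis H with tie correction, computed from first principles."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    i = 0
    for g in groups:
        sz = len(g)
        r = ranks[i:i + sz].sum()
        h += r * r / sz
        i += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / tie if tie < 1 else h


def kw_permutation_p(groups):
    """Exact permutation p for Kruskal-Wallis by enumerating orderings."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    h_obs = kw_h(groups)
    hits = total = 0
    for perm in permutations(pooled):
        parts, i = [], 0
        for sz in sizes:
            parts.append(np.array(perm[i:i + sz]))
            i += sz
        total += 1
        if kw_h(parts) >= h_obs - 1e-9:
            hits += 1
    return hits / total


def cluster_transitive_closure(positions, max_gap):
    """All-pairs transitive closure clustering (union-find) of positions.

    Returns clusters as sorted tuples of indices; two probes join directly
    when |pos_i - pos_j| <= max_gap.
    """
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(tuple(sorted(c)) for c in clusters.values())


def binom_tail_ci(k, n, level=0.95, tol=1e-10):
    """Clopper-Pearson bounds by direct inversion of binomial tails.

    Bisects on p: the lower bound solves P(X >= k | p) = alpha/2, the upper
    bound solves P(X <= k | p) = alpha/2, using only binomial pmf sums.
    """
    from scipy.stats import binom

    alpha = 1 - level

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 0.0, 1.0)
    upper = 1.0 if k == n else bisect(
        lambda p: alpha / 2 - binom.cdf(k, n, p), 0.0, 1.0)
    return lower, upper
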