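"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: window enumeration for
run calling, direct rank arithmetic for the Friedman statistic, exhaustive
sign-flip enumeration for the signed-rank test, and naive all-pairs UPGMA
cophenetic heights.
"""

import itertools

import numpy as np


def brute_force_runs(directions, chromosomes, min_run=2):
    """All maximal same-direction windows of length >= min_run.

    ``directions`` is a list of 'hyper'/'hypo'/'none' per probe in manifest
    order, ``chromosomes`` the matching chromosome labels.  Returns a set of
    (chromosome, start_index, end_index_inclusive, direction) by checking
    every contiguous window for homogeneity and maximality.
    """
    n = len(directions)
    out = set()
    for i in range(n):
        for j in range(i + min_run - 1, n):
            window = directions[i:j + 1]
            chroms = set(chromosomes[i:j + 1])
            if len(chroms) != 1:
                continue
            d = window[0]
            if d == "none" or any(w != d for w in window):
                continue
            left_ok = (i == 0 or chromosomes[i - 1] != chromosomes[i]
                       or directions[i - 1] != d)
            right_ok = (j == n - 1 or chromosomes[j + 1] != chromosomes[j]
                        or directions[j + 1] != d)
            if left_ok and right_ok:
                out.add((chromosomes[i], i, j, d))
    return out


def friedman_by_ranks(values):
    """Friedman chi-square from first principles on an n x k block table."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.empty_like(values)
    for b in range(n):
        row = values[b]
        order = np.argsort(row, kind="mergesort")
        r = np.empty(k)
        i = 0
        while i < k:
            j = i
            while j + 1 < k and row[order[j + 1]] == row[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average rank for ties
            i = j + 1
        ranks[b] = r
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * (np.sum(col_sums ** 2) - n ** 2 * k * (k + 1) ** 2 / 4)
    denom = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4
    return 0.0 if denom == 0 else numer / denom, ranks


def signed_rank_exact_p(diffs, alternative="two-sided"):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = np.empty(n)
    order = np.argsort(np.abs(d), kind="mergesort")
    a = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    stats = []
    for signs in itertools.product([1, -1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s > 0))
    stats = np.array(stats)
    if alternative == "greater":
        return float(np.mean(stats >= w_plus))
    if alternative == "less":
        return float(np.mean(stats <= w_plus))
    one = min(np.mean(stats >= w_plus), np.mean(stats <= w_plus))
    return float(min(1.0, 2 * one))


def upgma_cophenetic(D):
    """Cophenetic distance matrix by naive all-pairs UPGMA agglomeration."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def mean_dist(a, b):
        return np.mean([D[i, j] for i in a for j in b])

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = mean_dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                coph[i, j] = coph[j, i] = d
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return coph


def hypergeom_upper_tail(overlap, universe, set_size, draw_size):
    """P(X >= overlap) by direct summation of hypergeometric masses."""
    from math import comb
    total = comb(universe, draw_size)
    p = 0.0
    for x in range(overlap, min(set_size, draw_size) + 1):
        if universe - set_size >= draw_size - x:
            p += comb(set_size, x) * comb(universe - set_size,
                                          draw_size - x) / total
    return p
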