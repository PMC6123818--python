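"""Independent brute-force oracles used to validate the fast implementations.

Deliberately naive: explicit sorting-based ranks, closed-form Pearson sums,
full permutation enumeration, and pair-counting Mann-Whitney. None of these
share code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_ranks(x) -> list[float]:
    """Average ranks computed by explicit sorting and tie grouping."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Spearman rho as Pearson correlation of brute-force ranks."""
    rx, ry = brute_ranks(x), brute_ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def upper_triangle_absdiff(r) -> list[float]:
    """Upper triangle of the |r_i - r_j| matrix, row-major."""
    n = len(r)
    return [abs(r[i] - r[j]) for i in range(n) for j in range(i + 1, n)]


def enumerate_permutation_p(responses, layer_upper, alpha_ignored=None) -> float:
    """Exact one-sided permutation p over all n! reshuffles of the responses.

    Matches the plus-one Monte-Carlo convention applied to the full
    enumeration: p = #{perm : rho_perm >= rho_obs} / n!, where the identity
    permutation is part of the enumeration (so p is never 0).
    """
    responses = list(responses)
    obs = brute_spearman(upper_triangle_absdiff(responses), layer_upper)
    n_ge = 0
    total = 0
    for perm in itertools.permutations(responses):
        rho = brute_spearman(upper_triangle_absdiff(perm), layer_upper)
        if rho >= obs - 1e-12:
            n_ge += 1
        total += 1
    return n_ge / total


def brute_mannwhitney_u(x, y) -> float:
    """U statistic for 'x tends to exceed y' by direct pair counting."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1
            elif a == b:
                u += 0.5
    return u


def exact_mannwhitney_p_greater(x, y) -> float:
    """Exact one-sided p for U by enumerating all group assignments."""
    x, y = list(x), list(y)
    obs = brute_mannwhitney_u(x, y)
    pooled = x + y
    n_ge = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), len(x)):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        if brute_mannwhitney_u(xs, ys) >= obs - 1e-12:
            n_ge += 1
        total += 1
    return n_ge / total


def monte_carlo_se(p: float, n: int) -> float:
    """Standard error of a Monte-Carlo p estimate from n draws."""
    return math.sqrt(max(p * (1 - p), 1e-12) / n)
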