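"""Independent brute-force oracles for rank statistics.

These deliberately avoid the library's code paths (and scipy's): tau and
U are computed by explicit O(n^2) pair enumeration, and the exact
Mann-Whitney null by enumerating all group labelings.
"""

from itertools import combinations
from math import sqrt


def kendall_pair_counts(x, y):
    """Classify all unordered pairs: concordant, discordant, tied-x-only,
    tied-y-only, tied-both."""
    conc = disc = tx = ty = txy = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = 1 if x[i] > x[j] else (-1 if x[i] < x[j] else 0)
            dy = 1 if y[i] > y[j] else (-1 if y[i] < y[j] else 0)
            if dx == 0 and dy == 0:
                txy += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    return conc, disc, tx, ty, txy


def kendall_tau_b(x, y):
    """Tie-corrected Kendall tau from pair counts."""
    conc, disc, tx, ty, txy = kendall_pair_counts(x, y)
    n0 = len(x) * (len(x) - 1) // 2
    denom = sqrt((n0 - tx - txy) * (n0 - ty - txy))
    return (conc - disc) / denom


def mann_whitney_u(a, b):
    """U of the first sample: #{a_i > b_j} plus half-credit for ties."""
    u = 0.0
    for ai in a:
        for bj in b:
            if ai > bj:
                u += 1.0
            elif ai == bj:
                u += 0.5
    return u


def mann_whitney_exact_p(a, b):
    """Exact two-sided p by enumerating all C(n1+n2, n1) group labelings.

    Two-sided as twice the smaller tail (capped at 1), matching the
    convention for the exact test on tie-free data.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mann_whitney_u(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        us.append(mann_whitney_u(ga, gb))
    n_total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / n_total
    hi = sum(1 for u in us if u >= u_obs) / n_total
    return min(1.0, 2 * min(lo, hi))
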