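"""Independent reference implementations used as oracles in tests.

These deliberately use slow, explicit per-element loops and a from-scratch
hypergeometric enumeration so they share no code path with the package.
"""

import math

import numpy as np


def naive_pair_likelihood(oral_col, gut_col, f_oral, f_gut):
    """Per-allele loop evaluation of (L_obs, L_min, P_raw) for one pair."""
    L_obs = 0.0
    L_min = 0.0
    for i in range(len(oral_col)):
        o, g = oral_col[i], gut_col[i]
        if o < 0 or g < 0:
            continue
        p11 = f_oral[i] * f_gut[i]
        p00 = (1 - f_oral[i]) * (1 - f_gut[i])
        p10 = f_oral[i] * (1 - f_gut[i])
        p01 = (1 - f_oral[i]) * f_gut[i]
        if o == 1 and g == 1:
            L_obs += math.log(p11)
        elif o == 0 and g == 0:
            L_obs += math.log(p00)
        elif o == 1 and g == 0:
            L_obs -= math.log(p10)
        else:
            L_obs -= math.log(p01)
        L_min += min(math.log(p11), math.log(p00))
    return L_obs, L_min, L_obs / L_min


def naive_clamped_incidence(matrix, site_cols):
    """Reference per-allele clamped incidence for one site."""
    f = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        covered = sum(1 for j in site_cols if matrix[i, j] >= 0)
        present = sum(1 for j in site_cols if matrix[i, j] == 1)
        raw = present / covered
        lo = 1.0 / (2.0 * covered)
        f[i] = min(max(raw, lo), 1.0 - lo)
    return f


def hypergeom_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of the hypergeometric.

    Fixes the margins of [[a, b], [c, d]] and sums the probabilities of all
    tables at most as probable as the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_choose(nn, kk):
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    denom = log_choose(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.exp(log_choose(r1, x) + log_choose(r2, c1 - x) - denom)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def naive_bh(p):
    """Step-up BH adjusted p-values, written out longhand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
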