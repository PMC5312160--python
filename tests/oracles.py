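"""Independent brute-force oracles for the defining formulas.

Each function evaluates its statistic directly from the definition,
without reusing any package internals, so tests can compare the pipeline
against a second, literal route.
"""

import math

import numpy as np


def tmm_factor_bruteforce(obs, ref, trim_m=0.30, trim_a=0.05):
    """TMM factor of one library against a reference, by explicit enumeration.

    Computes M/A/variance per gene, enumerates the doubly-trimmed gene set
    via sorted ranks, and evaluates the precision-weighted mean literally.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_obs, n_ref = obs.sum(), ref.sum()
    genes = [g for g in range(len(obs)) if obs[g] > 0 and ref[g] > 0]
    m = {g: math.log2((obs[g] / n_obs) / (ref[g] / n_ref)) for g in genes}
    a = {g: 0.5 * math.log2((obs[g] / n_obs) * (ref[g] / n_ref)) for g in genes}
    v = {
        g: (n_obs - obs[g]) / (n_obs * obs[g]) + (n_ref - ref[g]) / (n_ref * ref[g])
        for g in genes
    }
    if max(abs(x) for x in m.values()) < 1e-6:
        return 1.0
    n = len(genes)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)

    def ranks(values):
        order = sorted(genes, key=lambda g: values[g])
        r = {}
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # average rank, 1-based
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rm, ra = ranks(m), ranks(a)
    kept = [g for g in genes if lo_m <= rm[g] <= hi_m and lo_a <= ra[g] <= hi_a]
    if not kept:
        return 1.0
    num = sum(m[g] / v[g] for g in kept)
    den = sum(1.0 / v[g] for g in kept)
    return 2.0 ** (num / den)


def cpm_bruteforce(counts, effective_sizes, prior=0.0):
    """CPM cell by cell from the definition."""
    counts = np.asarray(counts, dtype=float)
    eff = np.asarray(effective_sizes, dtype=float)
    mean_eff = eff.mean()
    out = np.empty_like(counts)
    for g in range(counts.shape[0]):
        for k in range(counts.shape[1]):
            pk = prior * eff[k] / mean_eff
            out[g, k] = (counts[g, k] + pk) / (eff[k] + pk) * 1e6
    return out


def bh_bruteforce(p):
    """Benjamini-Hochberg step-up applied literally to the definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(1.0, p[i] * m / rank)
        running_min = min(running_min, value)
        adj[i] = running_min
    return adj


def hypergeom_tail_bruteforce(k, universe, n_success, n_draw):
    """P(X >= k) by explicit summation of hypergeometric point masses."""
    total = 0.0
    for x in range(k, min(n_success, n_draw) + 1):
        total += (
            math.comb(n_success, x)
            * math.comb(universe - n_success, n_draw - x)
            / math.comb(universe, n_draw)
        )
    return total


def chi2_2x2_bruteforce(a, b, c, d):
    """Pearson chi-square statistic from the closed form."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def t_test_bruteforce(x, y):
    """Equal-variance two-sample t-test p from the textbook formula."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    tstat = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * tdist.sf(abs(tstat), nx + ny - 2)
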