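"""Independent brute-force oracles used to cross-check the implementations.

Each oracle recomputes a statistic by direct enumeration or grid
maximization using different library routines than the code under test.
"""

import math

import numpy as np
from scipy.stats import betabinom, binom


def bb_grid_lrt(counts_a, counts_b, li=1, ls=1, psi_step=1e-4):
    """LRT statistic by brute-force grid maximization of the beta-binomial
    likelihood: psi on a fixed grid (step 1e-4), rho by staged geometric
    grid refinement. Uses scipy.stats.betabinom, not the package's own
    likelihood code."""
    psis = np.arange(psi_step, 1.0, psi_step)
    Ia, Sa = np.asarray(counts_a, float).T
    Ib, Sb = np.asarray(counts_b, float).T
    na, nb = Ia + Sa, Ib + Sb
    I0, n0 = np.concatenate([Ia, Ib]), np.concatenate([na, nb])

    def grid_ll(I, n, rho):
        theta = psis * li / (psis * li + (1 - psis) * ls)
        if rho < 1e-9:
            ll = binom.logpmf(I[None, :], n[None, :], theta[:, None]).sum(axis=1)
        else:
            c = (1 - rho) / rho
            ll = betabinom.logpmf(
                I[None, :], n[None, :], theta[:, None] * c, (1 - theta[:, None]) * c
            ).sum(axis=1)
        return ll.max()

    def prof(rho, model):
        if model == "h1":
            return grid_ll(Ia, na, rho) + grid_ll(Ib, nb, rho)
        return grid_ll(I0, n0, rho)

    def max_over_rho(model):
        lo, hi, best = 1e-6, 0.95, -np.inf
        for _ in range(3):
            rhos = np.geomspace(lo, hi, 24)
            lls = [prof(r, model) for r in rhos]
            i = int(np.argmax(lls))
            best = lls[i]
            lo, hi = rhos[max(i - 1, 0)], rhos[min(i + 1, 23)]
        return best

    return 2 * (max_over_rho("h1") - max_over_rho("h0"))


def anova_f_oracle(*groups):
    """One-way ANOVA F by the two-line sum-of-squares decomposition."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def hypergeom_tail_oracle(N, n_a, n_b, k):
    """P(overlap >= k) by exhaustive enumeration with exact integer combinatorics."""
    total = math.comb(N, n_b)
    num = sum(
        math.comb(n_a, j) * math.comb(N - n_a, n_b - j)
        for j in range(k, min(n_a, n_b) + 1)
        if n_b - j <= N - n_a
    )
    return num / total


def bh_stepup_oracle(p):
    """Benjamini-Hochberg adjusted p-values by the literal step-up recipe."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q
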