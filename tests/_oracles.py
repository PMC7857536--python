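"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy import stats


def brute_force_bh(p):
    """Textbook BH definition: q_(i) = min_{j >= i} m * p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_force_chisq(table):
    """Pearson chi-square by explicit loops over the contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, dof))


def brute_force_gaussian_loglik(residuals):
    """Maximized Gaussian log-likelihood via the explicit density sum."""
    r = np.asarray(residuals, dtype=float)
    sigma = np.sqrt(np.mean(r ** 2))
    return float(stats.norm.logpdf(r, 0.0, sigma).sum())
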