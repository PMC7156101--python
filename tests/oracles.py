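"""Independent brute-force oracles for the assay statistics.

Everything here is written from the textbook definitions (explicit sums of
squares, studentized-range tail, permutation resampling) and never calls the
package's own implementations.
"""

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import studentized_range
from scipy.stats import t as t_dist


def anova_by_hand(groups):
    """Classical one-way ANOVA from explicit sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    F = (ss_between / df_between) / (ss_within / df_within)
    return F, df_between, df_within, float(f_dist.sf(F, df_between, df_within))


def tukey_by_hand(groups):
    """Pairwise Tukey-HSD p-values from the studentized-range tail.

    q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), compared to
    the studentized range with k groups and the within df.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    df_within = sum(g.size for g in groups) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_within
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2 * (1 / groups[i].size + 1 / groups[j].size))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            out[(i, j)] = float(studentized_range.sf(q, k, df_within))
    return out


def one_sample_t_by_hand(values, mu0):
    arr = np.asarray(values, float)
    n = arr.size
    t = (arr.mean() - mu0) / (arr.std(ddof=1) / np.sqrt(n))
    return float(t), n - 1, float(2 * t_dist.sf(abs(t), n - 1))


def permutation_anova_p(groups, n_perm, rng):
    """Permutation p-value for the one-way F statistic, vectorised.

    Shuffles group labels n_perm times and counts F* >= F_obs.
    """
    sizes = [len(g) for g in groups]
    values = np.concatenate([np.asarray(g, float) for g in groups])
    F_obs = anova_by_hand(groups)[0]
    n = values.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = values[order]
    edges = np.cumsum([0] + sizes)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_between = np.zeros(n_perm)
    for a, b in zip(edges[:-1], edges[1:]):
        chunk = shuffled[:, a:b]
        ss_between += (b - a) * (chunk.mean(axis=1) - grand) ** 2
    df_b, df_w = len(sizes) - 1, n - len(sizes)
    F_star = (ss_between / df_b) / ((ss_total - ss_between) / df_w)
    return float((np.sum(F_star >= F_obs) + 1) / (n_perm + 1))


def noncentral_t_power(effect, n, alpha=0.05):
    """Two-sided one-sample t-test power at standardised effect size d."""
    from scipy.stats import nct

    df = n - 1
    crit = t_dist.ppf(1 - alpha / 2, df)
    nc = effect * np.sqrt(n)
    return float(nct.sf(crit, df, nc) + nct.cdf(-crit, df, nc))
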