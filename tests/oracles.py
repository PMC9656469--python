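"""Closed-form oracles used by the test suite, independent of the package."""

import numpy as np


def anova_2x2_oracle(tab, value="value", factor_a="genotype", factor_b="k_level"):
    """Balanced two-way ANOVA F statistics from textbook sums of squares."""
    y = tab[value].to_numpy(dtype=float)
    a = tab[factor_a].to_numpy()
    b = tab[factor_b].to_numpy()
    grand = y.mean()
    n = len(y)
    lev_a, lev_b = np.unique(a), np.unique(b)
    n_a, n_b = len(lev_a), len(lev_b)
    n_cell = n // (n_a * n_b)
    ss_a = sum(n // n_a * (y[a == la].mean() - grand) ** 2 for la in lev_a)
    ss_b = sum(n // n_b * (y[b == lb].mean() - grand) ** 2 for lb in lev_b)
    ss_cells = sum(
        n_cell * (y[(a == la) & (b == lb)].mean() - grand) ** 2 for la in lev_a for lb in lev_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ((y - grand) ** 2).sum() - ss_cells
    df_err = n - n_a * n_b
    ms_err = ss_err / df_err
    return {
        factor_a: (ss_a / (n_a - 1)) / ms_err,
        factor_b: (ss_b / (n_b - 1)) / ms_err,
        "interaction": (ss_ab / ((n_a - 1) * (n_b - 1))) / ms_err,
    }
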