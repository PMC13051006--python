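"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (bisection,
explicit arithmetic, textbook balanced-design formulas) and never calls the
package's own code paths, so that agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # forward normal CDF only; never its inverse


def inverse_normal_cdf(p):
    """High-precision z(p) by bisecting the forward normal CDF."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    lo = np.full_like(p, -12.0)
    hi = np.full_like(p, 12.0)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        below = ndtr(mid) < p
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return out if out.size > 1 else float(out[0])


def sdt_from_counts(k_hit, n_match, k_fa, n_mismatch):
    """d' and C recomputed from raw counts with the extreme-rate rule."""

    def rate(k, n):
        if k == 0:
            return 0.5 / n
        if k == n:
            return (n - 0.5) / n
        return k / n

    zh = inverse_normal_cdf(rate(k_hit, n_match))
    zf = inverse_normal_cdf(rate(k_fa, n_mismatch))
    return zh - zf, -(zh + zf) / 2.0


def cic_table():
    """All 36 CIC values computed directly from the quoted piecewise rule."""
    out = {}
    for u in range(1, 7):
        for a in range(1, 7):
            if a == u:
                v = 0.0
            elif a > u:
                v = (a - u) / (6 - u)
            else:
                v = (a - u) / (u - 1)
            out[(u, a)] = v
    return out


def pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def midranks(x):
    """Average ranks with ties shared, by explicit counting."""
    x = np.asarray(x, float)
    out = np.empty(x.size)
    for i, v in enumerate(x):
        less = (x < v).sum()
        eq = (x == v).sum()
        out[i] = less + (eq + 1) / 2.0
    return out


def spearman(x, y):
    return pearson(midranks(x), midranks(y))


def welch_unpaired(x, y):
    """Welch t, Satterthwaite df and pooled-SD Cohen's d by hand."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    v1 = ((x - x.mean()) ** 2).sum() / (n1 - 1)
    v2 = ((y - y.mean()) ** 2).sum() / (n2 - 1)
    t = (x.mean() - y.mean()) / np.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (x.mean() - y.mean()) / sp
    return float(t), float(df), float(d)


def cronbach(matrix):
    """Spreadsheet-style alpha: explicit variances, denominator n-1."""
    x = np.asarray(matrix, float)
    n, k = x.shape

    def var(v):
        return ((v - v.mean()) ** 2).sum() / (len(v) - 1)

    item_vars = sum(var(x[:, j]) for j in range(k))
    total_var = var(x.sum(axis=1))
    return k / (k - 1) * (1 - item_vars / total_var)


def balanced_mixed_anova(y, group_labels):
    """Textbook cell-means split-plot ANOVA for a *balanced* 2x2 design.

    ``y`` is (n_subjects, 2) with the two within-condition values; groups
    must have equal size.  Returns dict of (F, df1, df2, partial eta sq)
    per effect.  Balanced, so Type I/II/III coincide.
    """
    y = np.asarray(y, float)
    g = np.asarray(group_labels)
    levels = sorted(set(g.tolist()))
    assert len(levels) == 2
    n = (g == levels[0]).sum()
    assert n == (g == levels[1]).sum(), "oracle requires balanced groups"
    grand = y.mean()
    m = y.mean(axis=1)  # subject means
    ss_between_subj = 2 * ((m - grand) ** 2).sum()
    ss_A = 2 * n * sum((m[g == lv].mean() - grand) ** 2 for lv in levels)
    ss_subj_within = ss_between_subj - ss_A
    col_means = y.mean(axis=0)
    ss_B = 2 * n * ((col_means - grand) ** 2).sum()
    ss_AB = 0.0
    for lv in levels:
        for j in range(2):
            cell = y[g == lv, j].mean()
            ss_AB += n * (cell - m[g == lv].mean() - col_means[j] + grand) ** 2
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_B - ss_AB
    df_err = 2 * n - 2

    def eff(ss, ss_err):
        F = ss / (ss_err / df_err)
        return {"F": F, "df1": 1, "df2": df_err, "pes": ss / (ss + ss_err)}

    return {
        "between": eff(ss_A, ss_subj_within),
        "within": eff(ss_B, ss_err_within),
        "interaction": eff(ss_AB, ss_err_within),
        "ss_total": ss_total,
    }
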