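"""Inferential statistics for the aided face-matching analyses.

The central piece is a 2 x 2 mixed ANOVA (one two-level within-subject
factor, one two-level between-subject factor) computed with Type III sums of
squares under sum-to-zero contrasts, which is what mainstream psychology
software reports for unbalanced group sizes.  The module also provides Welch
t tests with Cohen's d, Pearson/Spearman correlation pairs, split-half
reliability of pair-level rating profiles, the participant-level correlation
table, and the per-pair CIC-versus-similarity regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "mixed_anova_2x2",
    "oneway_anova",
    "welch_t",
    "correlations",
    "split_half",
    "correlation_table",
    "table1",
    "cic_similarity_regression",
]


@dataclass(frozen=True)
class EffectResult:
    """F test for one ANOVA effect with its partial eta squared."""

    ss: float
    df1: int
    df2: int
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    """Effects of the 2 x 2 mixed design.

    ``between`` is the group (experiment) main effect, ``within`` the aid
    main effect, ``interaction`` their interaction.  Within-stratum effects
    are tested against the aid-by-subject error; the between effect against
    the subjects-within-groups error.
    """

    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    ss_error_between: float
    ss_error_within: float
    ss_total: float


def _typeIII_ss(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Type III SS per column of an effect-coded design matrix, plus RSS."""
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    ss = beta**2 / np.diag(xtx_inv)
    return ss, float(resid @ resid)


def _effect(ss: float, ss_err: float, df1: int, df2: int) -> EffectResult:
    if ss_err <= 0:
        # degenerate data (e.g. all values identical): no error variance
        return EffectResult(ss, df1, df2, float("nan"), float("nan"),
                            float("nan"))
    F = (ss / df1) / (ss_err / df2)
    return EffectResult(
        ss=float(ss),
        df1=df1,
        df2=df2,
        F=float(F),
        p=float(sps.f.sf(F, df1, df2)),
        partial_eta_sq=float(ss / (ss + ss_err)),
    )


def mixed_anova_2x2(unaided, aided, group) -> AnovaResult:
    """Mixed ANOVA for a 2-level within factor crossed with 2 groups.

    Parameters
    ----------
    unaided, aided
        The two within-subject measurements, one value per participant.
    group
        Between-subject labels (exactly two distinct values, >= 2
        participants each).

    Uses the split-plot decomposition: subject means carry the between-group
    comparison, within-subject half-differences carry the aid effect and the
    interaction.  Effect sums of squares are Type III under sum-to-zero
    contrasts, so with unbalanced groups the aid effect tests the unweighted
    average of the two group mean changes.  Partial eta squared is
    SS_effect / (SS_effect + SS_error) with the error from the matching
    stratum.
    """
    y1 = np.asarray(unaided, dtype=float)
    y2 = np.asarray(aided, dtype=float)
    g = np.asarray(group)
    if not (y1.shape == y2.shape == g.shape) or y1.ndim != 1:
        raise ValueError("unaided, aided and group must be equal-length 1-D")
    if np.isnan(y1).any() or np.isnan(y2).any():
        bad = np.argwhere(np.isnan(y1) | np.isnan(y2)).ravel().tolist()
        raise ValueError(f"missing within-level value for participants {bad}")
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    n = y1.size
    n_per = [(g == lv).sum() for lv in levels]
    if min(n_per) < 2:
        raise ValueError("need >= 2 participants per group")

    code = np.where(g == levels[0], 1.0, -1.0)  # sum-to-zero contrast
    m = (y1 + y2) / 2.0  # subject means: between stratum
    h = (y2 - y1) / 2.0  # half-differences: within stratum

    X = np.column_stack([np.ones(n), code])
    # factor 2: each subject contributes two observations, and the stratum
    # decomposition of the raw SS carries 2*(m - ...)^2 and 2*h^2 terms
    ss_m, rss_m = _typeIII_ss(X, m)
    ss_h, rss_h = _typeIII_ss(X, h)
    ss_between = 2.0 * ss_m[1]
    ss_err_between = 2.0 * rss_m
    ss_within = 2.0 * ss_h[0]  # intercept of h: the aid main effect
    ss_interaction = 2.0 * ss_h[1]
    ss_err_within = 2.0 * rss_h

    y_all = np.concatenate([y1, y2])
    ss_total = float(((y_all - y_all.mean()) ** 2).sum())
    df_err = n - 2
    return AnovaResult(
        between=_effect(ss_between, ss_err_between, 1, df_err),
        within=_effect(ss_within, ss_err_within, 1, df_err),
        interaction=_effect(ss_interaction, ss_err_within, 1, df_err),
        ss_error_between=ss_err_between,
        ss_error_within=ss_err_within,
        ss_total=ss_total,
    )


def oneway_anova(values, group) -> EffectResult:
    """One-way between-subjects ANOVA with partial eta squared."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    grand = y.mean()
    ss_effect = sum((g == lv).sum() * (y[g == lv].mean() - grand) ** 2 for lv in levels)
    ss_err = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in levels)
    return _effect(float(ss_effect), float(ss_err), len(levels) - 1, y.size - len(levels))


def welch_t(x, y, paired: bool = False) -> tuple[float, float, float, float]:
    """t test with Cohen's d; Welch-Satterthwaite df when unpaired.

    Returns ``(t, df, p, cohen_d)`` with a two-sided p.  Cohen's d uses the
    pooled standard deviation of the two samples in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        res = sps.ttest_rel(x, y)
        df = float(x.size - 1)
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
    sp = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    d = float((x.mean() - y.mean()) / sp) if sp > 0 else float("nan")
    return float(res.statistic), float(df), float(res.pvalue), d


def correlations(x, y) -> tuple[float, float, int]:
    """Pearson r and Spearman rho (mid-rank ties) for paired data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    r = sps.pearsonr(x, y).statistic
    rho = sps.spearmanr(x, y).statistic
    return float(r), float(rho), int(x.size)


def split_half(
    rating_matrix,
    n_splits: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Split-half reliability of per-pair mean ratings.

    ``rating_matrix`` is participants x pairs.  Participants are randomly
    divided into two halves; the two halves' per-pair mean ratings are
    correlated (Pearson); the average r over ``n_splits`` seeded splits is
    returned, without Spearman-Brown correction.
    """
    x = np.asarray(rating_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("need a participants x pairs matrix with >= 4 participants")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    rs = np.empty(n_splits)
    for i in range(n_splits):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2 :]
        rs[i] = sps.pearsonr(x[a].mean(axis=0), x[b].mean(axis=0)).statistic
    return float(rs.mean())


def correlation_table(
    measures: dict[str, np.ndarray],
    afr_similarity=None,
    n_splits: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlations between per-pair human measures, AFR similarity appended.

    ``measures`` maps a measure name to a participants x pairs rating matrix
    (all over the same pairs).  Off-diagonal cells hold the Pearson r between
    the two measures' per-pair means; the leading diagonal holds each
    measure's split-half reliability.  If ``afr_similarity`` (one value per
    pair) is given, an extra row reports Pearson r with Spearman rho in
    brackets, mirroring how similarity-score correlations are conventionally
    reported alongside rating correlations.
    """
    names = list(measures)
    pair_means = {k: np.asarray(v, dtype=float).mean(axis=0) for k, v in measures.items()}
    n_pairs = {len(v) for v in pair_means.values()}
    if len(n_pairs) != 1:
        raise ValueError("all measures must cover the same pairs")
    tab = pd.DataFrame(index=names, columns=names, dtype=object)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                tab.loc[a, b] = round(
                    split_half(measures[a], n_splits=n_splits, seed=seed), 4
                )
            elif i > j:
                r, _, _ = correlations(pair_means[a], pair_means[b])
                tab.loc[a, b] = round(r, 4)
            else:
                tab.loc[a, b] = ""
    if afr_similarity is not None:
        row = {}
        for a in names:
            r, rho, _ = correlations(pair_means[a], afr_similarity)
            row[a] = f"{r:.2f} ({rho:.2f})"
        tab.loc["afr_similarity"] = pd.Series(row)
    return tab


def table1(summaries: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Pairwise Pearson correlations between participant-level measures.

    ``summaries`` holds one row per participant with columns such as trust,
    self/AFR accuracy estimates, unaided and aided accuracy, and adherence.
    Returns a long-format table with r, n, p and a significance flag at the
    ``alpha`` threshold (the conventional p < .01 star).
    """
    cols = list(summaries.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[:i]:
            x = summaries[a].to_numpy(dtype=float)
            y = summaries[b].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            res = sps.pearsonr(x[ok], y[ok])
            rows.append(
                {
                    "measure_a": a,
                    "measure_b": b,
                    "r": float(res.statistic),
                    "n": int(ok.sum()),
                    "p": float(res.pvalue),
                    "significant": bool(res.pvalue < alpha),
                }
            )
    return pd.DataFrame(rows)


def cic_similarity_regression(
    mean_cic, displayed_similarity
) -> tuple[float, float, int, float]:
    """OLS of per-pair mean CIC on displayed AFR similarity.

    Returns ``(slope, r, df, p)`` with df = n_pairs - 2.  Run separately for
    match and mismatch pairs: the two pair types occupy disjoint similarity
    ranges and are reported separately.
    """
    x = np.asarray(displayed_similarity, dtype=float)
    y = np.asarray(mean_cic, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 pairs with matching lengths")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue), int(x.size - 2), float(res.pvalue)
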