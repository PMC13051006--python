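"""Tests for the inferential statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from afrmatch import (
    cic_similarity_regression,
    correlation_table,
    correlations,
    mixed_anova_2x2,
    oneway_anova,
    split_half,
    table1,
    welch_t,
)

from _oracles import balanced_mixed_anova, pearson, spearman, welch_unpaired


class TestMixedAnova:
    def _random_design(self, rng, n1=8, n2=8, aid_effect=0.0, group_effect=0.0):
        g = np.array(["a"] * n1 + ["b"] * n2)
        subj = rng.normal(0, 1, n1 + n2)
        un = subj + rng.normal(0, 1, n1 + n2) + np.where(g == "a", group_effect, 0)
        ai = subj + aid_effect + rng.normal(0, 1, n1 + n2) + np.where(g == "a", group_effect, 0)
        return un, ai, g

    def test_balanced_design_matches_cell_means_oracle(self, rng):
        for _ in range(5):
            un, ai, g = self._random_design(rng, aid_effect=0.8, group_effect=0.5)
            res = mixed_anova_2x2(un, ai, g)
            oracle = balanced_mixed_anova(np.column_stack([un, ai]), g)
            for name in ("between", "within", "interaction"):
                eff = getattr(res, name)
                assert eff.F == pytest.approx(oracle[name]["F"], rel=1e-8)
                assert eff.partial_eta_sq == pytest.approx(oracle[name]["pes"], rel=1e-8)
                assert (eff.df1, eff.df2) == (oracle[name]["df1"], oracle[name]["df2"])

    def test_balanced_design_matches_pingouin(self, rng):
        import pingouin

        un, ai, g = self._random_design(rng, n1=10, n2=10, aid_effect=0.5)
        res = mixed_anova_2x2(un, ai, g)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(20), 2),
                "group": np.tile(g, 2),
                "aid": np.repeat(["unaided", "aided"], 20),
                "y": np.concatenate([un, ai]),
            }
        )
        pg = pingouin.mixed_anova(
            df, dv="y", within="aid", subject="subject", between="group"
        ).set_index("Source")
        assert res.between.F == pytest.approx(pg.loc["group", "F"], rel=1e-8)
        assert res.within.F == pytest.approx(pg.loc["aid", "F"], rel=1e-8)
        assert res.interaction.F == pytest.approx(pg.loc["Interaction", "F"], rel=1e-8)
        assert res.within.partial_eta_sq == pytest.approx(pg.loc["aid", "np2"], rel=1e-6)

    def test_ss_decomposition_is_exact(self, rng):
        # SS_total = between-subjects SS + within-subjects SS, every dataset
        for n1, n2 in ((8, 8), (9, 14), (5, 23)):
            un, ai, g = self._random_design(rng, n1, n2, aid_effect=0.4)
            res = mixed_anova_2x2(un, ai, g)
            y = np.concatenate([un, ai])
            m = (un + ai) / 2
            ss_between_subjects = 2 * ((m - m.mean()) ** 2).sum()
            ss_within_subjects = ((y - np.concatenate([m, m])) ** 2).sum()
            assert ss_between_subjects + ss_within_subjects == pytest.approx(
                res.ss_total, rel=1e-12
            )
            # and the within stratum partitions into aid + interaction + error
            # only in the balanced case; the stratum error is shared
            assert res.ss_error_within > 0

    def test_unbalanced_effects_are_type_iii_model_comparisons(self, rng):
        # Type III SS for each within-stratum effect equals the RSS increase
        # from dropping that term out of the effect-coded half-difference
        # model (computed here independently with lstsq)
        un, ai, g = self._random_design(rng, n1=6, n2=13, aid_effect=0.6)
        res = mixed_anova_2x2(un, ai, g)
        h = (ai - un) / 2.0
        x = np.where(g == "a", 1.0, -1.0)
        full = np.column_stack([np.ones_like(h), x])

        def rss(design, y):
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ beta
            return float(r @ r)

        rss_full = rss(full, h)
        ss_aid = 2 * (rss(x[:, None], h) - rss_full)
        ss_inter = 2 * (rss(np.ones_like(h)[:, None], h) - rss_full)
        assert res.within.ss == pytest.approx(ss_aid, rel=1e-10)
        assert res.interaction.ss == pytest.approx(ss_inter, rel=1e-10)
        # and the aid effect tests the unweighted mean of group mean changes
        d_unweighted = (h[g == "a"].mean() + h[g == "b"].mean()) / 2
        assert np.sign(d_unweighted) == np.sign(
            (ai - un)[g == "a"].mean() + (ai - un)[g == "b"].mean()
        )

    def test_degenerate_constant_data_flagged(self):
        un = np.ones(8)
        ai = np.ones(8)
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = mixed_anova_2x2(un, ai, g)
        assert np.isnan(res.within.F)

    def test_missing_value_names_participant(self):
        with pytest.raises(ValueError, match="2"):
            mixed_anova_2x2([1, 2, np.nan, 4], [1, 2, 3, 4], ["a", "a", "b", "b"])

    def test_null_pvalues_uniform(self, rng):
        # Kolmogorov-Smirnov on the within-effect p under H0
        ps = []
        for _ in range(1000):
            un, ai, g = self._random_design(rng, n1=7, n2=9)
            ps.append(mixed_anova_2x2(un, ai, g).within.p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestWelchT:
    def test_identical_samples_t_zero(self):
        x = np.arange(10.0)
        t, df, p, d = welch_t(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formulas(self, rng):
        x = rng.normal(0, 1, 13)
        y = rng.normal(0.5, 2, 19)
        t, df, p, d = welch_t(x, y)
        t0, df0, d0 = welch_unpaired(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert d == pytest.approx(d0, abs=1e-10)
        assert p == pytest.approx(2 * sps.t.sf(abs(t0), df0), abs=1e-10)

    def test_equal_variance_equal_n_df_limit(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        _, df, _, _ = welch_t(x, y)
        assert df == pytest.approx(798, rel=0.02)

    def test_paired(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(0.3, 0.1, 15)
        t, df, p, d = welch_t(x, y, paired=True)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert df == 14


class TestCorrelations:
    def test_linear_relation(self):
        x = np.arange(10.0)
        r, rho, n = correlations(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_monotone_nonlinearity(self, rng):
        x = rng.normal(size=50)
        r, rho, _ = correlations(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_anti_ordered(self):
        x = np.arange(8.0)
        _, rho, _ = correlations(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_manual_computation_with_ties(self, rng):
        x = rng.integers(1, 5, 18).astype(float)
        y = rng.integers(1, 5, 18).astype(float) + 0.1 * x
        r, rho, _ = correlations(x, y)
        assert r == pytest.approx(pearson(x, y), abs=1e-12)
        assert rho == pytest.approx(spearman(x, y), abs=1e-12)


class TestSplitHalf:
    def test_identical_participants_fully_reliable(self):
        mat = np.tile(np.arange(20.0), (8, 1))
        assert split_half(mat, n_splits=10, seed=0) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        mat = rng.normal(size=(40, 400))
        assert abs(split_half(mat, n_splits=20, seed=1)) < 0.1

    def test_reproducible_given_seed(self, rng):
        mat = rng.normal(size=(12, 30)) + np.linspace(0, 1, 30)
        assert split_half(mat, seed=5) == split_half(mat, seed=5)

    def test_halving_lowers_reliability_vs_full_sample_correlation(self, rng):
        # two cohorts rating the same pairs: their full-sample per-pair means
        # correlate more strongly than either cohort's split halves do
        signal = rng.normal(size=60)
        a = signal + rng.normal(0, 2.0, size=(30, 60))
        b = signal + rng.normal(0, 2.0, size=(30, 60))
        between = pearson(a.mean(axis=0), b.mean(axis=0))
        assert split_half(a, n_splits=50, seed=2) < between
        assert split_half(b, n_splits=50, seed=2) < between

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            split_half(np.ones((3, 5)))


class TestTablesAndRegression:
    def test_table1_symmetric_content(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        out = table1(df)
        assert len(out) == 6  # lower triangle of 4 measures
        pair = out[(out.measure_a == "b") & (out.measure_b == "a")].iloc[0]
        assert pair.r == pytest.approx(pearson(df["a"], df["b"]), abs=1e-12)

    def test_constant_cic_flat_regression(self):
        slope, r, df, p = cic_similarity_regression(np.full(20, 0.4), np.linspace(0, 1, 20))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert df == 18

    def test_exact_linear_cic(self):
        x = np.linspace(0.5, 1.0, 16)
        slope, r, df, p = cic_similarity_regression(2 * x - 1, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert df == 14

    def test_correlation_table_layout(self, rng):
        mats = {
            "exp1a_rating": rng.normal(size=(10, 25)),
            "exp1b_rating": rng.normal(size=(10, 25)),
        }
        sim = rng.uniform(0.5, 1, 25)
        tab = correlation_table(mats, afr_similarity=sim, n_splits=5, seed=0)
        assert list(tab.index) == ["exp1a_rating", "exp1b_rating", "afr_similarity"]
        assert tab.loc["exp1a_rating", "exp1b_rating"] == ""  # upper triangle empty
        assert isinstance(tab.loc["afr_similarity", "exp1a_rating"], str)


class TestOnewayAnova:
    def test_matches_scipy(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        eff = oneway_anova(y, g)
        ref = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert eff.F == pytest.approx(ref.statistic, rel=1e-10)
        assert eff.p == pytest.approx(ref.pvalue, rel=1e-10)
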