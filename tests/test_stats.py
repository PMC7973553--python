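"""Statistical battery: aggregation, ANOVA, contrasts, partition test."""

import numpy as np
import pandas as pd
import pytest

import osrt
from osrt.stats import rm_anova_oneway, rm_anova_twoway, mixed_anova


def brute_force_oneway(X):
    """Independent sums-of-squares oracle for the one-way within design:
    explicit loops over subjects and conditions, epsilon from the eigenvalues
    of the double-centered covariance matrix."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = X.mean()
    ss_total = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_cond = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_cond - ss_subj
    F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    eta = ss_cond / (ss_cond + ss_err)
    S = np.cov(X, rowvar=False)
    centered = (S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True)
                + S.mean())
    lam = np.linalg.eigvalsh(centered)
    eps = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
    return F, eta, eps


class TestBlockRates:
    def make_records(self, labels, block=1, usable=None):
        n = len(labels)
        return pd.DataFrame({
            "participant": "p1", "trial": np.arange(2, n + 2), "block": block,
            "semantic": labels,
            "grammatical": ["grammatical" if l in ("main", "interference")
                            else "ungrammatical" for l in labels],
            "usable": [True] * n if usable is None else usable,
            "stuck_eligible": True, "correct": False,
        })

    def test_all_stuck_block(self):
        rates = osrt.block_rates(self.make_records(["stuck"] * 10))
        row = rates.iloc[0]
        assert row["pct_stuck"] == 100.0
        assert row["pct_main"] == row["pct_interference"] == row["pct_alternative"] == 0.0

    def test_equal_label_frequencies(self):
        labels = ["main", "interference", "stuck", "alternative"] * 5
        row = osrt.block_rates(self.make_records(labels)).iloc[0]
        assert all(row[f"pct_{l}"] == 25.0 for l in
                   ("main", "interference", "stuck", "alternative"))
        assert row["pct_grammatical"] == 50.0

    def test_toy_table_matches_hand_counts(self):
        labels = (["main"] * 7 + ["interference"] * 5 + ["stuck"] * 6
                  + ["alternative"] * 2)
        row = osrt.block_rates(self.make_records(labels)).iloc[0]
        assert row["pct_main"] == pytest.approx(100 * 7 / 20)
        assert row["pct_interference"] == pytest.approx(100 * 5 / 20)
        assert row["pct_stuck"] == pytest.approx(100 * 6 / 20)
        assert row["pct_alternative"] == pytest.approx(100 * 2 / 20)
        assert row["n_usable"] == 20

    def test_rates_sum_to_hundred_on_simulated_records(self, noise_free_participant):
        rates = osrt.block_rates(noise_free_participant["records"])
        sums = (rates[["pct_main", "pct_interference", "pct_stuck",
                       "pct_alternative"]].sum(axis=1))
        assert np.allclose(sums, 100.0)

    def test_window_rates_use_twelve_trial_spans(self):
        labels = ["main"] * 11 + ["stuck"] * 12
        rec = self.make_records(labels)  # trials 2..24
        win = osrt.window_rates(rec, window_len=12)
        # trials 2-12 fall in window 1 (all main), 13-24 in window 2
        assert win.loc[win["window"] == 1, "pct_main"].iloc[0] == 100.0
        assert win.loc[win["window"] == 2, "pct_stuck"].iloc[0] == 100.0

    def test_block_without_usable_isis_yields_missing(self):
        rec = self.make_records(["main"] * 3, usable=[False] * 3)
        row = osrt.block_rates(rec).iloc[0]
        assert np.isnan(row["pct_main"]) and row["n_usable"] == 0


class TestRmAnova:
    def test_identical_rows_give_zero_within_f(self):
        X = np.tile([3.0, 3.0, 3.0, 3.0], (6, 1)) + np.arange(6)[:, None]
        res = rm_anova_oneway(X)
        assert res.F == pytest.approx(0.0)

    def test_two_level_factor_has_unit_epsilon(self):
        X = np.random.default_rng(1).normal(size=(8, 2))
        res = rm_anova_oneway(X)
        assert res.eps == 1.0 and res.mauchly_p == 1.0

    def test_oneway_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1)) + [0, .3, .5, .2]
        mine = rm_anova_oneway(X)
        F, eta, eps = brute_force_oneway(X)
        assert mine.F == pytest.approx(F, rel=1e-10)
        assert mine.eta_p2 == pytest.approx(eta, rel=1e-10)
        assert mine.eps == pytest.approx(eps, rel=1e-10)

    def test_oneway_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
        df = pd.DataFrame({"s": np.repeat(np.arange(12), 5),
                           "b": np.tile(np.arange(5), 12), "y": X.ravel()})
        ref = pg.rm_anova(data=df, dv="y", within="b", subject="s",
                          correction=True, effsize="np2", detailed=True).iloc[0]
        mine = rm_anova_oneway(X)
        assert mine.F == pytest.approx(ref["F"], rel=1e-8)
        assert mine.p_unc == pytest.approx(ref["p_unc"], rel=1e-8)
        assert mine.eta_p2 == pytest.approx(ref["np2"], rel=1e-8)
        assert mine.eps == pytest.approx(ref["eps"], rel=1e-6)

    def test_twoway_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(9, 2, 6)) + rng.normal(size=(9, 1, 1))
        df = pd.DataFrame({
            "s": np.repeat(np.arange(9), 12),
            "t": np.tile(np.repeat(np.arange(2), 6), 9),
            "b": np.tile(np.arange(6), 18), "y": X.ravel()})
        ref = pg.rm_anova(data=df, dv="y", within=["t", "b"], subject="s",
                          effsize="np2")
        mine = rm_anova_twoway(X, names=("t", "b"))
        for row, res in zip(ref.itertuples(), mine):
            assert res.F == pytest.approx(row.F, rel=1e-8)
            assert res.p_unc == pytest.approx(row.p_unc, rel=1e-8)
            assert res.eta_p2 == pytest.approx(row.np2, rel=1e-8)

    def test_mixed_design_matches_pingouin_unbalanced(self, rng):
        pg = pytest.importorskip("pingouin")
        g1 = rng.normal(size=(14, 6))
        g2 = rng.normal(size=(16, 6)) + 0.3
        df = pd.concat([
            pd.DataFrame({"s": np.repeat(np.arange(14), 6), "g": "a",
                          "b": np.tile(np.arange(6), 14), "y": g1.ravel()}),
            pd.DataFrame({"s": np.repeat(np.arange(100, 116), 6), "g": "b",
                          "b": np.tile(np.arange(6), 16), "y": g2.ravel()})])
        ref = pg.mixed_anova(data=df, dv="y", within="b", subject="s",
                             between="g", effsize="np2")
        mine = mixed_anova([g1, g2])
        for row, res in zip(ref.itertuples(), mine):
            assert res.F == pytest.approx(row.F, rel=1e-8)
            assert res.p_unc == pytest.approx(row.p_unc, rel=1e-8)
            assert res.eta_p2 == pytest.approx(row.np2, rel=1e-8)

    def test_invariant_to_participant_order_and_constant_shift(self, rng):
        X = rng.normal(size=(10, 4))
        base = rm_anova_oneway(X)
        perm = rng.permutation(10)
        shifted = rm_anova_oneway(X[perm] + 17.3)
        assert shifted.F == pytest.approx(base.F)
        assert shifted.p == pytest.approx(base.p)

    def test_eta_invariant_to_positive_rescaling(self, rng):
        X = rng.normal(size=(10, 4))
        assert (rm_anova_oneway(X * 3.7).eta_p2
                == pytest.approx(rm_anova_oneway(X).eta_p2))

    def test_long_format_interface_with_listwise_deletion(self, rng):
        X = rng.normal(size=(8, 4))
        df = pd.DataFrame({"s": np.repeat(np.arange(8), 4),
                           "b": np.tile(np.arange(4), 8), "y": X.ravel()})
        df.loc[3, "y"] = np.nan  # knock out one cell of subject 0
        res = osrt.rm_anova(df, dv="y", subject="s", within="b")
        ref = rm_anova_oneway(X[1:])
        assert res.iloc[0]["F"] == pytest.approx(ref.F)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.ones((1, 4)))


class TestContrasts:
    def test_identical_vectors_give_zero_t_unit_p(self):
        res = osrt.contrast_tests([1.0, 2, 3, 4], [1.0, 2, 3, 4], mode="ttest")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df == 3

    def test_self_correlation_is_one(self):
        res = osrt.contrast_tests([1.0, 2, 3, 5], [1.0, 2, 3, 5], mode="correlation")
        assert res.statistic == pytest.approx(1.0)
        assert res.df == 2

    def test_textbook_formula_oracle(self, rng):
        a = rng.normal(size=29)
        b = a * 0.5 + rng.normal(size=29)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(29))
        r_oracle = (np.sum((a - a.mean()) * (b - b.mean()))
                    / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
        assert osrt.paired_ttest(a, b).statistic == pytest.approx(t_oracle, rel=1e-10)
        assert osrt.pearson_corr(a, b).statistic == pytest.approx(r_oracle, rel=1e-10)

    def test_zero_variance_correlation_signaled(self):
        with pytest.raises(ValueError):
            osrt.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartitionTest:
    def test_identical_series_never_significant(self, rng):
        A = rng.normal(50, 5, size=(12, 6))
        res = osrt.partition_test(A, A.copy(), n_partitions=50, seed=0)
        assert res.prop_main_significant == 0.0
        assert res.prop_interaction_significant == 0.0

    def test_even_cohort_splits_in_half(self, rng):
        A = rng.normal(size=(30, 6))
        res = osrt.partition_test(A, A + rng.normal(size=(30, 6)),
                                  n_partitions=10, seed=1)
        assert res.n_participants == 30

    def test_monotone_in_alpha(self, rng):
        A = rng.normal(size=(16, 6))
        B = rng.normal(size=(16, 6))
        lo = osrt.partition_test(A, B, n_partitions=200, seed=3, alpha=0.01)
        hi = osrt.partition_test(A, B, n_partitions=200, seed=3, alpha=0.2)
        assert lo.prop_main_significant <= hi.prop_main_significant
        assert lo.prop_interaction_significant <= hi.prop_interaction_significant

    def test_reproducible_under_seed(self, rng):
        A = rng.normal(size=(10, 6))
        B = rng.normal(size=(10, 6))
        r1 = osrt.partition_test(A, B, n_partitions=100, seed=9)
        r2 = osrt.partition_test(A, B, n_partitions=100, seed=9)
        assert r1 == r2

    def test_exchangeable_null_flags_near_alpha(self, rng):
        A = rng.normal(50, 8, size=(30, 6))
        B = rng.normal(50, 8, size=(30, 6))
        res = osrt.partition_test(A, B, n_partitions=400, seed=7)
        assert 0.0 <= res.prop_main_significant <= 0.15

    def test_invalid_partition_count_rejected(self, rng):
        with pytest.raises(ValueError):
            osrt.partition_test(rng.normal(size=(4, 6)),
                                rng.normal(size=(4, 6)), n_partitions=0)


class TestEffectSignRecovery:
    def test_injected_learning_signs(self):
        # rising Main rate with a block-7 dip: chronological earlier-minus-
        # later coding makes learning negative, interference positive,
        # recovery negative
        rates = {1: 20.0, 2: 25, 3: 30, 4: 33, 5: 35, 6: 38, 7: 22, 8: 36}
        s = osrt.effect_scores(rates)
        assert s.learning < 0 and s.interference > 0 and s.recovery < 0
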