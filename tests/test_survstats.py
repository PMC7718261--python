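import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats
from scipy.special import comb

from pgskit import (
    cox_fit,
    cox_score_test,
    fisher_exact_2x2,
    format_median,
    km_fit,
    km_median,
    logrank_test,
    simulate_two_group_survival,
    welch_t,
)


def km_bruteforce(times, events):
    """Direct product of (1 - d_i/n_i) at each event time."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    out = {}
    s = 1.0
    for tj in np.unique(t):
        n = (t >= tj).sum()
        d = ((t == tj) & (e == 1)).sum()
        if d:
            s *= 1 - d / n
        out[tj] = s
    return out


class TestKaplanMeier:
    def test_all_events_at_once(self):
        c = km_fit([5.0] * 8, [1] * 8)
        assert c.survival[-1] == 0.0 and c.median == 5.0

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000), n=st.integers(1, 60))
    def test_matches_bruteforce_product(self, seed, n):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 15, n).astype(float)  # force ties
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        c = km_fit(t, e)
        oracle = km_bruteforce(t, e)
        for tj, s in zip(c.times, c.survival):
            assert s == pytest.approx(oracle[tj], abs=1e-12)

    def test_matches_lifelines(self):
        table = simulate_two_group_survival(150, 2.0, 0.1, censor_rate=0.3, seed=8)
        t = table.data["dfs_months"].to_numpy()
        e = table.data["dfs_event"].to_numpy()
        c = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(c.survival, index=c.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for tj in c.times:
            assert ours[tj] == pytest.approx(theirs.loc[tj], abs=1e-10)

    def test_exponential_median_closed_form(self):
        table = simulate_two_group_survival(1000, 1.0, 0.1, censor_rate=0.0, seed=12)
        c = km_fit(table.data["dfs_months"], table.data["dfs_event"])
        assert km_median(c) == pytest.approx(np.log(2) / 0.1, rel=0.05)

    def test_undefined_median_reported_as_gt_max(self):
        # heavy censoring: survival never reaches 0.5
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 0, 0]
        c = km_fit(t, e)
        assert c.median is None
        assert format_median(c) == "> 4"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        e = np.array([1, 0, 1, 1, 0])
        chi2, p = logrank_test({"a": (t, e), "b": (t, e)})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_hand_calculation(self):
        # groups {2 subjects} vs {3 subjects}; one death at t=1 in group a.
        # O1 - E1 = 1 - 2/5 = 0.6; V = (2/5)(3/5) = 0.24; chi2 = 0.36/0.24 = 1.5
        chi2, p = logrank_test(
            {"a": ([1.0, 4.0], [1, 0]), "b": ([2.0, 3.0, 5.0], [0, 0, 0])}
        )
        assert chi2 == pytest.approx(1.5, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(1.5, 1), abs=1e-12)

    def test_power_under_hr3(self):
        hits = 0
        for seed in range(40):
            table = simulate_two_group_survival(200, 3.0, 0.05, seed=seed)
            df = table.data
            groups = {
                g: (sub["dfs_months"].to_numpy(), sub["dfs_event"].to_numpy())
                for g, sub in df.groupby("group")
            }
            _, p = logrank_test(groups)
            hits += p < 0.01
        assert hits >= 38  # >= 95% power

    def test_matches_lifelines(self):
        table = simulate_two_group_survival(120, 1.8, 0.1, censor_rate=0.2, seed=5)
        df = table.data
        a = df[df["group"] == 0]
        b = df[df["group"] == 1]
        chi2, p = logrank_test(
            {"a": (a["dfs_months"], a["dfs_event"]), "b": (b["dfs_months"], b["dfs_event"])}
        )
        ref = ll_logrank(
            a["dfs_months"], b["dfs_months"], a["dfs_event"], b["dfs_event"]
        )
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test({"a": ([1.0], [0]), "b": ([2.0], [0])})


class TestCox:
    def test_recovers_simulated_hazard_ratio(self):
        table = simulate_two_group_survival(600, 2.0, 0.05, censor_rate=0.0, seed=17)
        res = cox_fit(
            table.data["dfs_months"], table.data["dfs_event"], table.data[["group"]]
        )
        assert 1.8 <= res.hazard_ratio[0] <= 2.2
        assert res.ci_lower[0] < res.hazard_ratio[0] < res.ci_upper[0]

    def test_matches_lifelines_multivariate(self):
        rng = np.random.default_rng(3)
        n = 300
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.standard_normal(n)
        haz = 0.1 * np.exp(0.7 * x1 - 0.3 * x2)
        t = np.round(rng.exponential(1 / haz), 1)  # rounding induces ties
        e = (rng.random(n) > 0.2).astype(int)
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        res = cox_fit(t, e, df[["x1", "x2"]])
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(res.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(), atol=1e-5)
        assert res.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_efron_equals_breslow_without_ties(self):
        table = simulate_two_group_survival(100, 1.5, 0.1, seed=2)
        t = table.data["dfs_months"]
        e = table.data["dfs_event"]
        x = table.data[["group"]]
        a = cox_fit(t, e, x, ties="efron")
        b = cox_fit(t, e, x, ties="breslow")
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Covariate independent of outcome: p-values center at 1/2."""
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(200):
            table = simulate_two_group_survival(50, 1.0, 0.1, seed=seed)
            x = rng.permutation(table.data["group"].to_numpy()).astype(float)
            res = cox_fit(table.data["dfs_months"], table.data["dfs_event"], x[:, None])
            ps.append(res.pvalues[0])
        assert abs(np.mean(ps) - 0.5) < 0.05

    def test_score_test_equals_logrank(self):
        """Classical identity: Cox score test at beta=0 is the two-group
        log-rank chi-square (untied event times)."""
        table = simulate_two_group_survival(80, 2.5, 0.1, seed=9)
        df = table.data
        assert df["dfs_months"].nunique() == len(df)  # no ties
        chi2_score, _ = cox_score_test(df["dfs_months"], df["dfs_event"], df["group"])
        groups = {
            g: (sub["dfs_months"], sub["dfs_event"]) for g, sub in df.groupby("group")
        }
        chi2_lr, _ = logrank_test(groups)
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 0], np.ones((3, 1)))

    def test_monotone_likelihood_named(self):
        # perfectly separating covariate: all events in one arm, far apart
        t = np.r_[np.linspace(1, 2, 20), np.linspace(10, 11, 20)]
        e = np.r_[np.ones(20, int), np.ones(20, int)]
        x = pd.DataFrame({"sep": np.r_[np.ones(20), np.zeros(20)]})
        with pytest.raises(RuntimeError, match="sep"):
            cox_fit(t, e, x)


class TestExactAndWelch:
    def test_fisher_perfect_association_one_sided(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]], alternative="greater")
        assert p == pytest.approx(1 / comb(20, 10, exact=True), rel=1e-10)

    def test_fisher_symmetric_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        """Two-sided p = sum of hypergeometric probabilities <= observed."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            tab = rng.integers(0, 8, (2, 2))
            if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
                continue
            r1, r2 = tab.sum(1)
            c1 = tab.sum(0)[0]
            n = tab.sum()
            probs = []
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs.append(stats.hypergeom.pmf(a, n, r1, c1))
            obs = stats.hypergeom.pmf(tab[0, 0], n, r1, c1)
            p_enum = sum(pr for pr in probs if pr <= obs * (1 + 1e-10))
            assert fisher_exact_2x2(tab) == pytest.approx(p_enum, abs=1e-10)

    def test_fisher_zero_margin(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_welch_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], tails=2)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_satterthwaite_df(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 20.0, 30.0])
        t, df, p = welch_t(a, b, tails=2)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert df == pytest.approx(ref.df)
        assert p == pytest.approx(ref.pvalue)

    def test_welch_one_tailed_direction(self):
        a = [5.0, 6.0, 7.0]
        b = [1.0, 2.0, 3.0]
        _, _, p_greater = welch_t(a, b, tails=1, alternative="greater")
        _, _, p_less = welch_t(a, b, tails=1, alternative="less")
        assert p_greater < 0.05 < p_less
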