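import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dragonmorph import simulate
from dragonmorph.stats import (
    anova_time,
    fdr_bh,
    fit_timecourse,
    freeman_halton_exact,
    pairwise_adjusted,
    per_morph_trend,
)


def balanced_panel(cell_means, n_females=4, noise=None):
    """Fully crossed panel: every female at every timepoint."""
    rows = []
    for i in range(n_females):
        for t, mu in cell_means.items():
            eps = 0.0 if noise is None else noise[(i, t)]
            rows.append((f"F{i:02d}", t, mu + eps))
    return pd.DataFrame(rows, columns=["female_id", "timepoint",
                                       "testosterone"])


class TestAnovaTime:
    def test_study_design_degrees_of_freedom(self, hormone_panel):
        """44 records from 18 females at 3 timepoints yield the (2, 24)
        blocked design: 44 - 1 - 17 - 2 = 24 error df."""
        res = anova_time(hormone_panel)
        assert res.n_records == 44
        assert res.n_females == 18
        assert (res.df_num, res.df_den) == (2, 24)

    def test_null_when_response_depends_on_female_only(self):
        rng = np.random.default_rng(0)
        female_effect = {i: float(rng.uniform(50, 150)) for i in range(6)}
        rows = [(f"F{i}", t, female_effect[i])
                for i in range(6) for t in ("pre", "week1", "week4")]
        panel = pd.DataFrame(rows, columns=["female_id", "timepoint",
                                            "testosterone"])
        res = anova_time(panel)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-18)

    def test_balanced_panel_matches_hand_anova(self):
        """On a balanced 3x3 design the timepoint F equals the classical
        randomized-block decomposition computed by hand."""
        rng = np.random.default_rng(1)
        tps = ("pre", "week1", "week4")
        means = {"pre": 50.0, "week1": 250.0, "week4": 130.0}
        noise = {(i, t): float(rng.normal(0, 20))
                 for i in range(3) for t in tps}
        panel = balanced_panel(means, n_females=3, noise=noise)
        y = panel.pivot(index="female_id", columns="timepoint",
                        values="testosterone").loc[:, list(tps)].to_numpy()
        grand = y.mean()
        ss_time = y.shape[0] * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_female = y.shape[1] * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_time - ss_female
        df_err = (y.shape[0] - 1) * (y.shape[1] - 1)
        f_hand = (ss_time / 2) / (ss_err / df_err)
        res = anova_time(panel)
        assert res.f_statistic == pytest.approx(f_hand, rel=1e-9)
        assert res.df_den == df_err

    def test_female_constant_shift_invariance(self, hormone_panel):
        """Adding a per-female constant is absorbed by the female factor."""
        res0 = anova_time(hormone_panel)
        shifted = hormone_panel.copy()
        offs = {f: 10.0 * k for k, f in
                enumerate(sorted(shifted["female_id"].unique()))}
        shifted["testosterone"] += shifted["female_id"].map(offs)
        res1 = anova_time(shifted)
        assert res1.f_statistic == pytest.approx(res0.f_statistic, rel=1e-8)

    def test_duplicate_records_rejected(self, hormone_panel):
        dup = pd.concat([hormone_panel, hormone_panel.iloc[[0]]],
                        ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            anova_time(dup)

    def test_lsmeans_recover_cell_means_when_balanced(self):
        means = {"pre": 50.0, "week1": 250.0, "week4": 130.0}
        rng = np.random.default_rng(2)
        noise = {(i, t): float(rng.normal(0, 1))
                 for i in range(5) for t in means}
        res = anova_time(balanced_panel(means, n_females=5, noise=noise))
        for t, mu in means.items():
            est, se = res.lsmeans[t]
            assert est == pytest.approx(np.mean(
                [mu + noise[(i, t)] for i in range(5)]), abs=1e-9)


class TestPairwise:
    def test_null_gives_t_zero_p_one(self):
        panel = balanced_panel({"pre": 100.0, "week1": 100.0, "week4": 100.0},
                               n_females=4,
                               noise={(i, t): float(np.random.default_rng(
                                   i * 7 + hash(t) % 97).normal(0, 5))
                                   for i in range(4)
                                   for t in ("pre", "week1", "week4")})
        # same female noise per timepoint would be singular; reuse anova noise
        res = pairwise_adjusted(panel)
        for p in res:
            assert p.p_adjusted >= p.p_unadjusted - 1e-12

    def test_adjusted_at_least_unadjusted(self, hormone_panel):
        for p in pairwise_adjusted(hormone_panel):
            assert p.p_adjusted >= p.p_unadjusted - 1e-12

    def test_balanced_t_matches_hand_formula(self):
        """Balanced design: t = (mean_a - mean_b) / (s * sqrt(2/n)) with s^2
        the blocked-ANOVA error mean square."""
        rng = np.random.default_rng(3)
        tps = ("pre", "week1", "week4")
        noise = {(i, t): float(rng.normal(0, 15))
                 for i in range(6) for t in tps}
        panel = balanced_panel({"pre": 60.0, "week1": 260.0, "week4": 130.0},
                               n_females=6, noise=noise)
        y = panel.pivot(index="female_id", columns="timepoint",
                        values="testosterone").loc[:, list(tps)].to_numpy()
        grand = y.mean()
        ss_time = 6 * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_female = 3 * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((y - grand) ** 2).sum() - ss_time - ss_female
        s2 = ss_err / 10.0
        results = {p.pair: p for p in pairwise_adjusted(panel)}
        t_hand = ((y[:, 0].mean() - y[:, 1].mean())
                  / np.sqrt(s2 * 2.0 / 6.0))
        assert results[("pre", "week1")].t_statistic == pytest.approx(
            t_hand, rel=1e-9)

    def test_week1_spike_detected(self, hormone_panel):
        results = {p.pair: p for p in pairwise_adjusted(hormone_panel)}
        assert results[("pre", "week1")].p_adjusted < 0.001
        assert results[("pre", "week1")].t_statistic < 0


class TestFreemanHalton:
    def test_hand_enumerated_2x2(self):
        """[[3,1],[1,3]]: 5 tables share the margins; summing the
        hypergeometric mass of those at most as probable gives 34/70."""
        res = freeman_halton_exact([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)
        assert res.n_tables == 5

    def test_uniform_2x2_is_one(self):
        res = freeman_halton_exact([[1, 1], [1, 1]])
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_single_feasible_table(self):
        res = freeman_halton_exact([[2, 0], [0, 3]])
        assert res.p_value <= 1.0
        assert res.n_tables >= 1

    def test_matches_classic_fisher_on_random_2x2(self, rng):
        """On 50 random 2x2 tables the Freeman-Halton enumeration equals
        scipy's two-sided Fisher exact probability."""
        for _ in range(50):
            t = rng.integers(0, 11, size=(2, 2))
            t[0, 0] += 1
            t[1, 1] += 1   # ensure positive margins
            ours = freeman_halton_exact(t).p_value
            ref = sps.fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_morph_frequency_table_shape(self):
        # 2 x 4 sex-by-morph counts: female row from the study
        res = freeman_halton_exact([[10, 7, 7, 11], [12, 9, 8, 13]])
        assert 0 < res.p_value <= 1
        assert res.method == "enumeration"

    def test_enumeration_bound_enforced(self):
        big = np.full((2, 4), 40)
        with pytest.raises(ValueError, match="enumeration bound"):
            freeman_halton_exact(big)
        res = freeman_halton_exact(big, monte_carlo=True, seed=1,
                                   n_samples=2000)
        assert res.method == "monte_carlo"
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            freeman_halton_exact([[0, 0], [1, 2]])


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(0.001, 1.0, size=25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_threshold_reproduces_step_up_rejections(self, rng):
        """Adjusted p <= q selects exactly the BH step-up rejection set."""
        q = 0.05
        p = np.sort(rng.uniform(0.0001, 0.5, size=15))
        m = len(p)
        k = max([i + 1 for i in range(m) if p[i] <= (i + 1) / m * q],
                default=0)
        rejected_by_rule = set(range(k))
        rejected_by_adj = set(np.flatnonzero(fdr_bh(p) <= q))
        assert rejected_by_adj == rejected_by_rule

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 0.0])
        with pytest.raises(ValueError):
            fdr_bh([1.2])


class TestTimecourseModels:
    def test_zero_variance_components_reduce_to_ols(self):
        """With no female heterogeneity the mixed-model F values equal the
        ordinary least-squares fit of the same fixed effects."""
        import statsmodels.formula.api as smf
        tc = simulate.gen_timecourse(intercept_sd=0.0, residual_sd=0.03,
                                     seed=31)
        fit = fit_timecourse(tc)
        df = tc.copy()
        df["time"] = df["week"]
        df["time2"] = df["time"] ** 2
        ols = smf.ols("value ~ time + time2 + C(morph, Sum) "
                      "+ C(morph, Sum):time + C(morph, Sum):time2",
                      data=df).fit()
        # OLS F for the morph:time^2 term via a Wald test on its columns
        names = [n for n in ols.params.index if ":time2" in n]
        L = np.zeros((len(names), len(ols.params)))
        for r, n in enumerate(names):
            L[r, list(ols.params.index).index(n)] = 1.0
        f_ols = float(ols.f_test(L).fvalue)
        f_lmm = fit.fixed_effects.loc["morph:time^2", "F"]
        assert fit.intercept_variance < 1e-4
        assert f_lmm == pytest.approx(f_ols, rel=0.05)

    def test_quadratic_signal_detected_in_orange_morphs(self, timecourse):
        fit = fit_timecourse(timecourse)
        assert fit.fixed_effects.loc["morph:time^2", "p_value"] < 0.001
        assert fit.fixed_effects.loc["time", "p_value"] < 0.001
        assert fit.intercept_variance > 0

    def test_flat_trajectories_give_null_interaction(self):
        flat = {m: (0.2, 0.0, 0.0) for m in simulate.MORPH_COUNTS}
        tc = simulate.gen_timecourse(coefficients=flat, seed=33)
        fit = fit_timecourse(tc)
        assert fit.fixed_effects.loc["morph:time^2", "p_value"] > 0.01

    def test_constant_response_is_degenerate(self):
        tc = simulate.gen_timecourse(intercept_sd=0.0, residual_sd=0.0,
                                     coefficients={m: (0.5, 0.0, 0.0)
                                                   for m in ("orange",
                                                             "yellow")},
                                     seed=34)
        with pytest.raises(ValueError, match="degenerate|zero variance"):
            fit_timecourse(tc)

    def test_per_morph_trend_consistency(self, timecourse):
        """Morphs generated with a quadratic trajectory show a quadratic
        trend; flat morphs do not."""
        rising = per_morph_trend(timecourse, "orange")
        flat = per_morph_trend(timecourse, "grey")
        assert rising.fixed_effects.loc["time^2", "p_value"] < 0.01
        assert flat.fixed_effects.loc["time^2", "p_value"] > 0.01

    def test_single_week_rejected(self):
        tc = simulate.gen_timecourse(weeks=(3,), seed=35)
        with pytest.raises(ValueError, match="weeks"):
            fit_timecourse(tc)
        with pytest.raises(ValueError, match="weeks"):
            per_morph_trend(tc, "orange")

    def test_unknown_morph_rejected(self, timecourse):
        with pytest.raises(ValueError, match="no records"):
            per_morph_trend(timecourse, "blue")
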