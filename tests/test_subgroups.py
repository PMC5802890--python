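"""Subgroup assignment, KM/HR summaries, screens and backward-AIC Cox."""

import numpy as np
import pandas as pd
import pytest

from cutscan import (ClinicalTable, SurvivalOutcome, assign_subgroups,
                     dichotomize, multivariate_cox_backward_aic,
                     survival_summary, univariate_screen)

from conftest import ids, make_outcome, make_trait
from oracles import km_product_limit


class TestAssignSubgroups:
    def test_three_groups_floor_arithmetic(self, toy_trait):
        asg = assign_subgroups(toy_trait, [30, 70])
        assert asg.group_sizes == {"low": 3, "inter": 4, "high": 3}

    def test_single_cutpoint(self):
        t = make_trait(np.arange(100.0))
        asg = assign_subgroups(t, [75])
        assert asg.group_sizes == {"low": 75, "high": 25}

    def test_empty_group_names_cutpoint(self):
        t = make_trait(np.arange(5.0))
        with pytest.raises(ValueError, match="empty low group at cutpoint 10"):
            assign_subgroups(t, [10, 11])

    def test_matches_dichotomize_at_same_cut(self, toy_trait):
        asg = assign_subgroups(toy_trait, [50])
        lab = dichotomize(toy_trait, 50)
        assert np.array_equal(asg.mask("high").astype(int), lab.group)

    def test_groups_ordered_by_rank(self):
        rng = np.random.default_rng(0)
        t = make_trait(rng.normal(size=40))
        asg = assign_subgroups(t, [25, 75])
        assert t.values[asg.mask("low")].max() <= t.values[asg.mask("inter")].min()
        assert t.values[asg.mask("inter")].max() <= t.values[asg.mask("high")].min()


class TestSurvivalSummary:
    def test_km_matches_hand_product_limit(self):
        # 6-sample toy, all events: the low group's KM steps are 1 - k/3
        t = make_trait(np.arange(6.0))
        o = make_outcome([1., 2., 3., 4., 5., 6.], np.ones(6, int))
        asg = assign_subgroups(t, [50])
        summ = survival_summary(asg, o)
        km_t, km_s = km_product_limit([1., 2., 3.], [1, 1, 1])
        low = summ.km_curves["low"]
        got = low.set_index("time")["survival"]
        for tt, ss in zip(km_t, km_s):
            assert got.loc[tt] == pytest.approx(ss)

    def test_km_curves_monotone_and_start_at_one(self, planted_cohort):
        trait, outcome = planted_cohort
        summ = survival_summary(assign_subgroups(trait, [25, 75]), outcome)
        assert set(summ.km_curves) == {"low", "inter", "high"}
        for df in summ.km_curves.values():
            s = df["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert (np.diff(s) <= 1e-12).all()
            assert (np.diff(df["n_at_risk"].to_numpy()) <= 0).all()

    def test_identical_groups_hr_near_one(self):
        times = np.array([1., 2., 3., 4., 5., 1., 2., 3., 4., 5.])
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1, 1])
        t = make_trait(np.r_[np.zeros(5), np.ones(5)])
        o = make_outcome(times, events)
        summ = survival_summary(assign_subgroups(t, [50]), o)
        assert summ.hazard_ratios.loc["high", "hr"] == pytest.approx(1.0, abs=1e-6)

    def test_three_groups_two_hrs_vs_low(self, planted_cohort):
        trait, outcome = planted_cohort
        summ = survival_summary(assign_subgroups(trait, [25, 75]), outcome)
        assert list(summ.hazard_ratios.index) == ["inter", "high"]
        # hazard jump planted at 75%: only the high group departs from low
        assert summ.hazard_ratios.loc["high", "hr"] > 1.5

    def test_zero_event_group_flagged(self):
        t = make_trait(np.arange(6.0))
        o = make_outcome([1., 2., 3., 9., 9., 9.], [1, 1, 1, 0, 0, 0])
        summ = survival_summary(assign_subgroups(t, [50]), o)
        assert any("zero events" in f for f in summ.flags)


def _clinical(df, types):
    return ClinicalTable(df, types)


class TestUnivariateScreen:
    def test_identically_distributed_categorical(self):
        df = pd.DataFrame({"sex": ["M", "F"] * 10}, index=ids(20))
        groups = np.array([0] * 10 + [1] * 10)
        res = univariate_screen(_clinical(df, {"sex": "categorical"}), groups)
        assert res.loc["sex", "p"] == 1.0

    def test_exact_wilcoxon_most_extreme_arrangement(self):
        # {1,2,3} vs {4,5,6}: 2 of C(6,3)=20 arrangements are this extreme
        df = pd.DataFrame({"age": [1., 2., 3., 4., 5., 6.]}, index=ids(6))
        groups = np.array([0, 0, 0, 1, 1, 1])
        res = univariate_screen(_clinical(df, {"age": "continuous"}), groups)
        assert res.loc["age", "p"] == pytest.approx(0.1)
        assert res.loc["age", "test"] == "wilcoxon-exact"

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame({"stage": ["II"] * 8}, index=ids(8))
        res = univariate_screen(_clinical(df, {"stage": "categorical"}),
                                np.array([0, 1] * 4))
        assert np.isnan(res.loc["stage", "p"])
        assert res.loc["stage", "note"] == "constant covariate"

    def test_multilevel_categorical_falls_back_to_chi2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"grade": rng.choice(list("ABC"), 60)}, index=ids(60))
        res = univariate_screen(_clinical(df, {"grade": "categorical"}),
                                rng.integers(0, 2, 60))
        assert res.loc["grade", "test"] == "chi2"
        assert "k>2" in res.loc["grade", "note"]


class TestBackwardAIC:
    @staticmethod
    def _cohort(seed, n=150, with_noise=True):
        rng = np.random.default_rng(seed)
        strong = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(1.2 * strong)))
        e = (rng.random(n) > 0.2).astype(int)
        sids = ids(n)
        cols = {"strong": strong}
        if with_noise:
            cols["noise"] = noise
        clin = ClinicalTable(pd.DataFrame(cols, index=sids),
                             {k: "continuous" for k in cols})
        return clin, SurvivalOutcome(sids, np.maximum(t, 1e-9), e)

    def test_single_strong_covariate_retained(self):
        clin, outcome = self._cohort(3, with_noise=False)
        model = multivariate_cox_backward_aic(clin, outcome)
        assert model.retained == ("strong",)
        assert model.trace == ()

    def test_noise_covariate_eliminated_most_runs(self):
        # with the univariate screen in front, noise must first reach p<0.05
        # (~5% of runs) and then survive backward-AIC
        kept_noise = kept_strong = 0
        for seed in range(15):
            clin, outcome = self._cohort(100 + seed)
            model = multivariate_cox_backward_aic(clin, outcome)
            kept_noise += any(c.startswith("noise") for c in model.retained)
            kept_strong += "strong" in model.retained
        assert kept_noise <= 2
        assert kept_strong >= 13

    def test_all_fail_screen_returns_empty_model(self):
        rng = np.random.default_rng(9)
        n = 100
        sids = ids(n)
        clin = ClinicalTable(pd.DataFrame({"noise": rng.normal(size=n)}, index=sids),
                             {"noise": "continuous"})
        outcome = SurvivalOutcome(sids, rng.exponential(10, n) + 1e-9,
                                  (rng.random(n) > 0.2).astype(int))
        model = multivariate_cox_backward_aic(clin, outcome)
        assert model.summary is None
        assert "no covariate passed screen" in model.flags

    def test_trace_aic_strictly_decreasing_and_final_is_minimum(self):
        rng = np.random.default_rng(77)
        n = 200
        sids = ids(n)
        strong = rng.integers(0, 2, n).astype(float)
        cols = {"strong": strong,
                "n1": rng.normal(size=n), "n2": rng.normal(size=n),
                "n3": rng.normal(size=n)}
        clin = ClinicalTable(pd.DataFrame(cols, index=sids),
                             {k: "continuous" for k in cols})
        t = rng.exponential(1 / (0.1 * np.exp(1.0 * strong)))
        outcome = SurvivalOutcome(sids, np.maximum(t, 1e-9),
                                  (rng.random(n) > 0.2).astype(int))
        model = multivariate_cox_backward_aic(clin, outcome, candidates=list(cols))
        aics = [a for _, a in model.trace]
        assert all(b < a for a, b in zip(aics, aics[1:])) or len(aics) <= 1
        if aics:
            assert model.aic == pytest.approx(min(aics))
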