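"""Kaplan-Meier, log-rank and Cox proportional hazards (Breslow ties)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmeta.datatypes import SurvivalTable
from mirmeta.simulate import SurvivalSimSpec, simulate_survival_cohort
from mirmeta.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    median_dichotomize,
    stepwise_cox,
    univariate_screen,
)


def table(times, events, **covs):
    return SurvivalTable(pd.DataFrame({"time": times, "event": events, **covs}))


class TestMedianDichotomize:
    def test_even_split(self):
        assert median_dichotomize([1, 2, 3, 4]).tolist() == [
            "low", "low", "high", "high"]

    def test_median_value_goes_high(self):
        # odd n: the subject at the median is "high" (>= rule)
        assert median_dichotomize([1, 2, 3]).tolist() == ["low", "high", "high"]

    def test_group_size_imbalance_bounded_by_ties(self):
        # under the ">= median -> high" rule the tied subjects all go high,
        # so the imbalance is bounded by twice the tie count
        # (e.g. (1, 1, 1, 2, 3) splits 5/0 with 3 tied at the median)
        rng = np.random.default_rng(1)
        for n in range(2, 9):
            for _ in range(50):
                x = rng.integers(0, 4, size=n).astype(float)
                if np.ptp(x) == 0:
                    continue
                g = median_dichotomize(x)
                n_tied = (x == np.median(x)).sum()
                assert abs((g == "high").sum() - (g == "low").sum()) <= 2 * n_tied

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            median_dichotomize([2.0, 2.0, 2.0])


class TestKaplanMeier:
    def test_all_censored_survival_one(self):
        km = km_estimate(table([1, 2, 3], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_three_events_product_formula(self):
        km = km_estimate(table([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_interleaved_censoring_worked_example(self):
        # times 1, 2+, 3, 4+, 5, 6 with events at 1, 3, 5, 6
        km = km_estimate(table([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1]))
        assert km.survival_at(3) == pytest.approx((5 / 6) * (3 / 4))
        assert km.survival_at(5) == pytest.approx((5 / 6) * (3 / 4) * (1 / 2))
        assert km.survival_at(6) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40)
        km = km_estimate(table(t, np.ones(40, dtype=int)))
        for u in [1.0, 5.0, 15.0]:
            assert km.survival_at(u) == pytest.approx((t > u).mean())

    def test_greenwood_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        km = km_estimate(table(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = km.survival
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            table([-1, 2], [1, 1])


class TestLogRank:
    def test_duplicated_groups_chi2_zero(self):
        g = table([1, 3, 5, 7, 9], [1, 1, 0, 1, 0])
        chi2, p = logrank_test(g, g)
        assert chi2 == 0.0
        assert p == 1.0

    def test_separated_groups_hand_oracle(self):
        # A: 5 events at t=1; B: 5 events at t=10
        # t=1: O-E = 5 - 5*(5/10) = 2.5, V = 5*(1/4)*(5/9)
        a = table([1] * 5, [1] * 5)
        b = table([10] * 5, [1] * 5)
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(2.5**2 / (5 * 0.25 * 5 / 9))
        assert chi2 == pytest.approx(9.0)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = table(rng.exponential(10, 20), rng.integers(0, 2, 20) | 1)
        b = table(rng.exponential(14, 25), rng.integers(0, 2, 25) | 1)
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], abs=1e-12)

    def test_null_pvalues_uniform(self):
        ps = []
        for rep in range(500):
            marker = np.random.default_rng(900_000 + rep).normal(size=60)
            spec = SurvivalSimSpec(n_subjects=60, beta=(0.0,), baseline_rate=0.05,
                                   censor_rate=0.03, seed=3000 + rep)
            tab = simulate_survival_cohort(spec, pd.DataFrame({"m": marker}))
            grp = median_dichotomize(tab.data["m"])
            ps.append(logrank_test(tab.subset(grp == "high"),
                                   tab.subset(grp == "low"))[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(table([1, 2], [0, 0]), table([3, 4], [0, 0]))


class TestCox:
    def _cohort(self, n=400, beta=(0.7,), seed=5, censor=0.03):
        x = np.random.default_rng(seed + 10_000).normal(size=(n, len(beta)))
        spec = SurvivalSimSpec(n_subjects=n, beta=beta, baseline_rate=0.05,
                               censor_rate=censor, seed=seed)
        return simulate_survival_cohort(spec, x)

    def test_null_loglik_identity(self):
        # at beta = 0 the Breslow partial loglik is -sum(log |risk set|)
        tab = self._cohort(n=50, seed=2)
        fit = cox_fit(tab, ["x1"])
        t, d = tab.time, tab.event
        ref = -sum(np.log((t >= u).sum()) for u in t[d == 1])
        assert fit.loglik_null == pytest.approx(ref, abs=1e-9)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        tab = self._cohort(n=300, beta=(0.5, -0.3), seed=9)
        fit = cox_fit(tab, ["x1", "x2"])
        cph = CoxPHFitter().fit(tab.data, "time", "event")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_score_test_equals_logrank(self):
        rng = np.random.default_rng(15)
        n = 80
        x = rng.integers(0, 2, n)
        t = rng.exponential(10 / (1 + x), size=n)  # tie-free continuous times
        tab = table(t, np.ones(n, dtype=int), group=x.astype(float))
        chi2_lr, _ = logrank_test(tab.subset(x == 1), tab.subset(x == 0))
        assert cox_score_test(tab, "group") == pytest.approx(chi2_lr, abs=1e-6)

    def test_null_covariate_wald_calibrated(self):
        rejections = 0
        for rep in range(60):
            x = np.random.default_rng(rep).normal(size=(500, 1))
            spec = SurvivalSimSpec(n_subjects=500, beta=(0.0,), baseline_rate=0.05,
                                   censor_rate=0.03, seed=50_000 + rep)
            tab = simulate_survival_cohort(spec, x)
            fit = cox_fit(tab, ["x1"])
            assert abs(fit.beta[0]) < 0.5
            rejections += fit.wald_p[0] < 0.05
        assert rejections <= 9  # ~5% of 60, generous binomial bound

    def test_time_rescaling_and_covariate_shift_invariance(self):
        tab = self._cohort(n=200, seed=11)
        fit = cox_fit(tab, ["x1"])
        data2 = tab.data.copy()
        data2["time"] = data2["time"] * 30.4  # months -> days
        data2["x1"] = data2["x1"] + 100.0
        fit2 = cox_fit(SurvivalTable(data2), ["x1"])
        assert fit2.beta[0] == pytest.approx(fit.beta[0], abs=1e-7)

    def test_wald_ci_coverage(self):
        cover = 0
        for rep in range(200):
            x = np.random.default_rng(600_000 + rep).normal(size=(300, 1))
            spec = SurvivalSimSpec(n_subjects=300, beta=(0.7,), baseline_rate=0.05,
                                   censor_rate=0.03, seed=70_000 + rep)
            fit = cox_fit(simulate_survival_cohort(spec, x), ["x1"])
            lo, hi = fit.beta[0] - 1.96 * fit.se[0], fit.beta[0] + 1.96 * fit.se[0]
            cover += lo <= 0.7 <= hi
        assert 0.92 <= cover / 200 <= 0.98

    def test_separation_flagged(self):
        # covariate perfectly ordered with event time -> monotone likelihood
        n = 30
        t = np.arange(1.0, n + 1)
        tab = table(t, np.ones(n, dtype=int), x=t.astype(float))
        fit = cox_fit(tab, ["x"])
        assert fit.flagged_separation

    def test_constant_covariate_rejected(self):
        tab = self._cohort(n=50, seed=3)
        tab.data["c"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            cox_fit(tab, ["c"])


class TestScreenAndStepwise:
    def _panel(self, seed, n=300, hr=3.0):
        X = pd.DataFrame(
            np.random.default_rng(seed + 1_000_000).normal(size=(n, 4)),
            columns=["prog", "noise1", "noise2", "noise3"],
        )
        spec = SurvivalSimSpec(n_subjects=n, beta=(np.log(hr), 0, 0, 0),
                               baseline_rate=0.05, censor_rate=0.03, seed=seed)
        return simulate_survival_cohort(spec, X)

    def test_strong_covariate_always_screened_in(self):
        hits = sum(
            "prog" in univariate_screen(self._panel(rep), ["prog"], 0.05)[0]
            for rep in range(20)
        )
        assert hits == 20

    def test_noise_screened_out_at_nominal_rate(self):
        incl = 0
        for rep in range(60):
            sel, tab = univariate_screen(self._panel(rep), ["noise1"], 0.05)
            incl += "noise1" in sel
        assert incl <= 9

    def test_empty_candidate_list(self):
        sel, tab = univariate_screen(self._panel(0), [], 0.05)
        assert sel == [] and len(tab) == 0
        fit = stepwise_cox(self._panel(0), [])
        assert fit.covariates == []
        assert fit.loglik == fit.loglik_null

    def test_duplicated_covariate_enters_once(self):
        tab = self._panel(5)
        tab.data["prog_copy"] = tab.data["prog"]
        fit = stepwise_cox(tab, ["prog", "prog_copy"], 0.05, 0.05)
        assert fit.covariates == ["prog"]  # tie broken by name, copy skipped

    def test_no_candidate_below_p_enter_gives_null_model(self):
        tab = self._panel(6)
        fit = stepwise_cox(tab, ["noise1"], p_enter=1e-9, p_remove=1e-9)
        assert fit.covariates == []
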