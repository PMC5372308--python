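"""The integrated test: moderated t, permutation null, Fisher combination,
Hedges' g and DerSimonian-Laird pooling."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirmeta.config import PipelineConfig
from mirmeta.datatypes import MetaDataset
from mirmeta.meta_de import (
    combine_effects,
    estimate_fudge,
    fisher_combine,
    hedges_g,
    meta_significance,
    moderated_t,
    permute_study,
)

from conftest import make_study


class TestModeratedT:
    def test_identical_means_zero(self):
        t, md = moderated_t([1.0, 2.0], [2.0, 1.0], s0=0.7)
        assert t == 0.0 and md == 0.0

    def test_s0_zero_is_student_t(self):
        rng = np.random.default_rng(5)
        case, ctrl = rng.normal(size=8), rng.normal(size=6)
        t, _ = moderated_t(case, ctrl, s0=0.0)
        ref = stats.ttest_ind(case, ctrl).statistic
        assert abs(t - ref) < 1e-12

    def test_hand_oracle(self):
        # case (3,5), control (1,3): sp^2 = 2, se = sqrt(2), t = 2/(sqrt(2)+0.5)
        t, md = moderated_t([3.0, 5.0], [1.0, 3.0], s0=0.5)
        assert md == 2.0
        assert abs(t - 2.0 / (math.sqrt(2.0) + 0.5)) < 1e-12

    def test_constant_data_undefined(self):
        t, md = moderated_t([1.0, 1.0], [1.0, 1.0], s0=0.0)
        assert math.isnan(t) and md == 0.0


class TestEstimateFudge:
    def test_common_spread_gives_common_se(self):
        sm = make_study([[0.0, 2, 0, 2], [5.0, 7, 5, 7]], "TTNN")
        se = math.sqrt(2.0) * math.sqrt(0.5 + 0.5)  # sp=sqrt(2) per feature
        assert abs(estimate_fudge(sm, 0.5) - se) < 1e-12

    def test_quantile_zero_is_minimum(self, toy_study):
        from mirmeta.meta_de import _se_terms

        se = _se_terms(toy_study.values.to_numpy(), toy_study.class_mask("T"))
        assert estimate_fudge(toy_study, 0.0) == pytest.approx(se.min())

    def test_matches_sorted_quantile_oracle(self):
        rng = np.random.default_rng(10)
        sm = make_study(rng.normal(8, 1, size=(100, 10)), "TTTTTNNNNN")
        from mirmeta.meta_de import _se_terms

        se = np.sort(_se_terms(sm.values.to_numpy(), sm.class_mask("T")))
        assert estimate_fudge(sm, 0.3) == pytest.approx(np.quantile(se, 0.3))


class TestFisherCombine:
    def test_all_ones_zero(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == 0.0

    def test_closed_form(self):
        assert fisher_combine([0.1, 0.1]) == pytest.approx(9.21034, abs=1e-5)

    def test_order_invariant(self):
        assert fisher_combine([0.2, 0.7, 0.05]) == pytest.approx(
            fisher_combine([0.7, 0.05, 0.2]))

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.data())
    def test_monotone_in_each_p(self, ps, data):
        i = data.draw(st.integers(0, len(ps) - 1))
        smaller = list(ps)
        smaller[i] = ps[i] / 2
        assert fisher_combine(smaller) > fisher_combine(ps)


class TestPermutationNull:
    def _enumeration_oracle(self, sm, s0):
        """Brute force over all case-assignments using the scalar statistic."""
        X = sm.values.to_numpy()
        n = X.shape[1]
        n1 = int(sm.class_mask("T").sum())
        obs_idx = tuple(np.where(sm.class_mask("T"))[0])
        out = []
        for f in range(X.shape[0]):
            ts = {}
            for idx in combinations(range(n), n1):
                ctrl = [j for j in range(n) if j not in idx]
                ts[idx] = moderated_t(X[f, list(idx)], X[f, ctrl], s0)[0]
            t_obs = round(ts[obs_idx], 10)
            vals = np.round(list(ts.values()), 10)
            out.append((np.abs(vals) >= abs(t_obs)).sum() / len(vals))
        return np.array(out)

    def test_exact_enumeration_equals_brute_force(self):
        rng = np.random.default_rng(17)
        sm = make_study(rng.normal(0, 1, size=(10, 6)), "TTTNNN")
        s0 = estimate_fudge(sm)
        with pytest.warns(UserWarning, match="exact enumeration"):
            res = permute_study(sm, B=30, s0=s0, seed=0)
        assert res.exact
        np.testing.assert_allclose(res.p_two, self._enumeration_oracle(sm, s0),
                                   rtol=0, atol=0)

    def test_n2_grid(self):
        rng = np.random.default_rng(3)
        sm = make_study(rng.normal(size=(5, 4)), "TTNN")
        with pytest.warns(UserWarning):
            res = permute_study(sm, B=10, s0=0.1, seed=0)
        grid = np.arange(1, 7) / 6.0
        assert np.isin(np.round(res.p_two, 12), np.round(grid, 12)).all()

    def test_constant_feature_p_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(4, 10))
        vals[2] = 3.14
        sm = make_study(vals, "TTTTTNNNNN")
        res = permute_study(sm, B=99, s0=0.5, seed=1)
        assert res.p_two[2] == 1.0

    def test_one_sided_pvalues_cover_both_tails(self):
        rng = np.random.default_rng(9)
        sm = make_study(rng.normal(size=(20, 12)), "TTTTTTNNNNNN")
        res = permute_study(sm, B=50, s0=0.2, seed=2)
        assert (res.p_up + res.p_down >= 1.0 - 1e-12).all()
        assert (res.p_two >= 1.0 / res.n_pool).all()


class TestHedgesG:
    def test_equal_means(self):
        g, v = hedges_g([1.0, 3.0], [3.0, 1.0])
        assert g == 0.0
        assert v == pytest.approx(4.0 / 4.0)

    def test_hand_oracle(self):
        # case (2,4), control (0,2): d = sqrt(2), J = 4/7
        g, v = hedges_g([2.0, 4.0], [0.0, 2.0])
        assert g == pytest.approx((4.0 / 7.0) * math.sqrt(2.0), abs=1e-12)
        assert v == pytest.approx(1.0 + g * g / 8.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(1, 1, 7), rng.normal(0, 1, 9)
        assert hedges_g(a, b)[0] == pytest.approx(-hedges_g(b, a)[0], abs=1e-12)

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError, match="pooled SD"):
            hedges_g([1.0, 1.0], [1.0, 1.0])


class TestCombineEffects:
    def test_single_study(self):
        pe = combine_effects([0.4], [0.09])
        assert pe.mu_fixed == pe.mu_random == 0.4
        assert pe.tau2 == 0.0

    def test_two_identical_studies(self):
        pe = combine_effects([0.5, 0.5], [0.04, 0.04])
        assert pe.mu_fixed == pytest.approx(0.5)
        assert pe.se_fixed == pytest.approx(math.sqrt(0.04 / 2))
        assert pe.Q == pytest.approx(0.0, abs=1e-14)
        assert pe.I2 == 0.0

    def test_heterogeneous_hand_oracle(self):
        # w = 25 each, mu = 0.8, Q = 18, df = 2, tau2 = 16/50
        pe = combine_effects([0.2, 0.8, 1.4], [0.04, 0.04, 0.04])
        assert pe.mu_fixed == pytest.approx(0.8)
        assert pe.Q == pytest.approx(18.0)
        assert pe.tau2 == pytest.approx(16.0 / 50.0)
        assert pe.se_random > pe.se_fixed
        assert 0 <= pe.I2 <= 100

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            combine_effects([0.1, 0.2], [0.04, 0.0])


class TestMetaSignificance:
    def test_planted_up_feature_called_up(self):
        rng = np.random.default_rng(30)
        studies = []
        for k in range(5):
            vals = rng.normal(8, 1, size=(30, 30))
            vals[0, :15] += 2.0  # g = 2 planted up in all studies
            studies.append(make_study(vals, "T" * 15 + "N" * 15, study_id=f"s{k}"))
        # B=1000 so the minimum attainable p (1/1001) clears BH at 30 features
        cfg = PipelineConfig(n_permutations=1000, random_seed=1)
        res = meta_significance(MetaDataset(studies), cfg)
        assert res.table.iloc[0]["direction"] == "up"
        assert res.table.iloc[0]["q_bh"] < 0.05
        assert res.table.iloc[0]["mu_fixed"] > 0

    def test_split_direction_is_inconsistent(self):
        rng = np.random.default_rng(31)
        studies = []
        for k in range(6):
            vals = rng.normal(8, 1, size=(20, 24))
            shift = 2.5 if k < 3 else -2.5
            vals[0, :12] += shift
            studies.append(make_study(vals, "T" * 12 + "N" * 12, study_id=f"s{k}"))
        cfg = PipelineConfig(n_permutations=200, random_seed=2)
        res = meta_significance(MetaDataset(studies), cfg)
        assert res.table.iloc[0]["direction"] == "inconsistent"

    def test_q_never_below_p_and_direction_sign_agreement(self, small_meta):
        meta, _ = small_meta
        cfg = PipelineConfig(n_permutations=100, random_seed=3)
        res = meta_significance(meta, cfg)
        t = res.table
        assert (t["q_bh"] >= t["p_perm"] - 1e-12).all()
        assert (t.loc[t["direction"] == "up", "mu_fixed"] > 0).all()
        assert (t.loc[t["direction"] == "down", "mu_fixed"] < 0).all()
        assert (t["tau2"] >= 0).all()
        assert t["I2"].between(0, 100).all()
        # p_perm lower bound from the (1+count)/(B+1) estimator
        assert (t["p_perm"] >= 1.0 / 101).all()

    def test_bh_is_monotone_step_function(self, small_meta):
        meta, _ = small_meta
        cfg = PipelineConfig(n_permutations=100, random_seed=4)
        res = meta_significance(meta, cfg)
        t = res.table.sort_values("p_perm")
        assert (np.diff(t["q_bh"].to_numpy()) >= -1e-12).all()

    def test_significant_lists_consistent(self, small_meta):
        meta, truth = small_meta
        cfg = PipelineConfig(n_permutations=200, random_seed=5)
        res = meta_significance(meta, cfg)
        both = set(res.concordant_list())
        assert both <= set(res.fisher_list())
        assert both <= set(res.effect_list())
        # strong planted effects (g=2) are found by both routes
        assert set(truth["feature_id"]) <= both
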