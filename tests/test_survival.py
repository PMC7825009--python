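import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metpath as mp
from metpath.survival import cox_partial_loglik_grad

from conftest import make_surv


class TestPartialLoglik:
    def test_hand_computed_three_sample_instance(self):
        # theta = 0, times 1,2,3 all events: risk sets of size 3,2,1
        surv = make_surv([1, 2, 3], [1, 1, 1])
        pl = mp.cox_partial_loglik(np.zeros(3), surv)
        assert pl == pytest.approx(-np.log(6), abs=1e-12)

    @given(c=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(0)
        surv = make_surv(rng.exponential(size=12), rng.integers(0, 2, 12) | 1)
        theta = rng.normal(size=12)
        assert mp.cox_partial_loglik(theta + c, surv) == pytest.approx(
            mp.cox_partial_loglik(theta, surv), rel=1e-9
        )

    def test_breslow_ties_share_risk_set(self):
        # two events tied at t=1 plus one at t=2: pl = 2*(0 - ln 3) - ln 1
        surv = make_surv([1, 1, 2], [1, 1, 1])
        assert mp.cox_partial_loglik(np.zeros(3), surv) == pytest.approx(-2 * np.log(3))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        n = 20
        surv = make_surv(rng.exponential(size=n), rng.integers(0, 2, n))
        surv.event[0] = 1
        theta = rng.normal(size=n)
        g = cox_partial_loglik_grad(theta, surv)
        eps = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = eps
            fd = (mp.cox_partial_loglik(theta + e, surv) - mp.cox_partial_loglik(theta - e, surv)) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-6)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="events"):
            mp.cox_partial_loglik(np.zeros(3), make_surv([1, 2, 3], [0, 0, 0]))


class TestCIndex:
    def test_perfect_and_inverted_ranking(self):
        surv = make_surv([2, 4, 6], [1, 1, 1])
        assert mp.c_index(np.array([3.0, 2.0, 1.0]), surv) == 1.0
        assert mp.c_index(np.array([1.0, 2.0, 3.0]), surv) == 0.0

    def test_enumeration_example(self):
        surv = make_surv([2, 4, 6], [1, 1, 1])
        # pairs (0,1) concordant, (0,2) concordant? PI (2,3,1): (0,1) 2<3 disc,
        # (0,2) 2>1 conc, (1,2) 3>1 conc -> 2/3
        assert mp.c_index(np.array([2.0, 3.0, 1.0]), surv) == pytest.approx(2 / 3)

    def test_matches_pair_enumeration_with_censoring(self):
        rng = np.random.default_rng(2)
        n = 10
        t = rng.exponential(size=n)
        d = rng.integers(0, 2, n)
        d[:2] = 1
        pi = rng.normal(size=n)
        surv = make_surv(t, d)
        conc = ties = pairs = 0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and d[i] == 1:
                    pairs += 1
                    conc += pi[i] > pi[j]
                    ties += pi[i] == pi[j]
        assert mp.c_index(pi, surv) == pytest.approx((conc + 0.5 * ties) / pairs)

    def test_matches_lifelines_cross_check(self):
        from lifelines.utils import concordance_index as ll_c

        rng = np.random.default_rng(3)
        n = 60
        t = rng.exponential(size=n)
        d = rng.integers(0, 2, n)
        d[0] = 1
        pi = rng.normal(size=n)
        surv = make_surv(t, d)
        # lifelines scores predicted survival time (larger = longer life)
        assert mp.c_index(pi, surv) == pytest.approx(ll_c(t, -pi, d))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(4)
        surv = make_surv(rng.exponential(size=30), np.ones(30, dtype=int))
        pi = rng.normal(size=30)
        assert mp.c_index(pi, surv) + mp.c_index(-pi, surv) == pytest.approx(1.0)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(ValueError, match="comparable"):
            mp.c_index(np.array([1.0, 2.0]), make_surv([3, 1], [0, 0]))


class TestLogrank:
    def test_hand_computed_two_vs_two(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = np.array(["low", "low", "high", "high"], dtype=object)
        stat, p = mp.logrank_test(groups, surv)
        assert stat == pytest.approx(2.8823529, abs=1e-4)
        assert p == pytest.approx(0.0896, abs=5e-3)

    def test_identical_groups_give_zero(self):
        surv = make_surv([1, 2, 1, 2], [1, 1, 1, 1])
        stat, p = mp.logrank_test(np.array(["a", "a", "b", "b"], dtype=object), surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        surv = make_surv(rng.exponential(size=40), rng.integers(0, 2, 40) | 1)
        g = np.where(rng.random(40) < 0.5, "high", "low").astype(object)
        s1, _ = mp.logrank_test(g, surv)
        g2 = np.where(g == "high", "low", "high").astype(object)
        s2, _ = mp.logrank_test(g2, surv)
        assert s1 == pytest.approx(s2)

    def test_matches_lifelines_cross_check(self):
        from lifelines.statistics import logrank_test as ll_lr

        rng = np.random.default_rng(6)
        t = rng.exponential(size=50)
        d = rng.integers(0, 2, 50)
        g = rng.random(50) < 0.5
        surv = make_surv(t, d)
        stat, p = mp.logrank_test(np.where(g, "high", "low").astype(object), surv)
        ref = ll_lr(t[g], t[~g], d[g], d[~g])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)


class TestDichotomize:
    def test_median_split(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
        g = mp.dichotomize(np.array([0.1, 0.4, 0.6, 0.9]), surv, "median")
        assert list(g) == ["low", "low", "high", "high"]

    def test_quartile_split_type7(self):
        surv = make_surv(np.arange(1, 9), np.ones(8, dtype=int))
        g = mp.dichotomize(np.arange(1.0, 9.0), surv, "quartile")
        assert list(g) == ["low", "low"] + ["excluded"] * 4 + ["high", "high"]

    def test_event_ratio_counts(self):
        surv = make_surv(np.arange(1, 11), np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]))
        pi = np.arange(10.0)
        g = mp.dichotomize(pi, surv, "event_ratio")
        assert (g == "high").sum() == 3
        assert set(pi[g == "high"]) == {7.0, 8.0, 9.0}

    def test_q1_threshold_variant(self):
        surv = make_surv(np.arange(1, 9), np.ones(8, dtype=int))
        g = mp.dichotomize(np.arange(1.0, 9.0), surv, "q1_threshold")
        assert (g == "low").sum() == 2  # Q1 of 1..8 is 2.75

    def test_constant_pi_error(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="identical"):
            mp.dichotomize(np.ones(4), surv, "median")


class TestKM:
    def test_no_events_constant_one(self):
        surv = make_surv([1, 2, 3], [0, 0, 0])
        tab = mp.km_table(surv)
        assert (tab.survival == 1.0).all()

    def test_no_censoring_matches_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        surv = make_surv(t, np.ones(5, dtype=int))
        tab = mp.km_table(surv)
        for tt in t:
            s = tab[tab.time == tt].survival.iloc[0]
            assert s == pytest.approx(np.mean(t > tt))

    def test_non_increasing(self):
        rng = np.random.default_rng(7)
        surv = make_surv(rng.exponential(size=40), rng.integers(0, 2, 40))
        tab = mp.km_table(surv)
        assert (np.diff(tab.survival) <= 1e-12).all()
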