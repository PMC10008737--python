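import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from chromoscore.simulate import SimConfig, simulate_survival, substream
from chromoscore.survival_analysis import (
    cox_univariate,
    km_logrank,
    median_groups,
    response_rates,
    time_dependent_auc,
)


class TestMedianGroups:
    def test_even_distinct(self):
        v = pd.Series([1, 2, 3, 4], index=list("abcd"))
        high = median_groups(v)
        assert set(high[high].index) == {"c", "d"}

    def test_ties_at_median_go_low(self):
        v = pd.Series([1, 2, 2, 3], index=list("abcd"))
        high = median_groups(v)
        assert set(high[high].index) == {"d"}

    def test_odd_distinct_counts(self):
        for n in (5, 7, 9):
            v = pd.Series(np.arange(n, dtype=float))
            assert median_groups(v).sum() == (n - 1) // 2

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            median_groups(pd.Series([2.0, 2.0, 2.0]))


class TestKMLogrank:
    def test_hand_product_limit(self):
        # no censoring, times 1..4 all events in one group vs a reference
        time = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        event = pd.Series([1] * 8)
        groups = pd.Series([True] * 4 + [False] * 4)
        res = km_logrank(time, event, groups)
        high = res.curves["high"]
        surv = dict(zip(high["time"], high["survival"]))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[3.0] == pytest.approx(0.25)
        assert surv[4.0] == pytest.approx(0.0)
        assert res.median_survival["high"] == pytest.approx(2.0)

    def test_km_equals_empirical_without_censoring(self, rng):
        time = pd.Series(rng.exponential(10, 50))
        event = pd.Series(np.ones(50, dtype=int))
        groups = pd.Series([True] * 25 + [False] * 25)
        res = km_logrank(time, event, groups)
        curve = res.curves["high"]
        t_high = np.sort(time[groups.values].values)
        for t, s in zip(curve["time"][1:], curve["survival"][1:]):
            assert s == pytest.approx(np.mean(t_high > t))

    def test_identical_groups_p_one(self):
        time = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = pd.Series([1, 1, 1, 1, 1, 1])
        groups = pd.Series([True, True, True, False, False, False])
        res = km_logrank(time, event, groups)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(pd.Series([1.0, 2.0]), pd.Series([0, 0]),
                       pd.Series([True, False]))

    def test_high_cps_group_has_shorter_survival(self):
        cfg = SimConfig(n_samples=400, seed=10, censoring_rate=0.2)
        cps = substream(cfg, "labels").random(400)
        clin = simulate_survival(cps, cfg, substream(cfg, "survival"))
        high = median_groups(pd.Series(cps, index=clin["sample"]))
        res = km_logrank(clin["os_months"], clin["os_event"], high.values)
        assert res.median_survival["high"] < res.median_survival["low"]
        assert res.logrank_p < 0.01


class TestCox:
    def test_negating_covariate_inverts_hr(self, rng):
        time = pd.Series(rng.exponential(10, 100))
        event = pd.Series(rng.integers(0, 2, 100) | 1)
        x = pd.Series(rng.normal(size=100))
        a = cox_univariate(time, event, x)
        b = cox_univariate(time, event, -x)
        assert a["hr"] == pytest.approx(1 / b["hr"], rel=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(pd.Series([1.0, 2.0]), pd.Series([0, 0]),
                           pd.Series([0.0, 1.0]))

    def test_breslow_close_to_efron_on_untied_data(self, rng):
        time = pd.Series(rng.exponential(10, 150))
        event = pd.Series(np.ones(150, dtype=int))
        x = pd.Series(rng.normal(size=150))
        a = cox_univariate(time, event, x, ties="efron")
        b = cox_univariate(time, event, x, ties="breslow")
        assert a["beta"] == pytest.approx(b["beta"], abs=0.02)

    def test_binary_effect_recovered(self):
        """Planted binary HR=1.9: estimates center on the truth."""
        cfg = SimConfig(n_samples=600, seed=0, censoring_rate=0.2,
                        hazard_log_hr_per_cps=float(np.log(1.9)))
        hrs = []
        master = np.random.default_rng(77)
        for _ in range(30):
            group = master.integers(0, 2, 600).astype(float)
            clin = simulate_survival(group, cfg,
                                     np.random.default_rng(master.integers(2**31)),
                                     standardize=False)
            fit = cox_univariate(clin["os_months"], clin["os_event"], group)
            hrs.append(fit["hr"])
        assert 1.75 <= float(np.mean(hrs)) <= 2.05


class TestTimeDependentAUC:
    def test_independent_marker_near_half(self, rng):
        time = pd.Series(rng.exponential(10, 400))
        event = pd.Series(np.ones(400, dtype=int))
        marker = pd.Series(rng.normal(size=400))
        out = time_dependent_auc(time, event, marker, [2, 5, 10])
        assert np.all(np.abs(out["auc"] - 0.5) < 0.1)

    def test_perfect_marker_auc_one(self, rng):
        time = pd.Series(rng.exponential(10, 100))
        event = pd.Series(np.ones(100, dtype=int))
        marker = pd.Series(-time)  # higher marker = earlier event
        out = time_dependent_auc(time, event, marker, [2, 5, 10])
        assert np.allclose(out["auc"], 1.0)

    def test_matches_pairwise_concordance_without_censoring(self, rng):
        for _ in range(30):
            n = 40
            time = pd.Series(rng.exponential(10, n))
            event = pd.Series(np.ones(n, dtype=int))
            marker = pd.Series(rng.normal(size=n))
            grid = [float(np.quantile(time, q)) for q in (0.25, 0.5, 0.75)]
            out = time_dependent_auc(time, event, marker, grid)
            for t, auc in zip(out["time"], out["auc"]):
                cases = np.where(time <= t)[0]
                controls = np.where(time > t)[0]
                total = 0.0
                for i in cases:
                    for j in controls:
                        if marker[i] > marker[j]:
                            total += 1.0
                        elif marker[i] == marker[j]:
                            total += 0.5
                expected = total / (len(cases) * len(controls))
                assert auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_marker_transform(self, rng):
        time = pd.Series(rng.exponential(10, 100))
        event = pd.Series(rng.integers(0, 2, 100) | np.array([1] * 100))
        marker = pd.Series(rng.normal(size=100))
        out1 = time_dependent_auc(time, event, marker, [5.0])
        out2 = time_dependent_auc(time, event, np.exp(marker * 3), [5.0])
        assert out1["auc"].iloc[0] == pytest.approx(out2["auc"].iloc[0], abs=1e-12)

    def test_cross_check_against_ipcw_reference(self, rng):
        """Independent IPCW implementation (scikit-survival) agrees on
        censored data."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 300
        t_event = rng.exponential(10, n)
        t_cens = rng.exponential(25, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(bool)
        marker = -np.log(t_event) + rng.normal(0, 0.5, n)
        grid = [3.0, 6.0, 9.0]
        out = time_dependent_auc(pd.Series(time), pd.Series(event.astype(int)),
                                 pd.Series(marker), grid)
        y = Surv.from_arrays(event, time)
        ref_auc, _ = cumulative_dynamic_auc(y, y, marker, grid)
        np.testing.assert_allclose(out["auc"].values, ref_auc, atol=0.02)

    def test_grid_beyond_followup_dropped(self, rng):
        time = pd.Series([1.0, 2.0, 3.0])
        event = pd.Series([1, 1, 1])
        with pytest.warns(UserWarning, match="beyond"):
            out = time_dependent_auc(time, event, pd.Series([3.0, 2.0, 1.0]), [2.0, 99.0])
        assert list(out["time"]) == [2.0]


class TestResponseRates:
    def test_all_cr_rate_one_p_one(self):
        resp = pd.Series(["CR"] * 6)
        sd = pd.Series([np.nan] * 6)
        groups = pd.Series([True] * 3 + [False] * 3)
        out = response_rates(resp, sd, groups)
        assert out["responder_p"] == pytest.approx(1.0)
        assert out["responder_table"][0][1] == 0  # no non-responders

    def test_sd_duration_threshold(self):
        resp = pd.Series(["SD", "SD"], index=["a", "b"])
        sd = pd.Series([5.0, 7.0], index=["a", "b"])
        groups = pd.Series([True, False], index=["a", "b"])
        out = response_rates(resp, sd, groups)
        # SD of 5 months: non-responder (group True row); 7 months: responder
        assert out["responder_table"][0] == [0, 1]
        assert out["responder_table"][1] == [1, 0]

    def test_fisher_matches_enumeration(self):
        # responder table (3,7 / 6,4)
        resp = pd.Series(["CR"] * 3 + ["PD"] * 7 + ["CR"] * 6 + ["PD"] * 4)
        sd = pd.Series([np.nan] * 20)
        groups = pd.Series([True] * 10 + [False] * 10)
        out = response_rates(resp, sd, groups)
        a, n, K, N = 3, 20, 10, 9
        obs = hypergeom.pmf(a, n, K, N)
        p_exact = sum(
            hypergeom.pmf(x, n, K, N)
            for x in range(max(0, K + N - n), min(K, N) + 1)
            if hypergeom.pmf(x, n, K, N) <= obs * (1 + 1e-9)
        )
        assert out["responder_p"] == pytest.approx(p_exact, rel=1e-9)

    def test_fisher_invariant_to_joint_row_column_swap(self):
        from scipy.stats import fisher_exact

        tab = [[3, 7], [6, 4]]
        swapped = [[4, 6], [7, 3]]  # swap rows and columns together
        assert fisher_exact(tab)[1] == pytest.approx(fisher_exact(swapped)[1])

    def test_missing_sd_duration_excluded_with_warning(self):
        resp = pd.Series(["SD", "CR", "PD"])
        sd = pd.Series([np.nan, np.nan, np.nan])
        groups = pd.Series([True, True, False])
        with pytest.warns(UserWarning, match="SD"):
            out = response_rates(resp, sd, groups)
        assert sum(out["responder_table"][0]) + sum(out["responder_table"][1]) == 2


class TestMedianGroupProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                    min_size=2, max_size=50, unique=True))
    @settings(derandomize=True, max_examples=200)
    def test_high_group_strictly_above_median(self, values):
        v = pd.Series(values)
        high = median_groups(v)
        med = v.median()
        assert (v[high] > med).all()
        assert (v[~high] <= med).all()
        assert 0 < high.sum() < len(v)
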