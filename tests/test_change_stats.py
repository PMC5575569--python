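"""Power procedures and comparison statistics against independent oracles."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import streetcount as sc

from conftest import SURVEY_DATE, make_replicate


def _event(route_id, counts, label="e"):
    reps = [make_replicate(route_id, n, date=SURVEY_DATE + dt.timedelta(days=i))
            for i, n in enumerate(counts)]
    return sc.SurveyEvent(route_id, label, reps)


@pytest.fixture
def two_routes(small_params):
    return {f"sim-route-{i:02d}": sc.simulate_route(small_params, i) for i in range(2)}


class TestReplicateDifferences:
    def test_identical_replicates_give_zero(self, two_routes):
        events = [_event(rid, [10, 10]) for rid in two_routes]
        assert sc.replicate_differences(events, two_routes) == [0.0, 0.0]

    def test_first_minus_second_by_date(self, two_routes):
        rid = "sim-route-00"
        L = two_routes[rid].length_km
        events = [_event(rid, [25, 20])]
        (d,) = sc.replicate_differences(events, two_routes)
        assert d == pytest.approx(5 / L)

    def test_three_replicates_use_earliest_pair(self, two_routes):
        rid = "sim-route-00"
        L = two_routes[rid].length_km
        events = [_event(rid, [25, 20, 99])]
        (d,) = sc.replicate_differences(events, two_routes)
        assert d == pytest.approx(5 / L)

    def test_single_replicate_error_names_route(self, two_routes):
        events = [_event("sim-route-01", [5])]
        with pytest.raises(ValueError, match="sim-route-01"):
            sc.replicate_differences(events, two_routes)

    def test_null_simulation_mean_difference_near_zero(self):
        params = sc.SimParams(n_routes=40, route_length_km=10.0, lambda_per_km=8.0,
                              seed=5)
        d = sc.density_pair_differences(params, n_pairs=50)
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean()) < 4 * se + 1e-12


class TestMinDetectableChange:
    def test_matches_hand_computation_at_n5(self):
        diffs = [0.2, -0.1, 0.4, 0.0, 0.1]
        # independent arithmetic: mean, sample sd, tabulated t(0.975, df=4)
        m = sum(diffs) / 5
        sd = math.sqrt(sum((x - m) ** 2 for x in diffs) / 4)
        t_table = 2.776445105  # two-sided 5% critical value, 4 df
        res = sc.min_detectable_change(diffs, baseline_mean=2.0)
        assert res.mean_diff == pytest.approx(m)
        assert res.se_diff == pytest.approx(sd / math.sqrt(5))
        assert res.t_crit == pytest.approx(t_table, abs=1e-6)
        assert res.min_detectable_abs == pytest.approx(sd / math.sqrt(5) * t_table, rel=1e-6)
        assert res.min_detectable_pct == pytest.approx(
            100 * res.min_detectable_abs / 2.0)

    def test_zero_variance_gives_zero_threshold(self):
        res = sc.min_detectable_change([0.5, 0.5, 0.5], baseline_mean=1.0)
        assert res.min_detectable_abs == 0.0

    def test_summary_entry_point(self):
        res = sc.min_detectable_change(n=21, se_diff=0.29, baseline_mean=10.54)
        assert res.t_crit == pytest.approx(stats.t.ppf(0.975, 20))
        assert res.min_detectable_abs == pytest.approx(0.29 * stats.t.ppf(0.975, 20))

    @pytest.mark.parametrize("kwargs", [
        dict(diffs=[0.1], baseline_mean=1.0),
        dict(n=1, se_diff=0.1, baseline_mean=1.0),
        dict(diffs=[0.1, 0.2], baseline_mean=0.0),
        dict(diffs=[0.1, 0.2], baseline_mean=1.0, alpha=1.5),
        dict(diffs=[0.1, 0.2], n=2, se_diff=0.1, baseline_mean=1.0),
    ])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            sc.min_detectable_change(**kwargs)

    def test_threshold_shrinks_with_more_routes(self):
        # i.i.d. resamples of a fixed difference distribution: both t quantile
        # and 1/sqrt(n) shrink, so the expected threshold decreases with n
        rng = np.random.default_rng(42)
        pool = rng.normal(0.0, 0.5, size=5000)
        means = []
        for n in (5, 10, 20, 40):
            thresholds = [
                sc.min_detectable_change(rng.choice(pool, size=n),
                                         baseline_mean=5.0).min_detectable_abs
                for _ in range(200)
            ]
            means.append(np.mean(thresholds))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestCompositionChange:
    def test_equal_fractions_never_significant(self):
        res = sc.composition_change_test(8, 100, 16, 200)
        assert not res.significant

    def test_invariants_hold(self):
        res = sc.composition_change_test(10, 120, 30, 150)
        p = (10 + 30) / (120 + 150)
        assert res.p_pooled == pytest.approx(p)
        assert res.sd_null == pytest.approx(
            math.sqrt((1 / 120 + 1 / 150) * p * (1 - p)))
        assert res.z_crit == pytest.approx(1.959964, abs=1e-6)
        assert res.significant == (abs(res.p1 - res.p2) > res.z_crit * res.sd_null)

    def test_agrees_with_statsmodels_style_z(self):
        # hand-coded pooled two-proportion z for one configuration
        k1, n1, k2, n2 = 12, 80, 30, 90
        p1, p2 = k1 / n1, k2 / n2
        pp = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        res = sc.composition_change_test(k1, n1, k2, n2)
        assert res.significant == (abs(z) > 1.959964)
        assert res.significant  # this configuration is clearly significant

    def test_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            sc.composition_change_test(0, 0, 1, 10)

    def test_sd_null_maximised_at_half(self):
        n1, n2 = 40, 60
        sds = {}
        for k1 in range(0, n1 + 1, 5):
            for k2 in range(0, n2 + 1, 5):
                res = sc.composition_change_test(k1, n1, k2, n2)
                sds[res.p_pooled] = res.sd_null
        best = max(sds, key=sds.get)
        assert best == pytest.approx(0.5, abs=0.05)


class TestRequiredSecondSample:
    def test_unreachable_small_difference(self):
        res = sc.required_second_sample(50, 0.40, 0.41)
        assert not res.reachable and res.n2 is None

    def test_matches_independent_search_oracle(self):
        for n1, p1, p2 in [(500, 0.1, 0.2), (3236, 0.08, 0.11), (200, 0.3, 0.15)]:
            res = sc.required_second_sample(n1, p1, p2)
            # independent oracle: direct formula scan
            k1 = round(p1 * n1)
            expected = None
            for n2 in range(1, 200_000):
                k2 = round(p2 * n2)
                pp = (k1 + k2) / (n1 + n2)
                sd = math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
                if abs(k1 / n1 - k2 / n2) > stats.norm.ppf(0.975) * sd:
                    expected = n2
                    break
            assert res.reachable and res.n2 == expected

    def test_larger_difference_never_needs_more(self):
        base = sc.required_second_sample(1000, 0.10, 0.16).n2
        wider = sc.required_second_sample(1000, 0.10, 0.22).n2
        assert wider <= base

    def test_equal_fractions_rejected(self):
        with pytest.raises(ValueError):
            sc.required_second_sample(100, 0.2, 0.2)


class TestAnova:
    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(2, 9))
                      for _ in range(rng.integers(2, 6))]
            ours = sc.one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        F = sc.one_way_anova([a, b]).statistic
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_identical_values_give_zero(self):
        res = sc.one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    @given(st.floats(min_value=0.1, max_value=10), st.floats(min_value=-5, max_value=5))
    def test_affine_invariance(self, a, b):
        groups = [[1.0, 2.0, 3.5], [2.5, 4.0], [0.5, 1.5, 2.0, 6.0]]
        f0 = sc.one_way_anova(groups).statistic
        f1 = sc.one_way_anova([[a * v + b for v in g] for g in groups]).statistic
        assert f1 == pytest.approx(f0, rel=1e-6)

    def test_missing_values_dropped(self):
        res = sc.one_way_anova([[1.0, 2.0, None], [3.0, np.nan, 4.0]])
        ref = stats.f_oneway([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(ref.statistic)


class TestKruskalWallis:
    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.integers(0, 5, size=rng.integers(3, 9)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            ours = sc.kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_monotone_transform_invariance(self):
        groups = [[0.0, 1.2, 5.1], [2.2, 2.2, 0.0], [7.7, 0.4]]
        h0 = sc.kruskal_wallis(groups).statistic
        h1 = sc.kruskal_wallis([[math.exp(v) for v in g] for g in groups]).statistic
        assert h1 == pytest.approx(h0, rel=1e-12)

    def test_missing_values_excluded_before_ranking(self):
        res = sc.kruskal_wallis([[1.0, None, 2.0], [3.0, 4.0, np.nan]])
        ref = stats.kruskal([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(ref.statistic)

    def test_all_missing_group_raises(self):
        with pytest.raises(ValueError):
            sc.kruskal_wallis([[None, np.nan], [1.0, 2.0]])

    def test_all_tied_values_give_zero(self):
        res = sc.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_permutation_matches_enumeration_oracle(self):
        groups = [[1.2, 3.1, 2.0], [0.5, 0.7], [4.2, 1.1]]
        ours = sc.kruskal_wallis(groups, p_method="permutation")
        # independent oracle: enumerate all label arrangements with scipy's H
        values = [v for g in groups for v in g]
        sizes = [len(g) for g in groups]
        h_obs = stats.kruskal(*groups).statistic
        ge = total = 0
        for perm in set(itertools.permutations(range(len(values)))):
            split, i = [], 0
            for s in sizes:
                split.append([values[j] for j in perm[i:i + s]])
                i += s
            total += 1
            if stats.kruskal(*split).statistic >= h_obs - 1e-12:
                ge += 1
        assert ours.p_value == pytest.approx(ge / total, abs=1e-12)

    def test_permutation_caps_problem_size(self):
        with pytest.raises(ValueError):
            sc.kruskal_wallis([[1.0] * 6, [2.0] * 6], p_method="permutation")


class TestLinearTrend:
    def test_perfect_line_r2_one(self):
        dates = [dt.date(2013 + i, 6, 1) for i in range(5)]
        t0 = sc.decimal_year(dates[0])
        values = [2.0 - 0.3 * (sc.decimal_year(d) - t0) for d in dates]
        res = sc.linear_trend(dates, values)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.3, rel=1e-6)

    def test_constant_series(self):
        dates = [dt.date(2014 + i, 1, 1) for i in range(4)]
        res = sc.linear_trend(dates, [1.5] * 4)
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        from streetcount.datasets import load_route_series
        dates, values = load_route_series("Casco Viejo")
        res = sc.linear_trend(dates, values)
        # closed-form least squares, independently coded
        x = np.array([sc.decimal_year(d) for d in dates])
        y = np.array(values)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy ** 2 / (sxx * ((y - y.mean()) ** 2).sum())
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)
        assert res.slope < 0

    def test_too_few_points_or_duplicate_dates(self):
        with pytest.raises(ValueError):
            sc.linear_trend([dt.date(2014, 1, 1), dt.date(2015, 1, 1)], [1.0, 2.0])
        with pytest.raises(ValueError):
            sc.linear_trend([dt.date(2014, 1, 1)] * 3, [1.0, 2.0, 3.0])
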