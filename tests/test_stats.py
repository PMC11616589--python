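from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

import epimap as em
from epimap.errors import PairingError, ParameterError
from epimap.recording import PerfusateSample
from epimap.stats import (
    HeartSummary,
    classify_strength,
    exact_mann_whitney,
    group_compare_table,
    one_way_anova,
    pearson_correlation,
    unpaired_t_test,
)


def oracle_mann_whitney(a, b):
    """Independent brute-force oracle: U by explicit pair counting; exact
    two-sided p as twice the smaller enumeration tail, in exact rationals."""
    def u_of(x, y):
        u = Fraction(0)
        for xi in x:
            for yj in y:
                if yj < xi:
                    u += 1
                elif yj == xi:
                    u += Fraction(1, 2)
        return u

    u_obs = u_of(a, b)
    pooled = list(a) + list(b)
    n, n1 = len(pooled), len(a)
    us = []
    for comb in combinations(range(n), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in comb]
        us.append(u_of(ga, gb))
    total = len(us)
    p_low = Fraction(sum(u <= u_obs for u in us), total)
    p_high = Fraction(sum(u >= u_obs for u in us), total)
    return float(u_obs), float(min(1, 2 * min(p_low, p_high)))


class TestExactMannWhitney:
    def test_complete_separation_4v4(self):
        res = exact_mann_whitney([4.7, 9.0, 12.6, 17.8], [19.4, 23.2, 24.0, 24.2])
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / 70)
        assert res.method == "exact"

    def test_identical_samples_give_p_1(self):
        res = exact_mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_two_sided == 1.0

    def test_one_discordant_pair(self):
        res = exact_mann_whitney([1, 2, 3, 5], [4, 6, 7, 8])
        assert res.u_statistic == 1.0
        assert res.p_two_sided == pytest.approx(4 / 70)

    def test_full_p_ladder_at_4v4(self):
        """The exact two-sided p for U = 0..6 matches the enumerated ladder."""
        expected = {0: 2 / 70, 1: 4 / 70, 2: 8 / 70, 3: 14 / 70,
                    4: 24 / 70, 5: 34 / 70, 6: 48 / 70}
        fixtures = {
            0: ([1, 2, 3, 4], [5, 6, 7, 8]),
            1: ([1, 2, 3, 5], [4, 6, 7, 8]),
            2: ([1, 2, 3, 6], [4, 5, 7, 8]),
            3: ([1, 2, 3, 7], [4, 5, 6, 8]),
            4: ([1, 2, 3, 8], [4, 5, 6, 7]),
            5: ([1, 2, 4, 8], [3, 5, 6, 7]),
            6: ([1, 2, 5, 8], [3, 4, 6, 7]),
        }
        for u, (a, b) in fixtures.items():
            res = exact_mann_whitney(a, b)
            assert min(res.u_statistic, 16 - res.u_statistic) == u
            assert res.p_two_sided == pytest.approx(expected[u])

    def test_matches_brute_force_oracle_on_random_inputs(self):
        """>=100 random tied/untied draws at all group sizes <= 7."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(110):
            n1, n2 = rng.integers(1, 8, 2)
            a = rng.integers(0, 6, n1).astype(float).tolist()
            b = rng.integers(0, 6, n2).astype(float).tolist()
            u_exp, p_exp = oracle_mann_whitney(a, b)
            res = exact_mann_whitney(a, b)
            assert res.method == "exact"
            assert res.u_statistic == u_exp
            assert res.p_two_sided == pytest.approx(p_exp, abs=1e-12)
            checked += 1
        assert checked >= 100

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(2, 8, 2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            res = exact_mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(1.0, 1.0, size=30)
        res = exact_mann_whitney(a, b)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            exact_mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        e = pearson_correlation(x, 2 * x + 1)
        assert e.r == pytest.approx(1.0)
        assert e.strength == "strong"

    def test_perfect_negative_relation_is_strong(self):
        x = np.random.default_rng(0).normal(size=20)
        e = pearson_correlation(x, -x)
        assert e.r == pytest.approx(-1.0)
        assert e.strength == "strong"

    def test_strength_boundaries(self):
        assert classify_strength(0.29) == "weak"
        assert classify_strength(0.30) == "moderate"
        assert classify_strength(0.69) == "moderate"
        assert classify_strength(0.70) == "strong"
        assert classify_strength(-0.95) == "strong"

    def test_zero_variance_reported_missing(self):
        e = pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(e.r)
        assert e.strength is None


class TestLactate:
    def _series(self, values, times, site="arterial"):
        return [PerfusateSample("H1", t, site, v) for t, v in zip(times, values)]

    def test_slope_from_first_and_last_sample(self):
        trend = em.lactate_trend(self._series([9.0, 6.6], [20.0, 120.0]))
        assert trend.slope_um_min == pytest.approx(-24.0)

    def test_constant_series_gives_zero(self):
        trend = em.lactate_trend(self._series([8.0, 8.0, 8.0], [20, 40, 60]))
        assert trend.slope_um_min == 0.0

    def test_invariant_to_intermediate_samples(self):
        base = self._series([9.0, 6.6], [20.0, 120.0])
        dense = self._series([9.0, 123.0, 0.1, 6.6], [20.0, 40.0, 80.0, 120.0])
        assert em.lactate_trend(dense).slope_um_min == \
            em.lactate_trend(base).slope_um_min

    def test_venous_samples_ignored(self):
        series = self._series([9.0, 6.6], [20.0, 120.0]) + \
            self._series([100.0, 100.0], [30.0, 110.0], site="venous")
        assert em.lactate_trend(series).slope_um_min == pytest.approx(-24.0)

    def test_av_difference(self):
        art = self._series([8.0, 7.0], [20.0, 40.0])
        ven = self._series([7.6, 7.0], [20.0, 40.0], site="venous")
        assert em.av_lactate_difference(art, ven) == [(20.0, pytest.approx(0.4)),
                                                      (40.0, pytest.approx(0.0))]

    def test_unmatched_times_rejected(self):
        art = self._series([8.0], [20.0])
        ven = self._series([7.6], [25.0], site="venous")
        with pytest.raises(PairingError):
            em.av_lactate_difference(art, ven)


class TestTTestAnova:
    def test_identical_groups(self):
        t, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_direction_and_magnitude(self):
        t, p = unpaired_t_test([0.0, 0.01], [1.0, 1.01])
        assert t < 0 and p < 0.01

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.2, size=9)
        t, p = unpaired_t_test(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_manual = 2 * sps.t.sf(abs(t_manual), n1 + n2 - 2)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert p == pytest.approx(p_manual, abs=1e-10)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ParameterError):
            unpaired_t_test([1.0, 1.0], [1.0, 1.0])

    def test_anova_hand_computed_toy(self):
        res = one_way_anova({"anterior": [1, 2, 3], "lateral": [2, 3, 4],
                             "posterior": [3, 4, 5]})
        assert res.f_statistic == pytest.approx(3.0)

    def test_anova_degenerate_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})


def _summary(heart_id, ventricle, voltage):
    return HeartSummary(heart_id, ventricle, 1000, voltage, 1.0, -1.0, 80.0, 5.0)


class TestGroupCompareTable:
    def _summaries(self):
        g1_lv = [10.8, 4.7, 17.8, 9.0]
        g2_lv = [23.6, 19.4, 24.2, 23.7]
        out, groups = [], {}
        for i, v in enumerate(g1_lv):
            hid = f"G1H{i}"
            groups[hid] = "group1"
            out += [_summary(hid, "LV", v), _summary(hid, "RV", v / 2)]
        for i, v in enumerate(g2_lv):
            hid = f"G2H{i}"
            groups[hid] = "group2"
            out += [_summary(hid, "LV", v), _summary(hid, "RV", v / 2)]
        return out, groups

    def test_complete_separation_gives_p_0_029(self):
        summaries, groups = self._summaries()
        comps, _ = group_compare_table(summaries, groups)
        row = next(c for c in comps
                   if c.ventricle == "LV" and c.parameter == "Voltage (mV)")
        assert round(row.p_two_sided, 3) == 0.029
        assert row.u_statistic == 0.0

    def test_row_count_is_parameters_times_ventricles(self):
        summaries, groups = self._summaries()
        comps, df = group_compare_table(summaries, groups)
        assert len(comps) == 6 * 2
        assert len(df) == 12

    def test_identical_groups_give_p_1(self):
        summaries = [_summary(f"H{i}", "RV", 10.0) for i in range(8)]
        groups = {f"H{i}": "group1" if i < 4 else "group2" for i in range(8)}
        comps, _ = group_compare_table(summaries, groups)
        row = next(c for c in comps if c.parameter == "Voltage (mV)")
        assert row.p_two_sided == 1.0


class TestCorrelationMatrix:
    def test_symmetry_and_unit_diagonal(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        entries, rmat = em.correlation_matrix(df)
        np.testing.assert_allclose(rmat.to_numpy(), rmat.to_numpy().T)
        np.testing.assert_allclose(np.diag(rmat.to_numpy()), 1.0)
        assert len(entries) == 6

    def test_too_few_hearts_rejected(self):
        import pandas as pd
        with pytest.raises(ParameterError):
            em.correlation_matrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
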