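import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from nucmorph import stats as st


class TestWilson:
    def test_26_of_30_matches_printed_interval(self):
        est = st.wilson_ci(26, 30)
        assert est.point_pct == pytest.approx(86.7, abs=0.05)
        assert est.ci_low_pct == pytest.approx(70.32, abs=0.005)
        assert est.ci_high_pct == pytest.approx(94.69, abs=0.005)

    def test_12_of_20_matches_printed_interval(self):
        est = st.wilson_ci(12, 20)
        assert est.point_pct == pytest.approx(60.0)
        assert est.ci_low_pct == pytest.approx(38.66, abs=0.005)
        assert est.ci_high_pct == pytest.approx(78.12, abs=0.005)

    def test_19_of_20_boundary_variants(self):
        plain = st.wilson_ci(19, 20)
        assert plain.ci_low_pct == pytest.approx(76.39, abs=0.005)
        cc = st.wilson_ci(19, 20, method="wilson_cc")
        assert cc.ci_high_pct == pytest.approx(99.74, abs=0.005)
        both = st.proportion_estimates(19, 20)
        assert [e.method for e in both] == ["wilson", "wilson_cc"]

    def test_zero_successes_lower_bound_is_zero(self):
        est = st.wilson_ci(0, 10)
        assert est.ci_low_pct == 0.0
        assert est.point_pct == 0.0

    def test_all_successes_upper_bound_is_100(self):
        for method in ("wilson", "wilson_cc"):
            est = st.wilson_ci(20, 20, method=method)
            assert est.ci_high_pct == pytest.approx(100.0)

    @given(n=hst.integers(2, 200), pct=hst.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_interval_contains_point_and_shrinks_with_n(self, n, pct):
        x = int(round(pct * n))
        est = st.wilson_ci(x, n)
        assert est.ci_low_pct <= est.point_pct <= est.ci_high_pct
        bigger = st.wilson_ci(4 * x, 4 * n)
        assert (bigger.ci_high_pct - bigger.ci_low_pct) <= (
            est.ci_high_pct - est.ci_low_pct + 1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.wilson_ci(5, 0)
        with pytest.raises(ValueError):
            st.wilson_ci(11, 10)


class TestBinomialTest:
    def test_26_of_30_exact_value(self):
        # 2 * sum_{k=26..30} C(30,k) / 2^30, exact rational arithmetic
        expected = 2 * Fraction(sum(comb(30, k) for k in range(26, 31)), 2**30)
        assert st.binomial_test(26, 30) == pytest.approx(float(expected), rel=1e-12)

    def test_19_of_20_exact_value(self):
        expected = 2 * Fraction(21, 2**20)
        assert st.binomial_test(19, 20) == pytest.approx(float(expected), rel=1e-12)

    def test_balanced_count_gives_p_1(self):
        assert st.binomial_test(10, 20) == 1.0

    @pytest.mark.parametrize("null_p", [0.3, 0.5, 0.7])
    def test_matches_brute_force_tail_sum_all_n_up_to_25(self, null_p):
        for n in range(1, 26):
            for x in range(n + 1):
                pmf = [comb(n, k) * null_p**k * (1 - null_p) ** (n - k)
                       for k in range(n + 1)]
                lower = sum(pmf[: x + 1])
                upper = sum(pmf[x:])
                expected = min(1.0, 2 * min(lower, upper))
                assert st.binomial_test(x, n, null_p) == pytest.approx(
                    expected, rel=1e-9, abs=1e-12
                )

    def test_invalid_null(self):
        with pytest.raises(ValueError):
            st.binomial_test(5, 10, null_p=0.0)


class TestFisherExact:
    def test_morphology_timepoint_table_is_significant(self):
        table = [[0, 2, 12, 2, 8, 76], [7, 21, 14, 22, 0, 36]]
        res = st.fisher_exact_rxc(table, full_result=True)
        assert res.method == "enumeration"
        assert res.p_value < 1e-4

    def test_identical_rows_give_p_1(self):
        assert st.fisher_exact_rxc([[5, 3, 2], [5, 3, 2]]) == pytest.approx(1.0)

    def test_2x2_hand_enumeration(self):
        # table (5,0 / 0,5): only the observed and its mirror are as extreme
        assert st.fisher_exact_rxc([[5, 0], [0, 5]]) == pytest.approx(2 / comb(10, 5))

    @pytest.mark.parametrize(
        "table", [[[5, 3], [2, 8]], [[1, 9], [7, 2]], [[10, 2], [4, 9]]]
    )
    def test_2x2_matches_scipy(self, table):
        from scipy.stats import fisher_exact

        assert st.fisher_exact_rxc(table) == pytest.approx(
            fisher_exact(table)[1], rel=1e-9
        )

    def test_enumeration_and_monte_carlo_agree(self):
        rng = np.random.default_rng(7)
        for _ in range(4):
            table = rng.integers(0, 8, size=(2, 4)) + 1
            exact = st.fisher_exact_rxc(table, full_result=True)
            mc = st.fisher_exact_rxc(table, max_tables=1, n_mc=200_000,
                                     seed=3, full_result=True)
            assert mc.method == "monte_carlo"
            assert abs(mc.p_value - exact.p_value) <= 3 * mc.mc_se

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.fisher_exact_rxc([[0, 0], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups(self):
        r = st.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_pooled_and_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.6, 17)
        from scipy.stats import ttest_ind

        for welch in (False, True):
            r = st.two_sample_t(a, b, welch=welch)
            t, p = ttest_ind(a, b, equal_var=not welch)
            assert r.t == pytest.approx(t)
            assert r.p_value == pytest.approx(p)
            assert r.ci_low < r.mean_diff < r.ci_high

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ValueError):
            st.two_sample_t([0.0, 0.0], [1.0, 1.0])

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            st.two_sample_t([1.0], [1.0, 2.0])


def _plate(ic50s, noise=0.0, seed=0, doses=(0.0078, 0.0312, 0.125, 0.5, 2.0, 10.0)):
    from nucmorph.synth import generate_viability_plate

    return generate_viability_plate(ic50s, doses, reps=4, noise_sd_pct=noise, seed=seed)


class TestViability:
    def test_normalization_endpoints(self):
        plate = _plate({"control": 1.0})
        norm = st.normalize_viability(plate)
        treated = norm[~norm.is_background]
        assert treated.viability_pct.max() == pytest.approx(100.0)
        # background wells sit at ~0 after subtraction
        assert norm[norm.is_background].viability_pct.abs().max() < 1e-9

    def test_noiseless_curve_matches_hill_shape(self):
        plate = _plate({"control": 0.2})
        norm = st.normalize_viability(plate)
        treated = norm[~norm.is_background]
        doses = np.sort(treated.dose_uM.unique())
        hill = 1.0 / (1.0 + doses / 0.2)
        expected = 100.0 * hill / hill.max()
        got = treated.groupby("dose_uM").viability_pct.mean().loc[doses].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_missing_background_raises(self):
        plate = _plate({"c": 1.0})
        with pytest.raises(ValueError):
            st.normalize_viability(plate[~plate.is_background])

    def test_dosewise_separated_ic50s_detected(self):
        control = st.normalize_viability(_plate({"control": 1.0}, noise=2.0, seed=1))
        treated = st.normalize_viability(_plate({"pff": 0.05}, noise=2.0, seed=2))
        out = st.dosewise_comparison(control, treated)
        between = out[(out.dose_uM >= 0.05) & (out.dose_uM <= 1.0)]
        assert (between.p_adjusted < 0.01).all()
        assert "anova" in out.attrs

    def test_dosewise_identical_conditions_not_significant(self):
        a = st.normalize_viability(_plate({"c": 1.0}, noise=3.0, seed=3))
        b = st.normalize_viability(_plate({"c": 1.0}, noise=3.0, seed=4))
        out = st.dosewise_comparison(a, b)
        assert (out.p_adjusted > 0.05).all()

    def test_single_dose_rejected(self):
        a = st.normalize_viability(_plate({"c": 1.0}, doses=(0.5,)))
        b = st.normalize_viability(_plate({"c": 1.0}, doses=(0.5,)))
        with pytest.raises(ValueError):
            st.dosewise_comparison(a, b)

    def test_mismatched_dose_grids_rejected(self):
        a = st.normalize_viability(_plate({"c": 1.0}, doses=(0.5, 1.0)))
        b = st.normalize_viability(_plate({"c": 1.0}, doses=(0.25, 1.0)))
        with pytest.raises(ValueError):
            st.dosewise_comparison(a, b)
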