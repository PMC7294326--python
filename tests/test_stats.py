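"""Regression F-test, branch-type t-test and assay arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobulemorph import stats as ST


def brute_force_f(x, y):
    """Independent sums-of-squares oracle for the nested-model F-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = np.sum((y - X @ beta) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    return (tss - rss) / (rss / (n - 2)), beta


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = ST.fit_linear_ftest(x, 2 * x + 1)
        assert fit.r_squared == 1.0
        assert fit.p_value == 0.0
        assert np.isclose(fit.slope, 2.0) and np.isclose(fit.intercept, 1.0)

    def test_constant_response(self):
        fit = ST.fit_linear_ftest(np.arange(6.0), np.full(6, 3.3))
        assert fit.slope == 0.0
        assert fit.f_statistic == 0.0
        assert fit.p_value == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_sums_of_squares(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        fit = ST.fit_linear_ftest(x, y)
        f_ref, beta = brute_force_f(x, y)
        assert np.isclose(fit.f_statistic, f_ref, rtol=1e-10)
        assert np.isclose(fit.slope, beta[1], rtol=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 20)
        y = 0.5 - 2.0 * x + rng.normal(0, 0.3, 20)
        fit = ST.fit_linear_ftest(x, y)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.isclose(fit.f_statistic, res.fvalue, rtol=1e-9)
        assert np.isclose(fit.p_value, res.f_pvalue, rtol=1e-9)
        assert np.isclose(fit.r_squared, res.rsquared, rtol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ST.fit_linear_ftest([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ST.fit_linear_ftest([1.0, 2.0], [1.0, 2.0])


class TestBranchTypeTest:
    def test_identical_groups(self):
        t, p = ST.branch_type_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = 0.9 + rng.normal(0, 1e-3, 3)
        b = 0.1 + rng.normal(0, 1e-3, 3)
        _, p = ST.branch_type_test(a, b)
        assert p < 0.001

    def test_swapping_groups_negates_t(self):
        a, b = [0.6, 0.7, 0.65], [0.3, 0.35, 0.4]
        t1, p1 = ST.branch_type_test(a, b)
        t2, p2 = ST.branch_type_test(b, a)
        assert np.isclose(t1, -t2) and np.isclose(p1, p2)

    def test_welch_variant_differs_under_unequal_variance(self):
        a = [0.5, 0.9, 0.1, 0.7]
        b = [0.49, 0.50, 0.51, 0.50]
        _, p_pooled = ST.branch_type_test(a, b)
        _, p_welch = ST.branch_type_test(a, b, welch=True)
        assert p_pooled != p_welch

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            ST.branch_type_test([0.5], [0.4, 0.6])


class TestAssayFormulas:
    def test_ldh_fixed_point(self):
        assert ST.ldh_viability(0.1, 1.0, 0.1) == 100.0

    def test_ldh_background_subtracted_limit(self):
        assert ST.ldh_viability(1.0, 1.0, 0.0) == 0.0

    def test_ldh_direct_substitution(self):
        assert ST.ldh_viability(0.5, 1.0, 0.1) == 60.0

    def test_ldh_corrected_maps_lysis_control_to_zero(self):
        assert ST.ldh_viability(0.9, 0.9, 0.2, corrected=True) == 0.0
        assert ST.ldh_viability(0.2, 0.9, 0.2, corrected=True) == 100.0

    def test_ldh_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            ST.ldh_viability(0.5, 0.0, 0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(0.1, 2), st.floats(0, 1))
    def test_percent_formulas_affine_in_sample(self, s1, s2, c0, c100):
        """Viability is affine in the sample OD (two-point interpolation)."""
        mid = 0.5 * (s1 + s2)
        v = ST.ldh_viability
        assert np.isclose(v(mid, c0, c100),
                          0.5 * (v(s1, c0, c100) + v(s2, c0, c100)))

    @pytest.mark.parametrize("t,t0,expected", [(200.0, 200.0, 100.0),
                                               (0.0, 150.0, 0.0),
                                               (50.0, 200.0, 25.0)])
    def test_protein_recovery(self, t, t0, expected):
        assert ST.protein_recovery(t, t0) == expected

    def test_protein_recovery_zero_t0(self):
        with pytest.raises(ZeroDivisionError):
            ST.protein_recovery(10.0, 0.0)


class TestQpcr:
    def test_null_change(self):
        assert ST.ddct_fold(20.0, 18.0, 21.0, 19.0).fold == 1.0

    def test_one_cycle_gain_doubles(self):
        q = ST.ddct_fold(19.0, 18.0, 20.0, 18.0)
        assert q.delta_delta_ct == -1.0 and q.fold == 2.0

    def test_worked_example(self):
        q = ST.ddct_fold(20.0, 18.0, 23.0, 18.0)
        assert q.delta_delta_ct == -3.0 and q.fold == 8.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-5, 5))
    def test_shift_invariance(self, c):
        """Shifting both target CTs by c leaves the fold unchanged."""
        base = ST.ddct_fold(20.0, 18.0, 23.0, 19.0).fold
        shifted = ST.ddct_fold(20.0 + c, 18.0, 23.0 + c, 19.0).fold
        assert np.isclose(shifted, base)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ST.ddct_fold(np.nan, 18.0, 23.0, 18.0)

    def test_housekeeping_least_variable_wins(self):
        genes = {"GAPDH": [20.0, 21.5, 19.0], "HPRT": [22.0, 22.1, 21.9]}
        assert ST.housekeeping_stability(genes) == "HPRT"

    def test_housekeeping_tie_keeps_input_order(self):
        genes = {"A": [10.0, 11.0], "B": [20.0, 21.0]}
        assert ST.housekeeping_stability(genes) == "A"

    def test_housekeeping_constant_cts_win(self):
        genes = {"A": [10.0, 11.0], "B": [15.0, 15.0]}
        assert ST.housekeeping_stability(genes) == "B"

    def test_housekeeping_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ST.housekeeping_stability({"A": [10.0], "B": [12.0, 12.5]})
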