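"""Reliability statistics against independent oracles and known values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from romagree import agreement as ag

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_summary(values):
    """Accumulation-loop mean and sample SD."""
    n = len(values)
    total = 0.0
    for v in values:
        total += v
    mean = total / n
    ss = 0.0
    for v in values:
        ss += (v - mean) ** 2
    return mean, math.sqrt(ss / (n - 1)), n


def brute_force_icc_single(matrix):
    """Definitional variance-component estimate of the single-measure ICC.

    Estimates subject, measurement and error variance components from
    explicit sums over all subject/measurement pairs, then forms
    sigma_r^2 / (sigma_r^2 + sigma_c^2 + sigma_e^2).
    """
    m = np.asarray(matrix, float)
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    sse = sum(
        (m[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    var_e = sse / ((n - 1) * (k - 1))
    var_r = sum((rm - grand) ** 2 for rm in row_means) / (n - 1) - var_e / k
    var_c = sum((cm - grand) ** 2 for cm in col_means) / (k - 1) - var_e / n
    return var_r / (var_r + var_c + var_e)


def t_sf_by_quadrature(t_val, df):
    """Two-sided t-test p-value by numerical integration of the t density."""

    def pdf(x):
        c = math.exp(
            special.gammaln((df + 1) / 2) - special.gammaln(df / 2)
        ) / math.sqrt(df * math.pi)
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t_val), np.inf)
    return 2 * tail


# ---------------------------------------------------------------------------
# summary statistics and t-tests
# ---------------------------------------------------------------------------


class TestSummarize:
    def test_constant(self):
        s = ag.summarize([1.0, 1.0, 1.0])
        assert (s.mean, s.sd, s.n) == (1.0, 0.0, 3)

    def test_two_point(self):
        s = ag.summarize([0.0, 2.0])
        assert s.mean == 1.0
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_against_accumulation_oracle(self, rng):
        x = rng.normal(163.0, 11.0, 70)
        s = ag.summarize(x)
        mean, sd, n = brute_force_summary(x)
        assert s.mean == pytest.approx(mean, abs=1e-10)
        assert s.sd == pytest.approx(sd, abs=1e-10)
        assert s.n == n

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            ag.summarize([1.0])


class TestSummaryTTest:
    @pytest.mark.parametrize(
        "a,b,p_expected",
        [
            # shoulder forward-flexion and extension repetition comparisons
            ((163.413, 11.232, 70), (164.161, 10.46, 70), 0.684),
            ((48.189, 11.091, 70), (48.439, 11.455, 70), 0.896),
        ],
    )
    def test_reproduces_reported_p_values(self, a, b, p_expected):
        res = ag.t_test_from_summary(ag.SummaryStats(*a), ag.SummaryStats(*b))
        assert res.p == pytest.approx(p_expected, abs=0.002)
        assert res.df == 2 * a[2] - 2

    def test_identical_summaries(self):
        s = ag.SummaryStats(50.0, 5.0, 30)
        res = ag.t_test_from_summary(s, s)
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means_is_p_one(self):
        res = ag.t_test_from_summary(ag.SummaryStats(1, 0, 5), ag.SummaryStats(1, 0, 5))
        assert res.p == 1.0 and res.degenerate

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ag.DegenerateDataError):
            ag.t_test_from_summary(ag.SummaryStats(1, 0, 5), ag.SummaryStats(2, 0, 5))


class TestPairedTTest:
    def test_all_zero_differences(self):
        res = ag.paired_t_test([0.0] * 5)
        assert res.t == 0.0 and res.p == 1.0

    def test_symmetric_two_point(self):
        res = ag.paired_t_test([1.0, -1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        res = ag.paired_t_test([2.0, 2.0, 2.0])
        assert res.degenerate and res.p == 0.0 and res.t == math.inf

    def test_matches_quadrature_oracle(self, rng):
        d = rng.normal(0.3, 1.0, 25)
        res = ag.paired_t_test(d)
        assert res.p == pytest.approx(t_sf_by_quadrature(res.t, 24), abs=1e-6)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_series_degenerate(self, rng):
        x = rng.normal(size=20)
        res = ag.bland_altman(x, x)
        assert res.bias == 0.0 and res.sd_d == 0.0 and res.degenerate
        assert res.agreement_pct == 100.0

    def test_alternating_unit_differences_closed_form(self):
        # 70 paired cases whose differences alternate -1, +1
        d = np.tile([-1.0, 1.0], 35)
        x = np.zeros(70) + d
        y = np.zeros(70)
        res = ag.bland_altman(x, y)
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        assert res.sd_d == pytest.approx(math.sqrt(70 / 69), abs=1e-12)
        assert res.agreement_pct == 100.0
        assert res.n == 70

    def test_difference_sd_approaches_sqrt2_error_sd(self, rng):
        # variance addition: independent device errors of SD sigma_e each
        sigma_e = 2.5
        theta = rng.normal(100, 10, 20000)
        x = theta + rng.normal(0, sigma_e, 20000)
        y = theta + rng.normal(0, sigma_e, 20000)
        res = ag.bland_altman(x, y)
        assert res.sd_d == pytest.approx(math.sqrt(2) * sigma_e, rel=0.03)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ag.bland_altman([1.0, 2.0], [1.0])

    def test_loa_midpoint_is_bias(self, rng):
        x, y = rng.normal(size=(2, 40))
        res = ag.bland_altman(x, y)
        assert (res.loa_low + res.loa_high) / 2 == pytest.approx(res.bias, abs=1e-12)
        assert res.mdc95 / res.sem == pytest.approx(ag.MDC_FACTOR, abs=1e-12)


class TestAgreementPct:
    def test_62_of_70_inside(self):
        d = np.r_[np.zeros(62), np.full(8, 99.0)]
        assert ag.agreement_pct(d, -1.0, 1.0) == pytest.approx(88.571, abs=0.001)

    def test_34_of_35_inside(self):
        d = np.r_[np.zeros(34), [99.0]]
        assert ag.agreement_pct(d, -1.0, 1.0) == pytest.approx(97.143, abs=0.001)

    def test_all_inside_and_boundary_inclusive(self):
        assert ag.agreement_pct([-1.0, 0.0, 1.0], -1.0, 1.0) == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ag.agreement_pct([], 0.0, 1.0)


# ---------------------------------------------------------------------------
# ANOVA and ICC
# ---------------------------------------------------------------------------


class TestAnova:
    def test_hand_worked_two_by_two(self):
        ms = ag.anova_two_way([[0.0, 0.0], [1.0, 1.0]])
        assert (ms.msr, ms.msc, ms.mse) == (1.0, 0.0, 0.0)

    def test_constant_matrix(self):
        ms = ag.anova_two_way(np.full((4, 2), 3.0))
        assert (ms.msr, ms.msc, ms.mse) == (0.0, 0.0, 0.0)

    def test_sums_of_squares_conserve_total(self, rng):
        for _ in range(20):
            m = rng.normal(size=(10, 2))
            ms = ag.anova_two_way(m)
            sst = ((m - m.mean()) ** 2).sum()
            reconstructed = 9 * ms.msr + 1 * ms.msc + 9 * ms.mse
            assert reconstructed == pytest.approx(sst, rel=1e-12)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            ag.anova_two_way([[1.0, np.nan], [2.0, 3.0]])


class TestIcc:
    def test_identical_columns_perfect_agreement(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert ag.icc(m, "single").estimate == pytest.approx(1.0)
        assert ag.icc(m, "average").estimate == pytest.approx(1.0)

    def test_offset_columns_match_variance_component_oracle(self):
        m = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        est = ag.icc(m, "single").estimate
        assert est == pytest.approx(brute_force_icc_single(m), abs=1e-10)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(50):
            m = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, 10)[:, None]
            est = ag.icc(m, "single").estimate
            assert est == pytest.approx(brute_force_icc_single(m), abs=1e-10)

    def test_average_form_at_least_single_form(self, rng):
        for _ in range(50):
            m = rng.normal(0, 1, (12, 2)) + rng.normal(0, 2, 12)[:, None]
            s = ag.icc(m, "single").estimate
            a = ag.icc(m, "average").estimate
            if s >= 0 and a >= 0:
                assert a >= s - 1e-12

    def test_ci_brackets_estimate(self, rng):
        m = rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, 20)[:, None]
        for form in ("single", "average"):
            res = ag.icc(m, form)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_constant_matrix_undefined(self):
        with pytest.raises(ag.DegenerateDataError):
            ag.icc(np.full((5, 2), 1.0))

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(0, 1, (15, 2)) + rng.normal(0, 1.5, 15)[:, None]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "y": m.ravel(),
            }
        )
        table = pg.intraclass_corr(df, "subject", "rater", "y").set_index("Type")
        single = ag.icc(m, "single")
        average = ag.icc(m, "average")
        assert single.estimate == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert average.estimate == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-9)
        lo, hi = table.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 dp
        assert single.ci_low == pytest.approx(lo, abs=0.006)
        assert single.ci_high == pytest.approx(hi, abs=0.006)


class TestGrading:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.941, "excellent"),
            (0.90, "excellent"),
            (0.8999, "good"),
            (0.75, "good"),
            (0.7499, "fair"),
            (0.50, "fair"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_boundaries(self, value, grade):
        assert ag.grade_icc(value) == grade

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ag.grade_icc(float("nan"))


class TestMdc95:
    @pytest.mark.parametrize("sem,expected", [(0.444, 1.231), (0.574, 1.591), (0.0, 0.0)])
    def test_known_values(self, sem, expected):
        assert ag.mdc95(sem) == pytest.approx(expected, abs=0.002)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ag.mdc95(-0.1)


class TestLinCcc:
    def test_identity_is_one(self, rng):
        x = rng.normal(size=30)
        assert ag.lin_ccc(x, x) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ag.lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_bounded_by_pearson(self, rng):
        for _ in range(30):
            x = rng.normal(size=25)
            y = 0.5 * x + rng.normal(0, 0.5, 25) + rng.normal()
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ag.lin_ccc(x, y)) <= abs(r) + 1e-12

    def test_equals_pearson_only_without_shift(self, rng):
        x = rng.normal(size=25)
        r = np.corrcoef(x, x)[0, 1]
        assert ag.lin_ccc(x, x) == pytest.approx(r)
        assert ag.lin_ccc(x, x + 1.0) < r

    def test_both_constant_undefined(self):
        with pytest.raises(ag.DegenerateDataError):
            ag.lin_ccc([1.0, 1.0], [2.0, 2.0])
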