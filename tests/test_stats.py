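"""Contingency statistics, rank tests, correlations, and power analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import benmap as bm
from benmap.stats import Coding, DegenerateTableError

TABLE = bm.ContingencyTable2x2(20, 5, 8, 11)  # male/female by ADHD/control

tables = st.tuples(*[st.integers(0, 60)] * 4).filter(
    lambda t: min(t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3]) > 0
)


class TestChiSquare2x2:
    def test_study_gender_table(self):
        res = bm.chi_square_2x2(TABLE)
        assert res.chi2 == pytest.approx(6.699, abs=5e-4)
        assert res.p == pytest.approx(0.010, abs=5e-4)

    def test_balanced_table_is_zero(self):
        assert bm.chi_square_2x2(bm.ContingencyTable2x2(10, 10, 10, 10)).chi2 == 0.0

    def test_hand_oracle_table(self):
        # expected counts [[3.5, 6.5], [3.5, 6.5]] -> chi2 = 1.978022
        res = bm.chi_square_2x2(bm.ContingencyTable2x2(5, 5, 2, 8))
        assert res.chi2 == pytest.approx(1.978022, abs=1e-6)

    @given(tables)
    def test_matches_scipy_without_correction(self, cells):
        t = bm.ContingencyTable2x2(*cells)
        expected = sps.chi2_contingency(t.as_array(), correction=False)
        res = bm.chi_square_2x2(t)
        assert res.chi2 == pytest.approx(expected.statistic, abs=1e-10)
        assert res.p == pytest.approx(expected.pvalue, abs=1e-10)

    @given(tables)
    def test_invariant_under_transpose_and_swaps(self, cells):
        a, b, c, d = cells
        base = bm.chi_square_2x2(bm.ContingencyTable2x2(a, b, c, d)).chi2
        transpose = bm.chi_square_2x2(bm.ContingencyTable2x2(a, c, b, d)).chi2
        swapped = bm.chi_square_2x2(bm.ContingencyTable2x2(d, c, b, a)).chi2
        assert base == pytest.approx(transpose, abs=1e-10)
        assert base == pytest.approx(swapped, abs=1e-10)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            bm.chi_square_2x2(bm.ContingencyTable2x2(0, 0, 5, 5))


class TestPhiCoefficient:
    def test_study_gender_table_signed(self):
        res = bm.phi_coefficient(TABLE)
        assert res.r == pytest.approx(-0.390, abs=5e-4)
        assert res.p == pytest.approx(0.009, abs=5e-4)

    def test_independence_gives_zero(self):
        assert bm.phi_coefficient(bm.ContingencyTable2x2(10, 10, 10, 10)).r == 0.0

    @given(tables)
    def test_magnitude_identity_with_chi_square(self, cells):
        t = bm.ContingencyTable2x2(*cells)
        phi = bm.phi_coefficient(t)
        chi2 = bm.chi_square_2x2(t)
        assert abs(phi.r) == pytest.approx(np.sqrt(chi2.chi2 / t.total), abs=1e-10)

    def test_sign_flips_with_coding(self):
        flipped = Coding(group_codes=(("control", 2), ("ADHD", 1)))
        assert bm.phi_coefficient(TABLE, flipped).r == pytest.approx(
            -bm.phi_coefficient(TABLE).r
        )

    def test_matches_pearson_correlation_of_coded_subjects(self):
        """phi equals an explicit Pearson correlation over the 44 subjects."""
        coding = bm.DEFAULT_CODING
        gender = np.array([1] * 20 + [2] * 5 + [1] * 8 + [2] * 11)
        group = np.array([2] * 25 + [1] * 19)
        expected = sps.pearsonr(gender, group)
        res = bm.phi_coefficient(TABLE, coding)
        assert res.r == pytest.approx(expected.statistic, abs=1e-12)
        assert res.p == pytest.approx(expected.pvalue, abs=1e-12)


class TestTTest:
    def test_identical_samples(self):
        res = bm.t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_large_separation(self):
        res = bm.t_test_two_sample([1, 2, 3], [11, 12, 13])
        assert abs(res.t) > 10 and res.p < 1e-3

    def test_welch_variant_available(self):
        x, y = [1.0, 2.0, 3.0, 9.0], [2.0, 2.5, 3.0]
        pooled = bm.t_test_two_sample(x, y, equal_var=True)
        welch = bm.t_test_two_sample(x, y, equal_var=False)
        assert pooled.df == 5
        assert welch.df < pooled.df

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            bm.t_test_two_sample([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        res = bm.mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0.0 and res.z < 0

    def test_identical_samples_z_zero(self):
        res = bm.mann_whitney_u([5, 5, 5], [5, 5])
        assert res.z == 0.0 and res.p == 1.0

    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=8),
        st.lists(st.integers(0, 10), min_size=1, max_size=8),
    )
    def test_u_equals_pair_count_oracle(self, x, y):
        """U is the exhaustive count of (x_i > y_j) pairs plus half-ties."""
        oracle = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        assert bm.mann_whitney_u(x, y).u == pytest.approx(oracle)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bm.mann_whitney_u([], [1.0])

    def test_z_matches_scipy_p_without_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        res = bm.mann_whitney_u(x, y)
        scipy_p = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic",
                                   use_continuity=False).pvalue
        assert res.p == pytest.approx(float(scipy_p), abs=1e-10)


class TestPointBiserial:
    def test_values_equal_codes_gives_unit_magnitude(self):
        groups = ["ADHD"] * 3 + ["control"] * 3
        values = [2.0] * 3 + [1.0] * 3  # exactly the default codes
        res = bm.point_biserial(values, groups)
        assert abs(res.r) == 1.0 and res.p == 0.0

    def test_equal_group_means_gives_zero(self):
        groups = ["ADHD", "ADHD", "control", "control"]
        res = bm.point_biserial([1.0, 3.0, 2.0, 2.0], groups)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_pointbiserial(self):
        rng = np.random.default_rng(9)
        groups = ["ADHD"] * 12 + ["control"] * 10
        values = np.concatenate([rng.normal(0.56, 0.14, 12),
                                 rng.normal(0.64, 0.11, 10)])
        codes = [bm.DEFAULT_CODING.group[g] for g in groups]
        expected = sps.pointbiserialr(codes, values)
        res = bm.point_biserial(values, groups)
        assert res.r == pytest.approx(expected.correlation, abs=1e-12)
        assert res.p == pytest.approx(expected.pvalue, abs=1e-10)

    def test_sign_is_negative_when_adhd_has_lower_values(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            values = np.concatenate([rng.normal(0.56, 0.14, 25),
                                     rng.normal(0.64, 0.11, 19)])
            groups = ["ADHD"] * 25 + ["control"] * 19
            hits += bm.point_biserial(values, groups).r < 0
        assert hits / 200 > 0.95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bm.point_biserial([1.0, 2.0, 3.0], ["ADHD", "ADHD", "ADHD"])


class TestPower:
    def test_null_permutation_calibration(self):
        """Pooled t on permuted labels of a null cohort rejects at ~alpha."""
        rng = np.random.default_rng(17)
        values = rng.normal(0.6, 0.12, 44)
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(44)
            res = bm.t_test_two_sample(values[perm[:25]], values[perm[25:]])
            rejections += res.p < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)

    def test_analytic_power_near_half_at_study_design(self):
        power = bm.analytic_ttest_power(0.56, 0.14, 25, 0.64, 0.11, 19)
        assert power == pytest.approx(0.5, abs=0.1)

    def test_simulated_rejection_is_seeded(self):
        a = bm.simulate_ttest_rejection(0.56, 0.14, 25, 0.64, 0.11, 19, seed=3)
        b = bm.simulate_ttest_rejection(0.56, 0.14, 25, 0.64, 0.11, 19, seed=3)
        assert a == b
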