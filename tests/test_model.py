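"""Unit and property tests for the GLS model core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import block_diag

from iwsdesign import (
    COMPLETE,
    PLACEBO_T1,
    PLACEBO_T2,
    T1_T2,
    Combination,
    CovarianceSpec,
    NonEstimableContrastError,
    build_covariance_matrix,
    combination_covariance,
    combination_information,
    contrast_variance,
    information_matrix,
    mean_covariance,
)


class TestCovarianceConstruction:
    def test_heterogeneous_covariances_match_printed_values(self, example_cov):
        D = build_covariance_matrix(example_cov)
        assert D[0, 1] == pytest.approx(33.54, abs=0.005)
        assert D[0, 2] == pytest.approx(36.74, abs=0.005)
        assert D[1, 2] == pytest.approx(41.08, abs=0.005)
        np.testing.assert_allclose(np.diag(D), (100.0, 125.0, 150.0))
        np.testing.assert_allclose(D, D.T)

    def test_zero_correlation_gives_identity(self):
        spec = CovarianceSpec((1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        np.testing.assert_allclose(spec.matrix(), np.eye(3))

    def test_offdiagonals_follow_direct_formula(self):
        spec = CovarianceSpec((1.0, 2.0, 4.0), (0.5, 0.5, 0.5))
        D = spec.matrix()
        np.testing.assert_allclose(
            (D[0, 1], D[0, 2], D[1, 2]),
            (0.5 * np.sqrt(2.0), 0.5 * 2.0, 0.5 * np.sqrt(8.0)),
        )

    def test_from_covariances_recovers_correlations(self):
        spec = CovarianceSpec.from_covariances((100.0, 125.0, 150.0), (33.541, 36.742, 41.079))
        assert spec.correlations == pytest.approx((0.3, 0.3, 0.3), abs=1e-4)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            CovarianceSpec((1.0, -1.0, 1.0), (0.0, 0.0, 0.0))

    def test_indefinite_matrix_rejected_naming_minor(self):
        # rho_01 = rho_02 = 0.9 with rho_12 = -0.9 violates positive
        # definiteness of the full 3x3 matrix (order-3 minor < 0)
        with pytest.raises(ValueError, match="order 3"):
            CovarianceSpec((1.0, 1.0, 1.0), (0.9, 0.9, -0.9))

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            CovarianceSpec((1.0, 1.0, 1.0), (1.2, 0.0, 0.0))


class TestCombinationTypes:
    def test_valid_combinations(self):
        assert Combination((0, 1)).label == "01"
        assert Combination((0, 1, 2)).label == "012"
        assert len(Combination((1, 2))) == 2

    @pytest.mark.parametrize("conds", [(0,), (0, 0), (0, 2, 1), (0, 3)])
    def test_invalid_combinations_rejected(self, conds):
        with pytest.raises(ValueError):
            Combination(conds)


class TestCombinationMatrices:
    def test_pair_covariance_is_submatrix(self, example_D):
        V = combination_covariance(example_D, PLACEBO_T1)
        np.testing.assert_allclose(
            V, [[100.0, example_D[0, 1]], [example_D[0, 1], 125.0]]
        )

    def test_full_combination_covariance_is_D(self, example_D):
        np.testing.assert_allclose(combination_covariance(example_D, COMPLETE), example_D)

    def test_diagonal_D_pair_is_diagonal(self):
        D = np.diag([1.0, 2.0, 4.0])
        np.testing.assert_allclose(
            combination_covariance(D, T1_T2), np.diag([2.0, 4.0])
        )

    def test_full_combination_information_is_D_inverse(self, example_D):
        np.testing.assert_allclose(
            combination_information(example_D, COMPLETE), np.linalg.inv(example_D)
        )

    def test_missing_condition_rows_are_zero(self, example_D):
        info = combination_information(example_D, PLACEBO_T1)
        np.testing.assert_array_equal(info[2], 0.0)
        np.testing.assert_array_equal(info[:, 2], 0.0)
        assert np.linalg.matrix_rank(info) == 2

    def test_pair_information_matches_explicit_inverse(self, example_D):
        # independent oracle: explicit 2x2 inversion and embedding
        a, b, c = example_D[0, 0], example_D[0, 1], example_D[1, 1]
        det = a * c - b * b
        Vinv = np.array([[c, -b], [-b, a]]) / det
        X = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(
            combination_information(example_D, PLACEBO_T1), X.T @ Vinv @ X
        )


class TestInformationMatrix:
    def test_complete_design_information(self, example_D):
        M = information_matrix({COMPLETE: 7}, example_D)
        np.testing.assert_allclose(M, 7 * np.linalg.inv(example_D))

    def test_single_subject_equals_combination_information(self, example_D):
        M = information_matrix({PLACEBO_T1: 1, PLACEBO_T2: 0}, example_D)
        np.testing.assert_allclose(M, combination_information(example_D, PLACEBO_T1))

    def test_example_allocation_matches_summation_oracle(self, example_D):
        M = information_matrix({PLACEBO_T1: 64, PLACEBO_T2: 36}, example_D)
        oracle = 64 * combination_information(example_D, PLACEBO_T1) + \
            36 * combination_information(example_D, PLACEBO_T2)
        np.testing.assert_allclose(M, oracle)

    def test_additivity_in_allocations(self, example_D):
        a = {PLACEBO_T1: 3, T1_T2: 2}
        b = {PLACEBO_T1: 1, PLACEBO_T2: 5}
        merged = {PLACEBO_T1: 4, PLACEBO_T2: 5, T1_T2: 2}
        np.testing.assert_allclose(
            information_matrix(merged, example_D),
            information_matrix(a, example_D) + information_matrix(b, example_D),
        )


class TestMeanCovariance:
    def test_complete_design_closed_form(self, example_D):
        mc = mean_covariance(information_matrix({COMPLETE: 50}, example_D))
        assert mc.estimable.all()
        np.testing.assert_allclose(mc.matrix, example_D / 50, rtol=1e-10)

    def test_uninformed_condition_flagged(self, example_D):
        mc = mean_covariance(information_matrix({PLACEBO_T1: 10}, example_D))
        assert list(mc.estimable) == [True, True, False]
        assert np.isnan(mc.matrix[2]).all()
        assert np.isfinite(mc.matrix[:2, :2]).all()

    def test_all_zero_information(self, example_D):
        mc = mean_covariance(np.zeros((3, 3)))
        assert not mc.estimable.any()
        assert np.isnan(mc.matrix).all()

    def test_example_allocation_contrast_variances(self, example_D):
        mc = mean_covariance(
            information_matrix({PLACEBO_T1: 64, PLACEBO_T2: 36}, example_D)
        )
        assert round(contrast_variance(mc, 1), 1) == 2.2
        assert round(contrast_variance(mc, 2), 1) == 4.2

    def test_paired_difference_closed_form(self, example_cov, example_D):
        n = 17
        mc = mean_covariance(information_matrix({PLACEBO_T1: n}, example_D))
        v = example_cov.variances
        s01 = example_cov.covariances[0]
        assert contrast_variance(mc, 1) == pytest.approx((v[0] + v[1] - 2 * s01) / n)

    def test_non_estimable_contrast_raises(self, example_D):
        mc = mean_covariance(information_matrix({PLACEBO_T1: 10}, example_D))
        with pytest.raises(NonEstimableContrastError, match="mu_2"):
            contrast_variance(mc, 2)

    def test_scenario2_matches_stacked_gls_oracle(self, example_D):
        # brute-force: stack every subject's selector matrix and invert the
        # full block-diagonal GLS normal equations in one shot
        counts = {PLACEBO_T1: 4, PLACEBO_T2: 3, T1_T2: 2}
        Xs, Vs = [], []
        for combo, n in counts.items():
            for _ in range(n):
                Xs.append(combo.selector())
                Vs.append(combination_covariance(example_D, combo))
        X = np.vstack(Xs)
        V = block_diag(*Vs)
        oracle = np.linalg.inv(X.T @ np.linalg.inv(V) @ X)
        mc = mean_covariance(information_matrix(counts, example_D))
        np.testing.assert_allclose(mc.matrix, oracle, rtol=1e-9)
        for t in (1, 2):
            a = np.array([1.0, -1.0, 0.0]) if t == 1 else np.array([1.0, 0.0, -1.0])
            assert contrast_variance(mc, t) == pytest.approx(a @ oracle @ a)


counts_strategy = st.tuples(
    st.integers(min_value=0, max_value=8),
    st.integers(min_value=0, max_value=8),
    st.integers(min_value=0, max_value=8),
)


class TestModelProperties:
    @given(counts=counts_strategy, extra=st.sampled_from([PLACEBO_T1, PLACEBO_T2, T1_T2]))
    def test_adding_a_subject_never_increases_contrast_variances(
        self, counts, extra
    ):
        cov = CovarianceSpec((1.0, 2.0, 4.0), (0.5, 0.3, 0.2))
        D = cov.matrix()
        base = dict(zip((PLACEBO_T1, PLACEBO_T2, T1_T2), counts))
        grown = dict(base)
        grown[extra] += 1
        mc0 = mean_covariance(information_matrix(base, D))
        mc1 = mean_covariance(information_matrix(grown, D))
        for t in (1, 2):
            try:
                before = contrast_variance(mc0, t)
            except NonEstimableContrastError:
                continue  # infinite before; any value after is an improvement
            after = contrast_variance(mc1, t)
            assert after <= before * (1 + 1e-9)

    @given(counts=counts_strategy, scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_D_scales_contrast_variances(self, counts, scale):
        base = CovarianceSpec((1.0, 2.0, 4.0), (0.5, 0.3, 0.2))
        scaled = CovarianceSpec(
            tuple(scale * v for v in base.variances), base.correlations
        )
        alloc = dict(zip((PLACEBO_T1, PLACEBO_T2, T1_T2), counts))
        mc0 = mean_covariance(information_matrix(alloc, base.matrix()))
        mc1 = mean_covariance(information_matrix(alloc, scaled.matrix()))
        for t in (1, 2):
            try:
                v0 = contrast_variance(mc0, t)
            except NonEstimableContrastError:
                with pytest.raises(NonEstimableContrastError):
                    contrast_variance(mc1, t)
                continue
            assert contrast_variance(mc1, t) == pytest.approx(scale * v0, rel=1e-9)

    @given(counts=counts_strategy)
    def test_swapping_treatment_labels_swaps_contrast_variances(self, counts):
        cov = CovarianceSpec((1.0, 2.0, 4.0), (0.5, 0.3, 0.2))
        # swap treatments 1 and 2: variances, covariances and counts
        swapped = CovarianceSpec((1.0, 4.0, 2.0), (0.3, 0.5, 0.2))
        alloc = dict(zip((PLACEBO_T1, PLACEBO_T2, T1_T2), counts))
        alloc_sw = {
            PLACEBO_T1: counts[1], PLACEBO_T2: counts[0], T1_T2: counts[2]
        }
        mc = mean_covariance(information_matrix(alloc, cov.matrix()))
        mc_sw = mean_covariance(information_matrix(alloc_sw, swapped.matrix()))
        for t, t_sw in ((1, 2), (2, 1)):
            try:
                v = contrast_variance(mc, t)
            except NonEstimableContrastError:
                with pytest.raises(NonEstimableContrastError):
                    contrast_variance(mc_sw, t_sw)
                continue
            assert contrast_variance(mc_sw, t_sw) == pytest.approx(v, rel=1e-9)
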