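"""Group statistics: Fisher transforms, t tests, map correlations."""

import numpy as np
import pytest
import scipy.stats

from tvcentrality import (
    TimeVaryingCentrality,
    ValidationError,
    compare_map_correlations,
    covariate_correlation,
    fisher_z,
    fisher_z_inverse,
    group_average_r_map,
    group_test,
    parcel_signal_correlation,
    spatial_map_correlation,
    z_threshold,
)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.log(3) / 2, abs=1e-12)
        assert float(fisher_z(0.5)) == pytest.approx(0.5493, abs=1e-4)

    def test_round_trip_identity(self, rng):
        r = rng.uniform(-0.99, 0.99, 100)
        np.testing.assert_allclose(fisher_z_inverse(fisher_z(r)), r,
                                   atol=1e-15)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_out_of_domain_rejected(self, r):
        with pytest.raises(ValidationError):
            fisher_z(r)

    def test_strictly_monotone(self, rng):
        r = np.sort(rng.uniform(-0.99, 0.99, 50))
        assert np.all(np.diff(fisher_z(r)) > 0)


class TestParcelSignalCorrelation:
    def test_parcel_equal_to_signal_gives_unit_r(self, rng):
        sig = rng.standard_normal(100)
        mat = np.vstack([sig, rng.standard_normal(100)])
        r = parcel_signal_correlation(mat, sig)
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_has_small_r(self, rng):
        mat = rng.standard_normal((30, 900))
        sig = rng.standard_normal(900)
        r = parcel_signal_correlation(mat, sig)
        # null sd ~ 1/sqrt(900) = 0.033; 0.1 = 3 sigma
        assert np.all(np.abs(r) < 0.1)

    def test_time_varying_input_trimmed_to_window_centers(self, rng):
        vals = rng.standard_normal((4, 30))
        centers = np.arange(10, 40)
        tv = TimeVaryingCentrality(values=vals, centers=centers, kind="ec",
                                   tr_seconds=1.0)
        sig = rng.standard_normal(50)
        r = parcel_signal_correlation(tv, sig)
        expect = np.corrcoef(vals[0], sig[10:40])[0, 1]
        assert r[0] == pytest.approx(expect, abs=1e-12)

    def test_signal_not_covering_centers_rejected(self, rng):
        tv = TimeVaryingCentrality(values=rng.standard_normal((2, 20)),
                                   centers=np.arange(30, 50), kind="ec",
                                   tr_seconds=1.0)
        with pytest.raises(ValidationError, match="cover"):
            parcel_signal_correlation(tv, np.ones(40))

    def test_lag_shifts_alignment(self, rng):
        sig = rng.standard_normal(120)
        mat = np.roll(sig, 3)[None, :]  # parcel follows signal by 3 TR
        r0 = parcel_signal_correlation(mat, sig)
        r3 = parcel_signal_correlation(
            TimeVaryingCentrality(values=mat, centers=np.arange(120),
                                  kind="ec", tr_seconds=1.0),
            sig, lag_s=3.0)
        assert r3[0] > 0.99 > abs(r0[0]) + 0.5


class TestGroupTest:
    def test_values_symmetric_about_zero_give_null_stats(self):
        vals = np.array([[0.3], [-0.3], [0.3], [-0.3]])
        gr = group_test(vals, mode="one_sample")
        row = gr.table.iloc[0]
        assert row.t == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0, abs=1e-12)
        assert row.Z == pytest.approx(0.0, abs=1e-9)

    def test_detects_strong_effect_at_fwe_001(self, rng):
        vals = rng.normal(0.5, 0.1, size=(20, 1))
        gr = group_test(vals, n_tests=60, fwe_level=0.01,
                        is_correlation=False)
        row = gr.table.iloc[0]
        assert row.p_corrected < 0.01 and row.significant
        # recovered mean within its 95% CI of the truth
        half = scipy.stats.t.ppf(0.975, 19) * vals.std(ddof=1) / np.sqrt(20)
        assert abs(row["mean"] - 0.5) < half

    def test_bonferroni_correction_arithmetic(self, rng):
        vals = rng.normal(0.1, 0.2, size=(12, 30))
        gr = group_test(vals, n_tests=360, is_correlation=False)
        np.testing.assert_allclose(
            gr.table.p_corrected, np.minimum(1.0, gr.table.p * 360),
            atol=1e-15)
        assert np.all(gr.table.p_corrected >= gr.table.p - 1e-15)

    def test_paired_mode_matches_scipy_ttest_rel(self, rng):
        a = rng.normal(0.3, 0.1, size=(15, 5))
        b = rng.normal(0.2, 0.1, size=(15, 5))
        gr = group_test(a, mode="paired", values_b=b)
        t_ref, p_ref = scipy.stats.ttest_rel(fisher_z(a), fisher_z(b))
        np.testing.assert_allclose(gr.table.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(gr.table.p, p_ref, atol=1e-10)

    def test_zero_variance_parcel_flagged_not_fatal(self):
        vals = np.column_stack([np.full(5, 0.4), [0.1, 0.2, 0.3, 0.2, 0.1]])
        gr = group_test(vals, is_correlation=False)
        assert np.isnan(gr.table.t.iloc[0])
        assert not gr.table.significant.iloc[0]
        assert np.isfinite(gr.table.t.iloc[1])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValidationError):
            group_test(np.zeros((2, 4)))

    def test_z_threshold_matches_normal_quantile(self):
        assert z_threshold(0.05, 1) == pytest.approx(1.959964, abs=1e-5)
        # FWE 0.01 over 360 parcels: two-tailed Bonferroni bound ~ 4.19
        assert z_threshold(0.01, 360) == pytest.approx(4.19, abs=0.01)


class TestGroupAverageRMap:
    def test_identical_r_is_fixed_point(self):
        r = np.full((5, 4), 0.37)
        np.testing.assert_allclose(group_average_r_map(r), 0.37, atol=1e-12)

    def test_two_participant_closed_form(self):
        r = np.array([[0.2], [0.6]])
        expect = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert group_average_r_map(r)[0] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.416, abs=0.005)

    def test_invariant_to_participant_order(self, rng):
        r = rng.uniform(-0.8, 0.8, size=(8, 10))
        perm = rng.permutation(8)
        np.testing.assert_allclose(group_average_r_map(r),
                                   group_average_r_map(r[perm]), atol=1e-14)


class TestSpatialMapCorrelation:
    def test_identity_and_affine_negation(self, rng):
        m = rng.random(30)
        assert spatial_map_correlation(m, m) == pytest.approx(1.0)
        assert spatial_map_correlation(m, -m + 5) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        a, b = rng.random(50), rng.random(50)
        ac, bc = a - a.mean(), b - b.mean()
        expect = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert spatial_map_correlation(a, b) == pytest.approx(expect,
                                                              abs=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            spatial_map_correlation(np.ones(4), np.ones(5))


class TestCompareMapCorrelations:
    def test_equal_correlations_give_null(self):
        z, p = compare_map_correlations(0.5, 0.5, 100)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_under_swap(self):
        z1, p1 = compare_map_correlations(0.78, 0.60, 360)
        z2, p2 = compare_map_correlations(0.60, 0.78, 360)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_known_case_closed_form(self):
        # (atanh .78 - atanh .60) / sqrt(2/357), frozen from the formula
        z, p = compare_map_correlations(0.78, 0.60, 360)
        assert z == pytest.approx(4.705, abs=0.005)
        assert p < 1e-5

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_map_correlations(0.5, 0.2, 3)


class TestCovariateCorrelation:
    def test_covariate_equal_to_parcel_gives_unit_r(self, rng):
        c = rng.standard_normal((10, 4))
        r = covariate_correlation(c, c[:, 2])
        assert r[2] == pytest.approx(1.0, abs=1e-10)

    def test_independent_covariate_mostly_inside_null_band(self, rng):
        c = rng.standard_normal((50, 200))
        v = rng.standard_normal(50)
        r = covariate_correlation(c, v)
        # 95% null band at n=50 is ~ +/- 0.28
        assert np.mean(np.abs(r) < 0.28) > 0.90

    def test_matches_direct_formula_on_toy_table(self):
        c = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0],
                      [4.0, 3.0], [5.0, 4.0]])
        v = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r = covariate_correlation(c, v)
        for j in range(2):
            expect = np.corrcoef(c[:, j], v)[0, 1]
            assert r[j] == pytest.approx(expect, abs=1e-12)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValidationError):
            covariate_correlation(rng.standard_normal((6, 3)), np.ones(6))
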