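"""Voxel TCP model: alpha sampling, LQ survival, Poisson control, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from atlastcp import (
    ProstateModel,
    RadiosensitivityParams,
    TreatmentSchedule,
    VoxelGrid,
    alpha_quadrature,
    overall_tcp,
    sample_alpha,
    surviving_fraction,
    tcp_map,
    voxel_tcp,
)

from conftest import single_voxel_model


# ---------------------------------------------------------------------------
# alpha distribution
# ---------------------------------------------------------------------------


class TestSampleAlpha:
    def test_all_samples_inside_truncation_window(self, ref_params):
        vals = sample_alpha(ref_params, 10_000, seed=1)
        assert vals.min() >= ref_params.alpha_low
        assert vals.max() <= ref_params.alpha_high

    def test_deterministic_for_fixed_seed(self, ref_params):
        a = sample_alpha(ref_params, 500, seed=7)
        b = sample_alpha(ref_params, 500, seed=7)
        np.testing.assert_array_equal(a, b)
        c = sample_alpha(ref_params, 500, seed=8)
        assert not np.array_equal(a, c)

    def test_mean_matches_truncated_density_quadrature(self, ref_params):
        # oracle: first two moments of the truncated log-normal by quadrature
        dist = ref_params.alpha_distribution()
        lo, hi = ref_params.alpha_low, ref_params.alpha_high
        z = dist.cdf(hi) - dist.cdf(lo)
        mean = integrate.quad(lambda x: x * dist.pdf(x) / z, lo, hi)[0]
        var = integrate.quad(
            lambda x: (x - mean) ** 2 * dist.pdf(x) / z, lo, hi
        )[0]
        n = 100_000
        vals = sample_alpha(ref_params, n, seed=11)
        se = np.sqrt(var / n)
        assert abs(vals.mean() - mean) < 3 * se

    def test_degenerate_window_collapses_to_a_point(self):
        eps = 1e-6
        p = RadiosensitivityParams(alpha_low=0.15 - eps, alpha_high=0.15 + eps)
        vals = sample_alpha(p, 1000, seed=0)
        assert np.all(np.abs(vals - 0.15) <= eps)

    def test_infeasible_window_raises_naming_bounds(self):
        # window so narrow its probability mass vanishes in double precision
        p = RadiosensitivityParams(
            alpha_low=0.15 - 5e-15, alpha_high=0.15 + 5e-15
        )
        with pytest.raises(ValueError, match="0.15"):
            sample_alpha(p, 10, seed=0)

    def test_quadrature_weights_normalized_and_consistent(self, ref_params):
        nodes, w = alpha_quadrature(ref_params, 128)
        assert w.sum() == pytest.approx(1.0)
        # quadrature first moment agrees with the sampling mean estimate
        vals = sample_alpha(ref_params, 200_000, seed=3)
        assert np.dot(nodes, w) == pytest.approx(vals.mean(), abs=4e-4)


# ---------------------------------------------------------------------------
# LQ survival and voxel TCP
# ---------------------------------------------------------------------------


class TestSurvivingFraction:
    def test_zero_dose_zero_time_gives_unity(self):
        s = TreatmentSchedule(n_fractions=1, t_exp=0.0)
        assert surviving_fraction(0.15, 1.77, s, 0.0) == pytest.approx(1.0)

    def test_scalar_oracle_single_fraction(self):
        # exp(-0.15*2 - (0.15/1.77)*4), no repopulation
        s = TreatmentSchedule(n_fractions=1, t_exp=0.0)
        assert surviving_fraction(0.15, 1.77, s, 2.0) == pytest.approx(
            0.5278289263783819, rel=1e-12
        )

    def test_full_doubling_time_at_zero_dose_gives_two(self):
        s = TreatmentSchedule(n_fractions=5, t_exp=42.0, t_pot=42.0)
        assert surviving_fraction(0.2, 3.0, s, 0.0) == pytest.approx(2.0)

    def test_rejects_nonfinite_and_nonpositive_inputs(self):
        s = TreatmentSchedule(n_fractions=1)
        with pytest.raises(ValueError):
            surviving_fraction(np.nan, 1.77, s, 2.0)
        with pytest.raises(ValueError):
            surviving_fraction(-0.1, 1.77, s, 2.0)
        with pytest.raises(ValueError):
            surviving_fraction(0.15, 1.77, s, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(0.05, 0.4),
        ab1=st.floats(1.0, 8.0),
        delta=st.floats(0.01, 2.0),
        d=st.floats(0.1, 8.0),
    )
    def test_survival_increases_with_ab_ratio(self, alpha, ab1, delta, d):
        # larger alpha/beta -> smaller quadratic kill -> larger SF
        s = TreatmentSchedule(n_fractions=5, t_exp=0.0)
        sf1 = surviving_fraction(alpha, ab1, s, d)
        sf2 = surviving_fraction(alpha, ab1 + delta, s, d)
        assert sf2 > sf1


class TestVoxelTcp:
    def test_no_clonogens_certain_control(self):
        assert voxel_tcp(0.0, 0.73) == pytest.approx(1.0)

    def test_scalar_oracle(self):
        assert voxel_tcp(100.0, 0.05) == pytest.approx(0.006737946999085467)

    def test_huge_dose_limit_approaches_one(self):
        s = TreatmentSchedule(n_fractions=40, t_exp=0.0)
        sf = surviving_fraction(0.15, 1.77, s, 10.0)
        assert voxel_tcp(100.0, sf) == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            voxel_tcp(-1.0, 0.5)
        with pytest.raises(ValueError):
            voxel_tcp(10.0, -0.5)


# ---------------------------------------------------------------------------
# overall TCP and maps
# ---------------------------------------------------------------------------


def _uniform_model(shape, clonogens, d, ab, fixed_alpha=None):
    grid = VoxelGrid(shape, (2.0, 2.0, 2.0))
    mask = np.ones(shape, dtype=bool)
    return ProstateModel.homogeneous(grid, mask, clonogens, d, ab, fixed_alpha)


class TestOverallTcp:
    def test_single_voxel_fixed_alpha_equals_voxel_tcp(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        m = single_voxel_model(1e4, 3.0, 1.77, fixed_alpha=[(0.12, 1.0)])
        res = overall_tcp(m, s, ref_params, n_realizations=10, seed=0)
        sf = surviving_fraction(0.12, 1.77, s, 3.0)
        assert res.overall_tcp == pytest.approx(float(voxel_tcp(1e4, sf)))

    def test_two_voxel_product_rule(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        grid = VoxelGrid((2, 1, 1), (2.0, 2.0, 2.0))
        mask = np.ones((2, 1, 1), dtype=bool)
        m = ProstateModel.homogeneous(grid, mask, 5e3, 3.0, 1.77, [(0.13, 1.0)])
        m.clonogens[1, 0, 0] = 2e4
        res = overall_tcp(m, s, ref_params, 5, seed=0)
        sf = surviving_fraction(0.13, 1.77, s, 3.0)
        expected = float(voxel_tcp(5e3, sf) * voxel_tcp(2e4, sf))
        assert res.overall_tcp == pytest.approx(expected)

    def test_monte_carlo_matches_quadrature_oracle(self, ref_params):
        # 3x3x3 sampled-alpha model vs numerical integration over the
        # truncated log-normal density
        s = TreatmentSchedule.weekday(20, 60.0)
        m = _uniform_model((3, 3, 3), 400.0, 3.0, 1.77)
        n_real = 10_000
        res = overall_tcp(m, s, ref_params, n_real, seed=13)

        n_total = 400.0 * 27
        dist = ref_params.alpha_distribution()
        lo, hi = ref_params.alpha_low, ref_params.alpha_high
        z = dist.cdf(hi) - dist.cdf(lo)

        def integrand(alpha):
            sf = surviving_fraction(alpha, 1.77, s, 3.0)
            return float(np.exp(-n_total * sf)) * dist.pdf(alpha) / z

        expected = integrate.quad(integrand, lo, hi, limit=200)[0]
        second = integrate.quad(
            lambda a: (np.exp(-n_total * surviving_fraction(a, 1.77, s, 3.0)))
            ** 2 * dist.pdf(a) / z,
            lo, hi, limit=200,
        )[0]
        se = np.sqrt(max(second - expected**2, 0.0) / n_real)
        assert abs(res.overall_tcp - expected) < 3 * se

    def test_empty_mask_rejected(self, ref_params):
        grid = VoxelGrid((2, 2, 2), (1.0, 1.0, 1.0))
        m = ProstateModel.homogeneous(
            grid, np.zeros((2, 2, 2), dtype=bool), 10, 2.0, 1.77
        )
        with pytest.raises(ValueError, match="empty"):
            overall_tcp(m, TreatmentSchedule(1), ref_params, 1, seed=0)

    def test_conflicting_alpha_specs_rejected(self, ref_params):
        m = single_voxel_model(10, 2.0, 1.77, fixed_alpha=[(0.1, 1.0)])
        m.alpha_sample[:] = True  # voxel now claims both specs
        with pytest.raises(ValueError, match="both"):
            overall_tcp(m, TreatmentSchedule(1), ref_params, 1, seed=0)

    def test_result_reproducible_for_seed(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        m = _uniform_model((3, 3, 3), 300.0, 3.0, 1.77)
        r1 = overall_tcp(m, s, ref_params, 200, seed=5)
        r2 = overall_tcp(m, s, ref_params, 200, seed=5)
        assert r1.overall_tcp == r2.overall_tcp
        np.testing.assert_array_equal(r1.voxel_map, r2.voxel_map)


class TestTcpMap:
    def test_uniform_model_gives_constant_map(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        m = _uniform_model((4, 4, 4), 200.0, 3.0, 1.77, [(0.12, 1.0)])
        vm = tcp_map(m, s, ref_params, 5, seed=0)
        vals = vm[np.isfinite(vm)]
        assert vals.size == 64
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_clonogens_lowers_only_that_voxel(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        m1 = _uniform_model((3, 3, 3), 200.0, 3.0, 1.77, [(0.12, 1.0)])
        m2 = _uniform_model((3, 3, 3), 200.0, 3.0, 1.77, [(0.12, 1.0)])
        m2.clonogens[1, 1, 1] *= 2
        vm1 = tcp_map(m1, s, ref_params, 5, seed=0)
        vm2 = tcp_map(m2, s, ref_params, 5, seed=0)
        assert vm2[1, 1, 1] < vm1[1, 1, 1]
        other = np.ones((3, 3, 3), dtype=bool)
        other[1, 1, 1] = False
        np.testing.assert_allclose(vm2[other], vm1[other])

    def test_nonmask_voxels_flagged_absent(self, ref_params):
        grid = VoxelGrid((3, 3, 3), (1.0, 1.0, 1.0))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        m = ProstateModel.homogeneous(grid, mask, 100.0, 2.0, 1.77, [(0.1, 1.0)])
        vm = tcp_map(m, TreatmentSchedule.weekday(20, 60.0), ref_params, 3, seed=0)
        assert np.isfinite(vm[0, 0, 0])
        assert np.isnan(vm).sum() == 26


# ---------------------------------------------------------------------------
# Invariants
# ---------------------------------------------------------------------------


class TestModelInvariants:
    def test_tcp_monotone_in_clonogens_and_dose(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        base = _uniform_model((3, 3, 3), 300.0, 3.0, 1.77, [(0.12, 1.0)])
        t0 = overall_tcp(base, s, ref_params, 3, seed=0).overall_tcp
        heavier = _uniform_model((3, 3, 3), 450.0, 3.0, 1.77, [(0.12, 1.0)])
        assert overall_tcp(heavier, s, ref_params, 3, seed=0).overall_tcp < t0
        hotter = _uniform_model((3, 3, 3), 300.0, 3.3, 1.77, [(0.12, 1.0)])
        assert overall_tcp(hotter, s, ref_params, 3, seed=0).overall_tcp > t0

    def test_tcp_strictly_decreasing_in_ab_ratio(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        prev = None
        for ab in (1.5, 2.0, 3.0, 5.0, 8.0):
            m = _uniform_model((3, 3, 3), 300.0, 3.0, ab, [(0.12, 1.0)])
            t = overall_tcp(m, s, ref_params, 3, seed=0).overall_tcp
            if prev is not None:
                assert t < prev
            prev = t

    def test_product_decomposition_over_mask_partition(self, ref_params):
        s = TreatmentSchedule.weekday(20, 60.0)
        rng = np.random.default_rng(4)
        grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0))
        full = np.ones((4, 4, 4), dtype=bool)
        cl = rng.uniform(50, 500, size=(4, 4, 4))
        m_full = ProstateModel.homogeneous(grid, full, 0, 3.0, 1.77, [(0.12, 1.0)])
        m_full.clonogens = cl
        t_full = overall_tcp(m_full, s, ref_params, 1, seed=0).overall_tcp
        part = np.zeros((4, 4, 4), dtype=bool)
        part[:2] = True
        prod = 1.0
        for sub in (part, ~part):
            m = ProstateModel.homogeneous(
                grid, sub, 0, 3.0, 1.77, [(0.12, 1.0)]
            )
            m.clonogens = np.where(sub, cl, 0.0)
            prod *= overall_tcp(m, s, ref_params, 1, seed=0).overall_tcp
        assert t_full == pytest.approx(prod, rel=1e-9)

    def test_longer_treatment_time_never_raises_tcp(self, ref_params):
        short = TreatmentSchedule(20, 60.0, t_exp=25.0)
        longer = TreatmentSchedule(20, 60.0, t_exp=46.0)
        m = _uniform_model((3, 3, 3), 300.0, 3.0, 1.77, [(0.12, 1.0)])
        t_short = overall_tcp(m, short, ref_params, 3, seed=0).overall_tcp
        t_long = overall_tcp(m, longer, ref_params, 3, seed=0).overall_tcp
        assert t_long < t_short


class TestParameterValidation:
    def test_gp_alpha_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            RadiosensitivityParams(
                gp_alpha={2: 0.1, 3: 0.12, 4: 0.11, 5: 0.09}
            )

    def test_gs_ab_must_increase_within_bounds(self):
        good = dict(
            zip(
                ("2+2", "3+2", "3+3", "3+4", "4+3", "4+4", "4+5", "5+4", "5+5"),
                (1.54, 1.87, 2.05, 2.11, 2.16, 2.34, 2.67, 2.92, 3.05),
            )
        )
        RadiosensitivityParams(gs_ab=good)  # valid
        bad = dict(good, **{"5+5": 9.0})
        with pytest.raises(ValueError, match=r"\[1.0, 8.3\]"):
            RadiosensitivityParams(gs_ab=bad)

    def test_weekday_schedule_elapsed_days(self):
        # 20 fractions at 5/week: 3 full weeks + 4 weekdays
        assert TreatmentSchedule.weekday(20, 60.0).t_exp == 25.0
        assert TreatmentSchedule.weekday(5, 36.25).t_exp == 4.0
        assert TreatmentSchedule.weekday(1, 8.0).t_exp == 0.0
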