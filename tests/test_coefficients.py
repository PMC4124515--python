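"""Coefficient families, their derived quantities, and smallness checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurofrag as nf
from neurofrag.coefficients import b_star_quadrature


class TestThreshold:
    def test_pivot_activities_closed_form(self):
        # frozen from the closed form 1/(2e^a - 1), e^a/(2e^a - 1) at a = 2
        nm, np_ = nf.n_plus_minus(2.0)
        assert nm == pytest.approx(0.072578883495753825, rel=1e-14)
        assert np_ == pytest.approx(0.53628944174787691, rel=1e-14)

    def test_pivot_limits(self):
        nm, np_ = nf.n_plus_minus(1e-9)
        assert nm == pytest.approx(1.0, abs=1e-8)
        assert np_ == pytest.approx(1.0, abs=1e-8)
        nm, np_ = nf.n_plus_minus(30.0)
        assert nm < 1e-12
        assert np_ == pytest.approx(0.5, abs=1e-12)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            nf.n_plus_minus(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_pivot_ordering(self, alpha):
        nm, np_ = nf.n_plus_minus(alpha)
        assert 0.0 < nm < np_ < 1.0

    @pytest.mark.parametrize(
        "x, alpha, expected",
        [
            (0.0, 2.0, 4.0),  # weak stimulation: sigma = 2*alpha
            (1.0, 3.0, 3.0),  # strong stimulation: sigma = alpha
        ],
    )
    def test_sigma_plateaus(self, x, alpha, expected):
        rule = nf.ThresholdRule(alpha=alpha)
        assert nf.sigma_of(x, rule) == pytest.approx(expected, rel=1e-14)

    def test_sigma_at_upper_pivot_is_alpha(self):
        # 2a - ln(N+) + ln(N-) = 2a - a since N+/N- = e^a
        rule = nf.ThresholdRule(alpha=2.0)
        assert nf.sigma_of(rule.N_plus, rule) == pytest.approx(2.0, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.0, max_value=2.0),
        st.floats(min_value=0.0, max_value=2.0),
        st.floats(min_value=0.2, max_value=6.0),
    )
    def test_sigma_non_increasing(self, x1, x2, alpha):
        rule = nf.ThresholdRule(alpha=alpha)
        lo, hi = min(x1, x2), max(x1, x2)
        assert nf.sigma_of(lo, rule) >= nf.sigma_of(hi, rule) - 1e-12

    def test_sigma_range(self):
        rule = nf.ThresholdRule(alpha=1.7)
        x = np.linspace(0, 3, 301)
        sig = nf.sigma_of(x, rule)
        assert np.all(sig >= rule.sigma_minus - 1e-12)
        assert np.all(sig <= rule.sigma_plus + 1e-12)


class TestFiringRate:
    def test_step_indicator_with_closed_boundary(self):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        assert nf.firing_rate_eval(3.9, 0.0, rate) == 0.0
        assert nf.firing_rate_eval(4.0, 0.0, rate) == 1.0  # p(sigma, N) = pM

    def test_ramp_midpoint(self):
        rate = nf.FiringRate(
            family="regularized", threshold=1.0, pM=2.0, smoothing_width=0.2
        )
        assert nf.firing_rate_eval(0.9, 0.0, rate) == pytest.approx(1.0)
        assert nf.firing_rate_eval(1.0, 0.0, rate) == 2.0
        assert nf.firing_rate_eval(5.0, 0.0, rate) == 2.0

    def test_rate_bounds_and_ceiling_beyond_threshold(self):
        rate = nf.FiringRate(
            family="regularized",
            threshold=nf.ThresholdRule(alpha=1.5),
            pM=0.8,
            smoothing_width=0.1,
        )
        s = np.linspace(0, 10, 1001)
        for N in (0.0, 0.1, 0.5, 0.9):
            p = nf.firing_rate_eval(s, N, rate)
            assert np.all((0.0 <= p) & (p <= rate.pM))
            sig = rate.sigma(N)
            assert np.all(p[s >= sig] == rate.pM)

    def test_eta_bound(self):
        const = nf.FiringRate(family="regularized", threshold=0.3)
        assert const.eta_bound() == 0.0
        coupled_step = nf.FiringRate(
            family="step", threshold=nf.ThresholdRule(alpha=2.0)
        )
        assert math.isinf(coupled_step.eta_bound())


class TestKernel:
    def test_cdf_point_map_examples(self, half_reset_kernel, full_reset_kernel):
        assert nf.kernel_cdf(half_reset_kernel, 0.3, 0.4) == 1.0  # 0.3 >= 0.2
        assert nf.kernel_cdf(full_reset_kernel, 1e-6, 5.0) == 1.0
        assert nf.kernel_cdf(half_reset_kernel, 0.19, 0.4) == 0.0

    def test_cdf_saturates_at_discharge_state(self, half_reset_kernel):
        assert nf.kernel_cdf(half_reset_kernel, 0.4, 0.4) == 1.0
        assert nf.kernel_cdf(half_reset_kernel, 7.0, 0.4) == 1.0

    def test_cdf_matches_indicator_on_random_pairs(self, rng, half_reset_kernel):
        for _ in range(100):
            s, u = rng.uniform(0, 10, 2)
            expected = 1.0 if s >= 0.5 * u else 0.0
            assert nf.kernel_cdf(half_reset_kernel, s, u) == expected

    @pytest.mark.parametrize("slope, expected", [(0.5, 0.5), (0.0, 0.0), (0.9, 0.9)])
    def test_theta_linear_maps(self, slope, expected):
        kern = nf.FragmentationKernel.point_map_linear(slope)
        assert nf.kernel_theta(kern) == pytest.approx(expected, abs=1e-12)

    def test_theta_rejects_identity_map(self):
        kern = nf.FragmentationKernel(family="point_map", psi=lambda u: np.asarray(u))
        with pytest.raises(nf.KernelAdmissibilityError):
            nf.kernel_theta(kern)

    def test_density_kernel_theta_uniform(self):
        # K(s,u) = 1/u on [0,u]: first moment u/2, so theta = 1/2
        def density(s, u):
            s = np.asarray(s, dtype=float)
            if u == 0:
                return np.where(s == 0, 1.0, 0.0)
            return np.where(s <= u, 1.0 / u, 0.0)

        kern = nf.FragmentationKernel(family="density", density_values=density)
        assert nf.kernel_theta(kern) == pytest.approx(0.5, abs=5e-3)


class TestKernelDiscretization:
    @pytest.mark.parametrize("slope", [0.0, 0.5, 0.9])
    @pytest.mark.parametrize("n_cells", [37, 200])
    def test_columns_stochastic_point_maps(self, slope, n_cells):
        grid = nf.Grid(s_max=8.0, n_cells=n_cells)
        kd = nf.discretize_kernel(nf.FragmentationKernel.point_map_linear(slope), grid)
        colsums = np.asarray(kd.redistribution_matrix.sum(axis=0)).ravel()
        assert np.max(np.abs(colsums - 1.0)) < 1e-12

    def test_columns_stochastic_density_kernel(self):
        def density(s, u):
            s = np.asarray(s, dtype=float)
            if u == 0:
                return np.where(s == 0, 1.0, 0.0)
            return np.where(s <= u, 1.0 / u, 0.0)

        grid = nf.Grid(s_max=5.0, n_cells=101)
        kern = nf.FragmentationKernel(family="density", density_values=density)
        kd = nf.discretize_kernel(kern, grid)
        colsums = np.asarray(kd.redistribution_matrix.sum(axis=0)).ravel()
        assert np.max(np.abs(colsums - 1.0)) < 1e-12

    def test_lower_triangular(self, half_reset_kernel):
        grid = nf.Grid(s_max=4.0, n_cells=80)
        kd = nf.discretize_kernel(half_reset_kernel, grid)
        coo = kd.redistribution_matrix.tocoo()
        assert np.all(coo.row <= coo.col)

    def test_full_reset_deposits_in_first_cell(self, full_reset_kernel):
        grid = nf.Grid(s_max=4.0, n_cells=64)
        kd = nf.discretize_kernel(full_reset_kernel, grid)
        mass = np.ones(grid.n_cells)
        routed = kd.apply(mass)
        assert routed[0] == pytest.approx(grid.n_cells)
        assert np.all(routed[1:] == 0.0)

    def test_half_map_even_node_single_cell(self, half_reset_kernel):
        # psi(u_j) = j*ds/2 lands exactly on node j/2 for even j
        grid = nf.Grid(s_max=4.0, n_cells=40)
        kd = nf.discretize_kernel(half_reset_kernel, grid)
        col = kd.redistribution_matrix[:, 10].toarray().ravel()
        assert col[5] == pytest.approx(1.0)
        assert np.count_nonzero(col) == 1

    def test_first_moment_preserved(self, half_reset_kernel):
        grid = nf.Grid(s_max=4.0, n_cells=57)
        kd = nf.discretize_kernel(half_reset_kernel, grid)
        for j in (3, 20, 41):
            col = kd.redistribution_matrix[:, j].toarray().ravel()
            mean_arrival = float(np.sum(grid.nodes * col))
            assert mean_arrival == pytest.approx(0.5 * grid.nodes[j], abs=1e-12)


class TestSmallness:
    def test_b_star_closed_form(self):
        # p* = 1 on [0, 0.1], no variation, theta = 0.5:
        # B* = e^{0.1} * 0.5 * 0.1
        val = b_star_quadrature(lambda s: np.ones_like(s), 0.1, 0.5)
        assert val == pytest.approx(0.055258545903782381, rel=1e-10)

    def test_b_star_zero_when_flat_and_uncontracted(self):
        val = b_star_quadrature(lambda s: np.ones_like(s), 0.5, 0.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_b_star_matches_fine_quadrature(self, half_reset_kernel):
        rate = nf.FiringRate(
            family="regularized", threshold=0.4, pM=1.0, smoothing_width=0.25
        )
        coarse = nf.compute_B_star(rate, half_reset_kernel, 0.0, n_quad=4096)
        fine = nf.compute_B_star(rate, half_reset_kernel, 0.0, n_quad=40960)
        assert coarse == pytest.approx(fine, rel=1e-6)

    def test_step_rate_b_star_exceeds_one(self, half_reset_kernel):
        # sharp threshold rates of the oscillatory regime: B* = sigma* * pM
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        b = nf.compute_B_star(rate, half_reset_kernel, 0.0)
        assert b >= 1.0

    def test_condition_report_weak_coupling(self, weak_coupling_setup):
        rate, kern = weak_coupling_setup
        report = nf.check_assumptions(rate, kern, A_star=1.0)
        assert report.B_star < 1.0
        assert report.condition_15_holds
        assert report.condition_16_holds and report.mu_star > 0
        assert report.theta_estimate == pytest.approx(0.5, abs=1e-12)

    def test_condition_report_nu_b1_examples(self, full_reset_kernel, half_reset_kernel, constant_rate):
        rep_half = nf.check_assumptions(constant_rate, half_reset_kernel, A_star=0.0)
        assert rep_half.nu_B1 == pytest.approx(0.5, abs=1e-9)
        rep_full = nf.check_assumptions(constant_rate, full_reset_kernel, A_star=0.0)
        assert rep_full.theta_estimate == pytest.approx(0.0, abs=1e-12)
        assert rep_full.nu_B1 == pytest.approx(1.0, abs=1e-9)

    def test_condition_report_flags_step_rate(self, half_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        report = nf.check_assumptions(rate, half_reset_kernel, A_star=0.2)
        assert "outside smallness hypotheses" in report.notes
        assert report.nu_B1 is None
        assert not report.condition_15_holds
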