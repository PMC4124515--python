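"""Conservative transport-discharge-redistribution scheme."""

import math

import numpy as np
import pytest

import neurofrag as nf


def renewal_oracle(grid, p_vals, n0, T):
    """Independent age-structured solver: boundary influx n(0,t) = N(t)
    instead of a redistribution matrix (full-reset dynamics only)."""
    vals = n0.copy()
    for _ in range(int(round(T / grid.dt))):
        N = grid.ds * np.sum(p_vals * vals)
        vals = vals * np.exp(-p_vals * grid.dt)
        new = np.empty_like(vals)
        new[1:] = vals[:-1]
        new[0] = N
        vals = new
    return vals


class TestInitialData:
    def test_exp_decay_mass_and_origin(self):
        grid = nf.Grid(s_max=20.0, n_cells=2000)
        state = nf.initial_data("exp_decay", grid)
        assert state.mass == pytest.approx(1.0, abs=1e-14)
        assert state.values[0] == pytest.approx(1.0, abs=0.02)

    def test_multi_bump_structure(self):
        grid = nf.Grid(s_max=8.0, n_cells=800)
        state = nf.initial_data(
            "multi_bump", grid, centers=(1.0, 3.0), widths=0.2
        )
        assert state.mass == pytest.approx(1.0, abs=1e-14)
        v = state.values
        interior_maxima = np.nonzero(
            (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > 0.1 * v.max())
        )[0]
        assert len(interior_maxima) == 2

    def test_zero_profile_rejected(self):
        grid = nf.Grid(s_max=1.0, n_cells=10)
        with pytest.raises(ValueError, match="zero mass"):
            nf.initial_data("multi_bump", grid, centers=(50.0,), widths=0.01)


class TestActivityEquation:
    def test_constant_rate_gives_ceiling(self):
        rate = nf.FiringRate(family="regularized", threshold=0.0, pM=0.7)
        grid = nf.Grid(s_max=10.0, n_cells=500)
        state = nf.initial_data("exp_decay", grid)
        assert nf.solve_total_activity(state, rate, 0.0) == pytest.approx(0.7, rel=1e-12)

    def test_constant_threshold_tail_integral(self):
        rate = nf.FiringRate(family="step", threshold=2.0, pM=1.0)
        grid = nf.Grid(s_max=20.0, n_cells=2000)
        state = nf.initial_data("exp_decay", grid)
        N = nf.solve_total_activity(state, rate, 0.0)
        tail = grid.ds * state.values[grid.nodes >= 2.0].sum()
        assert N == pytest.approx(tail, rel=1e-12)

    def test_coupled_step_rate_exp_data(self):
        # e^{-s} initial data, alpha = 2: only the weak-stimulation branch
        # sigma = 4 is self-consistent, so N = e^{-4}
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        grid = nf.default_grid(rate, ds=0.01)
        state = nf.initial_data("exp_decay", grid)
        N = nf.solve_total_activity(state, rate, 0.0)
        assert N == pytest.approx(0.018315638888734180, rel=1e-6)

    def test_root_rules_agree_in_unique_regime(self):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        grid = nf.default_grid(rate, ds=0.02)
        state = nf.initial_data("exp_decay", grid)
        n_cont = nf.solve_total_activity(state, rate, 0.0, "continuation")
        n_large = nf.solve_total_activity(state, rate, 0.0, "largest")
        assert n_cont == pytest.approx(n_large, abs=1e-10)


class TestStep:
    def test_pure_shift_without_discharge(self):
        # threshold beyond the domain: p = 0 everywhere inside
        rate = nf.FiringRate(family="step", threshold=100.0, pM=1.0)
        grid = nf.Grid(s_max=4.0, n_cells=80)
        kd = nf.discretize_kernel(nf.FragmentationKernel.full_reset(), grid)
        state = nf.initial_data("multi_bump", grid, centers=(1.0,), widths=0.2)
        before = state.values.copy()
        new, N = nf.step(state, rate, kd, 0.0, reflecting_tail=False)
        assert N == 0.0
        assert np.array_equal(new.values[1:], before[:-1])
        assert new.values[0] == 0.0

    def test_constant_rate_stationary_profile_residual(self, full_reset_kernel):
        # pM e^{-pM s} solves the continuum steady problem; the discrete
        # drift after stepping shrinks linearly with ds
        drift = {}
        for ds in (0.04, 0.02):
            rate = nf.FiringRate(family="regularized", threshold=0.0, pM=1.0)
            grid = nf.Grid.from_ds(16.0, ds)
            kd = nf.discretize_kernel(full_reset_kernel, grid)
            vals = np.exp(-grid.nodes)
            vals /= grid.ds * vals.sum()
            state = nf.DensityState(grid, vals)
            for _ in range(10):
                state, _ = nf.step(state, rate, kd, 1.0)
            drift[ds] = grid.ds * np.abs(state.values - vals).sum()
        assert drift[0.04] < 0.1
        assert drift[0.02] < 0.65 * drift[0.04]

    def test_mass_conserved_over_100_steps(self, half_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        grid = nf.default_grid(rate, ds=0.02)
        kd = nf.discretize_kernel(half_reset_kernel, grid)
        state = nf.initial_data("exp_decay", grid)
        prev = 0.0
        for _ in range(100):
            state, prev = nf.step(state, rate, kd, prev)
        assert state.mass == pytest.approx(1.0, abs=1e-12)

    def test_positivity(self, half_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=4.0))
        grid = nf.default_grid(rate, ds=0.05)
        kd = nf.discretize_kernel(half_reset_kernel, grid)
        state = nf.initial_data("multi_bump", grid, centers=(1.0, 3.0), widths=0.2)
        prev = 0.0
        for _ in range(200):
            state, prev = nf.step(state, rate, kd, prev)
            assert np.all(state.values >= 0.0)


class TestRun:
    def test_zero_horizon(self, half_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        grid = nf.default_grid(rate, ds=0.05)
        traj = nf.run(nf.initial_data("exp_decay", grid), rate, half_reset_kernel, T=0.0)
        assert len(traj.times) == 1
        assert traj.N_values[0] == pytest.approx(math.exp(-4.0), rel=1e-4)

    def test_activity_bounds(self, full_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=4.0))
        grid = nf.default_grid(rate, ds=0.02)
        traj = nf.run(
            nf.initial_data("exp_decay", grid), rate, full_reset_kernel, T=40.0
        )
        assert np.all(traj.N_values >= 0.0)
        assert np.all(traj.N_values <= rate.pM + 1e-12)
        assert traj.max_mass_drift < 1e-10

    def test_snapshots_recorded(self, half_reset_kernel):
        rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
        grid = nf.default_grid(rate, ds=0.05)
        traj = nf.run(
            nf.initial_data("exp_decay", grid),
            rate,
            half_reset_kernel,
            T=2.0,
            snapshot_times=[0.0, 1.0, 2.0],
        )
        assert len(traj.snapshots) == 3
        assert [round(s.time, 6) for s in traj.snapshots] == [0.0, 1.0, 2.0]

    def test_late_profile_matches_renewal_steady_state(self, full_reset_kernel):
        # constant rate, full reset: late-time profile -> pM e^{-pM s},
        # first order in ds
        errs = {}
        for ds in (0.04, 0.02):
            rate = nf.FiringRate(family="regularized", threshold=0.0, pM=1.0)
            grid = nf.Grid.from_ds(20.0, ds)
            traj = nf.run(
                nf.initial_data("exp_decay", grid),
                rate,
                full_reset_kernel,
                T=30.0,
                snapshot_times=[30.0],
            )
            prof = traj.snapshots[-1].values
            exact = np.exp(-grid.nodes)
            errs[ds] = np.max(np.abs(prof[1:] - exact[1:]))
        assert errs[0.02] < 0.65 * errs[0.04]
        assert errs[0.02] < 0.011

    def test_agrees_with_independent_renewal_solver(self, full_reset_kernel):
        # full reset is equivalent to boundary influx n(0,t) = N(t);
        # the discrepancy between the two discretizations is O(ds)
        errs = {}
        for ds in (0.04, 0.02):
            rate = nf.FiringRate(family="regularized", threshold=0.0, pM=1.0)
            grid = nf.Grid.from_ds(20.0, ds)
            n0 = nf.initial_data("exp_decay", grid).values
            traj = nf.run(
                nf.DensityState(grid, n0.copy()),
                rate,
                full_reset_kernel,
                T=10.0,
                snapshot_times=[10.0],
            )
            oracle = renewal_oracle(grid, np.ones(grid.n_cells), n0, 10.0)
            errs[ds] = grid.ds * np.abs(traj.snapshots[-1].values - oracle).sum()
        assert errs[0.02] < 0.65 * errs[0.04]
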