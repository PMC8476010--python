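"""PSA-2D sweeps, oscillation amplitude, Sobol SA, fitness."""

import math

import numpy as np
import pytest

from rbmsim import (
    ParameterizationSet,
    SolverSettings,
    Status,
    SweepAxis,
    Trajectory,
    dopri5_integrate,
    fitness_relative_distance,
    oscillation_amplitude,
    psa_2d,
    run_batch,
    sa_output_statistic,
    saltelli_sample,
    sobol_indices,
)
from rbmsim.analysis import saltelli_rows, sweep_parameterizations


def make_traj(t, states):
    states = np.atleast_2d(states)
    if states.shape[0] != len(t):
        states = states.T
    return Trajectory(
        times=np.asarray(t, dtype=float),
        states=states,
        solver_used="DOPRI5",
        status=Status.SUCCESS,
    )


class TestAmplitude:
    def test_constant_series_scores_zero(self):
        t = np.linspace(0, 10, 101)
        assert oscillation_amplitude(make_traj(t, np.full(101, 2.0)), 0) == 0.0

    def test_sine_peak_to_trough(self):
        t = np.linspace(0, 50, 2001)
        y = 0.4 * np.sin(2 * np.pi * t / 5.0) + 1.0
        amp = oscillation_amplitude(make_traj(t, y), 0, transient_fraction=0.3)
        assert amp == pytest.approx(0.8, rel=0.02)

    def test_damped_sine_smaller_than_undamped(self):
        t = np.linspace(0, 50, 2001)
        und = 0.4 * np.sin(2 * np.pi * t / 5.0) + 1.0
        dam = 0.4 * np.exp(-0.05 * t) * np.sin(2 * np.pi * t / 5.0) + 1.0
        a_u = oscillation_amplitude(make_traj(t, und), 0, 0.3)
        a_d = oscillation_amplitude(make_traj(t, dam), 0, 0.3)
        assert 0.0 < a_d < a_u

    def test_failed_trajectory_rejected(self):
        t = np.linspace(0, 1, 5)
        traj = make_traj(t, np.zeros(5))
        traj.status = Status.STEP_LIMIT_EXCEEDED
        with pytest.raises(ValueError):
            oscillation_amplitude(traj, 0)


class TestPSA2D:
    def test_constant_summary_gives_constant_grid(self, reversible_pair):
        s = SolverSettings(t_out=np.linspace(0, 5, 21))
        ax1 = SweepAxis("k", np.array([0]), (0.5, 2.0), 3)
        ax2 = SweepAxis("x0", 1, (0.0, 0.5), 3)
        grid = psa_2d(reversible_pair, ax1, ax2, s, lambda tr: 7.5)
        np.testing.assert_array_equal(grid, np.full((3, 3), 7.5))

    def test_grid_shape_and_meshgrid_order(self, reversible_pair):
        s = SolverSettings(t_out=np.linspace(0, 5, 21))
        ax1 = SweepAxis("x0", 0, (1.0, 4.0), 4)
        ax2 = SweepAxis("x0", 1, (0.0, 1.0), 5)
        # total mass is conserved: final sum = x0_prey + x0_pred
        grid = psa_2d(
            reversible_pair, ax1, ax2, s, lambda tr: float(tr.states[-1].sum())
        )
        assert grid.shape == (4, 5)
        p1, p2 = np.linspace(1, 4, 4), np.linspace(0, 1, 5)
        expected = p1[:, None] + p2[None, :]
        np.testing.assert_allclose(grid, expected, rtol=1e-9)

    def test_oscillation_band(self, predator_prey):
        """Amplitude positive while limit cycles persist, zero once damped out."""
        s = SolverSettings(t_out=np.linspace(0, 60, 1201))
        rbm = predator_prey(0.01)
        ax1 = SweepAxis("k", np.array([3]), (0.01, 1.0), 3, scale="log")
        ax2 = SweepAxis("x0", 1, (1.0, 1.2), 2)
        grid = psa_2d(rbm, ax1, ax2, s, lambda tr: oscillation_amplitude(tr, 0, 0.5))
        assert np.all(grid[0] > 0.1)  # weak damping: sustained oscillations
        assert np.all(grid[-1] == 0.0)  # strong damping: non-oscillating

    def test_cells_match_individual_runs(self, predator_prey):
        rbm = predator_prey(0.05)
        s = SolverSettings(t_out=np.linspace(0, 30, 301))
        ax1 = SweepAxis("k", np.array([0]), (0.8, 1.2), 2)
        ax2 = SweepAxis("x0", 0, (1.0, 2.0), 2)
        grid = psa_2d(rbm, ax1, ax2, s, lambda tr: float(tr.states[-1, 0]),
                      batch_size=3)
        params, p1, p2 = sweep_parameterizations(rbm, ax1, ax2)
        for r in range(params.n_rows):
            res = run_batch(
                rbm,
                ParameterizationSet(
                    X0_batch=params.X0_batch[r : r + 1],
                    K_batch=params.K_batch[r : r + 1],
                ),
                s,
            )
            assert grid.flat[r] == res.trajectories[0].states[-1, 0]

    def test_invalid_axis_rejected(self, reversible_pair):
        with pytest.raises(ValueError):
            SweepAxis("x0", 7, (0, 1), 3).indices(reversible_pair)
        with pytest.raises(ValueError):
            SweepAxis("k", np.array([9]), (0, 1), 3).indices(reversible_pair)
        with pytest.raises(ValueError):
            SweepAxis("x0", 0, (1.0, 0.5), 3).points()


class TestSaltelli:
    def test_paper_sized_design(self):
        design = saltelli_sample([(0.0, 1e-5)] * 11, 512, second_order=True)
        assert design.shape == (12288, 11)

    def test_minimal_design(self):
        assert saltelli_sample([(0, 1)], 2, second_order=True).shape[0] == 8

    @pytest.mark.parametrize("D", [1, 3, 8, 16])
    @pytest.mark.parametrize("n_base", [2, 32, 256])
    def test_row_count_law(self, D, n_base):
        assert saltelli_rows(D, n_base, True) == n_base * (2 * D + 2)
        assert saltelli_rows(D, n_base, False) == n_base * (D + 2)

    def test_bounds_respected_and_spanned(self):
        bounds = [(-2.0, 3.0), (10.0, 20.0)]
        d = saltelli_sample(bounds, 256, second_order=False, seed=1)
        for j, (lo, hi) in enumerate(bounds):
            assert d[:, j].min() >= lo and d[:, j].max() <= hi
            assert d[:, j].min() < lo + 0.1 * (hi - lo)
            assert d[:, j].max() > hi - 0.1 * (hi - lo)


class TestSobol:
    def test_constant_output_degenerate(self):
        Y = np.full(saltelli_rows(3, 64), 2.0)
        res = sobol_indices(Y, D=3, n_base=64)
        assert res.degenerate
        np.testing.assert_array_equal(res.S1, 0.0)
        np.testing.assert_array_equal(res.ST, 0.0)

    def test_additive_linear_model(self):
        """y = sum a_j x_j on independent uniforms: S1_j = a_j^2 / sum a^2."""
        a = np.array([1.0, 2.0, 3.0])
        bounds = [(0.0, 1.0)] * 3
        X = saltelli_sample(bounds, 1024, second_order=True, seed=2)
        Y = X @ a
        res = sobol_indices(Y, D=3, n_base=1024, n_boot=200, seed=2)
        S1_true = a**2 / np.sum(a**2)
        assert res.S1.sum() == pytest.approx(1.0, abs=0.05)
        np.testing.assert_allclose(res.S1, S1_true, atol=0.05)
        np.testing.assert_allclose(res.ST, res.S1, atol=0.05)

    def test_ishigami_within_bootstrap_ci(self):
        a, b = 7.0, 0.1
        bounds = [(-math.pi, math.pi)] * 3
        X = saltelli_sample(bounds, 1024, second_order=True, seed=3)
        Y = (
            np.sin(X[:, 0])
            + a * np.sin(X[:, 1]) ** 2
            + b * X[:, 2] ** 4 * np.sin(X[:, 0])
        )
        res = sobol_indices(Y, D=3, n_base=1024, n_boot=500, seed=3)
        V = a**2 / 8 + b * math.pi**4 / 5 + b**2 * math.pi**8 / 18 + 0.5
        S1_true = np.array(
            [0.5 * (1 + b * math.pi**4 / 5) ** 2 / V, (a**2 / 8) / V, 0.0]
        )
        assert np.all(np.abs(res.S1 - S1_true) <= np.maximum(res.S1_conf, 0.01))
        assert np.all(res.ST >= res.S1 - res.S1_conf)

    def test_total_at_least_first_order(self):
        rng = np.random.default_rng(5)
        X = saltelli_sample([(0, 1)] * 4, 512, second_order=False, seed=5)
        Y = X[:, 0] * X[:, 1] + X[:, 2] + 0.1 * X[:, 3]
        res = sobol_indices(Y, D=4, n_base=512, second_order=False, n_boot=200)
        assert np.all(res.ST >= res.S1 - res.ST_conf - res.S1_conf)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sobol_indices(np.zeros(10), D=3, n_base=64)


class TestOutputStatistic:
    def test_reference_match_gives_zero(self):
        traj = make_traj([0.0, 1.0], np.array([[1.0], [0.5]]))
        assert sa_output_statistic(traj, 0, 0.5) == 0.0

    def test_signed_difference(self):
        traj = make_traj([0.0, 1.0], np.array([[1.0], [0.7]]))
        assert sa_output_statistic(traj, 0, 0.5) == pytest.approx(0.2)

    def test_self_consistency_with_base_run(self, reversible_pair):
        s = SolverSettings(t_out=np.linspace(0, 5, 11))
        traj = dopri5_integrate(reversible_pair.rhs, reversible_pair.X0, s)
        ref = float(traj.states[-1, 0])
        assert sa_output_statistic(traj, 0, ref) == 0.0


class TestFitness:
    def test_exact_match_is_zero(self):
        t = np.linspace(0, 1, 6)
        states = np.column_stack([np.exp(-t), np.cos(t)])
        traj = make_traj(t, states)
        assert fitness_relative_distance(traj, t, states) == 0.0

    def test_single_point_relative_error(self):
        traj = make_traj([1.0], np.array([[1.2]]))
        got = fitness_relative_distance(traj, [1.0], np.array([[1.0]]))
        assert got == pytest.approx(0.2)

    def test_invariant_to_species_ordering(self):
        t = np.linspace(0, 1, 6)
        states = np.column_stack([np.exp(-t), 2 * np.ones(6)])
        traj = make_traj(t, states)
        target = states * 1.1
        f12 = fitness_relative_distance(traj, t, target)
        traj_sw = make_traj(t, states[:, ::-1].copy())
        f21 = fitness_relative_distance(traj_sw, t, target[:, ::-1].copy())
        assert f12 == pytest.approx(f21, rel=1e-12)

    def test_failed_trajectory_scores_infinity(self):
        traj = make_traj([1.0], np.array([[1.0]]))
        traj.status = Status.STEP_SIZE_UNDERFLOW
        assert fitness_relative_distance(traj, [1.0], np.array([[1.0]])) == math.inf

    def test_target_times_must_be_simulated(self):
        traj = make_traj([0.0, 1.0], np.array([[1.0], [0.5]]))
        with pytest.raises(ValueError, match="subset"):
            fitness_relative_distance(traj, [0.7], np.array([[0.6]]))
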