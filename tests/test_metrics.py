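"""Tests for the trajectory-statistics suite."""

import math

import numpy as np
import pytest

from fbmotility import (MotilityParams, Trajectory, classify_diffusion,
                        ensemble_msd, initial_alignment,
                        msd_scaling_exponent, persistence_factor,
                        relative_turning_angle, relative_turning_angles,
                        run_simulation, trajectory_stats,
                        write_trajectory_csv, read_trajectory_csv)
from fbmotility.metrics import DegenerateGeometryError, MSDCurve


def _traj_from_positions(positions, params=None, **kw):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0] - 1
    return Trajectory(times=np.arange(n + 1) * 0.1, positions=positions,
                      thetas=np.zeros(n + 1),
                      step_vectors=np.diff(positions, axis=0),
                      params=params, **kw)


class TestPersistenceFactor:
    def test_straight_path_is_one(self):
        pos = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        assert persistence_factor(pos) == pytest.approx(1.0, abs=1e-12)

    def test_out_and_back_is_zero(self):
        out = np.linspace(0, 5, 6)
        pos = np.column_stack([np.concatenate([out, out[-2::-1]]),
                               np.zeros(11)])
        assert persistence_factor(pos) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_L_path(self):
        # two equal legs at a right angle: sqrt(2)L / 2L
        pos = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 3.0]])
        assert persistence_factor(pos) == pytest.approx(
            math.sqrt(2) / 2, abs=1e-12)

    def test_zero_total_distance_warns(self):
        pos = np.zeros((4, 2))
        with pytest.warns(UserWarning):
            assert persistence_factor(pos) == 0.0

    def test_bounded_on_random_walks(self, rng):
        steps = rng.normal(size=(500, 20, 2))
        for walk in np.cumsum(steps, axis=1):
            pf = persistence_factor(np.vstack([np.zeros(2), walk]))
            assert 0.0 <= pf <= 1.0

    def test_single_step_is_one(self):
        assert persistence_factor(np.array([[0.0, 0.0], [0.3, -0.4]])) == \
            pytest.approx(1.0, abs=1e-12)


class TestRelativeTurningAngle:
    @pytest.mark.parametrize("x1,x2,x3,expected", [
        ((0, 0), (1, 0), (2, 0), 0.0),          # collinear forward
        ((0, 0), (1, 0), (0, 0), math.pi),      # reversal
        ((0, 0), (1, 0), (1, 1), math.pi / 2),  # right angle
    ])
    def test_worked_examples(self, x1, x2, x3, expected):
        assert relative_turning_angle(x1, x2, x3) == pytest.approx(
            expected, abs=1e-12)

    def test_degenerate_triple_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            relative_turning_angle((0, 0), (0, 0), (1, 0))
        with pytest.raises(DegenerateGeometryError):
            relative_turning_angle((0, 0), (1, 0), (1, 0))

    def test_agrees_with_step_vector_angle_oracle(self, rng):
        # independent oracle: the angle between (x2-x1) and (x3-x2)
        pts = rng.normal(size=(10000, 3, 2))
        for x1, x2, x3 in pts:
            u, v = x2 - x1, x3 - x2
            oracle = math.atan2(abs(u[0] * v[1] - u[1] * v[0]), u @ v)
            assert abs(relative_turning_angle(x1, x2, x3) - oracle) < 1e-9

    def test_range_and_skip_count(self, rng):
        pos = np.cumsum(rng.normal(size=(200, 2)), axis=0)
        pos[50] = pos[49]  # inject one repeated point
        angles, skipped = relative_turning_angles(pos)
        assert skipped == 2  # both triples touching the repeat are dropped
        assert np.all((angles >= 0) & (angles <= math.pi))


class TestTrajectoryStats:
    def test_deterministic_run(self, deterministic_trajectory):
        s = trajectory_stats(deterministic_trajectory)
        assert s.total_distance == pytest.approx(100.0, abs=1e-9)
        assert s.displacement == pytest.approx(100.0, abs=1e-9)
        assert s.persistence_factor == pytest.approx(1.0, abs=1e-12)
        assert s.mean_increment == pytest.approx(0.1, abs=1e-12)
        assert s.mean_relative_angle == pytest.approx(0.0, abs=1e-6)

    def test_displacement_bounded_by_distance(self, rng):
        for s in range(20):
            traj = run_simulation(
                MotilityParams(Dr=1.0, alpha=0.25, H=0.75, n_steps=100),
                seed=s)
            st = trajectory_stats(traj)
            assert st.displacement <= st.total_distance + 1e-12


class TestInitialAlignment:
    def _traj_with_noise(self, noise0, theta0=0.0, alpha=0.25):
        params = MotilityParams(alpha=alpha, n_steps=2)
        pos = np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0]])
        t = _traj_from_positions(pos, params=params)
        t.thetas = np.full(3, theta0)
        t.noise_x = np.array([noise0[0], 0.0])
        t.noise_y = np.array([noise0[1], 0.0])
        return t

    def test_parallel_noise(self):
        assert initial_alignment(self._traj_with_noise((0.7, 0.0))) == \
            pytest.approx(0.25, abs=1e-12)

    def test_antiparallel_noise(self):
        assert initial_alignment(self._traj_with_noise((-0.7, 0.0))) == \
            pytest.approx(-0.25, abs=1e-12)

    def test_perpendicular_noise(self):
        assert initial_alignment(self._traj_with_noise((0.0, 0.7))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_noise_vector(self):
        assert initial_alignment(self._traj_with_noise((0.0, 0.0))) == 0.0

    def test_bounded_on_simulated_runs(self):
        p = MotilityParams(Dr=0.5, alpha=0.25, H=0.75, n_steps=50)
        for s in range(30):
            a = initial_alignment(run_simulation(p, seed=s))
            assert -0.25 <= a <= 0.25

    def test_unavailable_for_csv_trajectories(self, tmp_path):
        p = MotilityParams(n_steps=10)
        path = tmp_path / "t.csv"
        write_trajectory_csv(run_simulation(p, seed=0), path)
        loaded = read_trajectory_csv(path)[0]
        with pytest.raises(ValueError, match="noise record"):
            initial_alignment(loaded)
        assert math.isnan(trajectory_stats(loaded).initial_alignment)


class TestEnsembleMsd:
    def test_deterministic_ensemble_is_t_squared(self, deterministic_ensemble):
        curve = ensemble_msd(deterministic_ensemble)
        np.testing.assert_allclose(curve.values, curve.times**2,
                                   atol=1e-7, rtol=1e-9)
        assert curve.values[0] == 0.0
        assert curve.values[-1] == pytest.approx(10000.0, rel=1e-9)

    def test_single_trajectory_degenerate_average(self):
        p = MotilityParams(Dr=1.0, alpha=0.25, n_steps=50)
        traj = run_simulation(p, seed=1)
        curve = ensemble_msd([traj], sample_size=1)
        np.testing.assert_allclose(
            curve.values, (traj.positions**2).sum(axis=1), rtol=1e-12)

    def test_subsample_is_seeded(self, deterministic_ensemble):
        a = ensemble_msd(deterministic_ensemble, sample_size=5, seed=3)
        b = ensemble_msd(deterministic_ensemble, sample_size=5, seed=3)
        c = ensemble_msd(deterministic_ensemble, sample_size=5, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.replicate_ids == b.replicate_ids
        assert a.replicate_ids != c.replicate_ids

    def test_mismatched_grids_rejected(self, deterministic_ensemble):
        other = run_simulation(MotilityParams(Dr=0.0, alpha=0.0, n_steps=50),
                               seed=0)
        with pytest.raises(ValueError, match="time grid"):
            ensemble_msd([deterministic_ensemble[0], other])

    def test_bad_sample_size_rejected(self, deterministic_ensemble):
        with pytest.raises(ValueError):
            ensemble_msd(deterministic_ensemble, sample_size=0)
        with pytest.raises(ValueError):
            ensemble_msd(deterministic_ensemble,
                         sample_size=len(deterministic_ensemble) + 1)


class TestScalingExponent:
    def _curve(self, values, times=None):
        t = np.linspace(0, 100, 1001) if times is None else times
        return MSDCurve(times=t, values=values, sample_size=1,
                        replicate_ids=(0,))

    def test_ballistic_curve(self):
        t = np.linspace(0, 100, 1001)
        assert msd_scaling_exponent(self._curve(t**2)) == pytest.approx(
            2.0, abs=1e-9)

    def test_diffusive_curve(self):
        t = np.linspace(0, 100, 1001)
        assert msd_scaling_exponent(self._curve(3.7 * t)) == pytest.approx(
            1.0, abs=1e-9)

    def test_custom_window(self):
        t = np.linspace(0, 100, 1001)
        v = np.where(t < 50, t**2, 2500.0 / 50 * t)  # crossover curve
        late = msd_scaling_exponent(self._curve(v), fit_window=(60, 100))
        assert late == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 100, 1001)
        with pytest.raises(ValueError, match="3 points"):
            msd_scaling_exponent(self._curve(t**2), fit_window=(99.9, 100))

    def test_classification(self):
        assert classify_diffusion(2.0) == "superdiffusive"
        assert classify_diffusion(1.02) == "diffusive"
        assert classify_diffusion(0.5) == "subdiffusive"
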