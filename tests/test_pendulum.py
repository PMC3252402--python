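"""Pendulum dynamics: decay laws, energy, stick, marker rendering."""

import math

import numpy as np
import pytest

from jointcof.pendulum import (
    FrictionParams,
    LayoutError,
    MarkerLayout,
    PendulumConfig,
    default_layout,
    mechanical_energy,
    render_markers,
    simulate_free_oscillation,
)


class TestSimulation:
    def test_sampling_grid_matches_capture_rate(self, config):
        """10 s at 60 Hz gives exactly 601 samples on a uniform grid."""
        traj = simulate_free_oscillation(config, FrictionParams(mu=0.02), 10.0)
        assert len(traj.times) == 601
        assert np.allclose(np.diff(traj.times), 1.0 / 60.0, atol=1e-12)
        assert abs(traj.angles[0] - math.radians(12.0)) < 1e-9

    def test_undamped_extrema_conserve_amplitude(self, config):
        """With no friction every turning point returns to the release angle."""
        traj = simulate_free_oscillation(config, FrictionParams(), 10.0)
        assert len(traj.extrema_angles) > 10
        err = np.abs(np.abs(traj.extrema_angles) - math.radians(12.0))
        assert err.max() < 1e-6

    def test_half_cycle_decrement_matches_energy_balance(self, normalized_config):
        """Per-half-cycle amplitude loss equals 2 mu W r / (m g L) within 2%.

        Energy-balance oracle: friction torque 5e-4 N m against unit gravity
        torque coefficient predicts a 1.0e-3 rad decrement per half cycle.
        """
        friction = FrictionParams(mu=0.05)
        traj = simulate_free_oscillation(normalized_config, friction, 30.0)
        amp = np.abs(traj.extrema_angles)
        amp = amp[amp > math.radians(2.0)]  # stay in the small-angle regime
        decrements = -np.diff(amp)
        assert np.all(np.abs(decrements - 1.0e-3) < 0.02e-3)

    def test_energy_is_nonincreasing(self, config):
        for friction in (FrictionParams(mu=0.05), FrictionParams(mu=0.02, viscous_coeff=1e-7)):
            traj = simulate_free_oscillation(config, friction, 5.0)
            energy = mechanical_energy(config, traj)
            # tolerance: accumulated integrator error, not physical gain
            assert np.all(np.diff(energy) < 1e-8 * energy[0] + 1e-18)

    def test_coulomb_decay_is_linear(self, config):
        """Successive extremum amplitudes vs index: OLS R^2 >= 0.999."""
        traj = simulate_free_oscillation(config, FrictionParams(mu=0.05), 10.0)
        amp = np.abs(traj.extrema_angles)
        amp = amp[amp > math.radians(1.0)]
        idx = np.arange(len(amp))
        coef = np.polyfit(idx, amp, 1)
        resid = amp - np.polyval(coef, idx)
        r2 = 1 - np.sum(resid**2) / np.sum((amp - amp.mean()) ** 2)
        assert r2 >= 0.999

    def test_viscous_decay_is_exponential(self, config):
        """Log-amplitudes vs index are linear (R^2 >= 0.999) for mu = 0."""
        traj = simulate_free_oscillation(config, FrictionParams(viscous_coeff=2e-7), 10.0)
        amp = np.abs(traj.extrema_angles)
        amp = amp[amp > math.radians(0.5)]
        assert len(amp) >= 10
        idx = np.arange(len(amp))
        log_amp = np.log(amp)
        coef = np.polyfit(idx, log_amp, 1)
        resid = log_amp - np.polyval(coef, idx)
        r2 = 1 - np.sum(resid**2) / np.sum((log_amp - log_amp.mean()) ** 2)
        assert r2 >= 0.999

    def test_stick_condition_holds_at_termination(self, config):
        friction = FrictionParams(mu=0.08)
        traj = simulate_free_oscillation(config, friction, 20.0)
        assert traj.stopped_at is not None
        tau_f = friction.mu * config.joint_load * config.joint_radius
        held = traj.angles[-1]
        assert abs(config.gravity_torque * math.sin(held)) <= tau_f * (1 + 1e-9)
        assert np.all(traj.angles[traj.times >= traj.stopped_at] == held)

    def test_friction_enters_only_through_torque_product(self):
        """Equal mu*W*r with equal m g L and I gives identical trajectories."""
        base = PendulumConfig()
        doubled_load = PendulumConfig(joint_radius=base.joint_radius * 2)
        t1 = simulate_free_oscillation(base, FrictionParams(mu=0.06), 5.0)
        t2 = simulate_free_oscillation(doubled_load, FrictionParams(mu=0.03), 5.0)
        assert np.allclose(t1.angles, t2.angles, atol=1e-9)

    def test_release_at_equilibrium_sticks_immediately(self):
        config = PendulumConfig(start_angle=0.0)
        traj = simulate_free_oscillation(config, FrictionParams(mu=0.05), 1.0)
        assert traj.stopped_at == 0.0
        assert np.all(traj.angles == 0.0)

    def test_short_duration_flags_warning(self, config):
        with pytest.warns(UserWarning, match="half period"):
            traj = simulate_free_oscillation(config, FrictionParams(mu=0.02), 0.05)
        assert traj.short_duration

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"arm_mass": -1.0},
            {"sample_rate": 0.0},
            {"start_angle": 35.0},
            {"joint_radius": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PendulumConfig(**kwargs)

    def test_negative_friction_rejected(self):
        with pytest.raises(ValueError):
            FrictionParams(mu=-0.01)
        with pytest.raises(ValueError):
            FrictionParams(viscous_coeff=-1e-9)


class TestMarkers:
    def test_zero_noise_zero_angle_is_reference(self, layout):
        from jointcof.pendulum import TrialTrajectory

        traj = TrialTrajectory(
            times=np.array([0.0]),
            angles=np.array([0.0]),
            angular_velocities=np.array([0.0]),
        )
        frames = render_markers(traj, layout, noise_sd=0.0, seed=0)
        assert np.allclose(frames.arm_positions[0], layout.arm, atol=1e-12)
        assert np.allclose(frames.base_positions[0], layout.base, atol=1e-12)

    def test_pure_rotation_is_exact(self, layout):
        from jointcof.pendulum import TrialTrajectory

        angle = math.radians(5.0)
        traj = TrialTrajectory(
            times=np.array([0.0]),
            angles=np.array([angle]),
            angular_velocities=np.array([0.0]),
        )
        frames = render_markers(traj, layout, noise_sd=0.0, seed=0)
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        assert np.allclose(frames.arm_positions[0], layout.arm @ rot.T, atol=1e-9)
        assert np.allclose(frames.base_positions[0], layout.base, atol=1e-12)

    def test_rigid_distances_preserved_without_noise(self, config, layout):
        traj = simulate_free_oscillation(config, FrictionParams(mu=0.05), 3.0)
        frames = render_markers(traj, layout, noise_sd=0.0, seed=0)
        ref = np.linalg.norm(layout.arm[:, None, :] - layout.arm[None, :, :], axis=2)
        arm = frames.arm_positions
        dists = np.linalg.norm(arm[:, :, None, :] - arm[:, None, :, :], axis=3)
        assert np.max(np.abs(dists - ref[None])) < 1e-9
        assert np.max(np.abs(frames.base_positions - layout.base[None])) < 1e-12

    def test_noise_sd_calibrated(self, layout):
        """Per-coordinate sample SD of the added noise within 10% of nominal."""
        from jointcof.pendulum import TrialTrajectory

        n = 1000
        traj = TrialTrajectory(
            times=np.arange(n) / 60.0,
            angles=np.zeros(n),
            angular_velocities=np.zeros(n),
        )
        frames = render_markers(traj, layout, noise_sd=0.1, seed=42)
        clean = render_markers(traj, layout, noise_sd=0.0, seed=42)
        noise = frames.positions - clean.positions
        sd = noise.std(axis=0)
        assert np.all(np.abs(sd - 0.1) < 0.01)

    def test_reproducible_given_seed(self, config, layout):
        traj = simulate_free_oscillation(config, FrictionParams(mu=0.05), 2.0)
        a = render_markers(traj, layout, noise_sd=0.1, seed=7)
        b = render_markers(traj, layout, noise_sd=0.1, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_too_few_markers_rejected(self):
        with pytest.raises(LayoutError):
            MarkerLayout(arm=np.array([[0.0, -5.0], [0.0, -10.0]]), base=default_layout().base)
        with pytest.raises(LayoutError):
            MarkerLayout(arm=default_layout().arm, base=np.array([[30.0, 0.0]]))
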