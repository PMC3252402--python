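"""Rigid-pendulum dynamics for whole-joint friction measurement.

A limb is mounted so the knee is the fulcrum of a compound pendulum.  The
pendulum is rotated to a small start angle, released, and the free
oscillation decays through friction at the joint.  The equation of motion is

    I th'' = -m g L sin(th) - sgn(th') mu W r - c th'

with ``I`` the moment of inertia about the fulcrum, ``m g L`` the gravity
restoring-torque coefficient (arm mass x gravity x pivot-to-COM distance),
``mu W r`` the Coulomb friction torque (friction coefficient x joint normal
load x effective frictional moment arm) and ``c`` an optional viscous
coefficient.  Angles are deviations from the hanging equilibrium; the
anatomical flexion angle at equilibrium (~70 deg in the mouse knee) is
carried as metadata only.

Under pure Coulomb friction and small angles the oscillation amplitude
decays *linearly*: each half-cycle the amplitude drops by the constant
``2 mu W r / (m g L)`` (energy balance), which is what makes the linear
amplitude-decay fit in :mod:`jointcof.cof` an estimator of ``mu``.  Motion
terminates ("stick") the first time the pendulum is at rest where the
gravity torque cannot overcome static friction, i.e. ``|m g L sin th| <=
mu W r``.

Integration is piecewise between velocity zero-crossings with event
detection, so the sign of the friction torque is exact within each
half-cycle and the linear decay is preserved to integrator tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PendulumConfig",
    "FrictionParams",
    "TrialTrajectory",
    "MarkerLayout",
    "MarkerFrames",
    "IntegrationError",
    "LayoutError",
    "default_layout",
    "simulate_free_oscillation",
    "render_markers",
    "mechanical_energy",
]

STANDARD_GRAVITY = 9.80665  # m/s^2


class IntegrationError(RuntimeError):
    """Raised when the trajectory integration fails or stalls."""


class LayoutError(ValueError):
    """Raised for marker layouts that cannot support angle recovery."""


@dataclass
class PendulumConfig:
    """Geometry, inertia and sampling of the passive (measurement) pendulum.

    Parameters
    ----------
    arm_mass : float
        Pendulum arm mass in kg (default 0.050, i.e. the 50 g arm, roughly
        twice a mouse's body weight).
    com_distance : float
        Pivot to arm centre-of-mass distance L, in m.
    moment_of_inertia : float, optional
        Moment of inertia about the pivot, kg m^2.  Defaults to the
        slender-arm surrogate ``(4/3) m L^2``.
    joint_load : float, optional
        Normal force W across the joint surfaces, N.  Defaults to ``m g``.
    joint_radius : float
        Effective frictional moment arm r at the fulcrum, m.
    gravity : float
        Gravitational acceleration, m/s^2.
    equilibrium_angle : float
        Anatomical knee flexion at the hanging equilibrium, degrees.
        Metadata only; the dynamic angle is measured from equilibrium.
    start_angle : float
        Release angle in degrees from equilibrium (|start_angle| <= 30).
    sample_rate : float
        Motion-capture sampling rate, Hz (default 60).
    """

    arm_mass: float = 0.050
    com_distance: float = 0.012
    moment_of_inertia: float | None = None
    joint_load: float | None = None
    joint_radius: float = 0.001
    gravity: float = STANDARD_GRAVITY
    equilibrium_angle: float = 70.0
    start_angle: float = 12.0
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.moment_of_inertia is None:
            self.moment_of_inertia = (4.0 / 3.0) * self.arm_mass * self.com_distance**2
        if self.joint_load is None:
            self.joint_load = self.arm_mass * self.gravity
        for name in (
            "arm_mass",
            "com_distance",
            "moment_of_inertia",
            "joint_load",
            "joint_radius",
            "gravity",
            "sample_rate",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if abs(self.start_angle) > 30.0:
            raise ValueError(
                f"start_angle {self.start_angle} deg outside the +/-30 deg validity region"
            )
        if not np.isfinite(self.natural_frequency) or self.natural_frequency <= 0:
            raise ValueError("natural frequency sqrt(m g L / I) must be finite and positive")

    @property
    def gravity_torque(self) -> float:
        """Restoring-torque coefficient m g L, N m."""
        return self.arm_mass * self.gravity * self.com_distance

    @property
    def natural_frequency(self) -> float:
        """Small-angle angular frequency sqrt(m g L / I), rad/s."""
        return math.sqrt(self.gravity_torque / self.moment_of_inertia)

    @property
    def half_period(self) -> float:
        """Small-angle half period, s."""
        return math.pi / self.natural_frequency

    @property
    def start_angle_rad(self) -> float:
        return math.radians(self.start_angle)


@dataclass
class FrictionParams:
    """Friction at the joint fulcrum.

    ``mu`` is the dimensionless Coulomb coefficient of friction (the quantity
    the measurement chain reports); ``viscous_coeff`` (N m s/rad) is an
    extension used only as an internal diagnostic -- the linear-decay
    measurement model corresponds to ``viscous_coeff = 0``.
    """

    mu: float = 0.0
    viscous_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0 or not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite and >= 0, got {self.mu!r}")
        if self.viscous_coeff < 0 or not np.isfinite(self.viscous_coeff):
            raise ValueError(f"viscous_coeff must be finite and >= 0, got {self.viscous_coeff!r}")


@dataclass
class TrialTrajectory:
    """Simulated pendulum state on the uniform sampling grid.

    ``extrema_times``/``extrema_angles`` hold the turning points found by the
    integrator's velocity zero-crossing events; they are exact to integrator
    tolerance and serve as an internal oracle for envelope-based estimators.
    """

    times: np.ndarray
    angles: np.ndarray
    angular_velocities: np.ndarray
    stopped_at: float | None = None
    extrema_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    extrema_angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    short_duration: bool = False


def simulate_free_oscillation(
    config: PendulumConfig, friction: FrictionParams, duration: float
) -> TrialTrajectory:
    """Integrate the free oscillation from rest at the start angle.

    The motion is integrated piecewise between velocity zero-crossings
    (DOP853, rtol 1e-10 / atol 1e-12, terminal event on the angular
    velocity), holding the Coulomb torque sign fixed within each half-cycle.
    At every turning point the stick condition ``|m g L sin th| <= mu W r``
    is re-evaluated; once it holds the angle is frozen and ``stopped_at``
    records the time.  Output is sampled on the uniform ``1/sample_rate``
    grid covering ``[0, duration]``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration!r}")
    inertia = config.moment_of_inertia
    mgl = config.gravity_torque
    tau_f = friction.mu * config.joint_load * config.joint_radius
    c = friction.viscous_coeff

    theta = config.start_angle_rad
    t = 0.0
    short = duration < config.half_period
    if short:
        warnings.warn(
            f"duration {duration:.3g} s is shorter than one half period "
            f"({config.half_period:.3g} s); the decay envelope will be unusable",
            stacklevel=2,
        )

    segments: list[tuple[float, float, object]] = []  # (t0, t1, dense sol)
    ext_t: list[float] = []
    ext_a: list[float] = []
    stopped_at: float | None = None

    while t < duration:
        restoring = -mgl * math.sin(theta)
        if abs(restoring) <= tau_f:
            stopped_at = t
            break
        s = math.copysign(1.0, restoring)  # sign of the impending velocity

        def rhs(_tt, y, s=s):
            th, w = y
            return (w, (-mgl * math.sin(th) - s * tau_f - c * w) / inertia)

        def velocity_zero(_tt, y):
            return y[1]

        velocity_zero.terminal = True
        velocity_zero.direction = -s  # crossing back towards rest

        sol = solve_ivp(
            rhs,
            (t, duration),
            [theta, 0.0],
            method="DOP853",
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
            events=velocity_zero,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed in step starting at t={t:.6g} s: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"non-finite state in step starting at t={t:.6g} s")
        if sol.status == 1:  # hit a turning point
            t_event = float(sol.t_events[0][0])
            if t_event - t <= 1e-12:
                raise IntegrationError(f"integration stalled at t={t:.6g} s")
            segments.append((t, t_event, sol.sol))
            theta = float(sol.y_events[0][0][0])
            ext_t.append(t_event)
            ext_a.append(theta)
            t = t_event
        else:  # ran out the clock mid-swing
            segments.append((t, duration, sol.sol))
            t = duration
        if len(segments) > 200_000:
            raise IntegrationError("too many half-cycles; check friction parameters")

    n_samples = int(round(duration * config.sample_rate)) + 1
    times = np.arange(n_samples) / config.sample_rate
    angles = np.full(n_samples, theta, dtype=float)
    velocities = np.zeros(n_samples)
    for t0, t1, dense in segments:
        mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        if mask.any():
            state = dense(np.clip(times[mask], t0, t1))
            angles[mask] = state[0]
            velocities[mask] = state[1]
    if stopped_at is not None:
        held = times >= stopped_at
        angles[held] = theta
        velocities[held] = 0.0

    return TrialTrajectory(
        times=times,
        angles=angles,
        angular_velocities=velocities,
        stopped_at=stopped_at,
        extrema_times=np.asarray(ext_t),
        extrema_angles=np.asarray(ext_a),
        short_duration=short,
    )


def mechanical_energy(config: PendulumConfig, traj: TrialTrajectory) -> np.ndarray:
    """Total mechanical energy 0.5 I w^2 + m g L (1 - cos th) per sample, J."""
    return 0.5 * config.moment_of_inertia * traj.angular_velocities**2 + config.gravity_torque * (
        1.0 - np.cos(traj.angles)
    )


@dataclass
class MarkerLayout:
    """Reference marker coordinates in mm, pivot at the origin, equilibrium pose.

    ``arm`` markers rotate rigidly with the pendulum arm about the pivot;
    ``base`` markers are fixed to the apparatus frame.
    """

    arm: np.ndarray
    base: np.ndarray
    arm_names: tuple[str, ...] = ()
    base_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        if self.arm.ndim != 2 or self.arm.shape[1] != 2:
            raise LayoutError("arm markers must be an (n, 2) array of planar coordinates")
        if self.base.ndim != 2 or self.base.shape[1] != 2:
            raise LayoutError("base markers must be an (n, 2) array of planar coordinates")
        if len(self.arm) < 3:
            raise LayoutError("at least 3 arm markers are required for robust angle recovery")
        if len(self.base) < 3:
            raise LayoutError("at least 3 base markers are required for drift correction")
        if not self.arm_names:
            self.arm_names = tuple(f"arm{i + 1}" for i in range(len(self.arm)))
        if not self.base_names:
            self.base_names = tuple(f"base{i + 1}" for i in range(len(self.base)))

    @property
    def names(self) -> tuple[str, ...]:
        return self.arm_names + self.base_names


def default_layout() -> MarkerLayout:
    """Eight-marker layout: 4 on the arm (hanging down), 4 on the base frame."""
    arm = np.array([[0.0, -6.0], [0.0, -18.0], [5.0, -12.0], [-5.0, -12.0]])
    base = np.array([[-30.0, -30.0], [30.0, -30.0], [30.0, 15.0], [-30.0, 15.0]])
    return MarkerLayout(arm=arm, base=base)


@dataclass
class MarkerFrames:
    """Per-frame planar marker coordinates (mm): arm markers first, then base."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_markers, 2) mm
    marker_names: tuple[str, ...]
    n_arm: int
    noise_sd: float = 0.0

    @property
    def arm_positions(self) -> np.ndarray:
        return self.positions[:, : self.n_arm, :]

    @property
    def base_positions(self) -> np.ndarray:
        return self.positions[:, self.n_arm :, :]


def render_markers(
    traj: TrialTrajectory,
    layout: MarkerLayout | None = None,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> MarkerFrames:
    """Render a trajectory as noisy reflective-marker coordinates.

    Arm markers are the layout references rotated by each frame's angle about
    the pivot; base markers are static.  Isotropic i.i.d. Gaussian noise of
    standard deviation ``noise_sd`` (mm) is added per coordinate,
    reproducibly for a given ``seed``.
    """
    if layout is None:
        layout = default_layout()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    angles = np.asarray(traj.angles)
    n = len(angles)
    cos_t, sin_t = np.cos(angles), np.sin(angles)
    ax, ay = layout.arm[:, 0], layout.arm[:, 1]
    arm = np.empty((n, len(layout.arm), 2))
    arm[:, :, 0] = cos_t[:, None] * ax[None, :] - sin_t[:, None] * ay[None, :]
    arm[:, :, 1] = sin_t[:, None] * ax[None, :] + cos_t[:, None] * ay[None, :]
    base = np.broadcast_to(layout.base, (n, len(layout.base), 2)).copy()
    positions = np.concatenate([arm, base], axis=1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise_sd, size=positions.shape)
    return MarkerFrames(
        times=np.asarray(traj.times),
        positions=positions,
        marker_names=layout.names,
        n_arm=len(layout.arm),
        noise_sd=noise_sd,
    )
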