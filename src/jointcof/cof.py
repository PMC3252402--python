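"""Coefficient-of-friction estimation from pendulum decay envelopes.

The estimator follows the classical linear (Stanton-type) amplitude-decay
analysis for Coulomb-damped pendulums: successive oscillation extrema lose a
constant amplitude per half-cycle,

    delta = 2 mu W r / (m g L),

so an ordinary least-squares line through |extremum amplitude| versus
half-cycle index has slope ``-delta`` and the friction coefficient is
recovered as

    mu_hat = slope * (m g L) / (2 W r).

Extrema are located by sign changes of the discrete derivative and refined
by quadratic interpolation through the three straddling samples (at 60 Hz
sampling a raw sample can undershoot the true peak by ~1%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pendulum import (
    FrictionParams,
    MarkerLayout,
    PendulumConfig,
    render_markers,
    simulate_free_oscillation,
)
from .tracking import AngleSeries, estimate_angles

__all__ = [
    "PeakSequence",
    "StantonFit",
    "CofEstimate",
    "JointCof",
    "InsufficientOscillationError",
    "InvalidDecayError",
    "DEFAULT_MIN_AMPLITUDE",
    "detect_peaks",
    "fit_stanton",
    "estimate_cof",
    "estimate_cof_from_series",
    "average_trials",
    "auto_duration",
    "measure_trial",
    "measure_joint",
]

DEFAULT_MIN_AMPLITUDE = math.radians(1.0)  # discard the noisy near-stick tail


class InsufficientOscillationError(RuntimeError):
    """Fewer than 4 usable extrema; no decay fit possible."""


class InvalidDecayError(ValueError):
    """The fitted envelope grows rather than decays."""


@dataclass
class PeakSequence:
    """Oscillation extrema: half-cycle index, time, |amplitude| and sign."""

    index: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray  # rad, >= 0
    signs: np.ndarray

    def __len__(self) -> int:
        return len(self.index)


@dataclass
class StantonFit:
    slope: float  # rad per half-cycle, positive for a decaying envelope
    intercept: float  # rad
    r_squared: float
    no_decay: bool = False


@dataclass
class CofEstimate:
    """Decay-fit outputs and the derived friction coefficient for one trial."""

    slope: float
    intercept: float
    r_squared: float
    mu_hat: float
    n_peaks: int
    no_decay: bool = False


@dataclass
class JointCof:
    """Replicate-trial estimates for one joint and their mean."""

    trial_estimates: list[CofEstimate] = field(default_factory=list)
    mean_mu: float = float("nan")


def detect_peaks(series: AngleSeries | np.ndarray, min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
                 times: np.ndarray | None = None) -> PeakSequence:
    """Locate oscillation extrema and refine them to sub-sample precision.

    Accepts an :class:`AngleSeries` (or any object with ``times``/``angles``)
    or a raw angle array plus ``times``.  Extrema below ``min_amplitude`` are
    discarded and alternating-sign ordering is enforced by keeping the larger
    of any two consecutive same-sign extrema.
    """
    if hasattr(series, "angles"):
        y = np.asarray(series.angles, dtype=float)
        t = np.asarray(series.times, dtype=float)
    else:
        y = np.asarray(series, dtype=float)
        if times is None:
            raise ValueError("times must be supplied with a raw angle array")
        t = np.asarray(times, dtype=float)
    if min_amplitude <= 0:
        raise ValueError("min_amplitude must be > 0")
    if len(y) < 3:
        raise InsufficientOscillationError("series too short for extremum detection")

    d = np.diff(y)
    sign_d = np.sign(d)
    nz = np.nonzero(sign_d)[0]
    if len(nz) == 0:
        raise InsufficientOscillationError("series is constant; no oscillation to analyse")
    # forward-fill zero slopes so flat tops register a single extremum
    last_nz = np.maximum.accumulate(np.where(sign_d != 0, np.arange(len(d)), -1))
    filled = np.where(last_nz >= 0, sign_d[np.clip(last_nz, 0, None)], 0.0)
    vertex = np.nonzero(filled[:-1] * filled[1:] < 0)[0] + 1

    dt = np.median(np.diff(t))
    refined_t, refined_a = [], []
    for k in vertex:
        while k > 0 and y[k - 1] == y[k]:  # tie-break: earlier sample is the vertex
            k -= 1
        if k < 1 or k > len(y) - 2:
            continue
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom == 0.0:
            refined_t.append(t[k])
            refined_a.append(y1)
        else:
            offset = 0.5 * (y0 - y2) / denom
            refined_t.append(t[k] + offset * dt)
            refined_a.append(y1 - 0.25 * (y0 - y2) * offset)

    keep_t, keep_v = [], []
    for tt, vv in zip(refined_t, refined_a):
        if abs(vv) < min_amplitude:
            continue
        if keep_v and math.copysign(1.0, vv) == math.copysign(1.0, keep_v[-1]):
            if abs(vv) > abs(keep_v[-1]):  # enforce alternating signs
                keep_t[-1], keep_v[-1] = tt, vv
            continue
        keep_t.append(tt)
        keep_v.append(vv)

    if len(keep_v) < 4:
        raise InsufficientOscillationError(
            f"only {len(keep_v)} extrema above {math.degrees(min_amplitude):.2g} deg; need >= 4"
        )
    values = np.asarray(keep_v)
    return PeakSequence(
        index=np.arange(len(values)),
        times=np.asarray(keep_t),
        amplitudes=np.abs(values),
        signs=np.sign(values),
    )


def fit_stanton(peaks: PeakSequence) -> StantonFit:
    """Ordinary least squares of extremum amplitude on half-cycle index.

    The slope is reported as the (positive) per-half-cycle amplitude
    decrement.  A zero-variance envelope yields slope 0 with ``r_squared``
    defined as 1 and the ``no_decay`` flag raised.
    """
    if len(peaks) < 4:
        raise InsufficientOscillationError(f"need >= 4 peaks for the decay fit, got {len(peaks)}")
    a = peaks.amplitudes
    idx = peaks.index.astype(float)
    if np.ptp(a) == 0.0:
        return StantonFit(slope=0.0, intercept=float(a[0]), r_squared=1.0, no_decay=True)
    coef = np.polyfit(idx, a, 1)
    pred = np.polyval(coef, idx)
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    return StantonFit(
        slope=-float(coef[0]),
        intercept=float(coef[1]),
        r_squared=1.0 - ss_res / ss_tot,
    )


def estimate_cof(slope: float, config: PendulumConfig, slope_tol: float = 1e-9) -> float:
    """Convert the per-half-cycle decrement into a friction coefficient.

    ``mu_hat = slope * (m g L) / (2 W r)``; a slope more negative than
    ``-slope_tol`` (a growing envelope) raises :class:`InvalidDecayError`.
    """
    if slope < -slope_tol:
        raise InvalidDecayError(f"envelope grows (slope {slope:.3g} rad/half-cycle)")
    return max(slope, 0.0) * config.gravity_torque / (2.0 * config.joint_load * config.joint_radius)


def estimate_cof_from_series(
    series: AngleSeries,
    config: PendulumConfig,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> CofEstimate:
    """Full single-trial estimate: peaks -> linear decay fit -> mu_hat."""
    peaks = detect_peaks(series, min_amplitude=min_amplitude)
    fit = fit_stanton(peaks)
    mu_hat = estimate_cof(fit.slope, config)
    return CofEstimate(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        mu_hat=mu_hat,
        n_peaks=len(peaks),
        no_decay=fit.no_decay,
    )


def average_trials(estimates: list[CofEstimate]) -> JointCof:
    """Arithmetic mean of replicate-trial mu_hat values (3 trials expected)."""
    if not estimates:
        raise ValueError("no trial estimates to average")
    if len(estimates) != 3:
        warnings.warn(f"expected 3 replicate trials, got {len(estimates)}", stacklevel=2)
    mean_mu = float(np.mean([e.mu_hat for e in estimates]))
    return JointCof(trial_estimates=list(estimates), mean_mu=mean_mu)


def auto_duration(
    config: PendulumConfig,
    friction: FrictionParams,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> float:
    """Duration long enough to decay from the start angle to ``min_amplitude``."""
    theta0 = abs(config.start_angle_rad)
    half = config.half_period
    tau_f = friction.mu * config.joint_load * config.joint_radius
    if tau_f > 0:
        delta = 2.0 * tau_f / config.gravity_torque
        n_half = (theta0 - min_amplitude) / delta + 8.0
    elif friction.viscous_coeff > 0:
        gamma = friction.viscous_coeff / (2.0 * config.moment_of_inertia)
        n_half = math.log(max(theta0 / min_amplitude, 1.5)) / max(gamma * half, 1e-6) + 8.0
    else:
        n_half = 60.0
    return float(np.clip(n_half * half, 2.0, 120.0))


def measure_trial(
    config: PendulumConfig,
    friction: FrictionParams,
    layout: MarkerLayout | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float | None = None,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> CofEstimate:
    """One simulated measurement: simulate -> render markers -> track -> estimate."""
    if duration is None:
        duration = auto_duration(config, friction, min_amplitude)
    traj = simulate_free_oscillation(config, friction, duration)
    frames = render_markers(traj, layout=layout, noise_sd=noise_sd, seed=seed)
    series = estimate_angles(frames, layout=layout)
    return estimate_cof_from_series(series, config, min_amplitude=min_amplitude)


def measure_joint(
    config: PendulumConfig,
    friction: FrictionParams,
    n_trials: int = 3,
    layout: MarkerLayout | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> JointCof:
    """Replicate trials on one joint, averaged as in the measurement protocol."""
    rng = np.random.default_rng(seed)
    estimates = [
        measure_trial(
            config,
            friction,
            layout=layout,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            min_amplitude=min_amplitude,
        )
        for _ in range(n_trials)
    ]
    if n_trials == 3:
        return JointCof(estimates, float(np.mean([e.mu_hat for e in estimates])))
    return average_trials(estimates)
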