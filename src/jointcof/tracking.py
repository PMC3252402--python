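"""Angle recovery from 8-marker frames by planar rigid registration.

Each frame is processed in two stages: (i) the least-squares rigid transform
(2-D Kabsch / orthogonal Procrustes) of the observed base markers onto their
references is estimated and applied to all markers, removing any rigid drift
of the apparatus; (ii) the arm rotation about the pivot is solved in closed
form, ``psi = atan2(sum p x q, sum p . q)`` over the pivot-relative reference
(p) and drift-corrected observed (q) arm markers.  The recovered angle is
the rotation relative to the equilibrium reference pose, phase-unwrapped so
the series is continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pendulum import LayoutError, MarkerFrames, MarkerLayout

__all__ = ["AngleSeries", "ConditioningError", "TrackingError", "estimate_angles"]


class ConditioningError(ValueError):
    """Arm-marker geometry too degenerate for a stable rotation estimate."""


class TrackingError(RuntimeError):
    """Raised when too many frames are unusable."""


@dataclass
class AngleSeries:
    """Recovered pendulum angles with per-frame registration residuals."""

    times: np.ndarray
    angles: np.ndarray  # rad, deviation from equilibrium
    residual_rms: np.ndarray  # mm, arm-registration residual per frame
    n_interpolated: int = 0


def _rotation_angle(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least-squares rotation angle(s) taking point set p onto q (about the origin)."""
    dot = np.sum(p[..., 0] * q[..., 0] + p[..., 1] * q[..., 1], axis=-1)
    cross = np.sum(p[..., 0] * q[..., 1] - p[..., 1] * q[..., 0], axis=-1)
    return np.arctan2(cross, dot)


def _check_conditioning(arm_ref: np.ndarray) -> None:
    radii = np.linalg.norm(arm_ref, axis=1)
    if np.all(radii < 1e-9):
        raise ConditioningError("all arm markers coincide with the pivot")
    # Collinear through the pivot: every pairwise cross product ~ 0.
    cross = np.abs(arm_ref[:, None, 0] * arm_ref[None, :, 1] - arm_ref[:, None, 1] * arm_ref[None, :, 0])
    scale = np.outer(radii, radii)
    ok = scale > 1e-12
    if not np.any(cross[ok] / scale[ok] > 1e-8):
        raise ConditioningError("arm markers are collinear through the pivot")


def _rigid_to_reference(obs: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rigid transform (rotation angle, translation) mapping obs -> ref.

    ``obs`` has shape (n_frames, k, 2); returns (phi (n_frames,), t (n_frames, 2)).
    """
    c_obs = obs.mean(axis=1)
    c_ref = ref.mean(axis=0)
    phi = _rotation_angle(obs - c_obs[:, None, :], ref[None, :, :] - c_ref)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    rot_c = np.stack(
        [cos_p * c_obs[:, 0] - sin_p * c_obs[:, 1], sin_p * c_obs[:, 0] + cos_p * c_obs[:, 1]],
        axis=1,
    )
    return phi, c_ref[None, :] - rot_c


def _apply_rigid(points: np.ndarray, phi: np.ndarray, t: np.ndarray) -> np.ndarray:
    cos_p, sin_p = np.cos(phi)[:, None], np.sin(phi)[:, None]
    out = np.empty_like(points)
    out[..., 0] = cos_p * points[..., 0] - sin_p * points[..., 1] + t[:, None, 0]
    out[..., 1] = sin_p * points[..., 0] + cos_p * points[..., 1] + t[:, None, 1]
    return out


def estimate_angles(
    frames: MarkerFrames,
    layout: MarkerLayout | None = None,
    max_dropped_frac: float = 0.05,
) -> AngleSeries:
    """Recover the pendulum angle per frame from marker coordinates.

    Frames with missing (NaN) markers that retain at least 3 arm and 3 base
    markers are solved on the surviving subset; frames below that are
    flagged and their angle linearly interpolated from neighbours.  An error
    is raised if more than ``max_dropped_frac`` of frames are interpolated.
    """
    if layout is None:
        from .pendulum import default_layout

        layout = default_layout()
    arm_ref, base_ref = layout.arm, layout.base
    _check_conditioning(arm_ref)
    obs = np.asarray(frames.positions, dtype=float)
    n_frames = obs.shape[0]
    if obs.shape[1] != len(arm_ref) + len(base_ref):
        raise LayoutError(
            f"frames carry {obs.shape[1]} markers but layout defines {len(arm_ref) + len(base_ref)}"
        )
    arm_obs = obs[:, : len(arm_ref), :]
    base_obs = obs[:, len(arm_ref) :, :]

    angles = np.full(n_frames, np.nan)
    residual = np.full(n_frames, np.nan)
    finite = np.isfinite(obs).all(axis=2)
    clean = finite.all(axis=1)

    def _solve(a_obs, b_obs, a_ref, b_ref):
        phi, t = _rigid_to_reference(b_obs, b_ref)
        a_corr = _apply_rigid(a_obs, phi, t)
        psi = _rotation_angle(a_ref[None, :, :], a_corr)
        cos_s, sin_s = np.cos(psi)[:, None], np.sin(psi)[:, None]
        pred = np.stack(
            [
                cos_s * a_ref[None, :, 0] - sin_s * a_ref[None, :, 1],
                sin_s * a_ref[None, :, 0] + cos_s * a_ref[None, :, 1],
            ],
            axis=2,
        )
        res = np.sqrt(np.mean(np.sum((pred - a_corr) ** 2, axis=2), axis=1))
        return psi, res

    if clean.any():
        psi, res = _solve(arm_obs[clean], base_obs[clean], arm_ref, base_ref)
        angles[clean] = psi
        residual[clean] = res

    n_interp = 0
    for i in np.nonzero(~clean)[0]:
        arm_ok = finite[i, : len(arm_ref)]
        base_ok = finite[i, len(arm_ref) :]
        if arm_ok.sum() >= 3 and base_ok.sum() >= 3:
            psi, res = _solve(
                arm_obs[i : i + 1, arm_ok],
                base_obs[i : i + 1, base_ok],
                arm_ref[arm_ok],
                base_ref[base_ok],
            )
            angles[i] = psi[0]
            residual[i] = res[0]
        else:
            n_interp += 1

    missing = np.isnan(angles)
    if missing.all():
        raise TrackingError("no frame has enough markers to recover an angle")
    if n_interp > max_dropped_frac * n_frames:
        raise TrackingError(
            f"{n_interp} of {n_frames} frames dropped (> {max_dropped_frac:.0%}); refusing to interpolate"
        )
    good = ~missing
    unwrapped = np.unwrap(angles[good])
    angles[good] = unwrapped
    if missing.any():
        idx = np.arange(n_frames)
        angles[missing] = np.interp(idx[missing], idx[good], angles[good])
        residual[missing] = np.nan
        warnings.warn(f"interpolated angle in {n_interp} frame(s) with missing markers", stacklevel=2)

    return AngleSeries(
        times=np.asarray(frames.times),
        angles=angles,
        residual_rms=residual,
        n_interpolated=n_interp,
    )
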