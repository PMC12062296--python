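"""Discretely sampled stimulus paths for a condition.

A trajectory is the stimulus position (x, y in dva, fixation at the origin)
and contrast over time, sampled at the display update rate (1440 Hz, i.e.
dt = 1000/1440 ms).  The movement follows a circular arc whose maximum
deviation from the straight chord is 15% of the movement amplitude; the
coordinate along the movement axis advances at constant speed (or along a
gamma velocity profile) while the orthogonal coordinate follows the circle.
Static endpoints of configurable duration precede and follow the motion.

Two presentation layouts are supported:

``"centered"``
    the stimulus is on screen for a fixed 500 ms with its motion centered,
    contrast ramping linearly over the first and last 100 ms;
``"endpoints"``
    static endpoints of exactly ``endpoint_ms`` each side at full contrast
    (the endpoint-duration manipulation).

Motion-absent twins share the endpoint samples exactly: the ``"gap"`` variant
blanks the motion window, the ``"contrast_jump"`` variant applies the
mirrored-velocity contrast ramp and steps the position at the moment of peak
velocity (the single sample where contrast is exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import StimulusCondition, contrast_ramp, gamma_velocity_profile

__all__ = [
    "DT_DISPLAY_MS",
    "ARC_SAGITTA_FRACTION",
    "Trajectory",
    "arc_geometry",
    "arc_offset",
    "sample_trajectory",
    "motion_absent_trajectory",
]

#: Display update interval in ms (1440 Hz).
DT_DISPLAY_MS: float = 1000.0 / 1440.0

#: Maximum deviation of the arc from the straight chord, fraction of amplitude.
ARC_SAGITTA_FRACTION: float = 0.15

_SEGMENTS = ("pre_static", "motion", "post_static", "absent")


@dataclass
class Trajectory:
    """Time-stamped stimulus path.

    Attributes
    ----------
    t_ms : ndarray
        Sample times, ms, uniform grid.
    x, y : ndarray
        Stimulus position, dva, fixation at the origin.
    contrast : ndarray
        Stimulus contrast in [0, 1].
    segment : ndarray of str
        Per-sample label: pre_static / motion / post_static / absent.
    condition : StimulusCondition
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    contrast: np.ndarray
    segment: np.ndarray
    condition: StimulusCondition

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "x_dva": self.x,
                "y_dva": self.y,
                "contrast": self.contrast,
                "segment": self.segment,
            }
        )


def arc_geometry(amplitude: float, sagitta_fraction: float = ARC_SAGITTA_FRACTION):
    """Radius and center of the circular motion arc.

    The arc passes through the movement endpoints (chord of length
    ``amplitude`` on the movement axis) with sagitta ``s = 0.15 * amplitude``
    at the midpoint; the radius follows from sagitta-chord geometry,
    ``r = ((A/2)**2 + s**2) / (2 s)``.

    Returns
    -------
    radius : float
        Circle radius, dva.
    center : tuple of float
        Circle center in (along-chord, orthogonal) coordinates with the chord
        spanning ``[-A/2, A/2]`` at orthogonal coordinate 0 and the arc
        bulging toward positive orthogonal values.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    s = sagitta_fraction * amplitude
    r = ((amplitude / 2.0) ** 2 + s**2) / (2.0 * s)
    return r, (0.0, s - r)


def arc_offset(u, amplitude: float, sagitta_fraction: float = ARC_SAGITTA_FRACTION):
    """Orthogonal arc deviation at along-chord coordinate ``u`` in [-A/2, A/2]."""
    r, (_, cy) = arc_geometry(amplitude, sagitta_fraction)
    u = np.clip(np.asarray(u, dtype=float), -amplitude / 2.0, amplitude / 2.0)
    return cy + np.sqrt(r**2 - u**2)


def _motion_coordinates(cond: StimulusCondition, t_motion_ms: np.ndarray):
    """Along-chord u(t) over the motion window, from -A/2 to +A/2."""
    a = cond.amplitude
    if cond.profile == "constant":
        u = -a / 2.0 + cond.v * t_motion_ms / 1000.0
    else:
        prof = gamma_velocity_profile(a, cond.D_ms, dt_ms=float(t_motion_ms[1] - t_motion_ms[0]))
        # cumulative displacement on the same grid
        disp = np.concatenate(
            [[0.0], np.cumsum((prof.v[1:] + prof.v[:-1]) / 2.0 * np.diff(prof.t_ms) / 1000.0)]
        )
        disp *= a / disp[-1]  # absorb quadrature residue of the 99.9% truncation
        u = np.interp(t_motion_ms, prof.t_ms, disp) - a / 2.0
    return np.clip(u, -a / 2.0, a / 2.0)


def _axes_for_direction(direction: str):
    """Unit vectors (movement axis, orthogonal axis) in screen (x, y)."""
    if direction == "right":
        return np.array([1.0, 0.0]), np.array([0.0, 1.0])
    if direction == "left":
        return np.array([-1.0, 0.0]), np.array([0.0, 1.0])
    if direction == "up":
        return np.array([0.0, 1.0]), np.array([1.0, 0.0])
    if direction == "down":
        return np.array([0.0, -1.0]), np.array([1.0, 0.0])
    raise ValueError(f"unknown direction {direction!r}")


def _curvature_sign(cond: StimulusCondition) -> float:
    if cond.curvature == "none":
        return 0.0
    # orthogonal axis is y for horizontal motion ('up' positive), x for
    # vertical motion ('right' positive)
    return {"up": 1.0, "right": 1.0, "down": -1.0, "left": -1.0}[cond.curvature]


def sample_trajectory(
    cond: StimulusCondition,
    dt_ms: float = DT_DISPLAY_MS,
    layout: str = "endpoints",
    window_ms: float = 500.0,
    ramp_ms: float = 100.0,
) -> Trajectory:
    """Sample a condition into a stimulus path.

    Parameters
    ----------
    cond : StimulusCondition
    dt_ms : float
        Sample step, ms.  The display default is 1000/1440 ms; coarser grids
        are admissible for simulation (positions are exact at each sample,
        only quadrature of gamma profiles degrades, bounded by one grid step).
    layout : {"endpoints", "centered"}
        "endpoints": static endpoints of ``cond.endpoint_ms`` each, contrast 1
        throughout.  "centered": total ``window_ms`` presentation with motion
        centered and linear contrast ramps of ``ramp_ms`` at either end.
    """
    d = cond.D_ms
    if layout == "centered":
        if d > window_ms:
            raise ValueError(f"motion duration {d:.1f} ms exceeds the {window_ms:.0f} ms window")
        pre = (window_ms - d) / 2.0
        post = pre
        total = window_ms
    elif layout == "endpoints":
        pre = post = cond.endpoint_ms
        total = d + pre + post
    else:
        raise ValueError("layout must be 'endpoints' or 'centered'")

    n = int(round(total / dt_ms))
    t = np.arange(n + 1) * dt_ms
    segment = np.full(t.shape, "pre_static", dtype=object)
    in_motion = (t >= pre) & (t <= pre + d)
    segment[in_motion] = "motion"
    segment[t > pre + d] = "post_static"

    u = np.full(t.shape, -cond.amplitude / 2.0)
    u[t > pre + d] = cond.amplitude / 2.0
    if in_motion.any():
        u[in_motion] = _motion_coordinates(cond, t[in_motion] - pre)

    w = np.zeros_like(u)
    sign = _curvature_sign(cond)
    if sign != 0.0:
        w = sign * arc_offset(u, cond.amplitude)
        w[~in_motion & (t <= pre)] = 0.0
        w[~in_motion & (t > pre + d)] = 0.0

    axis_move, axis_orth = _axes_for_direction(cond.direction)
    x = u * axis_move[0] + w * axis_orth[0]
    y = u * axis_move[1] + w * axis_orth[1]

    contrast = np.ones_like(t)
    if layout == "centered" and ramp_ms > 0:
        contrast = np.minimum(1.0, np.minimum(t / ramp_ms, (total - t) / ramp_ms))
        contrast = np.clip(contrast, 0.0, 1.0)

    return Trajectory(t_ms=t, x=x, y=y, contrast=contrast, segment=segment, condition=cond)


def motion_absent_trajectory(
    cond: StimulusCondition,
    variant: str = "gap",
    dt_ms: float = DT_DISPLAY_MS,
    layout: str = "endpoints",
    window_ms: float = 500.0,
    ramp_ms: float = 100.0,
) -> Trajectory:
    """Motion-absent twin of :func:`sample_trajectory`.

    ``"gap"``: the stimulus disappears (contrast 0) for the duration it would
    have moved, reappearing at the movement endpoint.  ``"contrast_jump"``:
    contrast follows the mirrored gamma-velocity ramp ``1 - v/max v`` and the
    position jumps from start to end at the single sample where contrast is
    exactly zero (the moment of peak velocity of the motion-present twin).
    Endpoint samples are identical to the motion-present twin by construction.
    """
    traj = sample_trajectory(cond, dt_ms=dt_ms, layout=layout, window_ms=window_ms, ramp_ms=ramp_ms)
    in_motion = traj.segment == "motion"
    t_motion = traj.t_ms[in_motion] - traj.t_ms[in_motion][0]
    a = cond.amplitude
    axis_move, _ = _axes_for_direction(cond.direction)

    x = traj.x.copy()
    y = traj.y.copy()
    contrast = traj.contrast.copy()
    segment = traj.segment.copy()
    segment[in_motion] = "absent"

    if variant == "gap":
        contrast[in_motion] = 0.0
        # position parked at the start point until the gap ends
        x[in_motion] = -a / 2.0 * axis_move[0]
        y[in_motion] = -a / 2.0 * axis_move[1]
    elif variant == "contrast_jump":
        if cond.profile != "gamma":
            raise ValueError("contrast_jump variant requires a gamma-profile condition")
        prof = gamma_velocity_profile(a, cond.D_ms, dt_ms=max(float(t_motion[1] - t_motion[0]), 1e-3))
        ramp = np.interp(t_motion, prof.t_ms, contrast_ramp(prof))
        jump_idx = int(np.argmin(ramp))
        ramp[jump_idx] = 0.0  # contrast is exactly zero at the jump sample
        contrast[in_motion] = contrast[in_motion] * ramp
        u = np.where(np.arange(t_motion.size) < jump_idx, -a / 2.0, a / 2.0)
        x[in_motion] = u * axis_move[0]
        y[in_motion] = u * axis_move[1]
    else:
        raise ValueError("variant must be 'gap' or 'contrast_jump'")

    return Trajectory(t_ms=traj.t_ms, x=x, y=y, contrast=contrast, segment=segment, condition=cond)
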