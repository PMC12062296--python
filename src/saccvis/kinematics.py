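"""Saccadic main-sequence kinematics and stimulus condition design.

The main sequence links a saccade's amplitude :math:`A` (in degrees of visual
angle, dva) to its expected duration and peak velocity,

.. math::

    D_{sac}(A) = d_1 \\cdot A + d_0 \\quad\\text{[ms]}, \\qquad
    v_p(A) = c \\cdot A / D_{sac}(A) \\quad\\text{[dva/s]},

with the dimensionless proportionality constant ``c = 1.64`` and the linear
duration law ``2.7 ms/dva`` slope, ``23 ms`` intercept.  Moving stimuli are
parameterised relative to this law: a condition is a movement amplitude plus a
*relative speed* ``v_rel`` (fraction of the matching saccade's peak velocity),
from which the absolute speed ``v = v_rel * v_p(A)``, movement duration
``D = A / v`` and relative duration ``D_rel = D / D_sac(A) = 1/(c * v_rel)``
follow.

Internal units are dva for space, ms for time and dva/s for speed; every
function converts explicitly where a formula mixes seconds and milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MainSequence",
    "StimulusCondition",
    "VelocityProfile",
    "AMPLITUDES",
    "V_REL_GRID",
    "ENDPOINT_DURATIONS_MS",
    "REFERENCE_CONDITION_TABLE",
    "expected_saccade_duration",
    "expected_peak_velocity",
    "make_condition",
    "condition_table",
    "gamma_shape_from_duration",
    "gamma_velocity_profile",
    "contrast_ramp",
]

#: Movement amplitudes (dva) of the standard design.
AMPLITUDES: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)

#: Relative movement speeds (fractions of the matching saccade's peak velocity).
V_REL_GRID: tuple[float, ...] = (1 / 4, 1 / 3, 1 / 2, 2 / 3, 4 / 5, 1.0, 5 / 4)

#: Static-endpoint durations (ms) of the endpoint-manipulation design.
ENDPOINT_DURATIONS_MS: tuple[float, ...] = (0.0, 12.5, 50.0, 200.0)

_DIRECTIONS = ("left", "right", "up", "down")
_CURVATURES = ("up", "down", "left", "right", "none")
_PROFILES = ("constant", "gamma")


@dataclass(frozen=True)
class MainSequence:
    """Main-sequence law of saccadic kinematics.

    Parameters
    ----------
    c : float
        Dimensionless proportionality constant linking peak velocity to
        amplitude over duration.
    dur_slope : float
        Slope of the linear amplitude-duration relation, ms per dva.
    dur_intercept : float
        Intercept of the amplitude-duration relation, ms.
    """

    c: float = 1.64
    dur_slope: float = 2.7
    dur_intercept: float = 23.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"proportionality constant must be positive, got {self.c}")
        if self.dur_slope < 0:
            raise ValueError(f"duration slope must be >= 0, got {self.dur_slope}")
        if self.dur_intercept <= 0:
            raise ValueError(f"duration intercept must be positive, got {self.dur_intercept}")

    def saccade_duration(self, amplitude):
        """Expected saccade duration (ms) for an amplitude in dva."""
        amplitude = np.asarray(amplitude, dtype=float)
        if np.any(amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        out = self.dur_intercept + self.dur_slope * amplitude
        return float(out) if out.ndim == 0 else out

    def peak_velocity(self, amplitude):
        """Expected saccadic peak velocity (dva/s) for an amplitude in dva."""
        amplitude = np.asarray(amplitude, dtype=float)
        if np.any(amplitude <= 0):
            raise ValueError("amplitude must be positive")
        dur_s = (self.dur_intercept + self.dur_slope * amplitude) / 1000.0
        out = self.c * amplitude / dur_s
        return float(out) if out.ndim == 0 else out


_DEFAULT_MS = MainSequence()


def expected_saccade_duration(amplitude, main_sequence: MainSequence = _DEFAULT_MS):
    """Expected duration (ms) of a saccade of ``amplitude`` dva."""
    return main_sequence.saccade_duration(amplitude)


def expected_peak_velocity(amplitude, main_sequence: MainSequence = _DEFAULT_MS):
    """Expected peak velocity (dva/s) of a saccade of ``amplitude`` dva."""
    return main_sequence.peak_velocity(amplitude)


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the stimulus design.

    ``v``, ``D_ms`` and ``D_rel`` are derived from ``(amplitude, v_rel)`` via
    the main sequence; use :func:`make_condition` rather than constructing
    directly.
    """

    amplitude: float
    v_rel: float
    v: float
    D_ms: float
    D_rel: float
    endpoint_ms: float = 200.0
    profile: str = "constant"
    direction: str = "right"
    curvature: str = "up"
    main_sequence: MainSequence = field(default=_DEFAULT_MS, compare=False)

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.v_rel <= 0:
            raise ValueError("amplitude and v_rel must be positive")
        if self.endpoint_ms < 0:
            raise ValueError("endpoint_ms must be non-negative")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.curvature not in _CURVATURES:
            raise ValueError(f"curvature must be one of {_CURVATURES}")


def make_condition(
    amplitude: float,
    v_rel: float,
    endpoint_ms: float = 200.0,
    profile: str = "constant",
    direction: str = "right",
    curvature: str = "up",
    main_sequence: MainSequence = _DEFAULT_MS,
) -> StimulusCondition:
    """Build a :class:`StimulusCondition`, deriving speed and durations.

    All derived quantities are kept at full precision; rounding happens only
    in reporting layers such as :func:`condition_table`.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if v_rel <= 0:
        raise ValueError("v_rel must be positive")
    v_p = main_sequence.peak_velocity(amplitude)
    v = v_rel * v_p
    d_ms = amplitude / v * 1000.0
    d_rel = 1.0 / (main_sequence.c * v_rel)
    return StimulusCondition(
        amplitude=float(amplitude),
        v_rel=float(v_rel),
        v=float(v),
        D_ms=float(d_ms),
        D_rel=float(d_rel),
        endpoint_ms=float(endpoint_ms),
        profile=profile,
        direction=direction,
        curvature=curvature,
        main_sequence=main_sequence,
    )


def condition_table(
    amplitudes=AMPLITUDES,
    v_rels=V_REL_GRID,
    main_sequence: MainSequence = _DEFAULT_MS,
    round_digits: int | None = None,
) -> pd.DataFrame:
    """Full condition grid as a tidy frame.

    Columns: ``amplitude_dva, v_rel, v_dva_per_s, D_ms, D_rel``.  With
    ``round_digits`` the speed/duration columns are rounded (presentation
    layer); computation itself is always full precision.
    """
    rows = []
    for v_rel in v_rels:
        for a in amplitudes:
            c = make_condition(a, v_rel, main_sequence=main_sequence)
            rows.append(
                {
                    "amplitude_dva": c.amplitude,
                    "v_rel": c.v_rel,
                    "v_dva_per_s": c.v,
                    "D_ms": c.D_ms,
                    "D_rel": c.D_rel,
                }
            )
    df = pd.DataFrame(rows)
    if round_digits is not None:
        for col in ("v_dva_per_s", "D_ms"):
            df[col] = df[col].round(round_digits)
        df["D_rel"] = df["D_rel"].round(2)
    return df


# Published speeds (dva/s) and durations (ms) for the standard 5x7 design,
# amplitude columns 4, 6, 8, 10, 12 dva; used by the CLI self-check and tests.
REFERENCE_CONDITION_TABLE: dict[float, dict[str, tuple[float, ...]]] = {
    1 / 4: {
        "v": (48.5, 62.8, 73.5, 82.0, 88.8),
        "D": (82.4, 95.6, 108.8, 122.0, 135.1),
        "D_rel": (2.44,),
    },
    1 / 3: {
        "v": (64.7, 83.7, 98.1, 109.3, 118.4),
        "D": (61.8, 71.7, 81.6, 91.5, 101.3),
        "D_rel": (1.83,),
    },
    1 / 2: {
        "v": (97.0, 125.5, 147.1, 164.0, 177.6),
        "D": (41.2, 47.8, 54.4, 61.0, 67.6),
        "D_rel": (1.22,),
    },
    2 / 3: {
        "v": (129.4, 167.3, 196.1, 218.7, 236.8),
        "D": (30.9, 35.9, 40.8, 45.7, 50.7),
        "D_rel": (0.91,),
    },
    4 / 5: {
        "v": (155.3, 200.8, 235.3, 262.4, 284.2),
        "D": (25.8, 29.9, 34.0, 38.1, 42.2),
        "D_rel": (0.76,),
    },
    1.0: {
        "v": (194.1, 251.0, 294.2, 328.0, 355.2),
        "D": (20.6, 23.9, 27.2, 30.5, 33.8),
        "D_rel": (0.61,),
    },
    5 / 4: {
        "v": (242.6, 313.8, 367.7, 410.0, 444.0),
        "D": (16.5, 19.1, 21.8, 24.4, 27.0),
        "D_rel": (0.49,),
    },
}


@dataclass(frozen=True)
class VelocityProfile:
    """Sampled gamma-kernel velocity profile of a simulated saccadic movement.

    ``v(t) = alpha * (t/beta)**(gamma_shape - 1) * exp(-t/beta)`` with the
    shape parameter tied to the movement duration; alpha (dva/s) and beta (ms)
    are scaled so the profile travels ``amplitude`` dva in ``duration_ms`` ms
    (99.9%-displacement truncation, see :func:`gamma_velocity_profile`).
    """

    t_ms: np.ndarray
    v: np.ndarray
    gamma_shape: float
    alpha: float
    beta_ms: float
    amplitude: float
    duration_ms: float

    @property
    def peak_time_ms(self) -> float:
        """Closed-form mode of the gamma kernel, (gamma_shape - 1) * beta."""
        return (self.gamma_shape - 1.0) * self.beta_ms

    @property
    def peak_velocity(self) -> float:
        return float(self.v.max())

    def displacement(self) -> float:
        """Trapezoidal displacement (dva) over the sampled motion window."""
        return float(np.trapezoid(self.v, self.t_ms / 1000.0))


def gamma_shape_from_duration(duration_ms: float) -> float:
    """Shape parameter of the saccadic velocity profile for a duration in ms.

    ``gamma = 4 / (3.26 * D + 0.77)**2`` with D in seconds.  Shapes <= 1 make
    the profile lose its unimodal, positively skewed form and are rejected.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    d_s = duration_ms / 1000.0
    shape = 4.0 / (3.26 * d_s + 0.77) ** 2
    if shape <= 1.0:
        raise ValueError(
            f"gamma shape {shape:.3f} <= 1 for duration {duration_ms:.1f} ms; "
            "the gamma velocity profile is only defined for shapes > 1"
        )
    return shape


def gamma_velocity_profile(
    amplitude: float,
    duration_ms: float,
    dt_ms: float = 1000.0 / 1440.0,
    mass: float = 0.999,
) -> VelocityProfile:
    """Gamma-kernel velocity profile scaled to a given amplitude and duration.

    The gamma kernel has infinite support, so the motion duration is defined
    as the leading interval containing ``mass`` (99.9%) of the displacement:
    beta is set so that interval equals ``duration_ms`` and alpha so the
    displacement over it equals ``amplitude``.

    Parameters
    ----------
    amplitude : float
        Movement amplitude, dva.
    duration_ms : float
        Movement duration, ms.
    dt_ms : float
        Sample step of the returned grid, ms (display default 1000/1440).

    Returns
    -------
    VelocityProfile
        Samples on ``t = 0 .. duration_ms`` with ``v`` in dva/s.
    """
    if amplitude <= 0 or duration_ms <= 0 or dt_ms <= 0:
        raise ValueError("amplitude, duration and dt must be positive")
    shape = gamma_shape_from_duration(duration_ms)
    # time (unit scale) below which `mass` of the gamma displacement lies
    t_mass_unit = float(stats.gamma.ppf(mass, shape))
    beta_ms = duration_ms / t_mass_unit
    beta_s = beta_ms / 1000.0
    # displacement of alpha*(t/beta)^(g-1) exp(-t/beta) over [0, D] is
    # alpha * beta_s * Gamma(g) * P(g, D/beta); choose alpha to make it A
    alpha = amplitude / (beta_s * special.gamma(shape) * mass)
    n = max(int(round(duration_ms / dt_ms)), 2)
    t_ms = np.linspace(0.0, duration_ms, n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = alpha * (t_ms / beta_ms) ** (shape - 1.0) * np.exp(-t_ms / beta_ms)
    v[0] = 0.0
    return VelocityProfile(
        t_ms=t_ms,
        v=v,
        gamma_shape=shape,
        alpha=alpha,
        beta_ms=beta_ms,
        amplitude=float(amplitude),
        duration_ms=float(duration_ms),
    )


def contrast_ramp(profile: VelocityProfile) -> np.ndarray:
    """Mirrored-velocity contrast series ``c(t) = 1 - v(t)/max v`` in [0, 1].

    Used for motion-absent trials with a time-varying profile: contrast dips
    to exactly zero at the moment of peak velocity, when the motion-present
    twin would be fastest.
    """
    vmax = profile.v.max()
    if vmax <= 0:
        import warnings

        warnings.warn("all-zero velocity profile; returning constant contrast 1")
        return np.ones_like(profile.v)
    return 1.0 - profile.v / vmax
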