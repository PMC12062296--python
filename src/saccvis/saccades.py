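"""Saccade detection on eye traces, trial filtering, main-sequence fitting.

Detection follows the velocity-threshold scheme standard for video
eye-tracking: smoothed 2-D velocity (five-sample moving average), an
adaptive speed threshold of the median speed plus five median-based standard
deviations, a minimum above-threshold duration of 8 ms, and merging of
events separated by 10 ms or less (double detections from overshoots).

Empirical main sequences are fitted per observer × direction with

.. math::

    v_p = v_0 (1 - e^{-A/a_0}), \\qquad D = d_0 + c \\cdot A,

a saturating peak-velocity law and a linear duration law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EyeTrace",
    "smooth_velocity",
    "SaccadeDetector",
    "detect_saccades",
    "filter_saccade_trials",
    "filter_perceptual_trials",
    "MainSequenceFitter",
    "fit_main_sequence",
]


@dataclass
class EyeTrace:
    """Eye-position trace: uniformly sampled t (ms), x/y (dva), validity."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        dt = np.diff(self.t_ms)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform within a trace")
        if self.valid is None:
            self.valid = np.ones(self.t_ms.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EyeTrace":
        valid = df["valid"].to_numpy(dtype=bool) if "valid" in df.columns else None
        return cls(
            t_ms=df["t_ms"].to_numpy(dtype=float),
            x=df["x_dva"].to_numpy(dtype=float),
            y=df["y_dva"].to_numpy(dtype=float),
            valid=valid,
        )


def smooth_velocity(trace: EyeTrace) -> np.ndarray:
    """Smoothed 2-D velocity (dva/s), shape (n, 2).

    Central finite differences followed by a centered five-sample moving
    average; constant position maps to zero velocity and a linear ramp to its
    exact slope away from the edges.
    """
    if trace.t_ms.size < 5:
        raise ValueError("need at least 5 samples to smooth velocity")
    dt_s = trace.dt_ms / 1000.0
    v = np.column_stack([np.gradient(trace.x, dt_s), np.gradient(trace.y, dt_s)])
    return ndimage.uniform_filter1d(v, size=5, axis=0, mode="nearest")


def _median_sd(a: np.ndarray) -> float:
    """Median-based standard deviation: sqrt(median((a - median(a))**2))."""
    med = np.median(a)
    return float(np.sqrt(np.median((a - med) ** 2)))


class SaccadeDetector(BaseEstimator):
    """Adaptive velocity-threshold saccade detector.

    Parameters
    ----------
    threshold_sd : float
        Number of median-based SDs above the median speed.
    min_duration_ms : float
        Minimum above-threshold duration for an event.
    merge_gap_ms : float
        Events separated by at most this gap are merged into one.
    """

    def __init__(self, threshold_sd: float = 5.0, min_duration_ms: float = 8.0, merge_gap_ms: float = 10.0):
        self.threshold_sd = threshold_sd
        self.min_duration_ms = min_duration_ms
        self.merge_gap_ms = merge_gap_ms

    def fit(self, X=None, y=None):
        """No-op; the detector is parametric.  Present for API conformity."""
        self.fitted_ = True
        return self

    def detect(self, trace: EyeTrace) -> pd.DataFrame:
        """Detect saccades in a trace.

        Returns a frame with one row per event: onset/offset (ms), duration,
        amplitude (dva, onset-to-offset displacement), peak velocity (dva/s),
        direction (dominant displacement axis; oblique events flagged).
        An all-noise trace yields an empty frame.
        """
        v = smooth_velocity(trace)
        speed = np.hypot(v[:, 0], v[:, 1])
        thresh = np.median(speed) + self.threshold_sd * _median_sd(speed)
        above = speed > thresh

        dt = trace.dt_ms
        events = []
        # events are above-threshold runs of >= min_duration_ms; merging of
        # nearby events (overshoot double-detections) happens afterwards
        runs = [
            (start, stop)
            for start, stop in _runs(above)
            if (stop - start) * dt >= self.min_duration_ms
        ]
        merged = []
        for start, stop in runs:
            if merged and (start - merged[-1][1]) * dt <= self.merge_gap_ms:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        for start, stop in merged:
            dur = (stop - start) * dt
            seg = slice(start, min(stop + 1, trace.t_ms.size))
            dx = trace.x[seg.stop - 1] - trace.x[start]
            dy = trace.y[seg.stop - 1] - trace.y[start]
            amp = float(np.hypot(dx, dy))
            if abs(dx) >= abs(dy):
                direction = "right" if dx >= 0 else "left"
            else:
                direction = "up" if dy >= 0 else "down"
            dominant = max(abs(dx), abs(dy))
            oblique = bool(dominant > 0 and min(abs(dx), abs(dy)) > 0.5 * dominant)
            events.append(
                {
                    "onset_ms": float(trace.t_ms[start]),
                    "offset_ms": float(trace.t_ms[stop - 1] + dt),
                    "duration_ms": float(dur),
                    "amplitude_dva": amp,
                    "peak_velocity": float(speed[start:stop].max()),
                    "direction": direction,
                    "oblique": oblique,
                }
            )
        return pd.DataFrame(
            events,
            columns=[
                "onset_ms",
                "offset_ms",
                "duration_ms",
                "amplitude_dva",
                "peak_velocity",
                "direction",
                "oblique",
            ],
        )


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def detect_saccades(trace: EyeTrace, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`SaccadeDetector`."""
    return SaccadeDetector(**kwargs).detect(trace)


def filter_saccade_trials(
    events: pd.DataFrame,
    target_amplitude: float,
    gain_bounds: tuple[float, float] = (0.5, 1.5),
    max_peak_velocity: float = 800.0,
    max_duration_ms: float = 100.0,
    max_presaccade_dva: float = 1.0,
    missing_data: bool = False,
) -> pd.DataFrame:
    """Classify a trial's detected events as kept or rejected, with reasons.

    The response saccade is the event whose gain (amplitude / instructed
    eccentricity) is closest to 1.  The trial is rejected when that gain
    leaves ``gain_bounds``, the peak velocity exceeds 800 dva/s, the duration
    exceeds 100 ms, any earlier event exceeds ``max_presaccade_dva``, or the
    trial has missing data.

    Returns the events frame with ``kept`` and ``reason`` columns; the
    response-saccade row carries the trial-level verdict.
    """
    events = events.copy()
    events["kept"] = False
    events["reason"] = ""
    if missing_data:
        events["reason"] = "missing"
        return events
    if events.empty:
        return events

    gains = events["amplitude_dva"] / target_amplitude
    resp = (gains - 1.0).abs().idxmin()
    reasons = []
    if not (gain_bounds[0] <= gains.loc[resp] <= gain_bounds[1]):
        reasons.append("gain")
    if events.loc[resp, "peak_velocity"] > max_peak_velocity:
        reasons.append("peak_velocity")
    if events.loc[resp, "duration_ms"] > max_duration_ms:
        reasons.append("duration")
    pre = events.loc[events["onset_ms"] < events.loc[resp, "onset_ms"]]
    if (pre["amplitude_dva"] > max_presaccade_dva).any():
        reasons.append("presaccade")
    if reasons:
        events.loc[resp, "reason"] = "+".join(reasons)
    else:
        events.loc[resp, "kept"] = True
    return events


def filter_perceptual_trials(
    trace: EyeTrace,
    window_ms: tuple[float, float],
    max_saccade_dva: float = 1.0,
    skipped_frames: bool = False,
    detector: SaccadeDetector | None = None,
) -> tuple[bool, str]:
    """Keep/reject a fixation trial by eye behavior during the stimulus window.

    Rejects on any saccade larger than ``max_saccade_dva`` overlapping the
    stimulus window, on missing samples (blinks), or on a skipped-frames
    flag.  Returns ``(keep, reason)``.
    """
    if skipped_frames:
        return False, "skipped_frames"
    lo, hi = window_ms
    in_window = (trace.t_ms >= lo) & (trace.t_ms <= hi)
    if not np.all(trace.valid[in_window]):
        return False, "missing"
    detector = detector or SaccadeDetector()
    events = detector.detect(trace)
    for _, ev in events.iterrows():
        overlaps = ev["onset_ms"] <= hi and ev["offset_ms"] >= lo
        if overlaps and ev["amplitude_dva"] > max_saccade_dva:
            return False, "saccade"
    return True, ""


class MainSequenceFitter(BaseEstimator):
    """Empirical main-sequence fit for one observer × direction cell.

    Peak velocity is fitted by nonlinear least squares to the saturating law
    ``v_p = v0 * (1 - exp(-A/a0))`` (retrying from a grid of starts on
    non-convergence) and duration by ordinary least squares to
    ``D = d0 + c * A``.

    Attributes
    ----------
    v0_, a0_ : float
        Peak-velocity asymptote (dva/s) and amplitude scale (dva).
    d0_, c_dur_ : float
        Duration intercept (ms) and slope (ms/dva).
    converged_ : bool
    """

    def __init__(self, min_amplitudes: int = 5):
        self.min_amplitudes = min_amplitudes

    def fit(self, X, y=None, durations=None):
        """Fit from amplitudes ``X`` (dva), peak velocities ``y`` (dva/s) and
        ``durations`` (ms)."""
        A = np.asarray(X, dtype=float).reshape(-1)
        vp = np.asarray(y, dtype=float).reshape(-1)
        if np.unique(A).size < self.min_amplitudes:
            raise ValueError(f"need events at >= {self.min_amplitudes} distinct amplitudes")

        def law(a, v0, a0):
            return v0 * (1.0 - np.exp(-a / a0))

        self.converged_ = False
        best = None
        v0_starts = [vp.max(), 1.5 * vp.max(), 3.0 * vp.max()]
        a0_starts = [A.mean() / 2, A.mean(), 2 * A.mean()]
        for v00 in v0_starts:
            for a00 in a0_starts:
                try:
                    popt, _ = optimize.curve_fit(
                        law, A, vp, p0=(v00, a00), bounds=((1e-6, 1e-6), (1e5, 1e4)), maxfev=5000
                    )
                except RuntimeError:
                    continue
                resid = float(np.sum((law(A, *popt) - vp) ** 2))
                if best is None or resid < best[0]:
                    best = (resid, popt)
        if best is None:
            self.v0_ = self.a0_ = float("nan")
        else:
            self.v0_, self.a0_ = (float(p) for p in best[1])
            self.converged_ = True

        if durations is not None:
            D = np.asarray(durations, dtype=float).reshape(-1)
            slope, intercept = np.polyfit(A, D, 1)
            self.d0_ = float(intercept)
            self.c_dur_ = float(slope)
        else:
            self.d0_ = self.c_dur_ = float("nan")
        return self

    def predict_peak_velocity(self, amplitude):
        check_is_fitted(self, "v0_")
        a = np.asarray(amplitude, dtype=float)
        out = self.v0_ * (1.0 - np.exp(-a / self.a0_))
        return float(out) if out.ndim == 0 else out

    def predict_duration(self, amplitude):
        check_is_fitted(self, "d0_")
        a = np.asarray(amplitude, dtype=float)
        out = self.d0_ + self.c_dur_ * a
        return float(out) if out.ndim == 0 else out


def fit_main_sequence(
    events: pd.DataFrame,
    by=("observer", "direction"),
    amplitude_col: str = "amplitude_dva",
    vp_col: str = "peak_velocity",
    duration_col: str = "duration_ms",
    min_amplitudes: int = 5,
) -> pd.DataFrame:
    """Per-group main-sequence fits over an events table.

    Returns one row per group with v0, a0 (peak-velocity law), d0, c_dur
    (duration law) and a convergence flag.
    """
    rows = []
    for key, g in events.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fitter = MainSequenceFitter(min_amplitudes=min_amplitudes)
        fitter.fit(g[amplitude_col], g[vp_col], durations=g[duration_col])
        rows.append(
            dict(zip(by, key))
            | {
                "v0": fitter.v0_,
                "a0": fitter.a0_,
                "d0": fitter.d0_,
                "c_dur": fitter.c_dur_,
                "converged": fitter.converged_,
            }
        )
    return pd.DataFrame(rows)
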