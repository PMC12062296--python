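"""Early-vision model of high-speed motion visibility.

The model chains five stages:

1. **Spatiotemporal filtering.**  The stimulus (a Gaussian blob of
   ``sigma_stim = 1/3`` dva standing in for the Gabor aperture) is deposited
   on a retinotopic grid at its current position, weighted by contrast, and
   convolved with a spatial Gaussian receptive-field kernel
   (``sigma_RF = 0.15`` dva) and a temporal gamma kernel (shape ``k_RF = 1.6``,
   scale ``theta_RF = 12.5`` ms, latency ``delta_RF = 40`` ms), giving the
   linear response ``R(x, y, t)``.
2. **Normalization.**  ``O = R**2 / (R**2 + C**2)`` with the half-saturation
   constant ``C`` fixed at 30% of the maximum response across the condition
   set (two-pass).
3. **Readout and evidence.**  The spatial maximum ``O(t) = max_xy O(x,y,t)``
   of the motion-present trajectory is compared against its endpoints-only
   twin, and evidence for continuous motion is pooled by probability
   summation, ``E = (sum_t |O_move - O_stat|**beta)**(1/beta)`` with
   ``beta = 1.5``.
4. **Report sampling.**  A trial is correct when a draw from
   ``N(E, sigma_E)`` exceeds zero (``sigma_E = 4``), with a small lapse rate
   under which the response is a coin flip.
5. **Position decoding.**  A population position estimate at each time is the
   coordinate mean weighted by output (relative to its maximum) and by a
   Gaussian distance window around the output peak.

Uncertainty enters through fixational ocular drift (a self-avoiding random
walk jittering the stimulus position) and multiplicative response noise
``N(0, R/8)`` applied independently to the motion-present and endpoints-only
trajectories.  Negative noisy responses are rectified to zero before
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .kinematics import MainSequence, make_condition
from .trajectory import Trajectory, motion_absent_trajectory, sample_trajectory

__all__ = [
    "ModelParams",
    "ActivationGrid",
    "ActivationMap",
    "build_kernels",
    "compute_activation",
    "naka_rushton",
    "max_readout",
    "accumulate_evidence",
    "simulate_reports",
    "decode_position",
    "ocular_drift",
    "add_response_noise",
    "run_model_experiment",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the early-vision model.

    Units: dva for space, ms for time.  ``theta_RF`` is interpreted as a
    scale in ms (giving a ``delta_RF + k_RF*theta_RF = 60`` ms mean response
    latency).  ``noise_sd_mode`` selects whether the second argument of the
    response-noise distribution ``N(0, R/8)`` is read as an SD (default) or a
    variance.
    """

    sigma_stim: float = 1.0 / 3.0  # stimulus blob SD, dva
    sigma_RF: float = 0.15  # receptive-field SD, dva
    delta_RF: float = 40.0  # temporal latency, ms
    k_RF: float = 1.6  # temporal gamma shape
    theta_RF: float = 12.5  # temporal gamma scale, ms
    C_frac: float = 0.30  # half-saturation as fraction of max response
    beta_sum: float = 1.5  # probability-summation exponent
    sigma_E: float = 4.0  # evidence noise SD
    lapse: float = 0.02  # lapse probability
    sigma_I: float = 2.0  # decoding integration window SD, dva
    noise_factor: float = 1.0 / 8.0  # response-noise scale
    noise_sd_mode: str = "sd"  # 'sd' or 'variance'
    dx: float = 0.05  # grid resolution, dva
    dt: float = 1000.0 / 1440.0  # time step, ms
    runs_per_condition: int = 250
    trials_per_sample: int = 200

    def __post_init__(self) -> None:
        for name in (
            "sigma_stim",
            "sigma_RF",
            "delta_RF",
            "k_RF",
            "theta_RF",
            "sigma_E",
            "sigma_I",
            "noise_factor",
            "dx",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.C_frac < 1.0:
            raise ValueError("C_frac must lie in (0, 1)")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.noise_sd_mode not in ("sd", "variance"):
            raise ValueError("noise_sd_mode must be 'sd' or 'variance'")

    @property
    def sigma_eff(self) -> float:
        """Effective spatial SD of stimulus blob convolved with the RF."""
        return float(np.hypot(self.sigma_stim, self.sigma_RF))


@dataclass(frozen=True)
class ActivationGrid:
    """Retinotopic grid: origin and extent in dva, uniform spacing ``dx``."""

    x0: float
    y0: float
    nx: int
    ny: int
    dx: float

    @property
    def x(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny) * self.dx

    @classmethod
    def for_points(cls, x, y, margin: float, dx: float) -> "ActivationGrid":
        x0 = np.floor((np.min(x) - margin) / dx) * dx
        y0 = np.floor((np.min(y) - margin) / dx) * dx
        nx = int(np.ceil((np.max(x) + margin - x0) / dx)) + 1
        ny = int(np.ceil((np.max(y) + margin - y0) / dx)) + 1
        return cls(x0=float(x0), y0=float(y0), nx=nx, ny=ny, dx=float(dx))


@dataclass
class ActivationMap:
    """Model response on a retinotopic grid, array shape (t, y, x)."""

    R: np.ndarray
    t_ms: np.ndarray
    grid: ActivationGrid

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    @property
    def y(self) -> np.ndarray:
        return self.grid.y


def build_kernels(params: ModelParams, mass: float = 0.999):
    """Spatial and temporal response kernels on the model's grids.

    Returns
    -------
    spatial : ndarray, shape (k, k)
        2-D Gaussian of SD ``sigma_RF`` (in dva, sampled at ``dx``),
        normalized to unit sum.
    temporal : ndarray, shape (m,)
        Gamma density (shape ``k_RF``, scale ``theta_RF`` ms) shifted by the
        latency ``delta_RF``, truncated at 99.9% mass and renormalized to
        unit sum; index 0 corresponds to lag 0 ms.
    """
    if params.dt > params.theta_RF:
        warnings.warn(
            f"dt = {params.dt:.2f} ms exceeds theta_RF = {params.theta_RF:.2f} ms; "
            "the temporal kernel is undersampled"
        )
    sx = params.sigma_RF / params.dx
    radius = max(int(np.ceil(4 * sx)), 1)
    ax = np.arange(-radius, radius + 1)
    g1 = np.exp(-0.5 * (ax / sx) ** 2)
    spatial = np.outer(g1, g1)
    spatial /= spatial.sum()

    t_end = params.delta_RF + stats.gamma.ppf(mass, params.k_RF, scale=params.theta_RF)
    lags = np.arange(0.0, t_end + params.dt, params.dt)
    temporal = stats.gamma.pdf(lags - params.delta_RF, params.k_RF, scale=params.theta_RF)
    total = temporal.sum()
    if total <= 0:
        raise ValueError("temporal kernel vanished; check dt against delta_RF/theta_RF")
    temporal = temporal / total
    return spatial, temporal


def _temporal_kernel(params: ModelParams) -> np.ndarray:
    return build_kernels(params)[1]


def compute_activation(
    traj: Trajectory,
    params: ModelParams,
    grid: ActivationGrid | None = None,
    drift: np.ndarray | None = None,
    dtype=np.float32,
) -> ActivationMap:
    """Linear response ``R(x, y, t)`` to a stimulus trajectory.

    The stimulus occupancy (a contrast-weighted point deposit at the current,
    optionally drift-jittered, position) is convolved with the temporal gamma
    kernel and with the effective spatial Gaussian
    ``sqrt(sigma_stim**2 + sigma_RF**2)`` — the closed form of blob-then-RF
    convolution.  The temporal pass exploits the single-deposit-per-frame
    sparsity; the time axis is extended by the kernel length so late
    responses are not clipped.

    Parameters
    ----------
    drift : ndarray, shape (n_samples, 2), optional
        Ocular-drift jitter (dva) added to the stimulus position per sample.
    """
    x_pos = traj.x.astype(float).copy()
    y_pos = traj.y.astype(float).copy()
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if drift.shape != (x_pos.size, 2):
            raise ValueError(f"drift must have shape ({x_pos.size}, 2), got {drift.shape}")
        x_pos += drift[:, 0]
        y_pos += drift[:, 1]

    margin = 4.0 * params.sigma_eff
    if grid is None:
        grid = ActivationGrid.for_points(x_pos, y_pos, margin, params.dx)
    else:
        if (
            np.min(x_pos) < grid.x0
            or np.max(x_pos) > grid.x0 + (grid.nx - 1) * grid.dx
            or np.min(y_pos) < grid.y0
            or np.max(y_pos) > grid.y0 + (grid.ny - 1) * grid.dx
        ):
            raise ValueError("trajectory (plus drift) leaves the activation grid")

    kernel_t = _temporal_kernel(params)
    n_in = traj.t_ms.size
    n_t = n_in + kernel_t.size - 1
    R = np.zeros((n_t, grid.ny, grid.nx), dtype=dtype)

    # bilinear deposit, pre-multiplied by the temporal kernel (scatter-add)
    fx = (x_pos - grid.x0) / grid.dx
    fy = (y_pos - grid.y0) / grid.dx
    ix = np.clip(np.floor(fx).astype(int), 0, grid.nx - 2)
    iy = np.clip(np.floor(fy).astype(int), 0, grid.ny - 2)
    wx = fx - ix
    wy = fy - iy
    kt = kernel_t.astype(dtype)
    m = kt.size
    contrast = traj.contrast.astype(float)
    for i in range(n_in):
        c = contrast[i]
        if c == 0.0:
            continue
        sl = slice(i, i + m)
        w00 = c * (1 - wx[i]) * (1 - wy[i])
        w01 = c * wx[i] * (1 - wy[i])
        w10 = c * (1 - wx[i]) * wy[i]
        w11 = c * wx[i] * wy[i]
        R[sl, iy[i], ix[i]] += kt * dtype(w00)
        R[sl, iy[i], ix[i] + 1] += kt * dtype(w01)
        R[sl, iy[i] + 1, ix[i]] += kt * dtype(w10)
        R[sl, iy[i] + 1, ix[i] + 1] += kt * dtype(w11)

    sigma_px = params.sigma_eff / params.dx
    ndimage.gaussian_filter1d(R, sigma_px, axis=1, output=R, mode="constant")
    ndimage.gaussian_filter1d(R, sigma_px, axis=2, output=R, mode="constant")

    t_ms = np.arange(n_t) * params.dt
    return ActivationMap(R=R, t_ms=t_ms, grid=grid)


def naka_rushton(R, C: float):
    """Hyperbolic-squared normalization ``R**2 / (R**2 + C**2)``.

    ``C`` is the response at which the output reaches 0.5 (half-saturation).
    Output lies in [0, 1).
    """
    if C <= 0:
        raise ValueError("half-saturation constant C must be positive")
    R = np.asarray(R, dtype=float)
    R2 = R * R
    return R2 / (R2 + C * C)


def max_readout(O: np.ndarray) -> np.ndarray:
    """Spatial maximum per time sample of a (t, y, x) output map."""
    O = np.asarray(O)
    return O.reshape(O.shape[0], -1).max(axis=1)


def accumulate_evidence(o_move: np.ndarray, o_stat: np.ndarray, beta_sum: float = 1.5) -> float:
    """Probability-summation evidence for continuous motion.

    ``E = (sum_t |O_move(t) - O_stat(t)|**beta)**(1/beta)``.  Identical
    readout series give exactly zero evidence.
    """
    o_move = np.asarray(o_move, dtype=float)
    o_stat = np.asarray(o_stat, dtype=float)
    if o_move.shape != o_stat.shape:
        raise ValueError(f"readout series differ in length: {o_move.shape} vs {o_stat.shape}")
    return float(np.sum(np.abs(o_move - o_stat) ** beta_sum) ** (1.0 / beta_sum))


def simulate_reports(
    E: float,
    sigma_E: float = 4.0,
    lapse: float = 0.02,
    n_trials: int = 200,
    rng=None,
    n_resamples: int = 1000,
):
    """Sample perceptual reports from the evidence decision rule.

    A trial is correct when ``N(E, sigma_E) > 0``; with probability ``lapse``
    the response is instead a uniform guess between the two alternatives.
    The confidence interval is the (0.025, 0.975) quantile pair of the
    proportion correct over ``n_resamples`` repetitions.

    Returns
    -------
    p_correct : float
    ci : tuple of float
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    draws = rng.standard_normal((n_resamples, n_trials)) * sigma_E + E
    correct = draws > 0
    if lapse > 0:
        lapsed = rng.random((n_resamples, n_trials)) < lapse
        guesses = rng.random((n_resamples, n_trials)) < 0.5
        correct = np.where(lapsed, guesses, correct)
    p = correct.mean(axis=1)
    lo, hi = np.quantile(p, [0.025, 0.975])
    return float(p.mean()), (float(lo), float(hi))


def decode_position(O_frame: np.ndarray, x: np.ndarray, y: np.ndarray, sigma_I: float = 2.0):
    """Population position estimate from one (y, x) output frame.

    Coordinates are averaged with weights ``w_O * w_delta`` where
    ``w_O = O / max O`` and ``w_delta`` is a Gaussian of SD ``sigma_I``
    centered on the coordinates of the output maximum (first occurrence in
    row-major order on ties).  An all-zero frame has no defined estimate and
    returns ``(nan, nan)``.
    """
    O_frame = np.asarray(O_frame, dtype=float)
    m = O_frame.max()
    if m <= 0:
        return (float("nan"), float("nan"))
    iy, ix = np.unravel_index(int(np.argmax(O_frame)), O_frame.shape)
    xx, yy = np.meshgrid(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    w_o = O_frame / m
    d2 = (xx - xx[iy, ix]) ** 2 + (yy - yy[iy, ix]) ** 2
    w_d = np.exp(-0.5 * d2 / sigma_I**2)
    w = w_o * w_d
    s = w.sum()
    return (float((w * xx).sum() / s), float((w * yy).sum() / s))


def ocular_drift(
    n_steps: int,
    rng=None,
    lattice_dva: float = 2.0,
    n_sites: int = 101,
    relaxation: float = 0.001,
    steepness: float = 1.0,
    smooth: int = 5,
) -> np.ndarray:
    """Fixational drift trace from a self-avoiding random walk.

    The walker lives on an ``n_sites`` square lattice spanning
    ``lattice_dva`` dva.  Each step it moves to the 4-neighbour with the
    smallest sum of activation (incremented where the walker has been,
    relaxing by ``relaxation`` per step) and a quadratic potential of the
    given ``steepness`` centered on the lattice.  The output positions (dva,
    relative to the lattice center) are smoothed with a ``smooth``-point
    running mean to remove lattice discreteness.

    Returns
    -------
    ndarray, shape (n_steps, 2)
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng)
    n = int(n_sites)
    center = (n - 1) / 2.0
    scale = lattice_dva / (n - 1)
    idx = np.arange(n)
    # quadratic potential, normalized so the lattice corner sits at `steepness`
    pot = steepness * (((idx[:, None] - center) ** 2 + (idx[None, :] - center) ** 2) / (2 * center**2))
    h = np.zeros((n, n))
    i, j = int(center), int(center)
    offsets = ((1, 0), (-1, 0), (0, 1), (0, -1))
    pos = np.empty((n_steps, 2))
    for step in range(n_steps):
        h[i, j] += 1.0
        best = None
        best_score = np.inf
        order = rng.permutation(4)
        for k in order:
            di, dj = offsets[k]
            ni, nj = i + di, j + dj
            if not (0 <= ni < n and 0 <= nj < n):
                continue
            score = h[ni, nj] + pot[ni, nj]
            if score < best_score:
                best_score = score
                best = (ni, nj)
        i, j = best
        h *= 1.0 - relaxation
        pos[step, 0] = (j - center) * scale
        pos[step, 1] = (i - center) * scale
    if smooth > 1 and n_steps >= smooth:
        kernel = np.ones(smooth) / smooth
        pos[:, 0] = np.convolve(pos[:, 0], kernel, mode="same")
        pos[:, 1] = np.convolve(pos[:, 1], kernel, mode="same")
    return pos


def add_response_noise(R: np.ndarray, noise_factor: float = 1.0 / 8.0, rng=None, mode: str = "sd"):
    """Add amplitude-dependent Gaussian noise ``N(0, noise_factor * R)``.

    ``mode='sd'`` reads the second argument as a standard deviation
    (SD = ``noise_factor * R``); ``mode='variance'`` as a variance.  Cells
    with zero response receive no noise.
    """
    R = np.asarray(R)
    rng = np.random.default_rng(rng)
    if mode == "sd":
        sd = noise_factor * R
    elif mode == "variance":
        sd = np.sqrt(noise_factor * R)
    else:
        raise ValueError("mode must be 'sd' or 'variance'")
    return R + rng.standard_normal(R.shape).astype(R.dtype) * sd


# ---------------------------------------------------------------------------
# full simulated experiment


def _weibull_decreasing(x, thresh, slope, guess=0.5, lapse=0.02):
    """Negative-slope Weibull on a linear stimulus scale.

    Performance falls from ``1 - lapse`` toward ``guess`` as x grows; the
    threshold parameter is where the curve has covered ``1 - 1/e`` of its
    range.
    """
    x = np.asarray(x, dtype=float)
    return guess + (1.0 - guess - lapse) * np.exp(-((x / thresh) ** slope))


def _fit_weibull_threshold(v_rel, p_correct, guess=0.5, lapse=0.02):
    """Least-squares fit of the decreasing Weibull; returns (threshold, slope).

    Non-convergent cells are flagged with NaNs instead of raising.
    """
    v_rel = np.asarray(v_rel, dtype=float)
    p_correct = np.asarray(p_correct, dtype=float)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, th, sl: _weibull_decreasing(x, th, sl, guess, lapse),
            v_rel,
            p_correct,
            p0=(np.median(v_rel), 2.0),
            bounds=((1e-3, 0.2), (20.0, 20.0)),
            maxfev=2000,
        )
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return float("nan"), float("nan")


def _condition_evidence_runs(cond, params: ModelParams, C: float, seed_seq: np.random.SeedSequence, n_runs: int):
    """Evidence per noisy run for one condition (motion vs endpoints-only)."""
    traj_move = sample_trajectory(cond, dt_ms=params.dt, layout="endpoints")
    traj_stat = motion_absent_trajectory(cond, variant="gap", dt_ms=params.dt, layout="endpoints")
    n_samples = traj_move.t_ms.size
    evidence = np.empty(n_runs)
    children = seed_seq.spawn(n_runs)
    for r, child in enumerate(children):
        rng_drift, rng_noise_m, rng_noise_s = [np.random.default_rng(s) for s in child.spawn(3)]
        o_series = []
        for traj, rng_noise in ((traj_move, rng_noise_m), (traj_stat, rng_noise_s)):
            drift = ocular_drift(n_samples, rng=rng_drift)
            amap = compute_activation(traj, params, drift=drift)
            R = add_response_noise(amap.R, params.noise_factor, rng=rng_noise, mode=params.noise_sd_mode)
            # Naka-Rushton is monotone on rectified responses, so the spatial
            # max can be taken first and normalized as a scalar series
            m = np.maximum(max_readout(R), 0.0)
            o_series.append(naka_rushton(m, C))
        evidence[r] = accumulate_evidence(o_series[0], o_series[1], params.beta_sum)
    return evidence


def _noise_free_max(cond, params: ModelParams) -> float:
    traj = sample_trajectory(cond, dt_ms=params.dt, layout="endpoints")
    return float(compute_activation(traj, params).R.max())


def run_model_experiment(
    amplitudes=(4.0, 8.0, 12.0),
    v_rels=(1 / 4, 1 / 2, 2 / 3, 1.0, 5 / 4),
    endpoint_durations=(0.0, 200.0),
    params: ModelParams | None = None,
    seed: int | None = None,
    main_sequence: MainSequence | None = None,
    n_ci_resamples: int = 200,
) -> dict:
    """Simulate the endpoint-duration experiment through the full model chain.

    For every amplitude × relative-speed × endpoint-duration condition the
    model is run ``params.runs_per_condition`` times with fresh drift and
    response noise; each run yields evidence ``E`` and
    ``params.trials_per_sample`` simulated reports.  The half-saturation
    constant is fixed in a first, noise-free pass as ``C_frac`` of the
    maximum response over the whole condition set.  Decreasing Weibull
    psychometric functions (guess 0.5, lapse 0.02 fixed) are then fitted to
    proportion correct versus linear relative speed within each amplitude ×
    endpoint cell.

    Returns
    -------
    dict with keys ``conditions`` (per-condition DataFrame: E_mean, E_sd,
    p_correct, ci_lo, ci_hi), ``thresholds`` (per amplitude × endpoint cell:
    Weibull threshold and slope), and ``C`` (half-saturation used).
    """
    params = params or ModelParams()
    ms = main_sequence or MainSequence()
    root = np.random.SeedSequence(seed)

    conds = [
        make_condition(a, vr, endpoint_ms=ep, profile="constant", curvature="up", main_sequence=ms)
        for a in amplitudes
        for ep in endpoint_durations
        for vr in v_rels
    ]
    # pass 1: half-saturation constant from the noise-free response maxima
    C = params.C_frac * max(_noise_free_max(c, params) for c in conds)

    rows = []
    seqs = root.spawn(len(conds))
    for cond, seq in zip(conds, seqs):
        ev = _condition_evidence_runs(cond, params, C, seq, params.runs_per_condition)
        rng_rep = np.random.default_rng(seq.spawn(1)[0])
        p_runs = np.empty(ev.size)
        for r, e in enumerate(ev):
            draws = rng_rep.standard_normal(params.trials_per_sample) * params.sigma_E + e
            correct = draws > 0
            if params.lapse > 0:
                lapsed = rng_rep.random(params.trials_per_sample) < params.lapse
                guesses = rng_rep.random(params.trials_per_sample) < 0.5
                correct = np.where(lapsed, guesses, correct)
            p_runs[r] = correct.mean()
        boot = np.random.default_rng(seq.spawn(1)[0])
        means = boot.choice(p_runs, size=(n_ci_resamples, p_runs.size), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [0.025, 0.975])
        rows.append(
            {
                "amplitude_dva": cond.amplitude,
                "v_rel": cond.v_rel,
                "endpoint_ms": cond.endpoint_ms,
                "E_mean": float(ev.mean()),
                "E_sd": float(ev.std(ddof=1)) if ev.size > 1 else 0.0,
                "p_correct": float(p_runs.mean()),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
            }
        )
    conditions = pd.DataFrame(rows)

    fit_rows = []
    for (a, ep), cell in conditions.groupby(["amplitude_dva", "endpoint_ms"]):
        cell = cell.sort_values("v_rel")
        th, sl = _fit_weibull_threshold(cell["v_rel"], cell["p_correct"], lapse=params.lapse)
        fit_rows.append(
            {"amplitude_dva": a, "endpoint_ms": ep, "threshold_v_rel": th, "slope": sl}
        )
    thresholds = pd.DataFrame(fit_rows)
    return {"conditions": conditions, "thresholds": thresholds, "C": float(C)}
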