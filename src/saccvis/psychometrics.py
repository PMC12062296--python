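"""Psychometric fitting and threshold analysis.

Performance as a function of a stimulus variable x (speed or duration) is
modeled with the Gumbel (log-Weibull) function on log10-transformed stimulus
values,

.. math::

    \\Psi(x; \\theta, \\beta, \\gamma, \\lambda)
        = \\gamma + (1 - \\gamma - \\lambda)\\,(1 - e^{-10^{\\beta (x - \\theta)}}),

where :math:`\\theta` is the threshold (the point where the curve has covered
:math:`1 - e^{-1} = 63.21\\%` of its range — 81.6% correct for a 2AFC task
with no lapses), :math:`\\beta` the slope, :math:`\\gamma` the guess rate
(fixed at 0.5 for 2AFC) and :math:`\\lambda` the lapse rate.  Variables for
which performance falls with the stimulus value (speed, relative duration)
are sign-inverted on the log10 scale before fitting and inverted back for
reporting.

The module also provides signal-detection sensitivity (d'), a saturating
Naka-Rushton fit of d' versus speed for detection-task thresholds, orthogonal
polynomial and Helmert contrasts over threshold profiles, the
retinal-versus-spatial direction-matching correlation analysis, and the
BIC-based Bayes-factor comparison of competing regressions.

Fitting is maximum likelihood on binomial counts with bootstrap percentile
confidence intervals (a deliberate, simpler replacement for hierarchical
Bayesian estimation; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "gumbel_psy",
    "threshold_performance",
    "GumbelPsychometric",
    "fit_gumbel_mle",
    "fit_gumbel_joint",
    "ContrastResult",
    "polynomial_contrasts",
    "helmert_contrasts",
    "dprime",
    "NakaRushtonSensitivity",
    "fit_naka_rushton_dprime",
    "OPPOSITE_DIRECTION",
    "correlate_thresholds_kinematics",
    "compare_regressions_bf",
]


def gumbel_psy(x, threshold, slope, guess=0.5, lapse=0.0):
    """Gumbel psychometric function on a log10 stimulus scale."""
    x = np.asarray(x, dtype=float)
    out = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-np.power(10.0, slope * (x - threshold))))
    return float(out) if out.ndim == 0 else out


def threshold_performance(guess=0.5, lapse=0.0) -> float:
    """Proportion correct at the Gumbel threshold parameter.

    The threshold sits at ``1 - exp(-1)`` (63.21%) of the function's range:
    ``gamma + (1 - e**-1) * (1 - gamma - lapse)``, i.e. 81.6% correct for a
    two-alternative forced choice with no lapses.
    """
    return float(guess + (1.0 - np.exp(-1.0)) * (1.0 - guess - lapse))


def _neg_log_likelihood(theta, slope, lapse, x, n_correct, n_total, guess):
    p = gumbel_psy(x, theta, slope, guess, lapse)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(n_correct * np.log(p) + (n_total - n_correct) * np.log1p(-p))


class GumbelPsychometric(BaseEstimator):
    """Maximum-likelihood Gumbel psychometric fit for one condition.

    Parameters
    ----------
    guess : float
        Fixed guess rate (0.5 for 2AFC).
    lapse : float or None
        Fixed lapse rate, or None to estimate it within ``lapse_max``.
    lapse_max : float
        Upper bound for a free lapse rate.
    decreasing : bool
        If True, performance falls with the stimulus value; the
        log10-transformed variable is sign-inverted before fitting and the
        reported threshold is back on the original stimulus scale.
    log10 : bool
        Log10-transform stimulus values (the standard Gumbel convention).
        If False, x is taken as already being on the fitting scale.
    n_boot : int
        Parametric-bootstrap replicates for the threshold CI (0 disables).
    random_state : int or None

    Attributes
    ----------
    threshold_ : float
        Threshold on the original stimulus scale.
    threshold_fit_ : float
        Threshold on the (possibly inverted) log10 fitting scale.
    slope_ : float
    lapse_ : float
    threshold_ci_ : tuple or None
        Bootstrap percentile CI on the original scale.
    extrapolated_ : bool
        True when the fitted threshold falls outside the sampled range.
    """

    def __init__(
        self,
        guess: float = 0.5,
        lapse: float | None = 0.0,
        lapse_max: float = 0.25,
        decreasing: bool = True,
        log10: bool = True,
        n_boot: int = 0,
        random_state=None,
    ):
        self.guess = guess
        self.lapse = lapse
        self.lapse_max = lapse_max
        self.decreasing = decreasing
        self.log10 = log10
        self.n_boot = n_boot
        self.random_state = random_state

    # -- scale bookkeeping ---------------------------------------------------
    def _to_fit_scale(self, x):
        x = np.asarray(x, dtype=float)
        if self.log10:
            if np.any(x <= 0):
                raise ValueError("stimulus values must be positive for a log10 transform")
            x = np.log10(x)
        return -x if self.decreasing else x

    def _from_fit_scale(self, xf):
        x = -xf if self.decreasing else xf
        return 10.0**x if self.log10 else x

    def _fit_counts(self, xf, n_correct, n_total, rng):
        free_lapse = self.lapse is None
        span = np.ptp(xf) or 1.0

        def nll(params):
            theta, slope = params[0], params[1]
            lapse = params[2] if free_lapse else self.lapse
            return _neg_log_likelihood(theta, slope, lapse, xf, n_correct, n_total, self.guess)

        best = None
        lo, hi = xf.min(), xf.max()
        bounds = [(lo - 2 * span, hi + 2 * span), (0.05, 100.0)]
        if free_lapse:
            bounds.append((0.0, self.lapse_max))
        for theta0 in np.linspace(lo, hi, 4):
            for slope0 in (1.0 / span, 4.0 / span):
                x0 = [theta0, slope0] + ([0.02] if free_lapse else [])
                res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
        theta, slope = best.x[0], best.x[1]
        lapse = best.x[2] if free_lapse else self.lapse
        return float(theta), float(slope), float(lapse)

    def fit(self, X, y, sample_weight=None):
        """Fit to binomial data.

        Parameters
        ----------
        X : array-like, shape (n_levels,) or (n_levels, 1)
            Stimulus values on their natural (linear) scale.
        y : array-like
            Proportion correct per level.
        sample_weight : array-like
            Number of trials per level (required; binomial denominators).
        """
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if sample_weight is None:
            raise ValueError("sample_weight (trials per level) is required for a binomial fit")
        n_total = np.asarray(sample_weight, dtype=float).reshape(-1)
        if X.size < 2 or np.unique(X).size < 2:
            raise ValueError("at least two distinct stimulus levels are required")
        n_correct = y * n_total

        rng = np.random.default_rng(self.random_state)
        xf = self._to_fit_scale(X)
        theta, slope, lapse = self._fit_counts(xf, n_correct, n_total, rng)

        self.threshold_fit_ = theta
        self.slope_ = slope
        self.lapse_ = lapse
        self.threshold_ = float(self._from_fit_scale(theta))
        self.extrapolated_ = bool(theta < xf.min() or theta > xf.max())
        self.threshold_ci_ = None
        if self.n_boot > 0:
            p_hat = np.clip(gumbel_psy(xf, theta, slope, self.guess, lapse), 1e-9, 1 - 1e-9)
            thr = np.empty(self.n_boot)
            for b in range(self.n_boot):
                nc = rng.binomial(n_total.astype(int), p_hat)
                tb, _, _ = self._fit_counts(xf, nc, n_total, rng)
                thr[b] = self._from_fit_scale(tb)
            self.threshold_ci_ = tuple(np.quantile(thr, [0.025, 0.975]))
        return self

    def predict(self, X):
        """Predicted proportion correct at stimulus values on the natural scale."""
        check_is_fitted(self, "threshold_fit_")
        xf = self._to_fit_scale(np.asarray(X, dtype=float).reshape(-1))
        return gumbel_psy(xf, self.threshold_fit_, self.slope_, self.guess, self.lapse_)


def fit_gumbel_mle(x, n_correct, n_total, **kwargs) -> GumbelPsychometric:
    """Functional wrapper over :class:`GumbelPsychometric`."""
    n_total = np.asarray(n_total, dtype=float)
    est = GumbelPsychometric(**kwargs)
    return est.fit(np.asarray(x, dtype=float), np.asarray(n_correct, dtype=float) / n_total, n_total)


def fit_gumbel_joint(
    trials: pd.DataFrame,
    level_col: str = "v",
    condition_cols=("amplitude_dva",),
    correct_col: str = "n_correct",
    total_col: str = "n_total",
    guess: float = 0.5,
    lapse_max: float = 0.25,
    decreasing: bool = True,
) -> pd.DataFrame:
    """Joint MLE over conditions with a lapse rate shared across conditions.

    Threshold and slope are free per condition; the lapse rate is a single
    shared parameter in [0, ``lapse_max``] — the per-observer constraint of
    the study design.  Returns one row per condition with columns
    ``threshold`` (original scale), ``slope``, ``lapse``.
    """
    condition_cols = list(condition_cols)
    groups = list(trials.groupby(condition_cols, sort=True))
    k = len(groups)
    if k == 0:
        raise ValueError("no conditions to fit")

    xs, ncs, nts = [], [], []
    helper = GumbelPsychometric(guess=guess, decreasing=decreasing)
    for _, g in groups:
        x = helper._to_fit_scale(g[level_col].to_numpy(dtype=float))
        xs.append(x)
        ncs.append(g[correct_col].to_numpy(dtype=float))
        nts.append(g[total_col].to_numpy(dtype=float))

    def nll(params):
        lapse = params[-1]
        total = 0.0
        for i in range(k):
            total += _neg_log_likelihood(
                params[2 * i], params[2 * i + 1], lapse, xs[i], ncs[i], nts[i], guess
            )
        return total

    x0, bounds = [], []
    for x in xs:
        span = np.ptp(x) or 1.0
        x0 += [float(np.median(x)), 2.0 / span]
        bounds += [(x.min() - 2 * span, x.max() + 2 * span), (0.05, 100.0)]
    x0.append(0.02)
    bounds.append((0.0, lapse_max))
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)

    rows = []
    for i, (key, _) in enumerate(groups):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(condition_cols, key))
            | {
                "threshold": float(helper._from_fit_scale(res.x[2 * i])),
                "slope": float(res.x[2 * i + 1]),
                "lapse": float(res.x[-1]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrasts


@dataclass
class ContrastResult:
    """Orthonormal-contrast decomposition of a threshold profile."""

    kind: str
    names: list
    estimates: np.ndarray
    matrix: np.ndarray
    ci: np.ndarray | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.estimates, index=self.names)


def _orthonormal_poly(n_levels: int) -> np.ndarray:
    """Orthonormal polynomial contrast rows (incl. intercept) for equally
    spaced levels."""
    x = np.arange(n_levels, dtype=float)
    x -= x.mean()
    V = np.vander(x, n_levels, increasing=True)
    Q, _ = np.linalg.qr(V)
    # fix signs so the linear row increases
    for i in range(n_levels):
        pivot = Q[-1, i]
        if pivot < 0:
            Q[:, i] *= -1
    return Q.T


def _orthonormal_helmert(n_levels: int) -> np.ndarray:
    """Orthonormal Helmert rows (incl. intercept): level i vs mean of the
    subsequent levels."""
    rows = [np.ones(n_levels) / np.sqrt(n_levels)]
    for i in range(n_levels - 1):
        row = np.zeros(n_levels)
        row[i] = 1.0
        row[i + 1 :] = -1.0 / (n_levels - 1 - i)
        rows.append(row / np.linalg.norm(row))
    return np.vstack(rows)


_POLY_NAMES = ("intercept", "linear", "quadratic", "cubic", "quartic", "quintic")


def polynomial_contrasts(values, boot_draws=None) -> ContrastResult:
    """Orthonormal polynomial contrasts of a threshold profile.

    ``values`` is one estimate per (equally spaced) level, e.g. thresholds
    over the five movement amplitudes.  ``boot_draws`` (n_draws, n_levels)
    propagates bootstrap uncertainty into per-term percentile CIs.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two levels")
    M = _orthonormal_poly(n)
    names = [_POLY_NAMES[i] if i < len(_POLY_NAMES) else f"poly{i}" for i in range(n)]
    est = M @ values
    ci = None
    if boot_draws is not None:
        draws = np.asarray(boot_draws, dtype=float) @ M.T
        ci = np.quantile(draws, [0.025, 0.975], axis=0).T
    return ContrastResult(kind="polynomial", names=names, estimates=est, matrix=M, ci=ci)


def helmert_contrasts(values, boot_draws=None) -> ContrastResult:
    """Orthonormal Helmert contrasts (each level vs the mean of later levels)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two levels")
    M = _orthonormal_helmert(n)
    names = ["intercept"] + [f"level{i + 1}_vs_rest" for i in range(n - 1)]
    est = M @ values
    ci = None
    if boot_draws is not None:
        draws = np.asarray(boot_draws, dtype=float) @ M.T
        ci = np.quantile(draws, [0.025, 0.975], axis=0).T
    return ContrastResult(kind="helmert", names=names, estimates=est, matrix=M, ci=ci)


# ---------------------------------------------------------------------------
# signal detection


def dprime(hit_rate: float, fa_rate: float, n_signal: int | None = None, n_noise: int | None = None) -> float:
    """Sensitivity ``d' = z(hit) - z(fa)`` with 1/(2N) clipping of 0/1 rates."""
    hit_rate = float(hit_rate)
    fa_rate = float(fa_rate)
    for rate, n, name in ((hit_rate, n_signal, "hit"), (fa_rate, n_noise, "false-alarm")):
        if (rate <= 0.0 or rate >= 1.0) and n is None:
            raise ValueError(f"extreme {name} rate {rate} needs a trial count for clipping")
    if n_signal is not None:
        hit_rate = np.clip(hit_rate, 1.0 / (2 * n_signal), 1.0 - 1.0 / (2 * n_signal))
    if n_noise is not None:
        fa_rate = np.clip(fa_rate, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise))
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


class NakaRushtonSensitivity(BaseEstimator):
    """Saturating Naka-Rushton fit of d' versus stimulus speed.

    With ``direction='decreasing'`` (visibility falling with speed),
    ``d'(v) = d_max * v50**n / (v**n + v50**n)``: the asymptote ``d_max`` is
    approached as v -> 0 and the curve crosses half the asymptote at the
    threshold speed ``v50``.  ``direction='increasing'`` uses the classic
    rising branch ``d_max * v**n / (v**n + v50**n)``.

    Attributes
    ----------
    asymptote_ : float
    threshold_ : float
        Speed at half the asymptotic sensitivity.
    degenerate_ : bool
        Flagged when the data do not constrain a saturating curve (flat d'
        or threshold far outside the sampled speed range).
    """

    def __init__(self, direction: str = "decreasing", exponent: float = 2.0):
        self.direction = direction
        self.exponent = exponent

    def _curve(self, v, d_max, v50):
        n = self.exponent
        if self.direction == "decreasing":
            return d_max * v50**n / (v**n + v50**n)
        return d_max * v**n / (v**n + v50**n)

    def fit(self, X, y):
        v = np.asarray(X, dtype=float).reshape(-1)
        d = np.asarray(y, dtype=float).reshape(-1)
        if v.size < 3:
            raise ValueError("need at least three speed levels")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")
        d_max0 = max(d.max(), 0.1)
        try:
            popt, _ = optimize.curve_fit(
                self._curve,
                v,
                d,
                p0=(d_max0, np.median(v)),
                bounds=((0.0, v.min() / 100.0), (20.0, v.max() * 100.0)),
                maxfev=5000,
            )
        except RuntimeError:
            self.asymptote_, self.threshold_, self.degenerate_ = float("nan"), float("nan"), True
            return self
        self.asymptote_ = float(popt[0])
        self.threshold_ = float(popt[1])
        spread = d.max() - d.min()
        self.degenerate_ = bool(
            spread < 0.2
            or self.threshold_ < v.min() / 10.0
            or self.threshold_ > v.max() * 10.0
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        return self._curve(np.asarray(X, dtype=float).reshape(-1), self.asymptote_, self.threshold_)


def fit_naka_rushton_dprime(speeds, dprimes, **kwargs) -> NakaRushtonSensitivity:
    """Functional wrapper over :class:`NakaRushtonSensitivity`."""
    return NakaRushtonSensitivity(**kwargs).fit(speeds, dprimes)


# ---------------------------------------------------------------------------
# threshold-kinematics covariation

OPPOSITE_DIRECTION = {"left": "right", "right": "left", "up": "down", "down": "up"}


def correlate_thresholds_kinematics(
    thresholds: pd.DataFrame,
    kinematics: pd.DataFrame,
    threshold_col: str = "threshold",
    kinematics_col: str = "value",
    demean: bool = False,
) -> dict:
    """Spearman correlations under retinal and spatial direction matching.

    Both frames need ``observer`` and ``direction`` columns (plus optionally
    ``amplitude_dva``, merged on when present in both).  Retinal matching
    pairs the threshold for motion direction d with the kinematics of
    saccades in the opposite direction (whose retinal motion has direction
    d); spatial matching pairs same with same.  With ``demean=True`` the
    across-observer mean of each variable is removed per condition
    (direction × amplitude cell) before correlating, stripping main effects
    such as the amplitude dependence shared by both variables.

    Returns a dict with ``retinal_rho/p``, ``spatial_rho/p``, ``n`` and the
    merged pair tables.
    """
    keys = ["observer", "direction"]
    extra = [c for c in ("amplitude_dva",) if c in thresholds.columns and c in kinematics.columns]
    keys_full = keys + extra
    for frame, name in ((thresholds, "thresholds"), (kinematics, "kinematics")):
        missing = [k for k in keys if k not in frame.columns]
        if missing:
            raise ValueError(f"{name} frame lacks columns {missing}")

    kin = kinematics[keys_full + [kinematics_col]].copy()
    thr = thresholds[keys_full + [threshold_col]].copy()

    out = {}
    pairs = {}
    for label, mapper in (("spatial", lambda d: d), ("retinal", lambda d: OPPOSITE_DIRECTION[d])):
        k = kin.copy()
        k["direction"] = k["direction"].map(mapper)
        merged = thr.merge(k, on=keys_full, how="inner", validate="one_to_one")
        if len(merged) < 3:
            raise ValueError(f"fewer than 3 matched pairs for {label} matching")
        if len(merged) < len(thr):
            raise ValueError(f"unmatched observer/direction keys under {label} matching")
        tv = merged[threshold_col]
        kv = merged[kinematics_col]
        if demean:
            cell = ["direction"] + extra
            merged["_t"] = merged[threshold_col] - merged.groupby(cell)[threshold_col].transform("mean")
            merged["_k"] = merged[kinematics_col] - merged.groupby(cell)[kinematics_col].transform("mean")
            tv, kv = merged["_t"], merged["_k"]
        rho, p = stats.spearmanr(tv, kv)
        out[f"{label}_rho"] = float(rho)
        out[f"{label}_p"] = float(p)
        pairs[label] = merged
    out["n"] = len(pairs["retinal"])
    out["pairs"] = pairs
    return out


def compare_regressions_bf(y, x_retinal, x_spatial) -> dict:
    """OLS comparison of the retinal- vs spatial-matched predictor.

    Fits ``y ~ x`` for each predictor and compares them through
    ``delta_bic = BIC(retinal) - BIC(spatial)`` and the Bayes factor
    ``BF = exp(-delta_bic / 2)``: BF > 1 favors the retinal-matched model.

    Returns a dict with per-model R², slope, SE, t, p, plus ``delta_bic``
    and ``bf``.
    """
    y = np.asarray(y, dtype=float)
    out = {}
    bics = {}
    for label, x in (("retinal", x_retinal), ("spatial", x_spatial)):
        x = np.asarray(x, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError("each regression needs >= 3 matched points")
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate (constant) {label} predictor")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out[label] = {
            "r2": float(model.rsquared),
            "beta": float(model.params[1]),
            "se": float(model.bse[1]),
            "t": float(model.tvalues[1]),
            "p": float(model.pvalues[1]),
            "bic": float(model.bic),
        }
        bics[label] = float(model.bic)
    delta = bics["retinal"] - bics["spatial"]
    out["delta_bic"] = delta
    out["bf"] = float(np.exp(-delta / 2.0))
    return out
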