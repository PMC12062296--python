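"""Gumbel fitting, contrasts, d', Naka-Rushton thresholds, correlations, BF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saccvis import (
    GumbelPsychometric,
    MainSequence,
    NakaRushtonSensitivity,
    compare_regressions_bf,
    correlate_thresholds_kinematics,
    dprime,
    fit_gumbel_joint,
    gumbel_psy,
    helmert_contrasts,
    polynomial_contrasts,
    threshold_performance,
)


class TestGumbelFunction:
    def test_threshold_identities(self):
        # 2AFC, no lapses: 81.6% correct at threshold
        assert gumbel_psy(0.0, 0.0, 2.0, 0.5, 0.0) == pytest.approx(0.8161, abs=5e-4)
        assert threshold_performance(0.5, 0.0) == pytest.approx(0.8161, abs=5e-4)
        # threshold sits at 1 - 1/e = 63.21% of the range
        frac = (threshold_performance(0.5, 0.0) - 0.5) / 0.5
        assert frac == pytest.approx(1 - np.exp(-1), abs=1e-9)
        assert threshold_performance(0.5, 0.02) == pytest.approx(0.8034, abs=5e-4)

    def test_asymptotes(self):
        assert gumbel_psy(-50.0, 0.0, 2.0, 0.5, 0.1) == pytest.approx(0.5)
        assert gumbel_psy(50.0, 0.0, 2.0, 0.5, 0.1) == pytest.approx(0.9)


def _simulate_trials(rng, theta_speed, beta, speeds, n_trials, lapse=0.0):
    p = gumbel_psy(-np.log10(speeds), -np.log10(theta_speed), beta, 0.5, lapse)
    return rng.binomial(n_trials, p)


class TestGumbelFit:
    def test_recovery_on_synthetic_observer(self, rng):
        speeds = np.array([50.0, 80.0, 120.0, 180.0, 260.0, 380.0])
        n = 200
        correct = _simulate_trials(rng, 150.0, 6.0, speeds, n)
        est = GumbelPsychometric(lapse=0.0, decreasing=True).fit(
            speeds, correct / n, sample_weight=np.full(speeds.size, n)
        )
        assert est.threshold_ == pytest.approx(150.0, rel=0.08)
        assert not est.extrapolated_

    def test_sign_inversion_round_trip(self):
        """Fitting -log10(v) reports the threshold back on the speed scale."""
        est = GumbelPsychometric(lapse=0.0, decreasing=True)
        xf = est._to_fit_scale(np.array([100.0]))
        assert xf[0] == pytest.approx(-2.0)
        assert est._from_fit_scale(xf[0]) == pytest.approx(100.0)

    def test_predict_matches_generating_curve(self, rng):
        speeds = np.geomspace(40, 400, 7)
        n = 400
        correct = _simulate_trials(rng, 120.0, 5.0, speeds, n)
        est = GumbelPsychometric(lapse=0.0).fit(speeds, correct / n, np.full(7, n))
        p_true = gumbel_psy(-np.log10(speeds), -np.log10(120.0), 5.0, 0.5, 0.0)
        assert np.max(np.abs(est.predict(speeds) - p_true)) < 0.05

    def test_chance_data_flagged_extrapolated(self, rng):
        speeds = np.geomspace(40, 400, 5)
        n = 60
        correct = rng.binomial(n, 0.5, size=5)
        est = GumbelPsychometric(lapse=0.0).fit(speeds, correct / n, np.full(5, n))
        assert est.extrapolated_

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            GumbelPsychometric().fit([100.0, 100.0], [0.8, 0.9], [50, 50])

    def test_bootstrap_ci_brackets_threshold(self, rng):
        speeds = np.geomspace(50, 350, 6)
        n = 150
        correct = _simulate_trials(rng, 140.0, 6.0, speeds, n)
        est = GumbelPsychometric(lapse=0.0, n_boot=80, random_state=3).fit(
            speeds, correct / n, np.full(6, n)
        )
        lo, hi = est.threshold_ci_
        assert lo < est.threshold_ < hi
        assert lo < 140.0 < hi

    def test_joint_fit_shares_lapse(self, rng):
        rows = []
        for a, theta in ((4.0, 100.0), (8.0, 150.0)):
            speeds = np.geomspace(40, 400, 6)
            correct = _simulate_trials(rng, theta, 6.0, speeds, 150, lapse=0.05)
            for v, nc in zip(speeds, correct):
                rows.append(
                    {"amplitude_dva": a, "v": v, "n_correct": int(nc), "n_total": 150}
                )
        fits = fit_gumbel_joint(pd.DataFrame(rows))
        assert len(fits) == 2
        assert fits["lapse"].nunique() == 1  # shared across conditions
        thetas = fits.sort_values("amplitude_dva")["threshold"].to_numpy()
        assert thetas[0] == pytest.approx(100.0, rel=0.15)
        assert thetas[1] == pytest.approx(150.0, rel=0.15)


class TestContrasts:
    def test_constant_profile_loads_only_on_intercept(self):
        res = polynomial_contrasts(np.full(5, 3.0))
        assert res.estimates[0] != 0
        np.testing.assert_allclose(res.estimates[1:], 0.0, atol=1e-12)
        res_h = helmert_contrasts(np.full(4, 3.0))
        np.testing.assert_allclose(res_h.estimates[1:], 0.0, atol=1e-12)

    def test_linear_profile_loads_only_on_linear_term(self):
        res = polynomial_contrasts(2.0 + 0.5 * np.arange(5))
        assert res.estimates[1] > 0
        np.testing.assert_allclose(res.estimates[2:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("fn, n", [(polynomial_contrasts, 5), (helmert_contrasts, 4)])
    def test_contrast_rows_orthonormal(self, fn, n):
        M = fn(np.zeros(n)).matrix
        np.testing.assert_allclose(M @ M.T, np.eye(n), atol=1e-12)

    def test_helmert_compares_level_to_later_mean(self):
        vals = np.array([10.0, 2.0, 2.0, 2.0])
        res = helmert_contrasts(vals)
        # first contrast: level 1 vs mean of the rest, positive here
        assert res.estimates[1] > 0
        np.testing.assert_allclose(res.estimates[2:], 0.0, atol=1e-12)

    def test_bootstrap_ci_propagation(self, rng):
        draws = rng.normal(loc=[1.0, 2.0, 3.0, 4.0, 5.0], scale=0.1, size=(500, 5))
        res = polynomial_contrasts(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), boot_draws=draws)
        assert res.ci.shape == (5, 2)
        assert res.ci[1, 0] < res.estimates[1] < res.ci[1, 1]

    def test_wrong_level_count(self):
        with pytest.raises(ValueError):
            polynomial_contrasts([1.0])


class TestDprime:
    def test_values(self):
        assert dprime(0.6, 0.6) == pytest.approx(0.0)
        assert dprime(0.841, 0.159) == pytest.approx(2.0, abs=0.01)

    def test_monotone_in_hit_rate(self):
        hits = np.linspace(0.1, 0.9, 9)
        ds = [dprime(h, 0.2) for h in hits]
        assert np.all(np.diff(ds) > 0)

    def test_extreme_rates_clipped_or_rejected(self):
        with pytest.raises(ValueError, match="trial count"):
            dprime(1.0, 0.2)
        d = dprime(1.0, 0.2, n_signal=50)
        assert d == pytest.approx(stats.norm.ppf(1 - 1 / 100) - stats.norm.ppf(0.2))


class TestNakaRushtonSensitivity:
    def test_half_asymptote_recovery(self, rng):
        v = np.geomspace(40, 500, 8)
        true = 2.8 * 150.0**2 / (v**2 + 150.0**2)
        est = NakaRushtonSensitivity().fit(v, true + rng.normal(0, 0.08, v.size))
        assert est.threshold_ == pytest.approx(150.0, rel=0.1)
        assert est.asymptote_ == pytest.approx(2.8, rel=0.1)
        assert not est.degenerate_

    def test_fitted_curve_halves_at_threshold(self, rng):
        v = np.geomspace(40, 500, 8)
        d = 2.0 * 120.0**2 / (v**2 + 120.0**2) + rng.normal(0, 0.05, v.size)
        est = NakaRushtonSensitivity().fit(v, d)
        assert est.predict([est.threshold_])[0] == pytest.approx(est.asymptote_ / 2, rel=1e-6)

    def test_flat_sensitivity_flagged_degenerate(self):
        v = np.geomspace(40, 500, 6)
        est = NakaRushtonSensitivity().fit(v, np.full(6, 1.5))
        assert est.degenerate_

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            NakaRushtonSensitivity().fit([1.0, 2.0], [1.0, 0.5])


def _threshold_kinematics_frames(asymmetry, rng=None, n_obs=8, noise=0.0):
    """Thresholds generated from opposite-direction peak velocities."""
    rng = np.random.default_rng(rng)
    thr_rows, kin_rows = [], []
    for o in range(n_obs):
        vps = {}
        for d in ("left", "right", "up", "down"):
            c = 1.64 * (1 + asymmetry * rng.standard_normal()) + 0.3 * rng.standard_normal()
            vps[d] = MainSequence(c=max(c, 0.5)).peak_velocity(8.0)
        for d, opp in (("left", "right"), ("right", "left"), ("up", "down"), ("down", "up")):
            thr = 0.53 * vps[opp] + noise * rng.standard_normal()
            thr_rows.append({"observer": f"o{o}", "direction": d, "threshold": thr})
            kin_rows.append({"observer": f"o{o}", "direction": d, "value": vps[d]})
    return pd.DataFrame(thr_rows), pd.DataFrame(kin_rows)


class TestThresholdKinematicsCorrelation:
    def test_retinal_matching_is_perfect_by_construction(self):
        thr, kin = _threshold_kinematics_frames(asymmetry=0.2, rng=1)
        res = correlate_thresholds_kinematics(thr, kin)
        assert res["retinal_rho"] == pytest.approx(1.0)
        assert res["spatial_rho"] < 1.0

    def test_independent_variables_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 200
        rows_t, rows_k = [], []
        for i in range(n):
            for d in ("left", "right"):
                rows_t.append({"observer": f"o{i}", "direction": d, "threshold": rng.normal()})
                rows_k.append({"observer": f"o{i}", "direction": d, "value": rng.normal()})
        res = correlate_thresholds_kinematics(pd.DataFrame(rows_t), pd.DataFrame(rows_k))
        assert abs(res["retinal_rho"]) < 0.12
        assert abs(res["spatial_rho"]) < 0.12

    def test_demeaning_removes_shared_amplitude_effect(self):
        """A pure amplitude main effect correlates both variables; demeaning
        strips it."""
        rng = np.random.default_rng(3)
        rows_t, rows_k = [], []
        for o in range(12):
            for a in (4.0, 8.0, 12.0):
                for d in ("left", "right"):
                    base = {"observer": f"o{o}", "direction": d, "amplitude_dva": a}
                    rows_t.append(base | {"threshold": 10 * a + rng.normal()})
                    rows_k.append(base | {"value": 5 * a + rng.normal()})
        thr, kin = pd.DataFrame(rows_t), pd.DataFrame(rows_k)
        raw = correlate_thresholds_kinematics(thr, kin)
        dem = correlate_thresholds_kinematics(thr, kin, demean=True)
        # amplitude drives both variables; within-amplitude ranks are noise,
        # so the raw correlation is high but bounded below 1
        assert raw["retinal_rho"] > 0.8
        assert abs(dem["retinal_rho"]) < 0.15

    def test_demeaned_rho_stable_under_common_main_effect(self):
        thr, kin = _threshold_kinematics_frames(asymmetry=0.15, rng=4, n_obs=16, noise=5.0)
        base = correlate_thresholds_kinematics(thr, kin, demean=True)["retinal_rho"]
        thr2 = thr.copy()
        kin2 = kin.copy()
        bump = thr2["direction"].map({"left": 40.0, "right": 40.0, "up": -40.0, "down": -40.0})
        thr2["threshold"] = thr2["threshold"] + bump
        kin2["value"] = kin2["value"] + bump
        shifted = correlate_thresholds_kinematics(thr2, kin2, demean=True)["retinal_rho"]
        assert shifted == pytest.approx(base, abs=0.02)

    def test_unmatched_keys_error(self):
        thr, kin = _threshold_kinematics_frames(asymmetry=0.2, rng=5)
        with pytest.raises(ValueError, match="nmatched"):
            correlate_thresholds_kinematics(thr, kin.iloc[:-3])


class TestRegressionBayesFactor:
    def test_identical_predictors_give_bf_one(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        res = compare_regressions_bf(y, x, x)
        assert res["delta_bic"] == pytest.approx(0.0, abs=1e-9)
        assert res["bf"] == pytest.approx(1.0, abs=1e-9)

    def test_published_bf_convention(self):
        """delta BIC of -58.82 converts to a Bayes factor of 5.9e12."""
        bf = np.exp(-(-58.82) / 2.0)
        assert bf == pytest.approx(5.9e12, rel=0.01)

    def test_better_predictor_wins(self, rng):
        x_good = rng.normal(size=60)
        x_bad = rng.normal(size=60)
        y = x_good + 0.3 * rng.normal(size=60)
        res = compare_regressions_bf(y, x_good, x_bad)
        assert res["delta_bic"] < 0
        assert res["bf"] > 1
        assert res["retinal"]["r2"] > res["spatial"]["r2"]

    def test_degenerate_predictor_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="degenerate"):
            compare_regressions_bf(y, np.ones(10), rng.normal(size=10))
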