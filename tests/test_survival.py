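"""Survival engine: KM, log-rank, Cox, Weibull, IPCW time-dependent AUC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import gardkit as gk
from gardkit.survival import censoring_km, weibull_from_survival_points


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = gk.km_estimate([3, 5, 8, 2, 9], [0, 0, 0, 0, 0])
        for t in (0.0, 4.0, 9.0):
            assert km.survival_at(t) == 1.0

    def test_uncensored_equals_empirical_survival(self):
        km = gk.km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        # censored at 1 and 3, events at 2 and 4: S(2) = 1 - 1/3, S(4) = 0
        km = gk.km_estimate([1, 2, 3, 4], [0, 1, 0, 1])
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(4) == pytest.approx(0.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        km = gk.km_estimate(rng.exponential(10, 200), rng.integers(0, 2, 200))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gk.km_estimate([-1, 2], [1, 1])

    def test_extrapolation_flagged(self):
        km = gk.km_estimate([1, 2], [1, 0])
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            km.survival_at(99.0)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 3, 5, 7], [1, 0, 1, 0]
        res = gk.logrank_statistic(t, e, t, e)
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # A events at 1,2; B events at 3,4: O_A=2, E_A=5/6, V=17/36
        res = gk.logrank_statistic([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.observed_a == pytest.approx(2.0)
        assert res.expected_a == pytest.approx(5 / 6)
        assert res.variance == pytest.approx(17 / 36)
        assert res.z == pytest.approx((2 - 5 / 6) / np.sqrt(17 / 36), abs=1e-12)

    def test_chi2_matches_lifelines_oracle(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(10, 40), rng.exponential(14, 35)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        res = gk.logrank_statistic(ta, ea, tb, eb)
        ll = logrank_test(ta, tb, ea, eb)
        assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ll.p_value, rel=1e-9)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(5, 20), rng.exponential(9, 25)
        r1 = gk.logrank_statistic(ta, np.ones(20, int), tb, np.ones(25, int))
        r2 = gk.logrank_statistic(tb, np.ones(25, int), ta, np.ones(20, int))
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)

    def test_time_rescaling_invariance(self):
        ta, tb = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        r1 = gk.logrank_statistic(ta, [1, 1, 0], tb, [1, 0, 1])
        r2 = gk.logrank_statistic(np.array(ta) * 7, [1, 1, 0], np.array(tb) * 7, [1, 0, 1])
        assert r1.z == pytest.approx(r2.z)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            gk.logrank_statistic([1, 2], [0, 0], [3, 4], [0, 0])


def _neg_log_partial_likelihood(beta, t, e, x):
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    ll = 0.0
    for i in range(t.size):
        if e[i]:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


class TestCox:
    def test_coefficient_matches_grid_oracle(self):
        # 5-record fixture, no ties: Efron == Breslow == plain partial likelihood
        t = np.array([2.0, 4.0, 5.0, 7.0, 11.0])
        e = np.array([1, 1, 0, 1, 1])
        x = np.array([0.2, -0.3, 0.8, 1.1, -0.6])
        df = pd.DataFrame({"time_months": t, "event": e, "x": x})
        fit = gk.fit_cox(df, ["x"])
        oracle = optimize.minimize_scalar(
            _neg_log_partial_likelihood, bounds=(-5, 5), args=(t, e, x), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-4)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(50, n),
                "event": np.ones(n, int),
                "x": rng.normal(size=n),
            }
        )
        fit = gk.fit_cox(df, ["x"])
        assert abs(fit.coefficients["x"]) < 0.05

    def test_binary_covariate_agrees_with_logrank_direction(self):
        rng = np.random.default_rng(2)
        t_good = rng.exponential(30, 80)
        t_bad = rng.exponential(10, 80)
        df = pd.DataFrame(
            {
                "time_months": np.r_[t_good, t_bad],
                "event": np.ones(160, int),
                "grp": np.r_[np.zeros(80), np.ones(80)],
            }
        )
        fit = gk.fit_cox(df, ["grp"])
        assert fit.hazard_ratios["grp"] > 1  # group 1 has worse survival
        assert fit.ci_lower["grp"] < fit.hazard_ratios["grp"] < fit.ci_upper["grp"]

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0], "x": [0.1, 0.5]})
        with pytest.raises(ValueError, match="event"):
            gk.fit_cox(df, ["x"])


class TestWeibull:
    def test_exponential_special_case_recovery(self):
        rng = np.random.default_rng(9)
        ev = rng.exponential(100, 500)
        cens = rng.uniform(0, 400, 500)
        t, e = np.minimum(ev, cens), (ev <= cens).astype(int)
        fit = gk.fit_weibull(t, e)
        assert 0.85 < fit.shape < 1.15
        assert fit.scale == pytest.approx(100, rel=0.2)

    def test_median_identity(self):
        m = gk.WeibullModel(shape=1.0, scale=100.0)
        assert m.survival_at(100 * np.log(2)) == pytest.approx(0.5)
        assert m.median == pytest.approx(100 * np.log(2))

    def test_closed_form_value(self):
        m = gk.WeibullModel(shape=2.0, scale=50.0)
        assert m.survival_at(50.0) == pytest.approx(np.exp(-1))

    def test_curve_fit_agrees_with_mle(self):
        rng = np.random.default_rng(10)
        t = 80.0 * rng.weibull(1.5, 2000)
        e = np.ones(2000, int)
        mle = gk.fit_weibull(t, e, method="mle")
        lsq = gk.fit_weibull(t, e, method="km-curve-fit")
        assert lsq.shape == pytest.approx(mle.shape, rel=0.05)
        assert lsq.scale == pytest.approx(mle.scale, rel=0.05)

    def test_zero_events_degenerate_plateau(self):
        fit = gk.fit_weibull([10, 20, 30], [0, 0, 0])
        assert fit.degenerate
        assert fit.survival_at(25.0) == 1.0

    def test_zero_events_pseudo_event_fallback(self):
        fit = gk.fit_weibull([10, 20, 30], [0, 0, 0], pseudo_event_fallback=True)
        assert not fit.degenerate
        assert fit.n_events == 1

    def test_two_point_solution_exact(self):
        m = weibull_from_survival_points(36.0, 0.9, 60.0, 0.8)
        assert m.survival_at(36.0) == pytest.approx(0.9, abs=1e-12)
        assert m.survival_at(60.0) == pytest.approx(0.8, abs=1e-12)


class TestTdAucIpcw:
    def test_perfect_marker_no_censoring(self):
        n = 50
        t = np.arange(1.0, n + 1)
        df = pd.DataFrame({"time_months": t, "event": np.ones(n, int), "risk": -t})
        assert gk.td_auc_ipcw(df, "risk", horizon=25.5) == 1.0

    def test_reduces_to_pair_count_oracle_without_censoring(self):
        rng = np.random.default_rng(12)
        n = 120
        t = rng.exponential(20, n)
        m = rng.normal(size=n)
        df = pd.DataFrame({"time_months": t, "event": np.ones(n, int), "m": m})
        horizon = float(np.median(t))
        auc = gk.td_auc_ipcw(df, "m", horizon)
        case, ctrl = t <= horizon, t > horizon
        mc, mk = m[case], m[ctrl]
        pairs = (mc[:, None] > mk[None, :]).mean() + 0.5 * (mc[:, None] == mk[None, :]).mean()
        assert auc == pytest.approx(pairs, abs=1e-12)

    def test_independent_marker_null_window(self):
        rng = np.random.default_rng(13)
        n = 1000
        ev = rng.exponential(40, n)
        cens = rng.uniform(10, 80, n)
        df = pd.DataFrame(
            {
                "time_months": np.minimum(ev, cens),
                "event": (ev <= cens).astype(int),
                "m": rng.normal(size=n),
            }
        )
        assert 0.45 < gk.td_auc_ipcw(df, "m", 36.0) < 0.55

    def test_matches_scikit_survival_uno_estimator(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(14)
        n = 300
        ev = rng.weibull(1.3, n) * 60
        cens = rng.uniform(20, 90, n)
        t, e = np.minimum(ev, cens), ev <= cens
        m = -ev + rng.normal(0, 20, n)  # informative marker
        df = pd.DataFrame({"time_months": t, "event": e.astype(int), "m": m})
        y = Surv.from_arrays(event=e, time=t)
        auc_ref, _ = cumulative_dynamic_auc(y, y, m, [36.0])
        assert gk.td_auc_ipcw(df, "m", 36.0) == pytest.approx(auc_ref[0], abs=1e-6)

    def test_horizon_outside_followup_rejected(self):
        df = pd.DataFrame({"time_months": [5.0, 8.0], "event": [1, 0], "m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="horizon"):
            gk.td_auc_ipcw(df, "m", 50.0)


class TestSurvivalAt:
    def test_km_step_function_with_ci(self):
        km = gk.km_estimate([1, 2, 3, 4], [0, 1, 0, 1])
        value, (lo, hi) = gk.survival_at(km, 2.5)
        assert value == pytest.approx(2 / 3)
        assert lo <= value <= hi

    def test_weibull_closed_form(self):
        assert gk.survival_at(gk.WeibullModel(2.0, 50.0), 50.0) == pytest.approx(np.exp(-1))

    def test_censoring_km_flips_indicator(self):
        G = censoring_km([1, 2, 3], [1, 1, 0])
        assert G.survival_at(3) == pytest.approx(0.0)  # the one censoring "event"
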