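"""Smoothed bootstrap, mixture prediction and the three in silico trial designs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gardkit as gk
from gardkit.trials import nrd0_bandwidth


class TestSmoothedBootstrap:
    def test_zero_bandwidth_is_plain_bootstrap(self):
        src = np.array([0.2, 0.3, 0.4, 0.5])
        out = gk.smoothed_bootstrap_rsi(src, 500, bandwidth=0.0, rng=1)
        assert set(np.round(out, 12)) <= set(np.round(src, 12))

    def test_single_source_value_degenerate_error(self):
        with pytest.raises(ValueError):
            gk.smoothed_bootstrap_rsi([0.3], 10, bandwidth="nrd0", rng=0)

    def test_nrd0_matches_silverman_formula(self):
        rng = np.random.default_rng(30)
        x = rng.normal(0.4, 0.1, 200)
        sd = np.std(x, ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 200 ** (-0.2)
        assert nrd0_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_large_sample_matches_kernel_density(self, rsi_source):
        out = gk.smoothed_bootstrap_rsi(rsi_source, 50_000, rng=31)
        se = np.std(rsi_source) / np.sqrt(len(out)) * np.sqrt(1 + 1)  # conservative
        assert abs(out.mean() - rsi_source.mean()) < 3 * max(se, 1e-3)
        # KS distance between the draws and the Gaussian-KDE mixture CDF
        bw = nrd0_bandwidth(rsi_source)
        grid = np.sort(out)
        kde_cdf = stats.norm.cdf(
            (grid[:, None] - rsi_source[None, :]) / bw
        ).mean(axis=1)
        emp = np.arange(1, grid.size + 1) / grid.size
        assert np.max(np.abs(emp - kde_cdf)) < 0.02

    def test_reproducible_under_seed(self):
        src = np.linspace(0.2, 0.6, 50)
        a = gk.smoothed_bootstrap_rsi(src, 100, rng=7)
        b = gk.smoothed_bootstrap_rsi(src, 100, rng=7)
        assert np.array_equal(a, b)


class TestMixturePrediction:
    def test_pure_high_equals_component(self, group_models):
        t = np.linspace(0, 60, 61)
        s = gk.predict_survival_mixture(group_models, {"low": 0.0, "high": 1.0}, t)
        assert np.allclose(s, group_models["high"].survival(t))

    def test_fifty_fifty_arithmetic(self):
        models = {
            "low": gk.weibull_from_survival_points(36, 0.90, 60, 0.80),
            "high": gk.weibull_from_survival_points(36, 0.9999, 60, 0.9998),
        }
        s = gk.predict_survival_mixture(models, {"low": 0.5, "high": 0.5}, [36.0])
        assert s[0] == pytest.approx(0.5 * 0.90 + 0.5 * 0.9999, abs=1e-4)

    def test_mixture_bounded_by_components(self, group_models):
        rng = np.random.default_rng(33)
        for _ in range(20):
            p = rng.uniform()
            t = rng.uniform(0, 60, 5)
            s = gk.predict_survival_mixture(group_models, {"low": p, "high": 1 - p}, t)
            lo = np.minimum(group_models["low"].survival(t), group_models["high"].survival(t))
            hi = np.maximum(group_models["low"].survival(t), group_models["high"].survival(t))
            assert np.all((s >= lo - 1e-12) & (s <= hi + 1e-12))

    def test_bad_proportions_rejected(self, group_models):
        with pytest.raises(ValueError, match="sum to 1"):
            gk.predict_survival_mixture(group_models, {"low": 0.6, "high": 0.6}, [10.0])


class TestUnselectedTrial:
    def test_identical_arms_no_difference(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(
            experimental_schedule=gk.STANDARD_SCHEDULE, replicates=20, seed=40
        )
        ts = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        diff = ts.arms["control"].os36_mean - ts.arms["experimental"].os36_mean
        se = ts.arms["control"].os36_replicates.std(ddof=1) / np.sqrt(20)
        assert abs(diff) < 2 * max(se, 1e-4) + 1e-3

    def test_deescalated_arm_has_lower_os(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=30, seed=41)
        ts = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        assert ts.arms["experimental"].os36_mean < ts.arms["control"].os36_mean
        # per-replicate arm comparison holds in nearly all replicates
        worse = (
            ts.arms["experimental"].os36_replicates < ts.arms["control"].os36_replicates
        ).mean()
        assert worse >= 0.95

    def test_high_group_shrinks_under_deescalation(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=20, seed=42)
        ts = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        assert ts.arms["experimental"].mean_n_high < ts.arms["control"].mean_n_high

    def test_group_counts_sum_to_arm_size(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=5, seed=43)
        ts = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        for arm in ts.arms.values():
            assert arm.mean_n_low + arm.mean_n_high == pytest.approx(200)

    def test_bit_for_bit_reproducible(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=5, seed=44)
        a = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        b = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        assert np.array_equal(a.arms["control"].os36_replicates, b.arms["control"].os36_replicates)
        assert np.array_equal(a.arms["control"].mean_curve, b.arms["control"].mean_curve)


class TestSelectedTrial:
    def test_unreachable_cut_means_no_deescalation(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(gard_cutpoint=1e6, replicates=5, seed=45)
        ts = gk.run_gard_selected_trial(spec, rsi_source, group_models)
        assert ts.eligibility_fraction == 0.0
        # nobody de-escalated: every patient is GARD-low at this cut, arms identical
        assert ts.arms["experimental"].os36_mean == pytest.approx(
            ts.arms["control"].os36_mean, abs=1e-9
        )

    def test_arm_survival_equal_within_noise(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=30, seed=46)
        ts = gk.run_gard_selected_trial(spec, rsi_source, group_models)
        diff = abs(ts.arms["control"].os36_mean - ts.arms["experimental"].os36_mean)
        se = ts.arms["control"].os36_replicates.std(ddof=1) / np.sqrt(30)
        assert diff < 3 * max(se, 1e-4)

    def test_eligibility_matches_source_tail_probability(
        self, rsi_source, group_models, gard_fit
    ):
        spec = gk.TrialDesignSpec(replicates=30, seed=47)
        ts = gk.run_gard_selected_trial(spec, rsi_source, group_models)
        # eligibility = P(GARD60 >= 42) = P(GARD70 >= 49) under the source KDE;
        # compare against the generating distribution's tail with MC slack
        p = float(gard_fit.sf(49.0))
        se = np.sqrt(p * (1 - p) / (30 * 200))
        assert abs(ts.eligibility_fraction - p) < 4 * se + 0.02

    def test_selected_beats_unselected_experimental_arm(self, rsi_source, group_models):
        spec = gk.TrialDesignSpec(replicates=30, seed=48)
        unsel = gk.run_unselected_deescalation_trial(spec, rsi_source, group_models)
        sel = gk.run_gard_selected_trial(spec, rsi_source, group_models)
        better = (
            sel.arms["experimental"].os36_replicates
            >= unsel.arms["experimental"].os36_replicates
        ).mean()
        assert better >= 0.95


class TestPersonalizedTrial:
    def test_patient_at_target_has_zero_delta(self):
        alpha = gk.alpha_g_from_gard(32.0, gk.STANDARD_SCHEDULE)
        df = pd.DataFrame(
            {
                "patient_id": ["P0"],
                "rsi": [gk.rsi_from_alpha_g(alpha)],
                "n_fractions": [35],
                "dose_per_fraction": [2.0],
                "time_months": [50.0],
                "event": [0],
            }
        )
        _, rx = gk.run_personalized_iso_gard(df, target_gard=32.0)
        assert rx["dose_delta"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert rx["required_dose"].iloc[0] == pytest.approx(70.0, abs=1e-9)

    def test_calibrated_cohort_spares_dose_on_average(self, synthetic_cohort_600):
        summary, rx = gk.run_personalized_iso_gard(synthetic_cohort_600, target_gard=32.0)
        assert summary.extras["mean_fraction_delta"] > 0
        # a nontrivial minority needs more than 60 Gy
        frac_above_60 = (rx["required_dose"] > 60.0).mean()
        assert 0.05 < frac_above_60 < 0.60

    def test_unreachable_patients_reported_not_fatal(self):
        # rsi = 1 gives alpha_g = -0.1, so alpha_g + beta*d = 0: no finite dose
        df = pd.DataFrame(
            {
                "patient_id": ["P0", "P1"],
                "rsi": [1.0, 0.3],
                "n_fractions": [35, 35],
                "dose_per_fraction": [2.0, 2.0],
                "time_months": [50.0, 40.0],
                "event": [0, 1],
            }
        )
        with pytest.warns(RuntimeWarning):
            summary, rx = gk.run_personalized_iso_gard(df, target_gard=32.0)
        assert summary.extras["n_unreachable"] == 1
        assert rx["unreachable"].iloc[0] != ""
        assert np.isfinite(rx["required_dose"].iloc[1])


class TestEquipoiseThreshold:
    def test_independent_marker_returns_smallest_grid_value(self):
        rng = np.random.default_rng(50)
        n = 200
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(100, n).clip(max=60),
                "event": rng.integers(0, 2, n),
                "gard": rng.uniform(20, 70, n),
            }
        )
        g, n_sub = gk.find_equipoise_threshold(df)
        assert g == pytest.approx(df["gard"].min())
        assert n_sub == n

    def test_subgroup_survival_self_consistency(self, synthetic_cohort_600):
        g, n_sub = gk.find_equipoise_threshold(synthetic_cohort_600, horizon=36.0)
        km_all = gk.km_estimate(
            synthetic_cohort_600["time_months"], synthetic_cohort_600["event"]
        )
        sub = synthetic_cohort_600[synthetic_cohort_600["gard"] >= g]
        km_sub = gk.km_estimate(sub["time_months"], sub["event"])
        assert km_sub.survival_at(36.0, warn_extrapolation=False) >= km_all.survival_at(
            36.0, warn_extrapolation=False
        )
        assert n_sub == sub.shape[0]

    def test_proper_subgroup_option_excludes_whole_cohort(self, synthetic_cohort_600):
        g, n_sub = gk.find_equipoise_threshold(
            synthetic_cohort_600, horizon=36.0, proper_subgroup=True
        )
        assert n_sub < synthetic_cohort_600.shape[0]
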